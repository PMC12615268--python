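"""Volume containers, axis conventions and file I/O.

Conventions used throughout the package
---------------------------------------
* Canonical axis order for 3D arrays is ``(z, y, x)``.
* An *orthoview* names a slicing direction:

  - ``"xy"``: slices along z; each slice has in-plane axes (y, x).
  - ``"xz"``: slices along y; each slice has in-plane axes (z, x).
  - ``"yz"``: slices along x; each slice has in-plane axes (z, y).

* Coordinates are 0-based voxel indices; a voxel is the unit cube at its
  index.
* Gradient fields are stored component-first: a 3D field has shape
  ``(3, Z, Y, X)`` with components ordered (z, y, x); a per-slice 2D field
  has shape ``(2, H, W)`` with components ordered as the slice's in-plane
  axes (axis 0, axis 1).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi

VIEWS = ("xy", "xz", "yz")

#: slicing axis (in canonical z,y,x order) for each view
VIEW_SLICE_AXIS = {"xy": 0, "xz": 1, "yz": 2}

#: the two canonical 3D axes spanned by a slice of each view, in slice
#: (axis0, axis1) order
VIEW_INPLANE_AXES = {"xy": (1, 2), "xz": (0, 2), "yz": (0, 1)}


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid with physical voxel spacing (z, y, x)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("not a 3D volume")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclasses.dataclass
class LabelVolume:
    """A 3D non-negative integer instance labeling; 0 is background."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("not a 3D volume")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must be integer typed")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


class OrthoViewSet:
    """Per-view stacks of 2D slices (labels, probabilities or gradients).

    Parameters
    ----------
    views
        Mapping from view name to a stack array.  Label/probability stacks
        have shape ``(n_slices, H, W)``; gradient stacks have shape
        ``(n_slices, 2, H, W)`` (component-first per slice).
    kind
        One of ``{"label", "probability", "gradient"}``.
    """

    def __init__(self, views: dict[str, np.ndarray], kind: str = "label"):
        if not views:
            raise ValueError("at least one view required")
        for name in views:
            if name not in VIEWS:
                raise ValueError(f"unknown view {name!r}")
        if kind not in ("label", "probability", "gradient"):
            raise ValueError(f"unknown stack kind {kind!r}")
        self.views = {k: np.asarray(v) for k, v in views.items()}
        self.kind = kind
        shapes = {self.volume_shape(v) for v in self.views}
        if len(shapes) != 1:
            raise ValueError("views disagree on the implied 3D shape")

    def volume_shape(self, view: str) -> tuple[int, int, int]:
        """(z, y, x) shape of the 3D volume implied by one view's stack."""
        stack = self.views[view]
        n = stack.shape[0]
        h, w = stack.shape[-2:]
        if view == "xy":
            return (n, h, w)
        if view == "xz":
            return (h, n, w)
        return (h, w, n)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume_shape(next(iter(self.views)))

    def __contains__(self, view: str) -> bool:
        return view in self.views

    def __getitem__(self, view: str) -> np.ndarray:
        return self.views[view]


def transpose_to_view(volume: np.ndarray, view: str) -> np.ndarray:
    """Re-arrange a canonical ``(z, y, x)`` volume into a stack of 2D slices
    for ``view`` (slice axis first)."""
    if view == "xy":
        return volume
    if view == "xz":
        return np.transpose(volume, (1, 0, 2))
    if view == "yz":
        return np.transpose(volume, (2, 0, 1))
    raise ValueError(f"unknown view {view!r}")


def restack(stack: np.ndarray, view: str) -> np.ndarray:
    """Inverse of :func:`transpose_to_view`: stack of slices -> (z,y,x)."""
    if view == "xy":
        return stack
    if view == "xz":
        return np.transpose(stack, (1, 0, 2))
    if view == "yz":
        return np.transpose(stack, (1, 2, 0))
    raise ValueError(f"unknown view {view!r}")


def read_volume(path, kind: str = "intensity"):
    """Read a multipage TIFF as a :class:`Volume` or :class:`LabelVolume`.

    Labels are read without interpolation or dtype coercion beyond integer
    casting.  Voxel spacing is parsed from ImageJ metadata when present,
    else (1, 1, 1).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = _parse_spacing(tf)
    if data.ndim == 2:
        raise ValueError("not a 3D volume")
    if data.ndim != 3:
        raise ValueError("not a 3D volume")
    if kind == "label":
        if not np.issubdtype(data.dtype, np.integer):
            data = np.round(data).astype(np.int32)
        return LabelVolume(data.astype(np.int32, copy=False), spacing)
    if kind == "intensity":
        return Volume(data.astype(np.float64), spacing)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(path, volume) -> None:
    """Write a Volume/LabelVolume (or bare 3D array) as a multipage TIFF."""
    if isinstance(volume, (Volume, LabelVolume)):
        data = volume.data
    else:
        data = np.asarray(volume)
    if data.ndim != 3:
        raise ValueError("not a 3D volume")
    spacing = getattr(volume, "spacing", (1.0, 1.0, 1.0))
    if np.issubdtype(data.dtype, np.integer):
        # ImageJ TIFF carries the z-spacing but only supports u8/u16/f32
        data = data.astype(np.uint16) if data.max() < 2**16 and data.min() >= 0 else data
    else:
        data = data.astype(np.float32)
    if data.dtype in (np.uint8, np.uint16, np.float32):
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / spacing[2], 1.0 / spacing[1]),
            metadata={"spacing": spacing[0], "unit": "pixel", "axes": "ZYX"},
        )
    else:
        tifffile.imwrite(path, data, resolution=(1.0 / spacing[2], 1.0 / spacing[1]))


def _parse_spacing(tf: tifffile.TiffFile) -> tuple[float, float, float]:
    sz = sy = sx = 1.0
    try:
        if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
            sz = float(tf.imagej_metadata["spacing"])
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None:
            num, den = xres.value
            if num:
                sx = den / num
        if yres is not None:
            num, den = yres.value
            if num:
                sy = den / num
    except Exception:
        pass
    return (sz, sy, sx)


def read_gradients(path) -> dict[str, np.ndarray]:
    """Read per-view gradient stacks from an ``.npz`` archive."""
    with np.load(path) as npz:
        return {k: npz[k] for k in npz.files}


def write_gradients(path, stacks: dict[str, np.ndarray]) -> None:
    np.savez_compressed(path, **{k: np.asarray(v, dtype=np.float32) for k, v in stacks.items()})


def resize_isotropic(volume, target_scale: float = 1.0):
    """Rescale to isotropic voxels, optionally zooming by ``target_scale``.

    Intensity volumes are resampled with linear interpolation, label
    volumes with nearest neighbor.  The output spacing is the smallest
    input spacing divided by ``target_scale``, applied on all axes.
    """
    if target_scale <= 0:
        raise ValueError("target_scale must be positive")
    spacing = np.asarray(volume.spacing, dtype=float)
    iso = spacing.min()
    zoom = spacing / iso * target_scale
    if isinstance(volume, LabelVolume):
        out = ndi.zoom(volume.data, zoom, order=0, mode="grid-constant", grid_mode=True)
        return LabelVolume(out.astype(volume.data.dtype), tuple([iso / target_scale] * 3))
    out = ndi.zoom(volume.data, zoom, order=1, mode="nearest", grid_mode=True)
    return Volume(out, tuple([iso / target_scale] * 3))
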