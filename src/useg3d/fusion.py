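"""Consensus fusion of orthoview stacks into 3D foreground and gradients.

Views are combined with a content-based averaging function F: each view's
per-voxel weight is the inverse of its local standard deviation (plus a
pseudo-count α), so locally inconsistent views are down-voted.  With a
1-voxel neighborhood every local SD is zero and F degenerates to the
simple mean.

The fused 3D gradient combines three separate component fusions — the
x-component is observed by the x-y and x-z views, the y-component by x-y
and y-z, the z-component by x-z and y-z.  Missing views simply contribute
nothing; components observed by no view are zero before post-smoothing and
are imputed only by it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from .preprocess import auto_threshold_probability, local_sd
from .volume_io import VIEW_INPLANE_AXES, OrthoViewSet, restack


@dataclasses.dataclass(frozen=True)
class FusionParams:
    P_grad: int = 1
    P_fg: int = 3
    alpha: float = 0.5
    epsilon: float = 1e-20
    sigma_pre: float = 1.0
    sigma_post: float = 1.0
    fg_threshold: float | str = 0.5  # numeric, or "auto" for multi-class Otsu

    def __post_init__(self) -> None:
        for P in (self.P_grad, self.P_fg):
            if P < 1 or P % 2 == 0:
                raise ValueError("P must be odd and >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.alpha < 0 or self.sigma_pre < 0 or self.sigma_post < 0:
            raise ValueError("alpha and sigmas must be non-negative")


@dataclasses.dataclass
class ForegroundMask:
    """Consensus 3D foreground binary; the domain of gradient descent."""

    B: np.ndarray


def content_average(volumes, P: int = 1, alpha: float = 0.5, epsilon: float = 1e-20) -> np.ndarray:
    """Inverse-local-SD weighted average of co-registered grids.

    out = Σ_i I_i/(σ_i+α) / (Σ_i 1/(σ_i+α) + ε), with σ_i the local SD of
    view i over a P-wide cube.  With P=1 this is the simple mean up to the
    ε regularizer.
    """
    volumes = [np.asarray(v, dtype=float) for v in volumes]
    if not volumes:
        raise ValueError("need at least one volume")
    shape = volumes[0].shape
    if any(v.shape != shape for v in volumes):
        raise ValueError("shape mismatch between views")
    num = np.zeros(shape)
    den = np.full(shape, epsilon)
    for v in volumes:
        w = 1.0 / (local_sd(v, P) + alpha)
        num += w * v
        den += w
    return num / den


def fuse_foreground(views: OrthoViewSet, params: FusionParams = FusionParams()) -> ForegroundMask:
    """Fuse per-view foregrounds (binary or probability slices) into B.

    Each view stack is restacked to canonical 3D, content-averaged with the
    foreground neighborhood ``P_fg`` and binarized: numeric thresholds are
    applied directly, ``"auto"`` uses Otsu on the fused map.
    """
    stacks = []
    for view, stack in views.views.items():
        arr = np.asarray(stack, dtype=float)
        if views.kind == "label":
            arr = (arr > 0).astype(float)
        stacks.append(restack(arr, view))
    fused = content_average(stacks, P=params.P_fg, alpha=params.alpha, epsilon=params.epsilon)
    if params.fg_threshold == "auto":
        thresh = auto_threshold_probability(fused)
    else:
        thresh = float(params.fg_threshold)
    return ForegroundMask(fused > thresh)


def fuse_gradients(
    view_fields: dict[str, np.ndarray],
    params: FusionParams = FusionParams(),
    foreground: np.ndarray | None = None,
) -> np.ndarray:
    """Fuse per-view 2-component gradient stacks into a unit 3D field.

    Per view, each slice component is pre-filtered with a 2D Gaussian
    (σ_pre) so view independence is preserved, then restacked into the 3D
    components it observes.  Each 3D component is content-averaged over its
    observing views, post-filtered with a 3D Gaussian (σ_post) and the
    final field is unit-normalized on the foreground support.

    Parameters
    ----------
    view_fields
        Mapping view -> stack of shape (n_slices, 2, H, W).
    foreground
        Optional binary support; the field is zeroed outside it.

    Returns
    -------
    (3, Z, Y, X) float array with per-voxel magnitude 0 or 1.
    """
    if not view_fields:
        raise ValueError("need at least one view")
    contributions: dict[int, list[np.ndarray]] = {0: [], 1: [], 2: []}
    vol_shape = None
    for view, stack in view_fields.items():
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 4 or stack.shape[1] != 2:
            raise ValueError(f"view {view!r}: expected (n, 2, H, W) gradient stack")
        if params.sigma_pre > 0:
            stack = np.stack(
                [
                    [ndi.gaussian_filter(stack[i, c], params.sigma_pre) for c in range(2)]
                    for i in range(stack.shape[0])
                ]
            )
        for c_slice, c_global in enumerate(VIEW_INPLANE_AXES[view]):
            comp3d = restack(stack[:, c_slice], view)
            contributions[c_global].append(comp3d)
            vol_shape = comp3d.shape
    fused = np.zeros((3,) + vol_shape)
    for c_global, comps in contributions.items():
        if comps:
            fused[c_global] = content_average(
                comps, P=params.P_grad, alpha=params.alpha, epsilon=params.epsilon
            )
    if params.sigma_post > 0:
        for c in range(3):
            fused[c] = ndi.gaussian_filter(fused[c], params.sigma_post)
    mag = np.sqrt(np.sum(fused**2, axis=0))
    nz = mag > 1e-12
    fused = np.where(nz, fused / np.where(nz, mag, 1.0), 0.0)
    if foreground is not None:
        fused[:, ~np.asarray(foreground, dtype=bool)] = 0.0
    return fused
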