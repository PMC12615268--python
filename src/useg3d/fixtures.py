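"""Synthetic 3D label fixtures, orthoview slicing and controlled corruption.

The generator spans three super-morphotypes observed across real 3D cell
datasets: ``convex`` (packings of non-overlapping digital spheres, e.g.
nuclei or plant cells), ``branched`` (tubes of a few segments meeting at a
junction, e.g. tissue macrophages or root primordia cells) and ``network``
(random trees of thin tubes, e.g. vasculature).  Slicing emulates running a
perfect 2D instance segmenter independently on every slice of every
orthoview: each contiguous in-plane region of each object becomes its own
2D "cell", with no identity linking across slices.  Corruption injects the
errors a real 2D segmenter makes: dropped, split and merged 2D labels and
boundary jitter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .volume_io import VIEWS, LabelVolume, OrthoViewSet, transpose_to_view


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic label volume."""

    morphotype: str  # convex | branched | network
    shape: tuple[int, int, int]  # (z, y, x) voxels
    object_count: int
    radius_range: tuple[float, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.morphotype not in ("convex", "branched", "network"):
            raise ValueError(f"unknown morphotype {self.morphotype!r}")
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ValueError("shape components must be >= 16")
        if self.object_count < 1:
            raise ValueError("object_count must be positive")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("radius_range must satisfy 0 < min <= max")


@dataclasses.dataclass(frozen=True)
class CorruptionSpec:
    """Per-slice 2D label corruption rates.

    All rates are probabilities in [0, 1]; rates of 0 with ``jitter_px=0``
    yield the identity.
    """

    drop_rate: float = 0.0
    split_rate: float = 0.0
    merge_rate: float = 0.0
    jitter_px: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.drop_rate, self.split_rate, self.merge_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be non-negative")


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed after bounded retries."""


# ---------------------------------------------------------------------------
# rasterization helpers


def _rasterize_ball(canvas: np.ndarray, center: np.ndarray, radius: float, value: int) -> np.ndarray:
    """Paint a digital ball (voxel-center distance <= radius) onto canvas."""
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, canvas.shape)
    grid = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum((g - c) ** 2 for g, c in zip(grid, center))
    sub = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    inside = d2 <= radius**2
    sub[inside] = value
    return inside


def _segment_mask(shape, a: np.ndarray, b: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of voxels within ``radius`` of the segment a-b."""
    lo = np.maximum(np.floor(np.minimum(a, b) - radius).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(a, b) + radius).astype(int) + 1, shape)
    if np.any(hi <= lo):
        return np.zeros(shape, dtype=bool)
    grid = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    p = np.stack(grid, axis=-1).astype(float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        t = np.zeros(p.shape[:-1])
    else:
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    d2 = np.sum((p - proj) ** 2, axis=-1)
    out = np.zeros(shape, dtype=bool)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d2 <= radius**2
    return out


def _tube_mask(shape, polyline: list[np.ndarray], radius: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for a, b in zip(polyline[:-1], polyline[1:]):
        mask |= _segment_mask(shape, a, b, radius)
    return mask


# ---------------------------------------------------------------------------
# generators


def make_labels(spec: SyntheticSpec) -> LabelVolume:
    """Generate a deterministic synthetic label volume for ``spec``.

    Objects are labeled 1..N with disjoint voxel sets; background is 0.
    Raises :class:`PlacementError` when the requested count does not fit
    after bounded rejection sampling.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    canvas = np.zeros(shape, dtype=np.int32)
    if spec.morphotype == "convex":
        _place_spheres(canvas, spec, rng)
    elif spec.morphotype == "branched":
        _place_branched(canvas, spec, rng)
    else:
        _place_networks(canvas, spec, rng)
    return LabelVolume(canvas)


def _place_spheres(canvas, spec, rng, max_tries: int = 500) -> None:
    lo, hi = spec.radius_range
    placed: list[tuple[np.ndarray, float]] = []
    shape = np.array(canvas.shape)
    for label in range(1, spec.object_count + 1):
        for _ in range(max_tries):
            r = float(rng.uniform(lo, hi))
            if np.any(shape - 2 * r - 2 <= 0):
                continue
            c = rng.uniform(r + 1, shape - r - 1)
            # allow touching (>=) but not overlapping
            if all(np.linalg.norm(c - c2) >= r + r2 for c2, r2 in placed):
                _rasterize_ball(canvas, c, r, label)
                placed.append((c, r))
                break
        else:
            raise PlacementError(
                f"could not place sphere {label}/{spec.object_count} "
                f"in shape {tuple(shape)} with radii {spec.radius_range}"
            )


def _branched_tube(shape, rng, radius: float) -> np.ndarray:
    """One branched object: a trunk with 1-4 arms diverging from its end."""
    shape = np.array(shape)
    span = shape.min()
    seg_len = rng.uniform(0.18, 0.30) * span
    margin = radius + 2
    junction = rng.uniform(margin + seg_len * 0.5, shape - margin - seg_len * 0.5)
    n_arms = int(rng.integers(1, 5))  # total segments: trunk + arms in 2..5
    mask = np.zeros(tuple(shape), dtype=bool)

    def rand_dir():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    trunk_dir = rand_dir()
    a = np.clip(junction - trunk_dir * seg_len, margin, shape - margin)
    mask |= _segment_mask(tuple(shape), a, junction, radius)
    for _ in range(n_arms):
        d = rand_dir()
        # arms diverge from the trunk direction so slices show a fork
        d = d - (d @ trunk_dir) * trunk_dir * 0.5
        d /= np.linalg.norm(d)
        b = np.clip(junction + d * seg_len, margin, shape - margin)
        mask |= _segment_mask(tuple(shape), junction, b, radius)
    return mask


def _place_branched(canvas, spec, rng, max_tries: int = 200) -> None:
    lo, hi = spec.radius_range
    for label in range(1, spec.object_count + 1):
        for _ in range(max_tries):
            r = float(rng.uniform(lo, hi))
            mask = _branched_tube(canvas.shape, rng, r)
            grown = ndi.binary_dilation(mask)
            if mask.any() and not (grown & (canvas > 0)).any():
                canvas[mask] = label
                break
        else:
            raise PlacementError(f"could not place branched object {label}")


def _place_networks(canvas, spec, rng, max_tries: int = 200) -> None:
    lo, hi = spec.radius_range
    shape = np.array(canvas.shape)
    for label in range(1, spec.object_count + 1):
        for _ in range(max_tries):
            r = float(np.clip(rng.uniform(lo, hi), 1.0, 3.0))
            n_nodes = int(rng.integers(4, 8))
            margin = r + 2
            nodes = rng.uniform(margin, shape - margin, size=(n_nodes, 3))
            mask = np.zeros(tuple(shape), dtype=bool)
            # random tree: connect each node to its nearest already-connected node
            connected = [0]
            for i in range(1, n_nodes):
                dists = [np.linalg.norm(nodes[i] - nodes[j]) for j in connected]
                j = connected[int(np.argmin(dists))]
                mask |= _segment_mask(tuple(shape), nodes[i], nodes[j], r)
                connected.append(i)
            grown = ndi.binary_dilation(mask)
            if mask.any() and not (grown & (canvas > 0)).any():
                canvas[mask] = label
                break
        else:
            raise PlacementError(f"could not place network object {label}")


def make_two_spheres(
    shape=(96, 96, 96), centers=((32, 32, 32), (64, 64, 64)), radii=(12.0, 12.0)
) -> LabelVolume:
    """Deterministic two-sphere fixture (optionally touching) used widely in
    tests; spheres are rasterized with voxel-center distance <= r."""
    canvas = np.zeros(shape, dtype=np.int32)
    for i, (c, r) in enumerate(zip(centers, radii), start=1):
        _rasterize_ball(canvas, np.asarray(c, dtype=float), r, i)
    return LabelVolume(canvas)


def make_y_tube(shape=(96, 96, 96), radius: float = 4.0, offset=(0, 0, 0)) -> LabelVolume:
    """Deterministic Y-shaped tube: trunk along z, two arms diverging in y.

    x-y slices above the fork contain two disjoint in-plane regions.
    """
    shape = tuple(shape)
    zc, yc, xc = (np.array(shape) - 1) / 2.0 + np.asarray(offset, dtype=float)
    trunk_lo = np.array([shape[0] * 0.12, yc, xc])
    fork = np.array([zc, yc, xc])
    arm_top = shape[0] * 0.88
    arm_spread = shape[1] * 0.25
    arm1 = np.array([arm_top, yc - arm_spread, xc])
    arm2 = np.array([arm_top, yc + arm_spread, xc])
    canvas = np.zeros(shape, dtype=np.int32)
    mask = _tube_mask(shape, [trunk_lo, fork, arm1], radius)
    mask |= _segment_mask(shape, fork, arm2, radius)
    canvas[mask] = 1
    return LabelVolume(canvas)


# ---------------------------------------------------------------------------
# slicing and corruption


def slice_orthoviews(labels: LabelVolume, views=VIEWS) -> OrthoViewSet:
    """Slice a 3D labeling into per-view stacks of 2D instance images.

    Within each slice, every contiguous in-plane region of every 3D object
    receives its own fresh 2D ID (8-connectivity in-plane); no identity is
    preserved across slices.  The union of 2D foregrounds in any view
    reproduces the 3D foreground voxel-for-voxel.
    """
    data = labels.data
    out: dict[str, np.ndarray] = {}
    for view in views:
        if view not in VIEWS:
            raise ValueError(f"unknown view {view!r}")
        stack = transpose_to_view(data, view)
        relabeled = np.zeros_like(stack, dtype=np.int32)
        for i in range(stack.shape[0]):
            relabeled[i] = _relabel_slice(stack[i])
        out[view] = relabeled
    return OrthoViewSet(out, kind="label")


def _relabel_slice(sl: np.ndarray) -> np.ndarray:
    """Unique ID per (3D label, in-plane 8-connected component) pair."""
    out = np.zeros_like(sl, dtype=np.int32)
    nxt = 1
    for lab in np.unique(sl):
        if lab == 0:
            continue
        comp, n = measure.label(sl == lab, connectivity=2, return_num=True)
        out[comp > 0] = comp[comp > 0] + (nxt - 1)
        nxt += n
    return out


def corrupt_views(views: OrthoViewSet, c: CorruptionSpec) -> OrthoViewSet:
    """Inject per-slice drop/split/merge/jitter artifacts, deterministically.

    Each slice is corrupted independently in a fixed order (drop, split,
    merge, jitter) so a given seed reproduces the exact corruption mask.
    """
    rng = np.random.default_rng(c.seed)
    out: dict[str, np.ndarray] = {}
    for view in sorted(views.views):
        stack = views[view].copy()
        for i in range(stack.shape[0]):
            stack[i] = _corrupt_slice(stack[i], c, rng)
        out[view] = stack
    return OrthoViewSet(out, kind=views.kind)


def _corrupt_slice(sl: np.ndarray, c: CorruptionSpec, rng) -> np.ndarray:
    sl = sl.copy()
    ids = [int(i) for i in np.unique(sl) if i != 0]
    if ids and rng.random() < c.drop_rate:
        victim = ids[int(rng.integers(len(ids)))]
        sl[sl == victim] = 0
        ids.remove(victim)
    if ids and rng.random() < c.split_rate:
        victim = ids[int(rng.integers(len(ids)))]
        mask = sl == victim
        coords = np.argwhere(mask)
        centroid = coords.mean(axis=0)
        theta = rng.uniform(0, np.pi)
        normal = np.array([np.cos(theta), np.sin(theta)])
        side = (coords - centroid) @ normal > 0
        new_id = max(ids) + 1
        sl[tuple(coords[side].T)] = new_id
        ids.append(new_id)
    if len(ids) >= 2 and rng.random() < c.merge_rate:
        pair = _touching_pair(sl, ids, rng)
        if pair is not None:
            a, b = pair
            sl[sl == b] = a
            ids.remove(b)
    if c.jitter_px > 0 and ids:
        for lab in ids:
            amount = int(rng.integers(-c.jitter_px, c.jitter_px + 1))
            if amount == 0:
                continue
            mask = sl == lab
            if amount > 0:
                grown = ndi.binary_dilation(mask, iterations=amount)
                sl[grown & (sl == 0)] = lab
            else:
                shrunk = ndi.binary_erosion(mask, iterations=-amount)
                sl[mask & ~shrunk] = 0
    return sl


def _touching_pair(sl, ids, rng):
    order = list(rng.permutation(len(ids)))
    for oi in order:
        a = ids[oi]
        grown = ndi.binary_dilation(sl == a)
        nbrs = np.unique(sl[grown])
        nbrs = [int(n) for n in nbrs if n not in (0, a)]
        if nbrs:
            return a, nbrs[int(rng.integers(len(nbrs)))]
    return None


def synth_probability(
    views: OrthoViewSet, sharpness: float = 4.0, noise_sd: float = 0.0, seed: int = 0
) -> OrthoViewSet:
    """Turn label views into unnormalized per-slice logit maps.

    Logits are ``+sharpness`` inside labels and ``-sharpness`` outside,
    plus optional Gaussian noise.  With ``noise_sd=0``, passing the result
    through the logistic normalization and a 0.5 threshold recovers the
    label foreground exactly.
    """
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for view in sorted(views.views):
        stack = views[view]
        logits = sharpness * (2.0 * (stack > 0) - 1.0)
        if noise_sd > 0:
            logits = logits + rng.normal(0.0, noise_sd, size=logits.shape)
        out[view] = logits.astype(np.float32)
    return OrthoViewSet(out, kind="probability")
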