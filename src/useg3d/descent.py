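"""Suppressed gradient descent: advect foreground voxels to attractors.

Every foreground voxel of the consensus binary B is advected along the
fused unit gradient field for a fixed number of iterations T.  The update
uses momentum (the previous iteration's sampled gradient) and a decaying
step size

    eta(t) = delta / (1 + t * tau)

so thin, elongated shapes stop eroding before they fragment (larger tau
suppresses propagation sooner).  The field is sampled with nearest-voxel
(rounding) interpolation; coordinates are clipped to the volume at every
step.  Because the stored field already points toward the attractor, the
update *adds* the step.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np


@dataclasses.dataclass(frozen=True)
class DescentParams:
    T: int = 250
    delta: float = 1.0
    mu: float = 0.95
    tau: float = 0.5

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if not (self.delta >= self.mu >= 0):
            raise ValueError("need delta >= mu >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclasses.dataclass
class TrajectorySet:
    """Initial (integer) and final (float) positions of advected voxels.

    Index i refers to the same physical voxel in both arrays; this linkage
    carries attractor IDs back from the eroded space to image space.
    """

    coords0: np.ndarray  # (N, 3) int, the B=1 voxels at t=0
    coordsT: np.ndarray  # (N, 3) float, clipped to volume bounds
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.coords0) != len(self.coordsT):
            raise ValueError("coords0/coordsT cardinality mismatch")


def step_size(t: int, delta: float = 1.0, tau: float = 0.5) -> float:
    """Decayed step size eta = delta / (1 + t*tau); constant when tau=0."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return delta / (1.0 + t * tau)


def advect(
    coords0: np.ndarray, field: np.ndarray, params: DescentParams = DescentParams()
) -> TrajectorySet:
    """Advect points along ``field`` for ``params.T`` iterations.

    ``field`` has shape (3, Z, Y, X); ``coords0`` is (N, 3) in (z, y, x)
    order.  The momentum term reuses the gradient sampled at the previous
    iteration's position (zero history at the first step, so the first
    move is the current gradient scaled by delta/(delta+mu)).
    """
    field = np.asarray(field, dtype=np.float32)
    shape = field.shape[1:]
    coords0 = np.asarray(coords0)
    pos = coords0.astype(np.float32).copy()
    if len(pos) == 0 or params.T == 0:
        return TrajectorySet(coords0, pos, shape)
    upper = np.asarray(shape, dtype=np.float32) - 1.0
    g_prev = np.zeros_like(pos)
    denom = params.delta + params.mu
    for t in range(params.T):
        idx = np.clip(np.rint(pos), 0, upper).astype(np.intp)
        g_curr = field[:, idx[:, 0], idx[:, 1], idx[:, 2]].T
        eta = step_size(t, params.delta, params.tau)
        pos += eta * (params.delta * g_curr + params.mu * g_prev) / denom
        np.clip(pos, 0.0, upper, out=pos)
        g_prev = g_curr
    return TrajectorySet(coords0, pos, shape)


def _tile_starts(size: int, tile: int, overlap: int) -> list[int]:
    """Evenly spaced tile start offsets covering [0, size) with >= overlap."""
    if tile >= size:
        return [0]
    n = max(2, math.ceil((size - overlap) / (tile - overlap)))
    return [int(round(s)) for s in np.linspace(0, size - tile, n)]


def advect_tiled(
    B: np.ndarray,
    field: np.ndarray,
    params: DescentParams = DescentParams(),
    tile_shape: tuple[int, int, int] = (128, 256, 256),
    overlap_frac: float = 0.25,
) -> TrajectorySet:
    """Tile-parallel variant of :func:`advect` with per-tile clipping.

    The volume is covered by overlapping tiles; every foreground voxel is
    advected inside exactly one owning tile (the tile whose non-overlap
    core contains it — cores partition the volume at the midpoints of the
    overlap regions).  Coordinates are clipped to the *tile* bounds during
    descent and globalized by adding the tile offset, so results are
    independent of tile iteration order.  Cells whose attractor basin is
    visible within the overlap margin reproduce the untiled result.
    """
    B = np.asarray(B, dtype=bool)
    field = np.asarray(field, dtype=np.float32)
    if not 0 <= overlap_frac < 0.5:
        raise ValueError("overlap_frac must be in [0, 0.5)")
    shape = B.shape
    tile_shape = tuple(min(t, s) for t, s in zip(tile_shape, shape))
    overlaps = [int(round(t * overlap_frac)) for t in tile_shape]
    if any(t - o <= 0 for t, o in zip(tile_shape, overlaps)):
        raise ValueError("tile too small for the requested overlap")
    starts = [_tile_starts(s, t, o) for s, t, o in zip(shape, tile_shape, overlaps)]
    # core boundaries: midpoints between adjacent tile windows
    bounds = []
    for ax, st in enumerate(starts):
        ends = [min(s + tile_shape[ax], shape[ax]) for s in st]
        cuts = [0]
        for i in range(1, len(st)):
            cuts.append((st[i] + ends[i - 1]) // 2)
        cuts.append(shape[ax])
        bounds.append(cuts)

    all0, allT = [], []
    for iz, sz in enumerate(starts[0]):
        for iy, sy in enumerate(starts[1]):
            for ix, sx in enumerate(starts[2]):
                offset = np.array([sz, sy, sx])
                tile_sl = tuple(
                    slice(o, min(o + t, s)) for o, t, s in zip(offset, tile_shape, shape)
                )
                core_sl = tuple(
                    slice(b[i], b[i + 1]) for b, i in zip(bounds, (iz, iy, ix))
                )
                core = np.zeros(shape, dtype=bool)
                core[core_sl] = True
                owned = np.argwhere(B & core)
                if len(owned) == 0:
                    continue
                sub_field = field[(slice(None),) + tile_sl]
                local = advect(owned - offset, sub_field, params)
                all0.append(owned)
                allT.append(local.coordsT + offset)
    if not all0:
        return TrajectorySet(np.zeros((0, 3), dtype=int), np.zeros((0, 3)), shape)
    coords0 = np.concatenate(all0)
    coordsT = np.concatenate(allT)
    order = np.lexsort((coords0[:, 2], coords0[:, 1], coords0[:, 0]))
    return TrajectorySet(coords0[order], coordsT[order], shape)
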