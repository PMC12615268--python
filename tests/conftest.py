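"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from useg3d import fixtures


# ---------------------------------------------------------------------------
# geometric fixtures


@pytest.fixture(scope="session")
def two_spheres_sep():
    """Two well-separated spheres in a 64-cube."""
    return fixtures.make_two_spheres(
        shape=(64, 64, 64), centers=((20, 20, 20), (44, 44, 44)), radii=(9.0, 9.0)
    )


@pytest.fixture(scope="session")
def two_spheres_touching():
    """Two spheres whose centers are exactly 2r apart (touching)."""
    return fixtures.make_two_spheres(
        shape=(72, 72, 72), centers=((36, 36, 24), (36, 36, 48)), radii=(12.0, 12.0)
    )


@pytest.fixture(scope="session")
def y_tube():
    return fixtures.make_y_tube(shape=(96, 96, 96), radius=4.0)


@pytest.fixture()
def disk_mask():
    from skimage.draw import disk

    m = np.zeros((41, 41), dtype=bool)
    rr, cc = disk((20, 20), 15)
    m[rr, cc] = True
    return m


# ---------------------------------------------------------------------------
# independent oracles (never share code with the implementation)


def brute_components(mask: np.ndarray, connectivity: int = 1) -> int:
    """Count connected components by BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    ndim = mask.ndim
    offsets = []
    for delta in np.ndindex(*([3] * ndim)):
        d = np.array(delta) - 1
        if not d.any():
            continue
        if np.abs(d).sum() <= connectivity or connectivity >= ndim:
            offsets.append(d)
    seen = np.zeros_like(mask)
    count = 0
    for start in np.argwhere(mask):
        if seen[tuple(start)]:
            continue
        count += 1
        stack = [start]
        seen[tuple(start)] = True
        while stack:
            p = stack.pop()
            for d in offsets:
                q = p + d
                if np.all(q >= 0) and np.all(q < mask.shape):
                    if mask[tuple(q)] and not seen[tuple(q)]:
                        seen[tuple(q)] = True
                        stack.append(q)
    return count


def brute_flood_labels(mask: np.ndarray) -> np.ndarray:
    """BFS flood-fill labeling with full (26/8) connectivity."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for start in np.argwhere(mask):
        if out[tuple(start)]:
            continue
        nxt += 1
        stack = [start]
        out[tuple(start)] = nxt
        while stack:
            p = stack.pop()
            for d in np.ndindex(*([3] * mask.ndim)):
                q = p + np.array(d) - 1
                if np.all(q >= 0) and np.all(q < mask.shape):
                    if mask[tuple(q)] and not out[tuple(q)]:
                        out[tuple(q)] = nxt
                        stack.append(q)
    return out


def brute_edt(mask: np.ndarray) -> np.ndarray:
    """Per-pixel min distance to any background pixel (border = background)."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    bg = np.argwhere(~padded)
    out = np.zeros(mask.shape, dtype=float)
    for p in np.argwhere(mask):
        out[tuple(p)] = np.sqrt(np.min(np.sum((bg - (p + 1)) ** 2, axis=1)))
    return out


def brute_local_sd(x: np.ndarray, P: int) -> np.ndarray:
    """Sliding-window population SD with symmetric padding."""
    x = np.asarray(x, dtype=float)
    half = P // 2
    padded = np.pad(x, half, mode="symmetric")
    out = np.zeros_like(x)
    for idx in np.ndindex(*x.shape):
        window = padded[tuple(slice(i, i + P) for i in idx)]
        out[idx] = window.std()
    return out


def brute_best_assignment(iou_mat: np.ndarray) -> float:
    """Max total IoU one-to-one assignment by exhaustive enumeration."""
    from itertools import permutations

    m, n = iou_mat.shape
    if m <= n:
        best = 0.0
        for perm in permutations(range(n), m):
            best = max(best, sum(iou_mat[i, j] for i, j in enumerate(perm)))
        return best
    return brute_best_assignment(iou_mat.T)
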