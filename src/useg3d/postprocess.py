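"""Quality control and guide-image refinement of consensus segmentations.

The recommended chain is: remove implausibly small cells (and keep only
each label's largest connected component), remove cells whose recomputed
gradients disagree with the field used for descent, remove statistically
oversized cells, then refine the survivors against a guide image — first
by label diffusion on an intensity/adjacency affinity graph, then by a
guided filter that transfers high-frequency guide structure (protrusions,
vessel fingers) into the mask boundary zone.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from skimage import filters, measure

from .fusion import FusionParams, fuse_gradients
from .transforms import labels_to_gradients
from .volume_io import VIEWS, Volume, transpose_to_view

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class QCParams:
    min_size: int = 200
    mae_threshold: float = 0.85
    k_vol: float = 5.0
    pad: int = 25

    def __post_init__(self) -> None:
        if self.min_size < 0 or self.k_vol <= 0 or self.pad < 0:
            raise ValueError("invalid QC parameters")


@dataclasses.dataclass(frozen=True)
class DiffusionParams:
    alpha_mix: float = 0.5  # intensity-vs-adjacency affinity weight
    gamma_clamp: float = 0.75  # how strongly the original labels are pinned
    T_diff: int = 25

    def __post_init__(self) -> None:
        if not (0 <= self.alpha_mix <= 1 and 0 <= self.gamma_clamp <= 1):
            raise ValueError("alpha_mix and gamma_clamp must be in [0, 1]")
        if self.T_diff < 0:
            raise ValueError("T_diff must be >= 0")


@dataclasses.dataclass(frozen=True)
class GuidedFilterParams:
    radius: int = 35
    eps_gf: float = 1e-4
    alpha_guide: float = 0.5

    def __post_init__(self) -> None:
        if self.radius < 1 or self.eps_gf <= 0 or not 0 <= self.alpha_guide <= 1:
            raise ValueError("invalid guided filter parameters")


def _guide_data(guide):
    return guide.data if isinstance(guide, Volume) else np.asarray(guide, dtype=float)


def _cell_crop(labels: np.ndarray, lab: int, pad: int):
    mask = labels == lab
    sl = ndi.find_objects(mask.astype(np.int8))[0]
    sl = tuple(
        slice(max(s.start - pad, 0), min(s.stop + pad, dim))
        for s, dim in zip(sl, labels.shape)
    )
    return sl, mask[sl]


# ---------------------------------------------------------------------------
# removal filters


def filter_small(labels: np.ndarray, min_size: int = 200) -> np.ndarray:
    """Drop labels below ``min_size`` voxels; keep only each survivor's
    largest connected component (cells must be spatially contiguous)."""
    labels = np.asarray(labels)
    out = labels.copy()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        if mask.sum() < min_size:
            out[mask] = 0
            continue
        comp, n = measure.label(mask, return_num=True, connectivity=3)
        if n > 1:
            sizes = np.bincount(comp.ravel())
            keep = int(np.argmax(sizes[1:])) + 1
            out[mask & (comp != keep)] = 0
    return out


def filter_gradient_inconsistent(
    labels: np.ndarray,
    field_in: np.ndarray,
    kind: str = "edt",
    mae_threshold: float = 0.85,
    fusion_params: FusionParams = FusionParams(),
    pad: int = 2,
) -> np.ndarray:
    """Drop cells whose own-mask gradients disagree with the descent field.

    Per cell, its binary mask is sliced into the three orthoviews, the 2D
    transform of the same ``kind`` is recomputed and fused to 3D, and the
    mean (over the cell's voxels) Euclidean norm of the difference with
    ``field_in`` is compared against ``mae_threshold``.  Well-segmented
    cells reproduce the field they were eroded with (MAE near 0); spurious
    cells carved from unrelated gradients do not.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    field_in = np.asarray(field_in)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sl, mask = _cell_crop(labels, lab, pad)
        view_fields = {}
        for view in VIEWS:
            stack = transpose_to_view(mask.astype(np.int32), view)
            grads = np.stack([labels_to_gradients(s, kind)[0] for s in stack])
            view_fields[view] = grads
        g_seg = fuse_gradients(view_fields, fusion_params, foreground=mask)
        g_in = field_in[(slice(None),) + sl]
        diff = np.linalg.norm(g_seg - g_in, axis=0)
        mae = float(diff[mask].mean())
        if mae > mae_threshold:
            log.info("dropping cell %d: gradient MAE %.3f > %.3f", lab, mae, mae_threshold)
            out[out == lab] = 0
    return out


def filter_large(labels: np.ndarray, k_vol: float = 5.0) -> np.ndarray:
    """Drop cells with volume > mean + k_vol*std of all cell volumes.

    Single pass over the volumes observed on entry; with fewer than two
    cells (or zero spread) nothing is removed.
    """
    labels = np.asarray(labels)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if len(ids) < 2:
        return labels.copy()
    cutoff = counts.mean() + k_vol * counts.std()
    out = labels.copy()
    for lab, vol in zip(ids, counts):
        if vol > cutoff:
            log.info("dropping cell %d: volume %d > cutoff %.1f", lab, vol, cutoff)
            out[out == lab] = 0
    return out


# ---------------------------------------------------------------------------
# guide-image refinement


def make_guide(I_norm, I_ridge, alpha_guide: float = 0.5):
    """Convex blend of the normalized image and its ridge enhancement."""
    a = _guide_data(I_norm)
    b = _guide_data(I_ridge)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return alpha_guide * a + (1.0 - alpha_guide) * b


def _neighbor_pairs(shape):
    """Index pairs of 6-connected voxel neighbors on a dense grid."""
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    pairs = []
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        pairs.append((idx[tuple(sl_a)].ravel(), idx[tuple(sl_b)].ravel()))
    i = np.concatenate([p[0] for p in pairs])
    j = np.concatenate([p[1] for p in pairs])
    return i, j


def diffuse_labels(
    labels: np.ndarray,
    guide,
    dparams: DiffusionParams = DiffusionParams(),
    pad: int = 25,
) -> np.ndarray:
    """Refine each cell by semi-supervised label diffusion against a guide.

    Per cell (binary versus background) on its padded crop, an affinity
    graph blends guide-intensity similarity, exp(-D^2 / (2*mean(D)^2)) on
    6-neighbor edges, with plain spatial adjacency (weight ``alpha_mix``
    versus ``1 - alpha_mix``).  Rows are sum-normalized so the iteration

        z <- (1-gamma) * A z + gamma * L

    is a contraction; after ``T_diff`` rounds each voxel takes the argmax
    source.  ``gamma_clamp=1`` or ``T_diff=0`` pins z to the one-hot input
    and is the identity.  Refined cells are reduced to their largest
    connected component and never overwrite other cells' voxels.
    """
    labels = np.asarray(labels)
    guide = _guide_data(guide)
    if guide.shape != labels.shape:
        raise ValueError("guide not co-registered with labels")
    if dparams.T_diff == 0 or dparams.gamma_clamp == 1.0:
        return labels.copy()
    out = labels.copy()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sl, mask = _cell_crop(labels, lab, pad)
        sub_guide = guide[sl]
        refined = _diffuse_binary(mask, sub_guide, dparams)
        refined &= ~((out[sl] > 0) & (out[sl] != lab))  # never invade neighbors
        comp, n = measure.label(refined, return_num=True, connectivity=3)
        if n > 1:
            sizes = np.bincount(comp.ravel())
            refined = comp == (int(np.argmax(sizes[1:])) + 1)
        region = out[sl]
        region[region == lab] = 0
        region[refined] = lab
    return out


def _diffuse_binary(mask: np.ndarray, guide: np.ndarray, dparams: DiffusionParams) -> np.ndarray:
    shape = mask.shape
    n = mask.size
    i, j = _neighbor_pairs(shape)
    g = guide.ravel()
    d = np.abs(g[i] - g[j])
    md = d.mean()
    w_int = np.exp(-(d**2) / (2.0 * md**2)) if md > 0 else np.ones_like(d)
    w = dparams.alpha_mix * w_int + (1.0 - dparams.alpha_mix)
    rows = np.concatenate([i, j, np.arange(n)])
    cols = np.concatenate([j, i, np.arange(n)])
    vals = np.concatenate([w, w, np.ones(n)])
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    A = sparse.diags(1.0 / rowsum) @ A
    L = np.stack([(~mask).ravel(), mask.ravel()], axis=1).astype(float)
    z = np.zeros_like(L)
    gamma = dparams.gamma_clamp
    for _ in range(dparams.T_diff):
        z = (1.0 - gamma) * (A @ z) + gamma * L
    # softmax is monotone per row, so argmax on z is the final assignment
    return (z[:, 1] > z[:, 0]).reshape(shape)


def diffuse_multilabel(
    seeds: np.ndarray,
    guide,
    dparams: DiffusionParams = DiffusionParams(),
) -> np.ndarray:
    """Joint multi-label diffusion from a (possibly partial) seeding.

    Unlike the per-cell binary route, all labels compete jointly: voxels
    with seed 0 start unlabeled (zero one-hot row) and take the label that
    diffuses to them most strongly.  With a uniform guide and symmetric
    seeds the decision boundary falls on the spatial midline.
    """
    seeds = np.asarray(seeds)
    guide = _guide_data(guide)
    ids = [int(v) for v in np.unique(seeds) if v != 0]
    if not ids:
        return seeds.copy()
    shape = seeds.shape
    n = seeds.size
    i, j = _neighbor_pairs(shape)
    g = guide.ravel()
    d = np.abs(g[i] - g[j])
    md = d.mean()
    w_int = np.exp(-(d**2) / (2.0 * md**2)) if md > 0 else np.ones_like(d)
    w = dparams.alpha_mix * w_int + (1.0 - dparams.alpha_mix)
    rows = np.concatenate([i, j, np.arange(n)])
    cols = np.concatenate([j, i, np.arange(n)])
    vals = np.concatenate([w, w, np.ones(n)])
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A = sparse.diags(1.0 / np.asarray(A.sum(axis=1)).ravel()) @ A
    flat = seeds.ravel()
    L = np.stack([(flat == lab).astype(float) for lab in ids], axis=1)
    z = np.zeros_like(L)
    gamma = dparams.gamma_clamp
    for _ in range(dparams.T_diff):
        z = (1.0 - gamma) * (A @ z) + gamma * L
    assigned = np.asarray(ids)[np.argmax(z, axis=1)]
    assigned[z.max(axis=1) <= 0] = 0
    return assigned.reshape(shape).astype(seeds.dtype)


def _box(x: np.ndarray, r: int) -> np.ndarray:
    return ndi.uniform_filter(x, size=2 * r + 1, mode="reflect")


def guided_filter(p: np.ndarray, I: np.ndarray, r: int, eps: float) -> np.ndarray:
    """Standard local-linear guided filter (cube window of half-width r)."""
    I = np.asarray(I, dtype=float)
    p = np.asarray(p, dtype=float)
    mean_I = _box(I, r)
    mean_p = _box(p, r)
    cov = _box(I * p, r) - mean_I * mean_p
    var = _box(I * I, r) - mean_I * mean_I
    a = cov / (var + eps)
    b = mean_p - a * mean_I
    return _box(a, r) * I + _box(b, r)


def guided_filter_refine(
    labels: np.ndarray,
    guide,
    gparams: GuidedFilterParams = GuidedFilterParams(),
    pad: int = 25,
) -> np.ndarray:
    """Feather each cell mask with the guide and rebinarize by Otsu.

    The guided filter transfers guide structure (e.g. ridge-enhanced
    protrusions shorter than the window radius) into an alpha matte around
    the mask boundary; two-class Otsu recovers a binary mask, and voxels
    occupied by other cells are masked out.  Edits are confined to each
    cell's padded crop.
    """
    labels = np.asarray(labels)
    guide = _guide_data(guide)
    if guide.shape != labels.shape:
        raise ValueError("guide not co-registered with labels")
    out = labels.copy()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sl, mask = _cell_crop(labels, lab, pad)
        q = guided_filter(mask.astype(float), guide[sl], gparams.radius, gparams.eps_gf)
        if q.max() <= q.min():
            continue
        t = filters.threshold_otsu(q)
        refined = q > t
        refined &= ~((out[sl] > 0) & (out[sl] != lab))
        region = out[sl]
        region[region == lab] = 0
        region[refined] = lab
    return out


def qc_chain(
    labels: np.ndarray,
    field_in: np.ndarray | None = None,
    kind: str = "edt",
    qc: QCParams = QCParams(),
    fusion_params: FusionParams = FusionParams(),
) -> np.ndarray:
    """Default removal chain: small -> gradient-inconsistent -> large."""
    out = filter_small(labels, qc.min_size)
    if field_in is not None:
        out = filter_gradient_inconsistent(
            out, field_in, kind, qc.mae_threshold, fusion_params
        )
    return filter_large(out, qc.k_vol)
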