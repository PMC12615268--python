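"""Instance-matching metrics: IoU, optimal matching, AP and F1 curves.

Predicted and reference cells are matched one-to-one by solving the linear
sum assignment on 1 - IoU costs (optionally restricted to centroid
nearest-neighbor candidates for large images); only spatially overlapping
pairs (IoU > 0) are kept.  At a given IoU cutoff, matched pairs above the
cutoff are true positives; unmatched predictions and references are false
positives and false negatives,

    AP = TP / (TP + FP + FN),     F1 = 2*TP / (2*TP + FP + FN),

and curves are reported over 11 IoU cutoffs equisampling [0.5, 1.0].
Because approximate matching is not invariant to label-ID permutation,
both inputs are relabeled sequentially after an indirect stable sort of
their centroids before matching.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from skimage import measure

IOU_THRESHOLDS = np.linspace(0.5, 1.0, 11)


@dataclasses.dataclass
class MatchResult:
    """One-to-one matching of predicted to reference instances."""

    pairs: list[tuple[int, int, float]]  # (pred ID, ref ID, IoU); IoU > 0
    n_pred: int
    n_ref: int

    def counts(self, iou_cutoff: float) -> tuple[int, int, int]:
        """(TP, FP, FN) at a given IoU cutoff."""
        tp = sum(1 for _, _, v in self.pairs if v >= iou_cutoff)
        return tp, self.n_pred - tp, self.n_ref - tp

    @property
    def mean_iou(self) -> float:
        return float(np.mean([v for _, _, v in self.pairs])) if self.pairs else 0.0


@dataclasses.dataclass
class MetricCurve:
    thresholds: np.ndarray
    values: np.ndarray

    def at(self, thr: float) -> float:
        return float(self.values[np.argmin(np.abs(self.thresholds - thr))])


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two boolean masks; both-empty is defined as 0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def _labels_data(x):
    return np.asarray(x.data if not isinstance(x, np.ndarray) and hasattr(x, "data") else x)


def _overlap_matrix(pred: np.ndarray, ref: np.ndarray):
    """Dense IoU matrix between positive labels via the joint histogram."""
    pred_ids = np.unique(pred[pred > 0])
    ref_ids = np.unique(ref[ref > 0])
    p_index = {v: k for k, v in enumerate(pred_ids)}
    r_index = {v: k for k, v in enumerate(ref_ids)}
    iou_mat = np.zeros((len(pred_ids), len(ref_ids)))
    both = (pred > 0) | (ref > 0)
    pv, rv = pred[both], ref[both]
    pair_keys = pv.astype(np.int64) * (ref.max() + 1) + rv
    uniq, counts = np.unique(pair_keys, return_counts=True)
    p_sizes = dict(zip(*np.unique(pred[pred > 0], return_counts=True)))
    r_sizes = dict(zip(*np.unique(ref[ref > 0], return_counts=True)))
    inter = {}
    for key, cnt in zip(uniq, counts):
        pi, ri = divmod(int(key), int(ref.max() + 1))
        if pi > 0 and ri > 0:
            inter[(pi, ri)] = cnt
    for (pi, ri), cnt in inter.items():
        union = p_sizes[pi] + r_sizes[ri] - cnt
        iou_mat[p_index[pi], r_index[ri]] = cnt / union
    return pred_ids, ref_ids, iou_mat


def match_instances(pred, ref, k_nn: int = 10) -> MatchResult:
    """Optimal one-to-one matching minimizing 1 - IoU.

    For images with more than 50 objects on either side, candidate pairs
    are restricted to each prediction's ``k_nn`` nearest reference cells by
    centroid distance; smaller images use the exact dense matching.
    """
    pred = _labels_data(pred)
    ref = _labels_data(ref)
    pred_ids, ref_ids, iou_mat = _overlap_matrix(pred, ref)
    if len(pred_ids) == 0 or len(ref_ids) == 0:
        return MatchResult([], len(pred_ids), len(ref_ids))
    if max(len(pred_ids), len(ref_ids)) > 50:
        keep = np.zeros_like(iou_mat, dtype=bool)
        p_cent = np.array(ndi.center_of_mass(pred > 0, pred, pred_ids))
        r_cent = np.array(ndi.center_of_mass(ref > 0, ref, ref_ids))
        tree = cKDTree(r_cent)
        k = min(k_nn, len(ref_ids))
        _, nbrs = tree.query(p_cent, k=k)
        nbrs = np.atleast_2d(nbrs.T).T
        for i in range(len(pred_ids)):
            keep[i, nbrs[i]] = True
        iou_mat = np.where(keep, iou_mat, 0.0)
    rows, cols = linear_sum_assignment(1.0 - iou_mat)
    pairs = [
        (int(pred_ids[i]), int(ref_ids[j]), float(iou_mat[i, j]))
        for i, j in zip(rows, cols)
        if iou_mat[i, j] > 0
    ]
    return MatchResult(pairs, len(pred_ids), len(ref_ids))


def relabel_by_centroid(labels) -> np.ndarray:
    """Sequential relabeling after an indirect stable sort of centroids.

    Canonicalizes label IDs so matching (and any scan-order-dependent
    labeling) is invariant to input ID permutation.
    """
    labels = _labels_data(labels)
    ids = np.unique(labels[labels > 0])
    if len(ids) == 0:
        return labels.copy()
    cents = np.array(ndi.center_of_mass(labels > 0, labels, ids))
    order = np.lexsort((cents[:, 0], cents[:, 1], cents[:, 2]))  # sort by (x, y, z)
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for new, old_idx in enumerate(order, start=1):
        lut[ids[old_idx]] = new
    return lut[labels]


def ap_f1_curve(pred, ref, restrict: float | None = None, k_nn: int = 10):
    """AP and F1 curves over the 11-threshold IoU grid.

    ``restrict`` applies the reference-foreground restriction (see
    :func:`restrict_to_reference_foreground`) before matching.
    """
    pred = _labels_data(pred)
    ref = _labels_data(ref)
    if restrict is not None:
        pred = restrict_to_reference_foreground(pred, ref, restrict)
    pred = relabel_by_centroid(pred)
    ref = relabel_by_centroid(ref)
    match = match_instances(pred, ref, k_nn=k_nn)
    ap_vals, f1_vals = [], []
    for thr in IOU_THRESHOLDS:
        tp, fp, fn = match.counts(thr)
        if tp + fp + fn == 0:
            ap_vals.append(1.0)  # no objects and no errors
            f1_vals.append(1.0)
        else:
            ap_vals.append(tp / (tp + fp + fn))
            f1_vals.append(2 * tp / (2 * tp + fp + fn))
    return (
        MetricCurve(IOU_THRESHOLDS.copy(), np.array(ap_vals)),
        MetricCurve(IOU_THRESHOLDS.copy(), np.array(f1_vals)),
        match,
    )


def restrict_to_reference_foreground(pred, ref, overlap_frac: float = 0.25) -> np.ndarray:
    """Drop predicted cells outside annotated reference foreground regions.

    Connected components of the predicted foreground qualify when they
    share at least ``overlap_frac`` of their volume with some reference
    foreground component; predictions in non-qualifying components are
    removed.  Datasets that only annotate a primary object use 0.25; thin
    vessel references use 0.01.  ``overlap_frac=0`` is the identity.
    """
    pred = _labels_data(pred)
    ref = _labels_data(ref)
    if overlap_frac <= 0:
        return pred.copy()
    pred_fg_comps = measure.label(pred > 0, connectivity=3)
    ref_fg = ref > 0
    out = pred.copy()
    for comp_id in np.unique(pred_fg_comps[pred_fg_comps > 0]):
        comp = pred_fg_comps == comp_id
        frac = np.count_nonzero(comp & ref_fg) / np.count_nonzero(comp)
        if frac < overlap_frac:
            out[comp] = 0
    return out
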