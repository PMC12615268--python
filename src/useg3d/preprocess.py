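"""Intensity conditioning and semiautomated predictor tuning.

These operations condition raw volumes for an external 2D instance
segmenter (percentile normalization, ratiometric illumination correction,
gamma correction, ridge enhancement) and adapt a pretrained predictor via
two scores: a gradient-contrast score scanned over candidate object
diameters, and multi-class Otsu thresholding of the predicted cell
probability.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import filters

from .volume_io import Volume

log = logging.getLogger(__name__)

#: logistic clip bound that keeps exp() finite in IEEE float32
LOGIT_CLIP = 88.72


@dataclasses.dataclass(frozen=True)
class NormalizeParams:
    p_lower: float = 2.0
    p_upper: float = 99.8

    def __post_init__(self) -> None:
        if not 0 <= self.p_lower < self.p_upper <= 100:
            raise ValueError("need 0 <= p_lower < p_upper <= 100")


@dataclasses.dataclass
class ContrastScoreCurve:
    """Contrast score vs candidate diameter, with its smoothed argmax."""

    diameters: np.ndarray
    scores: np.ndarray
    smoothed: np.ndarray
    window: int
    d_opt: float


def _data(I):
    return I.data if isinstance(I, Volume) else np.asarray(I, dtype=float)


def _wrap_like(I, out):
    return Volume(out, I.spacing) if isinstance(I, Volume) else out


def normalize_percentile(I, p: NormalizeParams = NormalizeParams()):
    """Map the ``p_lower`` percentile to 0 and ``p_upper`` to 1, clipping.

    Zeroes dim fluorescence background and clips sporadic saturated
    intensities; errors on constant images where the scaling is undefined.
    """
    data = _data(I)
    lo, hi = np.percentile(data, [p.p_lower, p.p_upper])
    if hi <= lo:
        raise ValueError("constant image: percentile scaling undefined")
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return _wrap_like(I, out)


def correct_illumination(I, sigma_bg: float = 5.0, ds: int = 8):
    """Ratiometric uneven-illumination correction: mean(I) * I / I_bg.

    The background I_bg is estimated by ``ds``-fold downsampling, Gaussian
    smoothing (σ = ``sigma_bg``) and upsampling back; zeros in I_bg are
    guarded by a small epsilon.
    """
    if sigma_bg <= 0 or ds < 1:
        raise ValueError("sigma_bg must be positive and ds >= 1")
    data = _data(I)
    if data.min() < 0:
        raise ValueError("intensity must be non-negative")
    if ds > 1:
        small = ndi.zoom(data, 1.0 / ds, order=1)
        bg = ndi.gaussian_filter(small, sigma_bg)
        bg = ndi.zoom(bg, np.array(data.shape) / np.array(bg.shape), order=1)
    else:
        bg = ndi.gaussian_filter(data, sigma_bg)
    eps = 1e-8 * max(bg.max(), 1.0)
    if (bg <= 0).any():
        log.info("illumination background contains zeros; guarding with eps=%g", eps)
    out = data.mean() * data / (bg + eps)
    return _wrap_like(I, out)


def gamma_correct(I, g: float):
    """Raise the linearly [0,1]-rescaled intensity to the power ``g``."""
    if g <= 0:
        raise ValueError("gamma must be positive")
    data = _data(I)
    lo, hi = data.min(), data.max()
    scaled = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    return _wrap_like(I, scaled**g)


def enhance_ridges(I, sigmas=(1.0, 2.0, 3.0)):
    """Hessian-eigenvalue ridge enhancement, max-pooled over scales.

    Uses the Meijering neurite filter, which needs no shape-prior
    hyperparameters and responds to thin bright tubes, vessels and
    protrusion edges.
    """
    sigmas = list(sigmas)
    if not sigmas:
        raise ValueError("need at least one sigma")
    data = _data(I)
    out = filters.meijering(data, sigmas=sigmas, black_ridges=False)
    return _wrap_like(I, out)


def normalize_probability(p_raw):
    """Clip logits to ±88.72 (float32-safe) and apply the logistic map."""
    p = np.clip(np.asarray(p_raw, dtype=float), -LOGIT_CLIP, LOGIT_CLIP)
    return 1.0 / (1.0 + np.exp(-p))


def auto_threshold_probability(
    p,
    classes: int = 2,
    pick: str = "only",
    floor: float = 0.0,
    round_down: bool = False,
) -> float:
    """Multi-class Otsu threshold of a normalized probability map.

    With 3 classes, ``pick`` selects the lower or higher of the two Otsu
    thresholds.  The result is floored at ``floor`` and optionally rounded
    down to one decimal.
    """
    p = np.asarray(p, dtype=float)
    if p.min() == p.max():
        raise ValueError("constant probability map")
    if classes == 2:
        t = float(filters.threshold_otsu(p))
    elif classes == 3:
        lo_t, hi_t = filters.threshold_multiotsu(p, classes=3)
        if pick == "lower":
            t = float(lo_t)
        elif pick == "higher":
            t = float(hi_t)
        else:
            raise ValueError("3-class thresholding needs pick='lower' or 'higher'")
    else:
        raise ValueError("classes must be 2 or 3")
    t = max(t, floor)
    if round_down:
        t = np.floor(t * 10.0) / 10.0
    return t


def local_sd(x: np.ndarray, P: int) -> np.ndarray:
    """Population SD over a P-wide hypercube window, symmetric edge padding."""
    if P < 1 or P % 2 == 0:
        raise ValueError("P must be odd and >= 1")
    if P == 1:
        return np.zeros_like(np.asarray(x, dtype=float))
    x = np.asarray(x, dtype=float)
    m = ndi.uniform_filter(x, size=P, mode="reflect")
    m2 = ndi.uniform_filter(x * x, size=P, mode="reflect")
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


def contrast_score(gx, gy, p=None, P: int = 9, use_p: bool = True) -> float:
    """Mean weighted local-SD of the two gradient components.

    High values indicate crisp per-object gradient structure at the scale
    the predictor was run with; uniform fields score exactly 0.
    """
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    if gx.shape != gy.shape:
        raise ValueError("component shape mismatch")
    w = 1.0
    if use_p and p is not None:
        p = np.asarray(p, dtype=float)
        if p.shape != gx.shape:
            raise ValueError("weight shape mismatch")
        w = p
    score = w * (local_sd(gx, P) + local_sd(gy, P))
    return float(np.mean(score))


def scan_diameter(
    predictor,
    image2d: np.ndarray,
    d_low: float = 10.0,
    d_high: float = 120.0,
    step: float = 5.0,
    P: int = 9,
    window: int = 5,
    use_p: bool = True,
) -> ContrastScoreCurve:
    """Scan candidate diameters, score each and smooth the score curve.

    ``predictor(image2d, d)`` must return ``(gx, gy, p_raw)``.  The raw
    probability is logistic-normalized and used as the pixel weight.  The
    curve is smoothed by a centered moving average (symmetric padding) and
    ``d_opt`` is the argmax of the smoothed curve.
    """
    if d_low >= d_high:
        raise ValueError("d_low must be < d_high")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    diameters = np.arange(d_low, d_high + 1e-9, step)
    scores = []
    for d in diameters:
        try:
            gx, gy, p_raw = predictor(image2d, d)
        except Exception as exc:
            raise RuntimeError(f"predictor failed at diameter {d}") from exc
        p = normalize_probability(p_raw) if p_raw is not None else None
        scores.append(contrast_score(gx, gy, p=p, P=P, use_p=use_p))
    scores = np.asarray(scores)
    if window == 1:
        smoothed = scores.copy()
    else:
        half = window // 2
        padded = np.pad(scores, half, mode="symmetric")
        kernel = np.ones(window) / window
        smoothed = np.convolve(padded, kernel, mode="valid")
    d_opt = float(diameters[int(np.argmax(smoothed))])
    return ContrastScoreCurve(diameters, scores, smoothed, window, d_opt)


def select_reference_slice(v, strategy: str = "focus", index: int | None = None) -> int:
    """Pick the 2D reference slice used for 3D diameter tuning.

    ``focus`` picks the slice with the highest mean Sobel magnitude (the
    most in-focus slice); ``intensity`` the brightest; ``mid`` the middle;
    ``index`` a user-chosen slice.
    """
    data = _data(v)
    n = data.shape[0]
    if n < 1:
        raise ValueError("need at least one slice")
    if strategy == "focus":
        return int(np.argmax([np.mean(filters.sobel(data[i])) for i in range(n)]))
    if strategy == "intensity":
        return int(np.argmax(data.reshape(n, -1).mean(axis=1)))
    if strategy == "mid":
        return n // 2
    if strategy == "index":
        if index is None or not 0 <= index < n:
            raise ValueError("index out of range")
        return index
    raise ValueError(f"unknown strategy {strategy!r}")
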