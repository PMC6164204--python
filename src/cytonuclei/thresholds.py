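"""Histogram thresholding: six global criteria plus local adaptive thresholding.

All global selectors share one convention: a threshold t in [0, 254] splits
the 256-level histogram into a "below" class {0..t} and an "above" class
{t+1..255}, and ``apply_threshold`` marks pixels with intensity <= t as
foreground (nuclei are dark).  Each selector is a pure criterion function of
(histogram, t) evaluated by one shared exhaustive optimizer over all 255
candidate splits; ties are broken toward the smallest t.  The only iterative
selector is Isodata, whose defining procedure is a fixed-point iteration on
the midpoint of the two class means.

Criteria implemented:

* Otsu            -- minimize the within-class (intraclass) variance.
* Isodata         -- iterate t <- (mu_below + mu_above)/2 from the global mean.
* Maximum entropy -- Kapur: maximize the sum of the Shannon entropies of the
                     two class-conditional distributions.
* Cross entropy   -- Li & Lee: minimize the cross entropy between the image
                     and its two-level reconstruction (intensities shifted by
                     +1 for log-domain safety).
* Fuzzy entropy   -- minimize the total fuzzy (Shannon) entropy of
                     distance-to-class-mean memberships.
* Minimum error   -- Kittler & Illingworth: minimize the Gaussian
                     classification-error criterion J(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateHistogramError

__all__ = [
    "Threshold",
    "compute_histogram",
    "otsu_criterion",
    "max_entropy_criterion",
    "cross_entropy_criterion",
    "fuzzy_entropy_criterion",
    "min_error_criterion",
    "exhaustive_threshold",
    "otsu_threshold",
    "isodata_threshold",
    "max_entropy_threshold",
    "cross_entropy_threshold",
    "fuzzy_entropy_threshold",
    "min_error_threshold",
    "adaptive_threshold",
    "apply_threshold",
]

_LEVELS = np.arange(256, dtype=np.float64)


@dataclass(frozen=True)
class Threshold:
    """A selected gray-level threshold and the criterion value attaining it."""

    t: int
    criterion_value: float
    criterion_name: str


def compute_histogram(image: np.ndarray) -> np.ndarray:
    """Normalized 256-bin intensity histogram; float intensities are rounded."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot build a histogram from an empty image")
    levels = np.clip(np.rint(image), 0, 255).astype(np.intp)
    hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    return hist / hist.sum()


def _check_hist(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.count_nonzero(p) < 2:
        raise DegenerateHistogramError("histogram needs at least 2 nonempty bins")
    return p


def _split(p: np.ndarray, t: int):
    """Class masses and (mass-weighted) slices below/above the split."""
    w0 = p[: t + 1].sum()
    w1 = p[t + 1 :].sum()
    return w0, w1


# ---------------------------------------------------------------------------
# Pure criterion functions of (histogram, t).  Each returns np.nan for an
# inadmissible split (e.g. an empty class where the criterion is undefined).
# ---------------------------------------------------------------------------

def otsu_criterion(p: np.ndarray, t: int) -> float:
    """Within-class variance sigma_w^2(t) = w0*var0 + w1*var1 (minimize)."""
    w0, w1 = _split(p, t)
    sigma = 0.0
    if w0 > 0:
        mu0 = (p[: t + 1] * _LEVELS[: t + 1]).sum() / w0
        sigma += (p[: t + 1] * (_LEVELS[: t + 1] - mu0) ** 2).sum()
    if w1 > 0:
        mu1 = (p[t + 1 :] * _LEVELS[t + 1 :]).sum() / w1
        sigma += (p[t + 1 :] * (_LEVELS[t + 1 :] - mu1) ** 2).sum()
    return float(sigma)


def max_entropy_criterion(p: np.ndarray, t: int) -> float:
    """Kapur's criterion H_below(t) + H_above(t) (maximize); 0*log0 := 0."""
    w0, w1 = _split(p, t)
    if w0 <= 0 or w1 <= 0:
        return np.nan
    h = 0.0
    for cls, w in ((p[: t + 1], w0), (p[t + 1 :], w1)):
        q = cls[cls > 0] / w
        h -= float((q * np.log(q)).sum())
    return h


def cross_entropy_criterion(p: np.ndarray, t: int) -> float:
    """Li-Lee cross entropy (minimize), with intensities shifted by +1."""
    w0, w1 = _split(p, t)
    if w0 <= 0 or w1 <= 0:
        return np.nan
    g = _LEVELS + 1.0
    eta = 0.0
    for sl in (slice(0, t + 1), slice(t + 1, 256)):
        w = p[sl].sum()
        mu = (p[sl] * g[sl]).sum() / w
        eta += float((g[sl] * p[sl] * np.log(g[sl] / mu)).sum())
    return eta


def fuzzy_entropy_criterion(p: np.ndarray, t: int) -> float:
    """Total fuzzy entropy of distance-to-class-mean memberships (minimize).

    Membership of gray level g to its class is mu(g) = 1/(1 + |g - m|/C)
    with m the class mean and C the occupied gray-level range; each level
    contributes p_g * S(mu) with S the Shannon function of a fuzzy bit.
    """
    w0, w1 = _split(p, t)
    if w0 <= 0 or w1 <= 0:
        return np.nan
    occupied = np.nonzero(p)[0]
    c = float(occupied[-1] - occupied[0])
    if c <= 0:
        return np.nan
    e = 0.0
    for sl in (slice(0, t + 1), slice(t + 1, 256)):
        w = p[sl].sum()
        m = (p[sl] * _LEVELS[sl]).sum() / w
        mu = 1.0 / (1.0 + np.abs(_LEVELS[sl] - m) / c)
        s = np.zeros_like(mu)
        inner = (mu > 0) & (mu < 1)
        mi = mu[inner]
        s[inner] = -mi * np.log(mi) - (1 - mi) * np.log(1 - mi)
        e += float((p[sl] * s).sum())
    return e


def min_error_criterion(p: np.ndarray, t: int) -> float:
    """Kittler-Illingworth minimum-error criterion J(t) (minimize).

    J = 1 + 2*(P1*ln(s1) + P2*ln(s2)) - 2*(P1*ln(P1) + P2*ln(P2)); splits
    where either class is empty or has zero variance are inadmissible.
    """
    w0, w1 = _split(p, t)
    if w0 <= 0 or w1 <= 0:
        return np.nan
    j = 1.0
    for sl, w in ((slice(0, t + 1), w0), (slice(t + 1, 256), w1)):
        mu = (p[sl] * _LEVELS[sl]).sum() / w
        var = (p[sl] * (_LEVELS[sl] - mu) ** 2).sum() / w
        if var <= 0:
            return np.nan
        j += 2.0 * w * np.log(np.sqrt(var)) - 2.0 * w * np.log(w)
    return float(j)


# ---------------------------------------------------------------------------
# Shared optimizer and the public selectors
# ---------------------------------------------------------------------------

def exhaustive_threshold(criterion, p: np.ndarray, maximize: bool, name: str) -> Threshold:
    """Evaluate ``criterion`` at every split t in [0, 254] and return the
    arg-optimum.  NaN values are inadmissible.  Ties — including floating
    near-ties within 1e-9 (relative) of the optimum — go to the smallest t.
    """
    p = _check_hist(p)
    values = np.array([criterion(p, t) for t in range(255)])
    admissible = ~np.isnan(values)
    if not admissible.any():
        raise DegenerateHistogramError(f"no admissible threshold for {name}")
    scored = np.where(admissible, values, -np.inf if maximize else np.inf)
    opt = scored.max() if maximize else scored.min()
    tol = 1e-9 * max(1.0, abs(opt))
    tied = scored >= opt - tol if maximize else scored <= opt + tol
    t = int(np.argmax(tied))  # first (smallest) t within tolerance of the optimum
    return Threshold(t=t, criterion_value=float(values[t]), criterion_name=name)


def otsu_threshold(p: np.ndarray) -> Threshold:
    return exhaustive_threshold(otsu_criterion, p, maximize=False, name="otsu")


def max_entropy_threshold(p: np.ndarray) -> Threshold:
    return exhaustive_threshold(max_entropy_criterion, p, maximize=True, name="max_entropy")


def cross_entropy_threshold(p: np.ndarray) -> Threshold:
    return exhaustive_threshold(cross_entropy_criterion, p, maximize=False, name="cross_entropy")


def fuzzy_entropy_threshold(p: np.ndarray) -> Threshold:
    return exhaustive_threshold(fuzzy_entropy_criterion, p, maximize=False, name="fuzzy_entropy")


def min_error_threshold(p: np.ndarray) -> Threshold:
    return exhaustive_threshold(min_error_criterion, p, maximize=False, name="min_error")


def isodata_threshold(p: np.ndarray, tol: float = 0.5, max_iter: int = 100) -> Threshold:
    """Isodata iteration: t <- (mu_below(t) + mu_above(t)) / 2.

    Starts from the global histogram mean and stops when the update moves by
    less than ``tol`` gray levels (or after ``max_iter`` iterations).  If one
    class is empty at an iterate, its mean is taken as t itself, which keeps
    the map well defined.  Returns the rounded fixed point; the residual
    |t - midpoint| at the returned t is stored as the criterion value.
    """
    p = _check_hist(p)
    t = float((p * _LEVELS).sum())

    def midpoint(t: float) -> float:
        below = _LEVELS <= t
        wb, wa = p[below].sum(), p[~below].sum()
        mu_b = (p[below] * _LEVELS[below]).sum() / wb if wb > 0 else t
        mu_a = (p[~below] * _LEVELS[~below]).sum() / wa if wa > 0 else t
        return 0.5 * (mu_b + mu_a)

    for _ in range(max_iter):
        t_next = midpoint(t)
        if abs(t_next - t) < tol:
            t = t_next
            break
        t = t_next
    # Round to the neighbouring integer level with the smaller residual.
    candidates = {int(np.clip(np.floor(t), 0, 255)), int(np.clip(np.ceil(t), 0, 255))}
    t_int = min(candidates, key=lambda c: (abs(midpoint(c) - c), c))
    return Threshold(t=t_int, criterion_value=abs(midpoint(t_int) - t_int),
                     criterion_name="isodata")


def adaptive_threshold(image: np.ndarray, window: int = 12, offset: float = 5.0) -> np.ndarray:
    """Local mean thresholding: foreground iff intensity < local_mean - offset.

    The local mean is taken over a window x window neighbourhood with reflect
    padding.  An even window is honoured as-is, anchored top-left of the
    center pixel (rows [i - w/2, i + w/2 - 1]).  The default window of 12 and
    offset of 5 gray levels suit dark nuclei on a locally brighter surround.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    if window >= max(image.shape):
        # window covers the whole image: local mean degenerates to global mean
        local_mean = np.full_like(image, image.mean())
    else:
        local_mean = ndimage.uniform_filter(image, size=window, mode="reflect")
    return image < local_mean - offset


def apply_threshold(image: np.ndarray, t: Threshold | int) -> np.ndarray:
    """Binary mask of dark pixels: foreground iff intensity <= t."""
    level = t.t if isinstance(t, Threshold) else int(t)
    if not 0 <= level <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {level}")
    return np.asarray(image) <= level
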