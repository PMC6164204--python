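"""Independent brute-force oracles used by the tests.

Everything here deliberately recomputes quantities through a different route
than the package (explicit slicing, np.average/np.var, per-candidate loops)
so that agreement is meaningful.
"""

import numpy as np

LEVELS = np.arange(256, dtype=float)


def random_histogram(rng: np.random.Generator) -> np.ndarray:
    """A normalized mixture of 1-3 discretized Gaussians over 256 levels."""
    k = int(rng.integers(1, 4))
    means = rng.uniform(10, 245, size=k)
    sigmas = rng.uniform(5, 30, size=k)
    weights = rng.dirichlet(np.ones(k))
    p = np.zeros(256)
    for m, s, w in zip(means, sigmas, weights):
        p += w * np.exp(-((LEVELS - m) ** 2) / (2 * s * s))
    return p / p.sum()


def _class_stats(p, sl):
    w = p[sl].sum()
    if w <= 0:
        return 0.0, None, None
    mean = np.average(LEVELS[sl], weights=p[sl])
    var = np.average((LEVELS[sl] - mean) ** 2, weights=p[sl])
    return w, mean, var


def oracle_within_class_variance(p, t):
    lo, hi = slice(0, t + 1), slice(t + 1, 256)
    total = 0.0
    for sl in (lo, hi):
        w, _, var = _class_stats(p, sl)
        if w > 0:
            total += w * var
    return total


def oracle_kapur_entropy(p, t):
    lo, hi = slice(0, t + 1), slice(t + 1, 256)
    h = 0.0
    for sl in (lo, hi):
        w = p[sl].sum()
        if w <= 0:
            return np.nan
        q = p[sl][p[sl] > 0] / w
        h += -(q * np.log(q)).sum()
    return h


def oracle_li_cross_entropy(p, t):
    g = LEVELS + 1.0
    eta = 0.0
    for sl in (slice(0, t + 1), slice(t + 1, 256)):
        w = p[sl].sum()
        if w <= 0:
            return np.nan
        mu = np.average(g[sl], weights=p[sl])
        eta += sum(g[i] * p[i] * np.log(g[i] / mu)
                   for i in range(sl.start, sl.stop) if p[i] > 0)
    return eta


def oracle_fuzzy_entropy(p, t):
    occupied = np.nonzero(p)[0]
    c = occupied[-1] - occupied[0]
    if c <= 0:
        return np.nan
    total = 0.0
    for sl in (slice(0, t + 1), slice(t + 1, 256)):
        w = p[sl].sum()
        if w <= 0:
            return np.nan
        mean = np.average(LEVELS[sl], weights=p[sl])
        for i in range(sl.start, sl.stop):
            if p[i] <= 0:
                continue
            mu = 1.0 / (1.0 + abs(i - mean) / c)
            if 0 < mu < 1:
                total += p[i] * (-mu * np.log(mu) - (1 - mu) * np.log(1 - mu))
    return total


def oracle_kittler_criterion(p, t):
    j = 1.0
    for sl in (slice(0, t + 1), slice(t + 1, 256)):
        w, _, var = _class_stats(p, sl)
        if w <= 0 or var is None or var <= 0:
            return np.nan
        j += 2 * w * np.log(np.sqrt(var)) - 2 * w * np.log(w)
    return j


def exhaustive_argopt(criterion, p, maximize):
    """Arg-optimum of a scalar criterion over t in [0, 254].

    Ties — including floating near-ties within 1e-9 (relative) of the
    optimum — go to the smallest t, matching the package's published
    tie-breaking rule.
    """
    values = [criterion(p, t) for t in range(255)]
    finite = [v for v in values if not np.isnan(v)]
    if not finite:
        return None
    opt = max(finite) if maximize else min(finite)
    tol = 1e-9 * max(1.0, abs(opt))
    for t, v in enumerate(values):
        if np.isnan(v):
            continue
        if (v >= opt - tol) if maximize else (v <= opt + tol):
            return t
    return None


def isodata_midpoint(p, t):
    """Midpoint of the two class means at split level t (below = levels <= t)."""
    below = LEVELS <= t
    wb, wa = p[below].sum(), p[~below].sum()
    mb = np.average(LEVELS[below], weights=p[below]) if wb > 0 else t
    ma = np.average(LEVELS[~below], weights=p[~below]) if wa > 0 else t
    return 0.5 * (mb + ma)


def lloyd_oracle(x, centers, max_iter=300, tol=1e-4):
    """Plain-python Lloyd iteration from the given initial centers."""
    centers = np.array(centers, dtype=float)
    k = len(centers)
    for _ in range(max_iter):
        assign = np.array([int(np.argmin([(xi - c) ** 2 for c in centers]))
                           for xi in x])
        new = centers.copy()
        for j in range(k):
            members = x[assign == j]
            if members.size:
                new[j] = members.mean()
        if max(abs(new - centers)) < tol:
            centers = new
            break
        centers = new
    assign = np.array([int(np.argmin([(xi - c) ** 2 for c in centers])) for xi in x])
    return centers, assign


def nearest_mean_mask(image, c_fg, c_bg):
    """Pointwise classification: foreground iff strictly closer to c_fg."""
    img = np.asarray(image, dtype=float) / 255.0
    return (img - c_fg) ** 2 < (img - c_bg) ** 2
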