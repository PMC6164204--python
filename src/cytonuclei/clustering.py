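"""Intensity-clustering segmenters: k-means, fuzzy c-means, and mean shift.

All three cluster pixel intensities only (normalized to [0, 1]); spatial
coordinates are deliberately not part of the feature vector — on Pap-stained
cytology fields the nuclei are separated from everything else by darkness, so
two intensity clusters ("dark" vs "bright") suffice, and the nuclei mask is
always the cluster with the smallest center.

k-means and fuzzy c-means use deterministic percentile-based initialization
(25th/75th percentile for two clusters) so results are exactly reproducible:
a poor random initialization is a known failure mode of Lloyd-type
iterations.  Mean shift runs over the 256-bin weighted intensity histogram
instead of per pixel; for a 1-D intensity feature at 8-bit quantization this
is exact and orders of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError

__all__ = [
    "ClusterModel",
    "MeanShiftParams",
    "kmeans_segment",
    "fcm_segment",
    "meanshift_segment",
]


@dataclass
class ClusterModel:
    """Fitted clustering state returned beside the segmentation mask."""

    centers: np.ndarray                 # intensity values, normalized [0, 1]
    assignments: np.ndarray             # per-pixel cluster index, image-shaped
    n_iter: int
    memberships: np.ndarray | None = None   # (n_pixels, c), fuzzy only
    objective_history: list[float] = field(default_factory=list)
    support: np.ndarray | None = None            # occupied bin values (mean shift)
    converged_positions: np.ndarray | None = None  # where each bin converged


@dataclass(frozen=True)
class MeanShiftParams:
    """Flat-kernel mean-shift settings on normalized intensity.

    bandwidth 0.2 (of the [0, 1] intensity range) separates dark nuclei from
    the brighter cytoplasm/background modes on these images; converged points
    closer than merge_radius (default bandwidth/2) collapse into one mode.
    """

    bandwidth: float = 0.2
    convergence_tol: float = 1e-4
    max_iter: int = 100
    merge_radius: float | None = None

    def resolved_merge_radius(self) -> float:
        return self.bandwidth / 2.0 if self.merge_radius is None else self.merge_radius


def _normalized(image: np.ndarray) -> np.ndarray:
    return np.asarray(image, dtype=np.float64) / 255.0


def _percentile_centers(x: np.ndarray, k: int) -> np.ndarray:
    if k == 2:
        qs = [25.0, 75.0]
    else:
        qs = [100.0 * (i + 0.5) / k for i in range(k)]
    return np.percentile(x, qs)


def kmeans_segment(image: np.ndarray, k: int = 2, seed: int = 0):
    """Lloyd's k-means on normalized intensities; mask = darkest cluster.

    Deterministic: centers start at evenly spaced intensity percentiles
    (25th/75th for k=2) and iterate until the largest center movement falls
    below 1e-4 or 300 iterations.  ``seed`` is accepted for interface
    uniformity but unused — nothing here is random.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    img = _normalized(image)
    x = img.ravel()
    if np.unique(x).size < k:
        raise DegenerateInputError(f"image has fewer than k={k} distinct values")
    centers = _percentile_centers(x, k)
    history: list[float] = []
    assign = np.zeros(x.size, dtype=np.intp)
    n_iter = 0
    for n_iter in range(1, 301):
        d2 = (x[:, None] - centers[None, :]) ** 2
        assign = np.argmin(d2, axis=1)
        history.append(float(d2[np.arange(x.size), assign].sum()))
        new_centers = centers.copy()
        for j in range(k):
            members = x[assign == j]
            if members.size:
                new_centers[j] = members.mean()
        if np.max(np.abs(new_centers - centers)) < 1e-4:
            centers = new_centers
            break
        centers = new_centers
    assign = np.argmin((x[:, None] - centers[None, :]) ** 2, axis=1)
    model = ClusterModel(centers=centers, assignments=assign.reshape(img.shape),
                         n_iter=n_iter, objective_history=history)
    mask = model.assignments == int(np.argmin(centers))
    return mask, model


def fcm_segment(image: np.ndarray, c: int = 2, m: float = 2.0):
    """Fuzzy c-means on normalized intensities; mask = darkest cluster.

    Standard alternating updates minimizing J_m = sum u_ik^m d_ik^2:
    memberships u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1)), then centers
    v_i = sum u_ik^m x_k / sum u_ik^m.  Pixels landing exactly on a center
    get full membership there.  Stops when the largest membership change is
    below 1e-4 or after 300 iterations; defuzzification is by maximum
    membership.
    """
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    img = _normalized(image)
    x = img.ravel()
    if np.unique(x).size < c:
        raise DegenerateInputError(f"image has fewer than c={c} distinct values")
    centers = _percentile_centers(x, c)
    expo = 2.0 / (m - 1.0)
    u = None
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, 301):
        d = np.abs(x[:, None] - centers[None, :])  # (n, c)
        zero = d <= 1e-15
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-expo)
            u_new = inv / inv.sum(axis=1, keepdims=True)
        on_center = zero.any(axis=1)
        if on_center.any():
            u_new[on_center] = zero[on_center] / zero[on_center].sum(axis=1, keepdims=True)
        history.append(float(((u_new**m) * d**2).sum()))
        num = (u_new**m).T @ x
        den = (u_new**m).sum(axis=0)
        centers = np.where(den > 0, num / den, centers)
        if u is not None and np.max(np.abs(u_new - u)) < 1e-4:
            u = u_new
            break
        u = u_new
    assign = np.argmax(u, axis=1)
    model = ClusterModel(centers=centers, assignments=assign.reshape(img.shape),
                         n_iter=n_iter, memberships=u, objective_history=history)
    mask = model.assignments == int(np.argmin(centers))
    return mask, model


def meanshift_segment(image: np.ndarray, params: MeanShiftParams | None = None):
    """Flat-kernel mean shift on the weighted 256-bin intensity histogram.

    Every occupied bin's position iterates to the weighted mean of all bins
    within ``bandwidth`` of it until the shift falls below convergence_tol.
    Converged positions within merge_radius of each other merge into modes
    (weighted means); pixels inherit their bin's mode.  The mask is the
    darkest mode's cluster; a single surviving mode means there is no
    dark/bright separation and the mask is empty.
    """
    params = params or MeanShiftParams()
    if params.bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    img = _normalized(image)
    levels = np.clip(np.rint(img * 255.0), 0, 255).astype(np.intp)
    weights = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    support = np.nonzero(weights)[0]
    positions = support / 255.0
    w = weights[support]
    data = positions.copy()
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        within = np.abs(positions[:, None] - data[None, :]) <= params.bandwidth
        shifted = (within * (w * data)[None, :]).sum(axis=1) / (within * w[None, :]).sum(axis=1)
        if np.max(np.abs(shifted - positions)) < params.convergence_tol:
            positions = shifted
            break
        positions = shifted

    # Merge converged positions into modes (greedy over sorted positions).
    order = np.argsort(positions)
    merge_r = params.resolved_merge_radius()
    mode_of_point = np.empty(len(positions), dtype=np.intp)
    modes: list[float] = []
    group: list[int] = []
    for idx in order:
        if group and positions[idx] - positions[group[-1]] > merge_r:
            modes.append(float(np.average(positions[group], weights=w[group])))
            for g in group:
                mode_of_point[g] = len(modes) - 1
            group = []
        group.append(idx)
    if group:
        modes.append(float(np.average(positions[group], weights=w[group])))
        for g in group:
            mode_of_point[g] = len(modes) - 1

    bin_to_mode = np.zeros(256, dtype=np.intp)
    bin_to_mode[support] = mode_of_point
    assignments = bin_to_mode[levels]
    centers = np.array(modes)
    model = ClusterModel(centers=centers, assignments=assignments, n_iter=n_iter,
                         support=support / 255.0, converged_positions=positions)
    if len(modes) < 2:
        mask = np.zeros(img.shape, dtype=bool)
    else:
        mask = assignments == int(np.argmin(centers))
    return mask, model
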