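"""Seeded generator of cytology-like scenes with per-nucleus ground truth.

Pap-stained pleural-effusion fields show dark (purple) cell nuclei surrounded
by lighter cytoplasm against a bright background, with occasional debris and
stain artefacts.  The generator emulates exactly that structure — rotated
elliptical nuclei with a brighter cytoplasm halo on a bright field, additive
Gaussian noise, and a configurable subset of enlarged "abnormal" nuclei — so
that every downstream stage (preprocessing, segmentation, postprocessing,
evaluation) can be exercised against a known pixel-exact ground truth.

Nothing here attempts photorealism: intensities are flat per structure (plus
noise) and nuclei are perfect ellipses.  See docs/methods.md for what that
does and does not validate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import PlacementError

__all__ = [
    "NucleusSpec",
    "SceneConfig",
    "SyntheticScene",
    "rasterize_ellipse",
    "generate_scene",
    "degrade_image",
    "standard_degraded_fixture",
    "save_scene",
]


@dataclass(frozen=True)
class NucleusSpec:
    """Geometry and intensity of one simulated nucleus.

    center      -- (row, col) in pixels
    axes        -- (semi-major, semi-minor) in pixels, both > 0
    rotation    -- orientation of the major axis, radians
    mean_intensity -- nominal gray level of the nucleus interior, in [0, 255],
                      strictly below the scene's background mean
    abnormal    -- True for enlarged/irregular nuclei flagged in ground truth
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation: float
    mean_intensity: float
    abnormal: bool


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Default palette: background 220, cytoplasm 180 (= background − cytoplasm_offset),
    normal nuclei 70, abnormal nuclei 50, Gaussian noise sigma 8 — dark nuclei on a
    bright field, cytoplasm in between.
    """

    image_size: tuple[int, int] = (256, 256)
    n_nuclei: int = 8
    n_abnormal: int = 2
    background_mean: float = 220.0
    cytoplasm_offset: float = 40.0
    normal_intensity: float = 70.0
    abnormal_intensity: float = 50.0
    noise_sigma: float = 8.0
    overlap_allowed: bool = False
    min_nucleus_area: int = 100
    # Half-axis ranges the nuclei are sampled from, pixels.
    normal_axis_range: tuple[float, float] = (6.5, 12.0)
    cytoplasm_ring: float = 4.0
    # Minimum clearance between *cytoplasm* boundaries of distinct cells when
    # overlap is disallowed, pixels.  Chosen so that morphological closing at
    # the default radius cannot bridge neighbouring nuclei.
    clearance: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValueError("image_size must be at least 1x1")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not 0 <= self.n_abnormal <= self.n_nuclei:
            raise ValueError("need 0 <= n_abnormal <= n_nuclei")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.min_nucleus_area < 1:
            raise ValueError("min_nucleus_area must be >= 1")
        if not (self.normal_intensity < self.background_mean
                and self.abnormal_intensity < self.background_mean):
            raise ValueError("nucleus intensities must lie below background_mean")


@dataclass
class SyntheticScene:
    """A generated image together with its pixel-exact ground truth."""

    image: np.ndarray          # uint8 (H, W)
    gt_mask: np.ndarray        # bool (H, W), union of all nuclei
    gt_labels: np.ndarray      # int32 (H, W), 0 = background, i = i-th nucleus
    nuclei: list[NucleusSpec] = field(default_factory=list)
    config: SceneConfig | None = None


def rasterize_ellipse(
    center: tuple[float, float],
    axes: tuple[float, float],
    rotation: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean footprint of a rotated ellipse.

    A pixel belongs to the ellipse iff its *center* satisfies the ellipse
    inequality (center-in convention): with (dr, dc) the offset from the
    ellipse center rotated into the ellipse frame,
    (u/a)^2 + (v/b)^2 <= 1.
    """
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    cos, sin = np.cos(rotation), np.sin(rotation)
    u = dr * cos + dc * sin
    v = -dr * sin + dc * cos
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _sample_axes(rng: np.random.Generator, lo: float, hi: float) -> tuple[float, float]:
    a = rng.uniform(lo, hi)
    b = rng.uniform(lo, min(a, hi))
    return (a, b)


def _abnormal_axes(rng: np.random.Generator, target_area: float) -> tuple[float, float]:
    """Half-axes of an abnormal nucleus with area >= target_area."""
    area = target_area * rng.uniform(1.05, 1.4)
    aspect = rng.uniform(1.0, 1.6)
    b = np.sqrt(area / (np.pi * aspect))
    return (aspect * b, b)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render a scene from ``config``; deterministic for a fixed seed.

    Nuclei are placed by rejection sampling.  When overlap is disallowed, the
    cytoplasm footprints (nucleus axes + cytoplasm_ring) padded by
    ``clearance`` must stay disjoint; abnormal (larger) nuclei are placed
    first to ease packing.  Raises PlacementError when a non-overlapping
    layout cannot be found within the retry budget.

    The noiseless composite is: background at background_mean, a cytoplasm
    halo at background_mean - cytoplasm_offset around each nucleus, and each
    nucleus at its own mean intensity.  gt_labels records each nucleus
    footprint before noise; i.i.d. Gaussian noise of noise_sigma is then
    added and the result clipped to [0, 255] and quantized to uint8.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    cyto_value = config.background_mean - config.cytoplasm_offset

    # --- sample nucleus geometries -----------------------------------------
    lo, hi = config.normal_axis_range
    n_normal = config.n_nuclei - config.n_abnormal
    normal_axes = [_sample_axes(rng, lo, hi) for _ in range(n_normal)]
    if normal_axes:
        mean_normal_area = float(np.mean([np.pi * a * b for a, b in normal_axes]))
    else:
        mean_normal_area = np.pi * ((lo + hi) / 2) ** 2
    # Invariant: abnormal nuclei have area >= 1.5x the normal-nucleus mean area.
    abnormal_axes = [
        _abnormal_axes(rng, 1.5 * mean_normal_area) for _ in range(config.n_abnormal)
    ]

    # Large nuclei first.
    geoms = [(ax, True) for ax in abnormal_axes] + [(ax, False) for ax in normal_axes]

    occupied = np.zeros((h, w), dtype=bool)  # padded cell footprints so far
    specs: list[NucleusSpec] = []
    pad = config.cytoplasm_ring + config.clearance
    for axes, abnormal in geoms:
        a, b = axes
        placed = False
        for _ in range(500):
            center = (rng.uniform(a, h - a), rng.uniform(a, w - a))
            rotation = rng.uniform(0.0, np.pi)
            if not config.overlap_allowed:
                padded = rasterize_ellipse(center, (a + pad, b + pad), rotation, (h, w))
                if (padded & occupied).any():
                    continue
                occupied |= padded
            base = config.abnormal_intensity if abnormal else config.normal_intensity
            intensity = float(np.clip(base + rng.uniform(-5.0, 5.0), 0.0, 254.0))
            specs.append(NucleusSpec(center, (a, b), rotation, intensity, abnormal))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {len(specs) + 1}/{config.n_nuclei} "
                f"without overlap on a {h}x{w} canvas"
            )

    # --- paint --------------------------------------------------------------
    clean = np.full((h, w), config.background_mean, dtype=np.float64)
    gt_labels = np.zeros((h, w), dtype=np.int32)
    # Cytoplasm halos first so no halo overwrites another cell's nucleus.
    for spec in specs:
        a, b = spec.axes
        ring = config.cytoplasm_ring
        halo = rasterize_ellipse(spec.center, (a + ring, b + ring), spec.rotation, (h, w))
        clean[halo] = cyto_value
    for i, spec in enumerate(specs, start=1):
        body = rasterize_ellipse(spec.center, spec.axes, spec.rotation, (h, w))
        clean[body] = spec.mean_intensity
        # Later nuclei overwrite earlier labels on contested pixels.
        gt_labels[body] = i

    noisy = clean
    if config.noise_sigma > 0:
        noisy = clean + rng.normal(0.0, config.noise_sigma, size=(h, w))
    image = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    return SyntheticScene(
        image=image,
        gt_mask=gt_labels > 0,
        gt_labels=gt_labels,
        nuclei=specs,
        config=config,
    )


def degrade_image(
    image: np.ndarray,
    noise_sigma: float,
    n_artefacts: int,
    seed: int,
    max_artefact_area: int = 40,
) -> np.ndarray:
    """Add Gaussian noise and small dark stain-like speckles to an image.

    Emulates the debris/noise/stained artefacts of real acquisitions.  Each
    artefact is a dark disk of area < ``max_artefact_area`` (well below any
    plausible nucleus area).  With noise_sigma == 0 and n_artefacts == 0 the
    input is returned unchanged.  Deterministic per seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0 and n_artefacts == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    out = np.asarray(image, dtype=np.float64).copy()
    h, w = out.shape
    max_radius = max(1, int(np.sqrt(max_artefact_area / np.pi)) - 1)
    for _ in range(n_artefacts):
        r = int(rng.integers(1, max_radius + 1))
        cr = float(rng.uniform(r + 1, h - r - 1))
        cc = float(rng.uniform(r + 1, w - r - 1))
        spot = rasterize_ellipse((cr, cc), (r, r), 0.0, (h, w))
        out[spot] = rng.uniform(40.0, 80.0)
    if noise_sigma > 0:
        out += rng.normal(0.0, noise_sigma, size=out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def standard_degraded_fixture(
    seed: int = 0,
    contrast: float = 0.3,
    n_impulses: int = 300,
    noise_sigma: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A (clean, degraded) pair emulating a poor acquisition.

    Models the three defects preprocessing has to cope with on real slides:
    weak stain contrast (cell structures reduced to ``contrast`` times their
    nominal deviation from background), a strong uneven-illumination ramp
    spanning the full dynamic range, and — in the degraded copy — dark
    single-pixel impulse speckles (debris) plus additive Gaussian noise.
    Used to rank the denoising filters by PSNR against the clean copy and the
    contrast enhancers by CII.
    """
    scene = generate_scene(SceneConfig(seed=seed, noise_sigma=0))
    base = scene.image.astype(np.float64)
    h, w = base.shape
    deviations = (base - 220.0) * contrast
    cc = np.arange(w, dtype=np.float64)[None, :]
    illumination = 255.0 * (cc / (w - 1) - 0.5)
    clean = np.clip(128.0 + deviations + illumination, 0, 255)
    rng = np.random.default_rng(seed + 1)
    degraded = clean.copy()
    idx = rng.choice(h * w, size=n_impulses, replace=False)
    degraded.ravel()[idx] = rng.uniform(0.0, 40.0, size=n_impulses)
    degraded = np.clip(degraded + rng.normal(0.0, noise_sigma, degraded.shape), 0, 255)
    return clean, degraded


def save_scene(scene: SyntheticScene, directory: str | Path, stem: str = "scene") -> None:
    """Write image + mask as 8-bit PNG and nucleus metadata as a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{stem}.png", scene.image)
    iio.imwrite(directory / f"{stem}_mask.png",
                (scene.gt_mask.astype(np.uint8) * 255))
    np.savetxt(directory / f"{stem}_labels.txt", scene.gt_labels, fmt="%d")
    meta = [asdict(spec) for spec in scene.nuclei]
    (directory / f"{stem}_nuclei.json").write_text(json.dumps(meta, indent=2))
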