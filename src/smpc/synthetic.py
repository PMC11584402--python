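"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: Gaussian-PSF
single-molecule field-of-view (FOV) images with optional photobleaching
stacks, hyperbolic probe-binding titrations, four-parameter-logistic
viability curves, JC-1 depolarization time series, and whole cohorts of
22-metric PPI profiles with a known linear relation to the ex vivo AUC.

All generators are pure functions of their parameters and a seed:
identical calls return identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import FovImage
from .model import EfficacyModel, transform_metrics
from .registry import (
    INTENSITY_METRICS,
    METRIC_REGISTRY,
    validate_metric_names,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PackingError",
    "gen_fov_image",
    "gen_photobleach_stack",
    "gen_titration",
    "gen_dose_response",
    "gen_cohort",
    "gen_bh3_timeseries",
    "default_ground_truth_model",
    "default_metric_logmeans",
    "default_metric_logsds",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Imaging-simulation parameters.

    Defaults emulate the acquisition geometry used throughout the
    package: a 100 x 100 um^2 FOV sampled at 0.1 um/px (1000 px per
    side), 5 frames per image, and a diffraction-limited isotropic
    Gaussian PSF of sigma 1.3 px (~130 nm). ``spot_intensity_mean/sd``
    set the per-spot peak amplitude distribution; ``noise_sd`` is the
    additive per-pixel Gaussian camera noise on top of a constant
    ``background_level``.
    """

    seed: int
    fov_px: int = 1000
    um_per_px: float = 0.1
    psf_sigma: float = 1.3
    spot_intensity_mean: float = 400.0
    spot_intensity_sd: float = 40.0
    background_level: float = 100.0
    noise_sd: float = 8.0
    n_frames: int = 5

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.fov_px <= 0 or self.um_per_px <= 0:
            raise ValueError("FOV geometry must be positive")

    @property
    def fov_um(self) -> float:
        return self.fov_px * self.um_per_px


@dataclass
class GroundTruth:
    """What a generator actually put into its output."""

    true_spot_count: int = 0
    true_coordinates: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    bleach_frames: np.ndarray | None = None  # per-spot first dark frame (1-based)
    amplitudes: np.ndarray | None = None
    true_kd: float | None = None
    true_coefficients: dict | None = None
    true_intercept: float | None = None
    true_ic50: float | None = None
    true_hill: float | None = None
    true_depolarization: float | None = None


class PackingError(RuntimeError):
    """Requested spot count cannot be packed at the minimum separation."""


# ---------------------------------------------------------------------------
# FOV images
# ---------------------------------------------------------------------------

def _place_spots(n, size, margin, min_separation, rng):
    """Uniform placement, optionally with a hard minimum pair distance."""
    if n == 0:
        return np.empty((0, 2))
    lo, hi = margin, size - margin
    if hi <= lo:
        raise ValueError("FOV too small for the spot margin")
    if min_separation is None:
        return rng.uniform(lo, hi, size=(n, 2))
    # spatial-hash rejection sampling; cells of side min_separation
    cell = float(min_separation)
    grid: dict[tuple[int, int], list[np.ndarray]] = {}
    pts: list[np.ndarray] = []
    attempts, limit = 0, 500 * n
    while len(pts) < n:
        attempts += 1
        if attempts > limit:
            raise PackingError(
                f"could not place {n} spots with separation {min_separation} "
                f"in a {size} px FOV"
            )
        p = rng.uniform(lo, hi, size=2)
        cx, cy = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for q in grid.get((cx + dx, cy + dy), ()):
                    if np.hypot(*(p - q)) < min_separation:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((cx, cy), []).append(p)
            pts.append(p)
    return np.array(pts)


def _render_spots(shape, coords, amplitudes, sigma):
    """Sum of isotropic 2-D Gaussians, rendered on +-4 sigma patches."""
    img = np.zeros(shape)
    r = int(np.ceil(4 * sigma))
    ax = np.arange(-r, r + 1)
    h, w = shape
    for (x, y), a in zip(coords, amplitudes):
        ix, iy = int(round(x)), int(round(y))
        gx = np.exp(-((ax + ix - x) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ax + iy - y) ** 2) / (2 * sigma**2))
        x0, x1 = max(ix - r, 0), min(ix + r + 1, w)
        y0, y1 = max(iy - r, 0), min(iy + r + 1, h)
        img[y0:y1, x0:x1] += a * np.outer(
            gy[y0 - (iy - r): y1 - (iy - r)], gx[x0 - (ix - r): x1 - (ix - r)]
        )
    return img


def gen_fov_image(
    n_spots: int,
    config: SimulationConfig,
    non_overlapping: bool = True,
    min_separation: float | None = None,
) -> tuple[FovImage, GroundTruth]:
    """One FOV image: background + Gaussian spots + pixel noise.

    In non-overlapping mode (default) spot centres keep a minimum pair
    distance of ``min_separation`` px (default 4 * psf_sigma, rounded up)
    so that every spot is resolvable; a :class:`PackingError` is raised
    when ``n_spots`` exceeds the packing capacity. With
    ``non_overlapping=False`` centres are uniform and may overlap.
    """
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")
    rng = np.random.default_rng(config.seed)
    sep = None
    if non_overlapping:
        sep = float(min_separation if min_separation is not None
                    else np.ceil(4 * config.psf_sigma))
    margin = int(np.ceil(4 * config.psf_sigma))
    coords = _place_spots(n_spots, config.fov_px, margin, sep, rng)
    amps = rng.normal(config.spot_intensity_mean, config.spot_intensity_sd,
                      size=n_spots).clip(min=1.0)
    clean = _render_spots((config.fov_px, config.fov_px), coords, amps,
                          config.psf_sigma)
    img = (clean + config.background_level
           + rng.normal(0.0, config.noise_sd, size=clean.shape))
    truth = GroundTruth(true_spot_count=n_spots, true_coordinates=coords,
                        amplitudes=amps)
    return FovImage(pixels=img, um_per_px=config.um_per_px), truth


def gen_photobleach_stack(
    n_spots: int,
    n_frames: int,
    bleach_prob: float,
    config: SimulationConfig,
    non_overlapping: bool = True,
    min_separation: float | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Frame stack in which each spot bleaches in a single step.

    A spot survives each frame-to-frame transition with probability
    ``1 - bleach_prob``, so the expected surviving fraction at frame t
    (0-based) is ``(1 - bleach_prob) ** t``. Returns the stack with shape
    ``(n_frames, fov_px, fov_px)`` and the per-spot first dark frame.
    """
    if not 0.0 < bleach_prob < 1.0:
        raise ValueError("bleach_prob must be in (0, 1)")
    if n_frames < 2:
        raise ValueError("need at least 2 frames for a bleaching trace")
    rng = np.random.default_rng(config.seed)
    sep = None
    if non_overlapping:
        sep = float(min_separation if min_separation is not None
                    else np.ceil(4 * config.psf_sigma))
    margin = int(np.ceil(4 * config.psf_sigma))
    coords = _place_spots(n_spots, config.fov_px, margin, sep, rng)
    amps = rng.normal(config.spot_intensity_mean, config.spot_intensity_sd,
                      size=n_spots).clip(min=1.0)
    # geometric(p) >= 1: spot is bright in frames 0 .. bleach-1
    bleach = rng.geometric(bleach_prob, size=n_spots) if n_spots else np.empty(0, int)
    frames = []
    for t in range(n_frames):
        alive = bleach > t
        clean = _render_spots((config.fov_px, config.fov_px),
                              coords[alive], amps[alive], config.psf_sigma)
        frames.append(clean + config.background_level
                      + rng.normal(0.0, config.noise_sd, size=clean.shape))
    truth = GroundTruth(true_spot_count=n_spots, true_coordinates=coords,
                        amplitudes=amps, bleach_frames=bleach)
    return np.stack(frames), truth


# ---------------------------------------------------------------------------
# titrations, dose-response, BH3 time series
# ---------------------------------------------------------------------------

def gen_titration(
    true_kd: float,
    probe_concs,
    n_baits: int = 2000,
    noise_model: str = "none",
    seed: int | None = None,
):
    """Probe-binding titration with hyperbolic occupancy.

    Expected bound count at probe concentration c is
    ``n_baits * c / (Kd + c)``. ``noise_model='binomial'`` draws each
    bound count from Binomial(n_baits, occupancy); ``'none'`` returns the
    expectation exactly.
    """
    from .assays import TitrationSeries

    concs = np.asarray(probe_concs, dtype=float)
    if (concs < 0).any():
        raise ValueError("probe concentrations must be non-negative")
    if true_kd <= 0:
        raise ValueError("true_kd must be positive")
    if n_baits <= 0:
        raise ValueError("n_baits must be positive")
    occ = concs / (true_kd + concs)
    if noise_model == "none":
        bound = n_baits * occ
    elif noise_model == "binomial":
        if seed is None:
            raise ValueError("binomial noise requires a seed")
        rng = np.random.default_rng(seed)
        bound = rng.binomial(n_baits, occ).astype(float)
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    baits = np.full_like(concs, float(n_baits))
    return TitrationSeries(probe_concs=concs, bound_counts=bound,
                           bait_counts=baits)


#: Concentration grid (nM) covering the tested 0-1 uM window.
DEFAULT_CONC_GRID = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)


def gen_dose_response(
    ic50: float,
    hill: float,
    top: float = 100.0,
    bottom: float = 0.0,
    conc_grid=DEFAULT_CONC_GRID,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Viability table from a four-parameter logistic curve.

    ``viability = bottom + (top - bottom) / (1 + (c / ic50)^hill)`` plus
    optional Gaussian noise (percentage points). The zero concentration
    is always included.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    concs = np.asarray(conc_grid, dtype=float)
    if 0.0 not in concs:
        concs = np.concatenate([[0.0], concs])
    concs = np.sort(concs)
    with np.errstate(divide="ignore"):
        ratio = np.where(concs > 0, (concs / ic50) ** hill, 0.0)
    viab = bottom + (top - bottom) / (1.0 + ratio)
    if noise_sd > 0:
        if seed is None:
            raise ValueError("noisy dose-response requires a seed")
        rng = np.random.default_rng(seed)
        viab = viab + rng.normal(0.0, noise_sd, size=viab.shape)
    return pd.DataFrame({"conc_nM": concs, "viability_pct": viab})


def gen_bh3_timeseries(
    depol_frac: float,
    duration_min: float = 180.0,
    interval_min: float = 5.0,
    rfu_scales: tuple[float, float] = (1000.0, 100.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """JC-1 RFU time series for a sample plus DMSO and FCCP controls.

    The DMSO control sags slowly from the high scale; the FCCP control
    collapses quickly towards the low scale. The sample series is the
    pointwise mixture ``(1 - f) * DMSO + f * FCCP`` so that the AUC-based
    depolarization statistic recovers ``f`` exactly in the noise-free
    case. Returns a long table (time_min, rfu, condition).
    """
    if not 0.0 <= depol_frac <= 1.0:
        raise ValueError("depol_frac must lie in [0, 1]")
    high, low = rfu_scales
    t = np.arange(0.0, duration_min + 0.5 * interval_min, interval_min)
    dmso = high * (1.0 - 0.2 * t / duration_min)
    fccp = low + (high - low) * np.exp(-t / 15.0)
    sample = (1.0 - depol_frac) * dmso + depol_frac * fccp
    frames = []
    for cond, series in (("sample", sample), ("DMSO", dmso), ("FCCP", fccp)):
        rfu = series
        if noise_sd > 0:
            if seed is None:
                raise ValueError("noisy BH3 series requires a seed")
            rng = np.random.default_rng(
                (seed, zlib.crc32(cond.encode()) % (2**31)))
            rfu = rfu + rng.normal(0.0, noise_sd, size=rfu.shape)
        frames.append(pd.DataFrame(
            {"time_min": t, "rfu": rfu, "condition": cond}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def default_metric_logmeans() -> dict[str, float]:
    """Per-metric log2 means: levels > PBA > complex counts; intensity
    metrics live on the a.u. scale (around 2e7)."""
    out = {}
    for name in METRIC_REGISTRY:
        if name in INTENSITY_METRICS:
            out[name] = 24.5
        elif name.endswith("LV"):
            out[name] = 11.0
        elif name.endswith("PBA"):
            out[name] = 10.5
        else:
            out[name] = 9.5
    return out


def default_metric_logsds() -> dict[str, float]:
    return {name: 1.0 for name in METRIC_REGISTRY}


def default_ground_truth_model(
    drug: str = "ABT-199",
    mean_score: float = 0.55,
) -> EfficacyModel:
    """Ground-truth linear model used by the cohort generator.

    The panel is the drug's driver/resistance combination (two positive
    BCL2 metrics, one negative BCLxL metric); the intercept is set so the
    expected score under the default metric distribution is
    ``mean_score``, placing both responder classes well inside the
    cohort.
    """
    coefs = {
        "BCL2-BIM_BH3 PBA": 0.12,
        "BCL2-BAX CPX": 0.157,
        "BCLxL-BAK CPX": -0.05,
    }
    logmeans = default_metric_logmeans()
    intercept = mean_score - sum(c * logmeans[m] for m, c in coefs.items())
    return EfficacyModel(
        drug=drug,
        metric_names=tuple(coefs),
        coefficients=tuple(coefs.values()),
        intercept=intercept,
    )


def gen_cohort(
    n_samples: int,
    model: EfficacyModel | None = None,
    metric_logmeans: dict[str, float] | None = None,
    metric_logsds: dict[str, float] | None = None,
    noise_sd: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Cohort of PPI profiles with a known linear metric -> AUC relation.

    Metrics are log2-normal per the supplied means/sds. The noise-free
    target is ``clip(intercept + sum coef * log2(floored metric), 0, 1)``
    computed on the same floored features the fitting pipeline uses, so
    a zero-noise cohort is exactly recoverable downstream; Gaussian noise
    of sd ``noise_sd`` is then added.
    """
    if seed is None:
        raise ValueError("gen_cohort requires a seed")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if model is None:
        model = default_ground_truth_model()
    logmeans = dict(default_metric_logmeans(), **(metric_logmeans or {}))
    logsds = dict(default_metric_logsds(), **(metric_logsds or {}))
    validate_metric_names(logmeans)
    missing = [m for m in model.metric_names if m not in logmeans]
    if missing:
        raise ValueError(f"model metrics absent from generator: {missing!r}")
    rng = np.random.default_rng(seed)
    names = list(logmeans)
    data = {
        name: np.exp2(rng.normal(logmeans[name], logsds[name], size=n_samples))
        for name in names
    }
    profiles = pd.DataFrame(
        data, index=[f"S{i + 1:03d}" for i in range(n_samples)]
    )
    profiles.index.name = "sample_id"
    features, _ = transform_metrics(profiles)
    lin = model.intercept + features[list(model.metric_names)].to_numpy() @ np.asarray(
        model.coefficients
    )
    auc = np.clip(lin, 0.0, 1.0)
    if noise_sd > 0:
        auc = auc + rng.normal(0.0, noise_sd, size=n_samples)
    target = pd.Series(auc, index=profiles.index, name="ex_vivo_auc")
    truth = GroundTruth(
        true_coefficients=dict(zip(model.metric_names, model.coefficients)),
        true_intercept=model.intercept,
    )
    return profiles, target, truth
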