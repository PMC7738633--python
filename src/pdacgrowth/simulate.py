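"""Synthetic cohorts with the statistical structure the analysis assumes.

Each simulated patient carries a delta class, a lognormally distributed
growth-rate constant whose class means default to 0.024 (low delta) and
0.088 month^-1 (high delta), an irregular pre-diagnostic scan schedule
(mean interval 7.5 months), exact Gompertz lesion volumes converted to
biaxial measurements with multiplicative measurement noise, linearly
declining tissue-volume series at class-specific wasting rates, and a
blood-glucose series with a class-specific slope. Ground-truth parameters
are stored in the cohort metadata so loop-back tests can compare estimates
against the values that generated the data.

Per-class alpha log-standard deviations are free parameters (no cohort
variance is published); the default 0.6 makes the two alpha distributions
overlap, so threshold selection and cross-validation are exercised away
from the trivially separable regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import (
    Cohort,
    DeltaClass,
    LesionObservation,
    PatientRecord,
    TimeSeries,
    TISSUES,
    mean_diameter,
    sphere_volume,
)
from .growth import DEFAULT_K_MM3, GompertzParams, gompertz_volume

logger = logging.getLogger(__name__)


def _default_tissue_rates() -> dict:
    # (low delta, high delta) % change/month
    return {"SAF": (-1.1, -8.7), "VAF": (-1.5, -10.2), "muscle": (-0.4, -8.8)}


def _default_tissue_baselines() -> dict:
    # single-slice compartment volumes, cm^3
    return {"SAF": 60.0, "VAF": 50.0, "muscle": 45.0}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_low: int = 26
    n_high: int = 29
    alpha_mean_low: float = 0.024   # month^-1
    alpha_mean_high: float = 0.088  # month^-1
    alpha_logsd_low: float = 0.6
    alpha_logsd_high: float = 0.6
    k: float = DEFAULT_K_MM3        # mm^3
    x0_range: tuple[float, float] = (50.0, 2000.0)  # mm^3
    scan_interval_mean: float = 7.5  # months
    scan_interval_sd: float = 3.0
    scan_interval_min: float = 1.0
    n_scans_range: tuple[int, int] = (2, 6)
    diameter_noise_cv: float = 0.05
    axis_ratio_range: tuple[float, float] = (1.0, 1.5)
    tissue_rate_means: dict = field(default_factory=_default_tissue_rates)
    tissue_rate_sd: float = 2.5      # %/month, both classes
    tissue_baselines: dict = field(default_factory=_default_tissue_baselines)
    tissue_baseline_cv: float = 0.25
    tissue_noise_cv: float = 0.05
    tissue_n_points: tuple[int, int] = (3, 5)
    tissue_window_months: float = 24.0
    bg_slope_low: float = 0.1        # mg/dL per month
    bg_slope_high: float = 1.5
    bg_slope_sd_low: float = 0.2
    bg_slope_sd_high: float = 0.5
    bg_baseline_mean: float = 100.0  # mg/dL
    bg_baseline_sd: float = 8.0
    bg_noise_sd: float = 5.0
    bg_n_points: tuple[int, int] = (4, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low < 0 or self.n_high < 0 or self.n_low + self.n_high == 0:
            raise ValueError("need a positive total patient count")
        for name in ("alpha_mean_low", "alpha_mean_high", "k", "scan_interval_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.x0_range[0] <= self.x0_range[1]):
            raise ValueError("invalid x0_range")

    def log_params(self, delta_class: DeltaClass) -> tuple[float, float]:
        """(mu, sigma) of log-alpha so that E[alpha] equals the class mean."""
        if delta_class is DeltaClass.LOW:
            mean, sd = self.alpha_mean_low, self.alpha_logsd_low
        else:
            mean, sd = self.alpha_mean_high, self.alpha_logsd_high
        return math.log(mean) - sd**2 / 2.0, sd


def _lesion_observations(rng, cfg: GeneratorConfig, alpha: float):
    """Scan schedule + noisy biaxial measurements off an exact Gompertz path."""
    n_scans = int(rng.integers(cfg.n_scans_range[0], cfg.n_scans_range[1] + 1))
    intervals = np.maximum(
        rng.normal(cfg.scan_interval_mean, cfg.scan_interval_sd, size=n_scans - 1),
        cfg.scan_interval_min,
    )
    times = np.concatenate([[0.0], np.cumsum(intervals)])
    x0 = float(rng.uniform(*cfg.x0_range))
    if x0 >= cfg.k:
        logger.warning("X0 %.1f >= K; truncating below carrying capacity", x0)
        x0 = 0.99 * cfg.k
    params = GompertzParams(alpha=alpha, x0=x0, k=cfg.k)
    volumes = gompertz_volume(times, params)
    diameters = (6.0 * volumes / math.pi) ** (1.0 / 3.0)
    ratios = rng.uniform(*cfg.axis_ratio_range, size=len(times))
    long_axes = diameters * np.sqrt(ratios)
    short_axes = diameters / np.sqrt(ratios)
    if cfg.diameter_noise_cv > 0:
        noise = rng.lognormal(
            -cfg.diameter_noise_cv**2 / 2, cfg.diameter_noise_cv, size=(len(times), 2)
        )
        long_axes = long_axes * noise[:, 0]
        short_axes = short_axes * noise[:, 1]
    lo = np.minimum(long_axes, short_axes)
    hi = np.maximum(long_axes, short_axes)
    # measurement noise can push the apparent volume past K; truncate so the
    # fit stage (which requires volumes < K) keeps every simulated patient
    max_diam = (6.0 * 0.999 * cfg.k / math.pi) ** (1.0 / 3.0)
    if np.any(np.sqrt(hi * lo) > max_diam):
        logger.warning("noisy measurement exceeded carrying capacity; truncated")
        scale = np.minimum(max_diam / np.sqrt(hi * lo), 1.0)
        hi, lo = hi * scale, lo * scale
    return [
        LesionObservation(float(t), float(h), float(l))
        for t, h, l in zip(times, hi, lo)
    ], x0


def _tissue_series(rng, cfg: GeneratorConfig, rate: float) -> TimeSeries:
    """Linear relative decline at `rate` %/month over a pre-diagnostic window.

    The window is capped so the final value stays >= 10% of baseline (a
    linear -8.7%/month decline cannot be sustained for a full 24 months).
    """
    span = float(rng.uniform(6.0, cfg.tissue_window_months))
    if rate < 0:
        span = min(span, 0.9 * 100.0 / abs(rate))
    n = int(rng.integers(cfg.tissue_n_points[0], cfg.tissue_n_points[1] + 1))
    interior = np.sort(rng.uniform(-span, 0.0, size=n - 2)) if n > 2 else []
    times = np.concatenate([[-span], interior, [0.0]])
    baseline = None
    while baseline is None or baseline <= 0:
        baseline = rng.normal(1.0, cfg.tissue_baseline_cv)
    values = baseline * (1.0 + rate / 100.0 * (times - times[0]))
    if cfg.tissue_noise_cv > 0:
        values = values * rng.lognormal(
            -cfg.tissue_noise_cv**2 / 2, cfg.tissue_noise_cv, size=n
        )
    return TimeSeries(tuple(times), tuple(np.maximum(values, 1e-6)))


def _bg_series(rng, cfg: GeneratorConfig, slope: float) -> TimeSeries:
    n = int(rng.integers(cfg.bg_n_points[0], cfg.bg_n_points[1] + 1))
    times = np.sort(rng.uniform(-24.0, 0.0, size=n))
    times[0] = min(times[0], -12.0)  # guarantee usable span
    baseline = max(float(rng.normal(cfg.bg_baseline_mean, cfg.bg_baseline_sd)), 60.0)
    values = baseline + slope * (times - times[0]) + rng.normal(0, cfg.bg_noise_sd, size=n)
    return TimeSeries(tuple(times), tuple(np.maximum(values, 30.0)))


def _make_patient(rng, cfg, pid, dclass, log_mu, log_sd, truth):
    alpha = float(rng.lognormal(log_mu, log_sd))
    alpha = min(alpha, 1.9)  # keep inside the fit box
    obs, x0 = _lesion_observations(rng, cfg, alpha)
    is_high = dclass is DeltaClass.HIGH
    tissue = {}
    true_rates = {}
    for name in TISSUES:
        low_r, high_r = cfg.tissue_rate_means[name]
        rate = float(rng.normal(high_r if is_high else low_r, cfg.tissue_rate_sd))
        true_rates[name] = rate
        tissue[name] = _tissue_series(rng, cfg, rate)
    slope_mean = cfg.bg_slope_high if is_high else cfg.bg_slope_low
    slope_sd = cfg.bg_slope_sd_high if is_high else cfg.bg_slope_sd_low
    bg_slope = float(rng.normal(slope_mean, slope_sd))
    truth[pid] = {
        "alpha": alpha,
        "x0": x0,
        "tissue_rates": true_rates,
        "bg_slope": bg_slope,
    }
    return PatientRecord(
        patient_id=pid,
        delta_class=dclass,
        observations=obs,
        tissue_series=tissue,
        bg_series=_bg_series(rng, cfg, bg_slope),
    )


def generate_cohort(config: GeneratorConfig | None = None, **overrides) -> Cohort:
    """Draw a synthetic cohort; deterministic for a fixed config.seed.

    Ground truth per patient (alpha, X0, tissue rates, BG slope) is stored
    under metadata['truth'].
    """
    cfg = config or GeneratorConfig(**overrides)
    if config is not None and overrides:
        raise TypeError("pass either a config object or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)
    truth: dict[str, dict] = {}
    patients = []
    for dclass, n in ((DeltaClass.LOW, cfg.n_low), (DeltaClass.HIGH, cfg.n_high)):
        log_mu, log_sd = cfg.log_params(dclass)
        for i in range(n):
            pid = f"{dclass.value}-{i + 1:03d}"
            patients.append(_make_patient(rng, cfg, pid, dclass, log_mu, log_sd, truth))
    return Cohort(
        patients=patients,
        metadata={"generator": "pdacgrowth.simulate", "seed": cfg.seed,
                  "config": asdict(cfg), "truth": truth},
    )


def null_cohort(config: GeneratorConfig | None = None, **overrides) -> Cohort:
    """Cohort whose labels carry no information about alpha.

    Both classes draw alpha from one pooled lognormal (log-parameters
    averaged across the two classes); tissue/BG structure is kept. Used to
    calibrate the classifier's null behavior (AUC ~ 0.5).
    """
    cfg = config or GeneratorConfig(**overrides)
    if config is not None and overrides:
        raise TypeError("pass either a config object or keyword overrides, not both")
    mu_l, sd_l = cfg.log_params(DeltaClass.LOW)
    mu_h, sd_h = cfg.log_params(DeltaClass.HIGH)
    mu, sd = (mu_l + mu_h) / 2.0, (sd_l + sd_h) / 2.0
    rng = np.random.default_rng(cfg.seed)
    truth: dict[str, dict] = {}
    patients = []
    for dclass, n in ((DeltaClass.LOW, cfg.n_low), (DeltaClass.HIGH, cfg.n_high)):
        for i in range(n):
            pid = f"{dclass.value}-{i + 1:03d}"
            patients.append(_make_patient(rng, cfg, pid, dclass, mu, sd, truth))
    return Cohort(
        patients=patients,
        metadata={"generator": "pdacgrowth.simulate(null)", "seed": cfg.seed,
                  "config": asdict(cfg), "truth": truth},
    )
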