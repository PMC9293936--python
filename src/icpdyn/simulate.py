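"""Synthetic TBI neuromonitoring cohorts.

Real ICP/MAP monitoring data from TBI intensive care are access-restricted,
so every stage of the package is exercised on simulated cohorts that carry
the statistical structure the algorithm assumes:

* a latent severity score per patient (standard normal) drives 30-day
  mortality through a logistic link whose intercept is solved numerically so
  the population mortality matches the preset target;
* ICP is a mean-reverting (Ornstein-Uhlenbeck / AR(1)) process whose level
  is shifted upward with severity, and non-survivors additionally acquire a
  positive per-hour drift -- the designed-in mechanism that makes prediction
  improve as monitoring accrues;
* MAP is an independent mean-reverting process (CPP = MAP - ICP then
  inherits the ICP signal); an optional coupling knob ties MAP to severity
  for sensitivity analyses;
* monitoring duration is a latent normal resampled below 24 h and censored
  at the 120-h study horizon, with the latent parameters calibrated at
  config time so the *observed* mean/SD match the preset; non-survivors are
  further truncated at a simulated death time (attrition);
* block missingness (monitor disconnections affecting both signals) and
  out-of-range artifact spikes (which must violate the preprocessing
  thresholds so the extreme-value filter is exercised) are injected last.

Presets named ``training``, ``stockholm`` and ``eicu`` mirror the printed
demographics of the three study cohorts (mortality, median age and IQR,
monitoring duration).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.signal import lfilter

from .vitals import Cohort, PatientRecord, VitalsSeries, build_patient, cohort_to_frames

logger = logging.getLogger(__name__)

HORIZON_MIN = 120 * 60


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator (rates per the units in the names)."""

    n_patients: int = 686
    seed: int = 0
    # outcome
    mortality_target: float = 0.17
    link_slope: float = 1.5            # logit(death) slope per severity SD
    # age quantile knots (years): min, q25, median, q75, max
    age_knots: tuple[float, ...] = (16.0, 28.0, 46.0, 59.0, 92.0)
    # monitoring duration (hours): observed mean/SD after [24, 120] handling
    duration_mean: float = 90.7
    duration_sd: float = 31.4
    # ICP process (mmHg)
    icp_baseline_mean: float = 11.0
    icp_baseline_sd: float = 3.5
    icp_process_sd: float = 4.0
    severity_shift: float = 2.5        # mmHg of mean ICP per severity SD
    nonsurvivor_drift: float = 0.08    # mmHg per hour per severity SD, deaths only
    # MAP process (mmHg)
    map_mean: float = 85.0
    map_sd: float = 8.0
    map_process_sd: float = 7.0
    map_severity_shift: float = 0.0    # optional MAP-outcome coupling
    # shared dynamics / noise
    ou_mean_reversion: float = 0.4     # per hour
    noise_sd: float = 1.5              # measurement noise, mmHg
    # sampling and corruption
    sample_interval: int = 1           # minutes between stored medians
    missing_block_rate: float = 1.0    # blocks per 24 h of monitoring
    missing_block_length: float = 30.0 # mean block length, minutes
    artifact_rate: float = 1.0         # artifacts per 1000 samples
    # attrition
    death_truncation: bool = True
    death_time_scale_h: float = 168.0  # mean of exponential death-time tail after 24 h

    def __post_init__(self) -> None:
        if not 0.0 < self.mortality_target < 1.0:
            raise ValueError("mortality_target must lie in (0, 1)")
        for name in ("missing_block_rate", "artifact_rate", "noise_sd",
                     "icp_process_sd", "map_process_sd", "ou_mean_reversion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if list(self.age_knots) != sorted(self.age_knots):
            raise ValueError("age_knots must be nondecreasing")
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be at least one minute")


PRESETS: dict[str, GeneratorConfig] = {
    "training": GeneratorConfig(),
    "stockholm": GeneratorConfig(
        n_patients=464, mortality_target=0.13,
        age_knots=(16.0, 33.0, 51.0, 62.0, 92.0)),
    "eicu": GeneratorConfig(
        n_patients=174, mortality_target=0.30,
        age_knots=(16.0, 24.0, 38.0, 57.0, 92.0)),
}


def preset(name: str, **overrides) -> GeneratorConfig:
    """A named preset, optionally with fields overridden."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


# ---------------------------------------------------------------------------
# calibrations solved once per config
# ---------------------------------------------------------------------------

def solve_link_intercept(target: float, slope: float) -> float:
    """Intercept a with E_s[sigmoid(a + slope*s)] = target, s ~ N(0,1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(101)
    weights = weights / np.sqrt(2 * np.pi)

    def prevalence(a: float) -> float:
        return float(weights @ (1.0 / (1.0 + np.exp(-(a + slope * nodes)))))

    try:
        return float(optimize.brentq(lambda a: prevalence(a) - target, -30, 30,
                                     xtol=1e-10))
    except ValueError as exc:  # pragma: no cover - unreachable for targets in (0,1)
        raise ValueError("mortality target cannot be reached by the link") from exc


def _censored_duration_moments(mu: float, sigma: float,
                               lo: float = 24.0, hi: float = 120.0) -> tuple[float, float]:
    """Mean and SD of min(X, hi) with X ~ N(mu, sigma) conditioned on X > lo."""
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    p_keep = stats.norm.sf(a)
    if p_keep <= 0:
        return hi, 0.0
    # continuous part on (lo, hi)
    z = np.linspace(a, b, 4001)
    x = mu + sigma * z
    w = stats.norm.pdf(z) / sigma
    m0 = np.trapezoid(w, x)
    m1 = np.trapezoid(w * x, x)
    m2 = np.trapezoid(w * x * x, x)
    atom = stats.norm.sf(b)           # mass censored at hi
    e1 = (m1 + atom * hi) / p_keep
    e2 = (m2 + atom * hi * hi) / p_keep
    return e1, float(np.sqrt(max(e2 - e1 * e1, 0.0)))


def solve_duration_latents(mean: float, sd: float) -> tuple[float, float]:
    """Latent normal (mu, sigma) whose resampled/censored law matches (mean, sd)."""

    def eqs(params):
        mu, sigma = params
        if sigma <= 1.0:
            return [1e3, 1e3]
        m, s = _censored_duration_moments(mu, sigma)
        return [m - mean, s - sd]

    sol = optimize.root(eqs, x0=[mean + 15.0, sd * 1.5], method="hybr")
    mu, sigma = sol.x
    m, s = _censored_duration_moments(mu, sigma)
    if not sol.success or abs(m - mean) > 0.1 or abs(s - sd) > 0.1:
        raise ValueError(
            f"duration preset (mean={mean}, sd={sd}) is not attainable by a "
            "lower-resampled, horizon-censored normal")
    return float(mu), float(sigma)


def sample_ages(u: np.ndarray, knots: tuple[float, ...]) -> np.ndarray:
    """Piecewise-linear quantile transform hitting median and IQR exactly."""
    q = np.linspace(0.0, 1.0, len(knots))
    return np.interp(u, q, knots)


# ---------------------------------------------------------------------------
# per-patient simulation
# ---------------------------------------------------------------------------

def _ar1(n: int, rho: float, stationary_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path of length n (exact OU discretization)."""
    if n == 0:
        return np.array([])
    innov_sd = stationary_sd * np.sqrt(max(1.0 - rho * rho, 0.0))
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, stationary_sd)
    y, _ = lfilter([1.0], [1.0, -rho], e, zi=np.array([0.0]))
    return y


def _inject_artifacts(values: np.ndarray, signal: str, rate_per_1000: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, int, int]:
    """Replace random samples with out-of-range spikes that the filter must drop.

    Returns the corrupted values plus the counts of high and low spikes, kept
    in the ground truth so tests can confirm the exclusion filter was
    actually exercised.
    """
    n = values.size
    n_art = rng.binomial(n, min(rate_per_1000 / 1000.0, 1.0)) if n else 0
    if n_art == 0:
        return values, 0, 0
    idx = rng.choice(n, size=n_art, replace=False)
    high = rng.random(n_art) < 0.5
    out = values.copy()
    if signal == "icp":
        out[idx] = np.where(high, rng.uniform(101.0, 180.0, n_art),
                            rng.uniform(-20.0, -0.5, n_art))
    else:
        out[idx] = np.where(high, rng.uniform(151.0, 250.0, n_art),
                            rng.uniform(1.0, 19.5, n_art))
    return out, int(high.sum()), int(n_art - high.sum())


@dataclass(frozen=True)
class LatentPatientState:
    """Ground truth retained for parameter-recovery and calibration tests."""

    patient_id: str
    severity: float
    p_death: float
    outcome: int
    age_years: float
    planned_duration_h: float
    death_time_h: float
    observed_duration_h: float
    icp_baseline: float
    icp_drift_per_h: float
    map_level: float
    n_artifacts_icp_high: int = 0
    n_artifacts_icp_low: int = 0
    n_artifacts_map_high: int = 0
    n_artifacts_map_low: int = 0


def generate_patient(config: GeneratorConfig, rng: np.random.Generator,
                     patient_id: str,
                     link_intercept: float,
                     duration_latents: tuple[float, float],
                     ) -> tuple[PatientRecord, LatentPatientState]:
    """One synthetic patient plus the latent state that produced them."""
    age = float(sample_ages(np.array([rng.random()]), config.age_knots)[0])
    severity = float(rng.standard_normal())
    p_death = float(1.0 / (1.0 + np.exp(-(link_intercept + config.link_slope * severity))))
    outcome = int(rng.random() < p_death)

    mu_d, sd_d = duration_latents
    planned = float(rng.normal(mu_d, sd_d))
    while planned <= 24.0:
        planned = float(rng.normal(mu_d, sd_d))
    planned = min(planned, 120.0)
    death_h = float("inf")
    if outcome == 1:
        death_h = 24.0 + float(rng.exponential(config.death_time_scale_h))
    observed = planned
    if config.death_truncation and death_h < observed:
        observed = max(death_h, 24.0)
    dur_min = int(round(observed * 60.0))

    times = np.arange(0, dur_min, config.sample_interval, dtype=np.int64)
    t_h = times / 60.0
    rho = float(np.exp(-config.ou_mean_reversion * config.sample_interval / 60.0))

    icp_baseline = (config.icp_baseline_mean
                    + config.icp_baseline_sd * rng.standard_normal()
                    + config.severity_shift * severity)
    drift = (config.nonsurvivor_drift * max(severity, 0.0)) if outcome == 1 else 0.0
    icp = (icp_baseline + drift * t_h
           + _ar1(times.size, rho, config.icp_process_sd, rng)
           + rng.normal(0.0, config.noise_sd, times.size))

    map_level = (config.map_mean + config.map_sd * rng.standard_normal()
                 + config.map_severity_shift * severity)
    map_vals = (map_level + _ar1(times.size, rho, config.map_process_sd, rng)
                + rng.normal(0.0, config.noise_sd, times.size))

    # shared missing blocks: disconnections hit both signals at once
    n_blocks = rng.poisson(config.missing_block_rate * observed / 24.0)
    keep = np.ones(times.size, dtype=bool)
    for _ in range(n_blocks):
        start = rng.uniform(0.0, dur_min)
        length = rng.exponential(config.missing_block_length)
        keep &= ~((times >= start) & (times < start + length))

    # artifacts go into the retained samples so every injected spike reaches
    # (and must be caught by) the extreme-value filter
    icp, icp_hi, icp_lo = _inject_artifacts(icp[keep], "icp",
                                            config.artifact_rate, rng)
    map_vals, map_hi, map_lo = _inject_artifacts(map_vals[keep], "map",
                                                 config.artifact_rate, rng)

    icp_series = VitalsSeries("icp", times[keep], icp)
    map_series = VitalsSeries("map", times[keep], map_vals)
    patient = build_patient(patient_id, age, outcome, icp_series, map_series,
                            monitoring_end_min=dur_min)
    state = LatentPatientState(
        patient_id=patient_id, severity=severity, p_death=p_death, outcome=outcome,
        age_years=age, planned_duration_h=planned, death_time_h=death_h,
        observed_duration_h=observed, icp_baseline=icp_baseline,
        icp_drift_per_h=drift, map_level=map_level,
        n_artifacts_icp_high=icp_hi, n_artifacts_icp_low=icp_lo,
        n_artifacts_map_high=map_hi, n_artifacts_map_low=map_lo)
    return patient, state


def generate_cohort(config: GeneratorConfig,
                    label: str = "synthetic") -> tuple[Cohort, pd.DataFrame]:
    """A full synthetic cohort plus the ground-truth sidecar table.

    All randomness flows through one seeded generator hierarchy, so the same
    config regenerates identical data.  The sidecar holds each patient's
    latent severity, death probability, planned (pre-death-truncation)
    monitoring duration and the solved link coefficients.
    """
    link_intercept = solve_link_intercept(config.mortality_target, config.link_slope)
    duration_latents = solve_duration_latents(config.duration_mean, config.duration_sd)
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    patients: list[PatientRecord] = []
    states: list[LatentPatientState] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        patient, state = generate_patient(config, rng, f"p{i:04d}",
                                          link_intercept, duration_latents)
        patients.append(patient)
        states.append(state)
    columns = list(LatentPatientState.__dataclass_fields__)
    truth = pd.DataFrame([asdict(s) for s in states], columns=columns)
    truth["link_intercept"] = link_intercept
    truth["link_slope"] = config.link_slope
    if len(truth):
        logger.info("generated %d patients (%.1f%% mortality)", len(patients),
                    100.0 * truth["outcome"].mean())
    return Cohort(patients, label=label), truth


def write_cohort(cohort: Cohort, ground_truth: pd.DataFrame, outdir,
                 config: GeneratorConfig | None = None) -> dict[str, Path]:
    """Write vitals/metadata CSVs in the ingestion dialect plus the sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vitals, meta = cohort_to_frames(cohort)
    paths = {
        "vitals": outdir / "vitals.csv",
        "metadata": outdir / "metadata.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    vitals.to_csv(paths["vitals"], index=False)
    meta.to_csv(paths["metadata"], index=False)
    ground_truth.to_csv(paths["ground_truth"], index=False)
    if config is not None:
        paths["config"] = outdir / "generator_config.json"
        with open(paths["config"], "w") as fh:
            json.dump(asdict(config), fh, indent=1, default=list)
    return paths
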