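"""Synthetic winter telemetry for home-range-resident deer, with ground truth.

Movement per animal is a discrete-time Ornstein–Uhlenbeck (OU) process about
an animal-specific range centre mu, observed at a regular fix interval with
Gaussian GPS error and i.i.d. fix dropout.  A capture-and-release event at
t = 0 injects two decaying disturbances, each engineered to be *exactly
exponential on the log scale the analysis uses* and mutually orthogonal:

* an outward radial shift: positions are ``p = mu + gamma(t) * z`` with
  ``gamma(t) = exp(A_c * exp(-t/tau_cog))`` and
  ``A_c = ln(1 + d0 / (sigma * sqrt(pi/2)))``, so the animal's expected
  distance to its range centre is elevated by exactly ``d0`` metres at
  release and log distance-to-centre carries the disturbance
  ``A_c * exp(-t/tau_cog)``;
* a suppression of movement amplitude: the OU mean-reversion factor is
  modulated as ``rho_k = 1 - (1 - rho) * q_k^2`` with
  ``q_k = s(t_k) / gamma(t_k)`` and ``s(t) = exp(ln(1-a0) * exp(-t/tau_step))``,
  together with innovation SD ``sigma * sqrt(1 - rho_k^2)``.  This keeps the
  stationary positional variance exactly ``sigma^2`` at every step (the step
  channel cannot leak into distance-to-centre) while the observed step
  length is scaled by ``s(t)`` — equal to the suppression factor ``1 - a0``
  at release and decaying back to 1 — so log step length carries the
  disturbance ``ln(1-a0) * exp(-t/tau_step)``.

Because both injected log-scale disturbances are single exponentials, the
day on which the zero-centred disturbance crosses zero over a monitoring
window of T days has the closed form

    t* = tau * ln( T / (tau * (1 - exp(-T / tau))) ),

which is the ground truth (`SimTruth`) that the full estimation pipeline is
validated against.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AGE_CLASSES, METHODS, SEXES, ConfigurationError, MONITORING_END_MD, SimConfig

__all__ = [
    "AnimalSpec",
    "SimTruth",
    "TruthEntry",
    "expected_zero_crossing",
    "simulate_trajectory",
    "simulate_dataset",
    "write_dataset",
    "EmptyDatasetError",
]

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%SZ"

#: age-class mixing proportions (fawn, yearling, adult), roughly the
#: composition of first-capture winter programmes.
AGE_MIX = (0.40, 0.15, 0.45)


class EmptyDatasetError(ValueError):
    """Raised when a simulation is requested for zero animals."""


def monitoring_end_date(capture_date: dt.date) -> dt.date:
    """15 April closing the capture season containing ``capture_date``.

    Winter capture seasons span the New Year: October–December captures
    belong to the season ending the following April.
    """
    year = capture_date.year + 1 if capture_date.month >= 7 else capture_date.year
    return dt.date(year, *MONITORING_END_MD)


def expected_zero_crossing(tau_days: float, horizon_days: float) -> float:
    """Analytic zero-crossing day of a centred exponential disturbance.

    For a disturbance g(t) = A * exp(-t/tau) observed on [0, T], the centred
    curve g(t) - mean(g) crosses zero where exp(-t/tau) equals its window
    mean, i.e. at t* = tau * ln( T / (tau * (1 - exp(-T/tau))) ).  The
    crossing does not depend on the amplitude A (nor its sign), and
    0 < t* < T, increasing in both tau and T (towards T/2 as tau -> inf).
    """
    tau = float(tau_days)
    T = float(horizon_days)
    if not (math.isfinite(tau) and math.isfinite(T)) or T <= 0:
        raise ConfigurationError(f"invalid tau/horizon: {tau_days!r}, {horizon_days!r}")
    if tau <= 0:
        return 0.0
    return tau * math.log(T / (tau * (-math.expm1(-T / tau))))


@dataclass(frozen=True)
class TruthEntry:
    metric: str  # "d_cog" | "step"
    method: str
    tau_days: float
    amplitude: float
    horizon_days: float
    t_star_days: float
    n_animals: int


@dataclass(frozen=True)
class SimTruth:
    """Injected decay constants and their analytic expected rebound days."""

    entries: tuple[TruthEntry, ...]

    def t_star(self, metric: str, method: str) -> float:
        for e in self.entries:
            if e.metric == metric and e.method == method:
                return e.t_star_days
        raise KeyError(f"no truth entry for metric={metric!r}, method={method!r}")

    def to_dict(self) -> dict:
        return {"entries": [dataclasses.asdict(e) for e in self.entries]}

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(entries=tuple(TruthEntry(**e) for e in d["entries"]))


@dataclass(frozen=True)
class AnimalSpec:
    """Everything animal-specific the trajectory simulator needs."""

    animal_id: str
    site_id: str
    capture_time: dt.datetime  # UTC, inside the capture season
    method: str
    sex: str
    age_class: str
    centre_x: float
    centre_y: float
    ou_sd_m: float  # animal-specific stationary positional SD


def _validate_spec(spec: AnimalSpec) -> None:
    for name in ("centre_x", "centre_y", "ou_sd_m"):
        v = getattr(spec, name)
        if not math.isfinite(v):
            raise ConfigurationError(f"animal spec field {name} is not finite: {v!r}")
    if spec.method not in METHODS:
        raise ConfigurationError(f"unknown capture method {spec.method!r}")


def simulate_trajectory(
    cfg: SimConfig, spec: AnimalSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate one animal's GPS fixes from capture to 15 April.

    The underlying deviation z is a zero-mean OU process with stationary SD
    ``spec.ou_sd_m``; the capture effect enters as the radial inflation
    gamma(t) and the mean-reversion modulation described in the module
    docstring.  Positions are ``mu + gamma(t_k) * z_k`` plus Gaussian
    observation noise; fixes are dropped i.i.d. with ``fix_loss_prob``.
    Returned timestamps are strictly increasing.
    """
    _validate_spec(spec)
    end = dt.datetime.combine(monitoring_end_date(spec.capture_time.date()), dt.time(0, 0))
    capture_naive = spec.capture_time.replace(tzinfo=None)
    total_h = (end - capture_naive).total_seconds() / 3600.0
    n = int(math.floor(total_h / cfg.fix_interval_h)) + 1
    if n <= 0:
        return _empty_fix_frame()

    dt_h = cfg.fix_interval_h
    t_days = np.arange(n) * dt_h / 24.0
    rho_bar = math.exp(-dt_h / cfg.ou_timescale_h)
    sigma = float(spec.ou_sd_m)
    tau_cog = cfg.tau_cog(spec.method)
    tau_step = cfg.tau_step(spec.method)
    a0 = cfg.step_suppression

    mu = np.array([spec.centre_x, spec.centre_y])
    # radial shift: expected extra distance-to-centre is cog_shift_m at t=0
    mean_dist = sigma * math.sqrt(math.pi / 2.0)
    amp_cog = math.log1p(cfg.cog_shift_m / mean_dist) if mean_dist > 0 else 0.0
    gamma = np.exp(amp_cog * np.exp(-t_days / tau_cog))
    # step suppression: observed step length scaled by s(t), s(0) = 1 - a0
    amp_step = math.log1p(-a0)  # ln(1 - a0) <= 0
    s = np.exp(amp_step * np.exp(-t_days / tau_step))
    q = np.clip(s / gamma, 1e-12, 1.0)
    # variance-preserving modulation: var(z_k) = sigma^2 for every k
    rho_k = 1.0 - (1.0 - rho_bar) * q * q
    innov_sd = sigma * np.sqrt(np.maximum(0.0, 1.0 - rho_k * rho_k))

    noise = rng.standard_normal((n, 2))
    z = np.empty((n, 2))
    z[0] = sigma * rng.standard_normal(2)  # stationary pre-capture deviation
    for k in range(n - 1):
        z[k + 1] = rho_k[k + 1] * z[k] + innov_sd[k + 1] * noise[k]
    positions = mu[None, :] + gamma[:, None] * z

    obs = positions + cfg.obs_noise_m * rng.standard_normal((n, 2))
    keep = rng.random(n) >= cfg.fix_loss_prob

    times = [capture_naive + dt.timedelta(hours=dt_h * k) for k in range(n)]
    frame = pd.DataFrame(
        {
            "animal_id": spec.animal_id,
            "site_id": spec.site_id,
            "timestamp_utc": pd.to_datetime(times, utc=True),
            "x_m": obs[:, 0],
            "y_m": obs[:, 1],
        }
    )
    return frame.loc[keep].reset_index(drop=True)


def _empty_fix_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": pd.Series(dtype=str),
            "site_id": pd.Series(dtype=str),
            "timestamp_utc": pd.Series(dtype="datetime64[ns, UTC]"),
            "x_m": pd.Series(dtype=float),
            "y_m": pd.Series(dtype=float),
        }
    )


def _animal_rng(seed: int, index: int) -> np.random.Generator:
    # one named substream per animal: adding/removing animals never
    # perturbs the streams of the others
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(1, index))))


def build_animal_specs(cfg: SimConfig) -> list[AnimalSpec]:
    """Draw capture metadata and per-animal movement parameters."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed, spawn_key=(0,))))
    methods = [m for m in METHODS if cfg.method_mix.get(m, 0.0) > 0]
    probs = np.array([cfg.method_mix[m] for m in methods], dtype=float)
    probs = probs / probs.sum()
    n_days = (cfg.season_end - cfg.season_start).days

    site_ids = [f"site_{i + 1:02d}" for i in range(cfg.sites)]
    site_centres = {sid: (50_000.0 * i, 0.0) for i, sid in enumerate(site_ids)}

    specs: list[AnimalSpec] = []
    for i in range(cfg.n_animals):
        method = methods[int(rng.choice(len(methods), p=probs))]
        sex = SEXES[int(rng.integers(len(SEXES)))]
        age = AGE_CLASSES[int(rng.choice(len(AGE_CLASSES), p=AGE_MIX))]
        site = site_ids[int(rng.integers(len(site_ids)))]
        day = int(rng.integers(n_days + 1))
        hour = float(rng.uniform(0.0, 24.0))
        capture = dt.datetime.combine(
            cfg.season_start + dt.timedelta(days=day), dt.time(0, 0), tzinfo=dt.timezone.utc
        ) + dt.timedelta(hours=hour)
        capture = capture.replace(microsecond=0)
        cx, cy = site_centres[site]
        cx += float(rng.uniform(-cfg.range_centre_spread_m, cfg.range_centre_spread_m))
        cy += float(rng.uniform(-cfg.range_centre_spread_m, cfg.range_centre_spread_m))
        ou_sd = cfg.ou_sd_m * math.exp(cfg.ou_sd_log_sigma * float(rng.standard_normal()))
        specs.append(
            AnimalSpec(
                animal_id=f"a{i + 1:04d}",
                site_id=site,
                capture_time=capture,
                method=method,
                sex=sex,
                age_class=age,
                centre_x=cx,
                centre_y=cy,
                ou_sd_m=ou_sd,
            )
        )
    return specs


def _compute_truth(cfg: SimConfig, specs: list[AnimalSpec]) -> SimTruth:
    horizons: dict[str, list[float]] = {}
    for s in specs:
        end = monitoring_end_date(s.capture_time.date())
        T = (
            dt.datetime.combine(end, dt.time(0, 0), tzinfo=dt.timezone.utc) - s.capture_time
        ).total_seconds() / 86400.0
        horizons.setdefault(s.method, []).append(T)

    entries: list[TruthEntry] = []
    for method in METHODS:
        if method not in horizons:
            continue
        T_mean = float(np.mean(horizons[method]))
        n = len(horizons[method])
        entries.append(
            TruthEntry(
                metric="d_cog",
                method=method,
                tau_days=cfg.tau_cog(method),
                amplitude=cfg.cog_shift_m,
                horizon_days=T_mean,
                t_star_days=expected_zero_crossing(cfg.tau_cog(method), T_mean),
                n_animals=n,
            )
        )
        entries.append(
            TruthEntry(
                metric="step",
                method=method,
                tau_days=cfg.tau_step(method),
                amplitude=cfg.step_suppression,
                horizon_days=T_mean,
                t_star_days=expected_zero_crossing(cfg.tau_step(method), T_mean),
                n_animals=n,
            )
        )
    return SimTruth(entries=tuple(entries))


def simulate_dataset(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the whole study: one capture event per animal, all fixes.

    Returns (fix table, capture-event table, SimTruth).  Identical
    configuration (including seed) yields identical outputs.
    """
    if cfg.n_animals == 0:
        raise EmptyDatasetError("simulate_dataset requires n_animals >= 1")
    specs = build_animal_specs(cfg)
    frames = [simulate_trajectory(cfg, s, _animal_rng(cfg.seed, i)) for i, s in enumerate(specs)]
    fixes = pd.concat(frames, ignore_index=True) if frames else _empty_fix_frame()
    captures = pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in specs],
            "site_id": [s.site_id for s in specs],
            "capture_time_utc": pd.to_datetime([s.capture_time for s in specs], utc=True),
            "method": [s.method for s in specs],
            "sex": [s.sex for s in specs],
            "age_class": [s.age_class for s in specs],
        }
    )
    return fixes, captures, _compute_truth(cfg, specs)


def write_dataset(
    fixes: pd.DataFrame, captures: pd.DataFrame, truth: SimTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write fixes.csv / captures.csv / truth.json with stable formatting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fixes": out / "fixes.csv",
        "captures": out / "captures.csv",
        "truth": out / "truth.json",
    }
    fx = fixes.copy()
    fx["timestamp_utc"] = fx["timestamp_utc"].dt.strftime(TIMESTAMP_FORMAT)
    fx.to_csv(paths["fixes"], index=False, float_format="%.3f")
    cp = captures.copy()
    cp["capture_time_utc"] = cp["capture_time_utc"].dt.strftime(TIMESTAMP_FORMAT)
    cp.to_csv(paths["captures"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
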