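"""Configuration objects: simulation settings and full pipeline runs.

Vocabularies (capture methods, sexes, age classes) are closed: every reader
and model in the package validates against them.
"""

from __future__ import annotations

import datetime as dt
import math
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

METHODS = ("box_trap", "box_trap_short", "net_drive", "net_drive_sedation", "net_trap")
SEXES = ("female", "male")
AGE_CLASSES = ("fawn", "yearling", "adult")

#: winter capture season limits (month, day): captures outside are rejected
#: when strict-season checking is on.
SEASON_START_MD = (10, 3)
SEASON_END_MD = (3, 25)
#: monitoring ends on 15 April of the capture season.
MONITORING_END_MD = (4, 15)


class ConfigurationError(ValueError):
    """Raised for invalid or non-finite configuration values."""


def _check_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ConfigurationError(f"{name} must be finite and > 0, got {value!r}")


def _check_fraction(name: str, value: float) -> None:
    if not math.isfinite(value) or not (0.0 <= value < 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1), got {value!r}")


@dataclass(frozen=True)
class SimConfig:
    """Settings for the synthetic winter roe-deer telemetry generator.

    Movement is a discrete-time Ornstein–Uhlenbeck (OU) process around an
    animal-specific range centre; the capture effect is a deterministic
    outward offset of the range centre of magnitude ``cog_shift_m *
    exp(-t/cog_decay_days)`` in a per-animal random direction, plus a
    suppression of the OU innovation SD by the factor
    ``1 - step_suppression * exp(-t/step_decay_days)``.

    Default method mixing proportions follow the observed composition of a
    large multi-site roe-deer capture programme (box trap 36%, box trap
    short 5%, net drive 25%, net drive with sedation 30%, net trap 4%).
    Scale defaults give winter home ranges of roughly 30 ha (stationary
    positional SD 150 m), a 2-sigma initial outward shift, and a decay time
    of 5 days for both effects.
    """

    n_animals: int = 100
    method_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "box_trap": 0.36,
            "box_trap_short": 0.05,
            "net_drive": 0.25,
            "net_drive_sedation": 0.30,
            "net_trap": 0.04,
        }
    )
    sites: int = 14
    season_start: dt.date = dt.date(2021, 10, 3)
    season_end: dt.date = dt.date(2022, 3, 25)
    fix_interval_h: float = 4.0
    range_centre_spread_m: float = 2000.0
    ou_sd_m: float = 150.0
    #: log-normal SD of the per-animal OU positional SD (home-range-size variation)
    ou_sd_log_sigma: float = 0.25
    ou_timescale_h: float = 12.0
    cog_shift_m: float = 300.0
    cog_decay_days: float = 5.0
    step_suppression: float = 0.5
    step_decay_days: float = 5.0
    fix_loss_prob: float = 0.1
    obs_noise_m: float = 15.0
    #: optional per-method decay-time overrides (days)
    tau_cog_by_method: Mapping[str, float] | None = None
    tau_step_by_method: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 0:
            raise ConfigurationError("n_animals must be >= 0")
        if self.sites < 1:
            raise ConfigurationError("sites must be >= 1")
        for name in (
            "fix_interval_h",
            "range_centre_spread_m",
            "ou_timescale_h",
            "cog_decay_days",
            "step_decay_days",
        ):
            _check_positive(name, getattr(self, name))
        # ou_sd_m = 0 is the degenerate (no-diffusion) case, allowed for testing
        for name in ("ou_sd_m", "cog_shift_m", "obs_noise_m", "ou_sd_log_sigma"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v!r}")
        _check_fraction("step_suppression", self.step_suppression)
        _check_fraction("fix_loss_prob", self.fix_loss_prob)
        if self.season_start >= self.season_end:
            raise ConfigurationError("season_start must precede season_end")
        unknown = set(self.method_mix) - set(METHODS)
        if unknown:
            raise ConfigurationError(f"unknown capture methods in method_mix: {sorted(unknown)}")
        total = sum(self.method_mix.values())
        if not math.isfinite(total) or total <= 0:
            raise ConfigurationError("method_mix proportions must sum to a positive number")
        for mapping, tag in (
            (self.tau_cog_by_method, "tau_cog_by_method"),
            (self.tau_step_by_method, "tau_step_by_method"),
        ):
            if mapping is not None:
                bad = set(mapping) - set(METHODS)
                if bad:
                    raise ConfigurationError(f"unknown methods in {tag}: {sorted(bad)}")
                for m, tau in mapping.items():
                    _check_positive(f"{tag}[{m}]", tau)

    def tau_cog(self, method: str) -> float:
        if self.tau_cog_by_method and method in self.tau_cog_by_method:
            return float(self.tau_cog_by_method[method])
        return float(self.cog_decay_days)

    def tau_step(self, method: str) -> float:
        if self.tau_step_by_method and method in self.tau_step_by_method:
            return float(self.tau_step_by_method[method])
        return float(self.step_decay_days)


@dataclass
class RunConfig:
    """Full pipeline settings: either input CSV paths or a simulation block.

    Defaults are the study protocol's values: max 6 fixes per 24 h (one per
    4 h), a 72-h maximum gap, minimum 20 days of monitoring with the first
    fix within 3 days of capture, home-range window days 11–21 with a
    minimum of 10 locations, monitoring to 15 April of the capture season.
    """

    fixes_path: Path | None = None
    captures_path: Path | None = None
    simulation: SimConfig | None = None
    out_dir: Path = Path("postcapture_out")
    seed: int = 0

    bin_hours: float = 4.0
    max_gap_hours: float = 72.0
    min_monitoring_days: float = 20.0
    max_first_fix_days: float = 3.0
    hr_window_days: tuple[float, float] = (11.0, 21.0)
    hr_min_locations: int = 10
    strict_season: bool = True

    basis_dim: int = 10
    select_by: str = "aicc"
    dcog_horizon_days: float = 60.0
    recovery_grid_step_days: float = 0.1
    make_plots: bool = False

    def __post_init__(self) -> None:
        for name in (
            "bin_hours",
            "max_gap_hours",
            "min_monitoring_days",
            "max_first_fix_days",
            "dcog_horizon_days",
            "recovery_grid_step_days",
        ):
            _check_positive(name, float(getattr(self, name)))
        lo, hi = self.hr_window_days
        if not (0 <= lo < hi):
            raise ConfigurationError("hr_window_days must satisfy 0 <= lo < hi")
        if self.hr_min_locations < 1:
            raise ConfigurationError("hr_min_locations must be >= 1")
        if self.basis_dim < 4:
            raise ConfigurationError("basis_dim must be >= 4 for a cubic spline basis")
        if self.simulation is None and (self.fixes_path is None or self.captures_path is None):
            raise ConfigurationError("provide either input CSV paths or a simulation block")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = None
        if "simulation" in raw:
            sim_raw = dict(raw.pop("simulation"))
            for key in ("season_start", "season_end"):
                if key in sim_raw and isinstance(sim_raw[key], str):
                    sim_raw[key] = dt.date.fromisoformat(sim_raw[key])
            sim = SimConfig(**sim_raw)
        kwargs: dict = {}
        for key, value in raw.items():
            if key in ("fixes_path", "captures_path", "out_dir"):
                kwargs[key] = Path(value)
            elif key == "hr_window_days":
                kwargs[key] = (float(value[0]), float(value[1]))
            else:
                kwargs[key] = value
        return cls(simulation=sim, **kwargs)

    def to_manifest_dict(self) -> dict:
        d = asdict(self)
        for key in ("fixes_path", "captures_path", "out_dir"):
            if d[key] is not None:
                d[key] = str(d[key])
        if d["simulation"] is not None:
            sim = d["simulation"]
            sim["season_start"] = sim["season_start"].isoformat()
            sim["season_end"] = sim["season_end"].isoformat()
            for k in ("method_mix", "tau_cog_by_method", "tau_step_by_method"):
                if sim[k] is not None:
                    sim[k] = dict(sim[k])
        d["hr_window_days"] = list(d["hr_window_days"])
        return d
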