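"""Simulation configuration for the synthetic laying-hen study population.

Defaults describe the emulated nucleus-farm structure: locations each
contributing a few consecutive hatches ('batches'), hens in individual
cages (row*level), egg collection on 1-4 day spans from onset of lay
until the batch is emptied between 91 and 105 weeks of age, batch-level
disturbance events of varying depth/duration, and low weekly mortality.

Genetic architecture: each animal carries breeding values for
(i) the logit-scale level of its daily lay probability, (ii) the log of
its sensitivity to disturbances (what makes ln(variance) of deviations
heritable), and (iii) a natural-antibody titer trait; plus an
independent maternal environmental effect shared by a dam's offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    # mating design (discrete generations, hierarchical sires x dams)
    n_generations: int = 3
    n_sires: int = 25
    n_dams_per_sire: int = 4
    n_offspring_per_dam: int = 14

    # farm structure
    n_locations: int = 3
    n_batches_per_location: int = 3
    n_rowlevels: int = 24

    # genetic (co)variances
    sigma2_a_level: float = 0.03       # additive var of lay-probability logit level
    sigma2_a_env: float = 0.08         # additive var of log disturbance-sensitivity
    r_a_level_env: float = 0.0
    sigma2_m: float = 0.015            # maternal environmental var (logit scale)
    sigma2_a_nab: float = 0.60         # antibody titer additive var
    r_a_nab_env: float = 0.0

    # cage / batch environment (logit scale)
    sigma2_rowlevel: float = 0.02
    sigma2_batch: float = 0.01

    # baseline lay curve (logit scale)
    onset_mean_weeks: float = 20.0
    onset_sd_weeks: float = 1.2
    plateau_p: float = 0.95
    plateau_week: float = 30.0
    decline_start_week: float = 60.0
    decline_logit_per_week: float = 0.045

    # disturbances: batch-wide events (heat, feed, management) plus
    # individual events (injury, transient illness); both depths are
    # scaled by the hen's multiplicative sensitivity exp(bv_env)
    disturbance_rate: float = 9.0        # batch events / batch / 100 weeks
    disturbance_depth: float = 2.2       # mean logit depth (Gamma, shape 2)
    disturbance_duration_weeks: float = 2.0  # mean duration (Exponential)
    indiv_disturbance_rate: float = 10.0  # individual events / hen / 100 weeks
    indiv_disturbance_depth: float = 2.2
    indiv_disturbance_duration_weeks: float = 1.25

    # mortality / batch end
    weekly_mortality_hazard: float = 0.0012
    batch_end_age_weeks: tuple[int, int] = (91, 105)

    # recording
    collection_span_days: dict = field(
        default_factory=lambda: {1: 0.2, 2: 0.3, 3: 0.3, 4: 0.2}
    )
    imputed_fraction: float = 0.02       # fraction of spans merged into longer ones
    double_egg_rate: float = 0.03        # chance an egg is booked on the next day

    # antibody sampling
    nab_sample_fraction: float = 0.25
    nab_mu: float = 7.0
    nab_age_beta: float = 0.2
    nab_sex_effect: float = 0.3
    nab_plate_sd: float = 0.3
    nab_sigma2_e: float = 1.2
    nab_plate_size: int = 90

    seed: int = 2024

    def __post_init__(self) -> None:
        counts = {
            "n_generations": self.n_generations,
            "n_sires": self.n_sires,
            "n_dams_per_sire": self.n_dams_per_sire,
            "n_offspring_per_dam": self.n_offspring_per_dam,
            "n_locations": self.n_locations,
            "n_batches_per_location": self.n_batches_per_location,
            "n_rowlevels": self.n_rowlevels,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v}")
        for name in (
            "sigma2_a_level", "sigma2_a_env", "sigma2_m", "sigma2_a_nab",
            "sigma2_rowlevel", "sigma2_batch", "nab_sigma2_e",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("r_a_level_env", "r_a_nab_env"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [-1, 1]")
        lo, hi = self.batch_end_age_weeks
        if not (91 <= lo <= hi <= 105):
            raise ConfigError("batch_end_age_weeks must lie within [91, 105]")
        p = self.collection_span_days
        if not p or any(k not in (1, 2, 3, 4) for k in p) or any(v < 0 for v in p.values()):
            raise ConfigError("collection_span_days must weight span lengths 1..4")
        total = sum(p.values())
        if abs(total - 1.0) > 1e-9:
            self.collection_span_days = {k: v / total for k, v in p.items()}

    @property
    def n_offspring_per_generation(self) -> int:
        return self.n_sires * self.n_dams_per_sire * self.n_offspring_per_dam

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["batch_end_age_weeks"] = list(self.batch_end_age_weeks)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "batch_end_age_weeks" in d:
            d["batch_end_age_weeks"] = tuple(d["batch_end_age_weeks"])
        if "collection_span_days" in d:
            d["collection_span_days"] = {
                int(k): float(v) for k, v in d["collection_span_days"].items()
            }
        return cls(**d)
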