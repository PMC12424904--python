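"""Configuration objects for simulation and analysis runs.

All tunable quantities of the pipeline live in small dataclasses that can be
constructed directly in Python or loaded from a YAML run-configuration file.
Hazards are piecewise constant on half-open 5-year age bins [a, a+5) covering
[0, 80) unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


AGE_BIN_WIDTH = 5.0

#: Default disease hazard per person-year by 5-year age bin on [0, 80).
#: Chosen to resemble a late-onset cardiometabolic disease (atrial
#: fibrillation-like): negligible before 30, rising steeply after 50,
#: cumulative incidence by 80 in the high teens once competing mortality
#: is accounted for.
DEFAULT_BASELINE_HAZARD = (
    1e-5, 1e-5, 1e-5, 1e-5, 1e-5, 1e-5,          # 0-30
    5e-4, 5e-4,                                   # 30-40
    1.5e-3, 1.5e-3,                               # 40-50
    4e-3, 4e-3,                                   # 50-60
    9e-3, 9e-3,                                   # 60-70
    1.8e-2, 1.8e-2,                               # 70-80
)

#: Default all-cause (disease-free) mortality hazard per person-year,
#: a Gompertz curve mu(a) = 2e-4 * exp(0.075 a) evaluated at bin midpoints.
DEFAULT_MORTALITY_HAZARD = tuple(
    float(2e-4 * np.exp(0.075 * (5 * k + 2.5))) for k in range(16)
)


@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic multi-study cohort.

    The generative model is proportional hazards on the age time scale:
    disease hazard for individual i in study s is

        lambda(a) * exp(beta_pgs_s * pgs_i + beta_edu * edu_i
                        + beta_inter * pgs_i * edu_i)

    with lambda piecewise constant per 5-year bin, beta_pgs_s = beta_pgs +
    N(0, tau_study^2) per study (between-study heterogeneity), competing
    mortality independent of covariates, and administrative censoring at
    ``admin_censor_age``.
    """

    n_per_study: int = 10_000
    n_studies: int = 3
    seed: int = 0
    beta_pgs: float = float(np.log(1.4))
    beta_edu: float = float(np.log(0.8))
    beta_inter: float = float(np.log(1.1))
    p_high_edu: float = 0.45
    rho_pgs_edu: float = 0.0
    baseline_hazard: Sequence[float] = DEFAULT_BASELINE_HAZARD
    mortality_hazard: Sequence[float] = DEFAULT_MORTALITY_HAZARD
    tau_study: float = 0.0
    entry_age_range: tuple[float, float] = (35.0, 80.0)
    admin_censor_age: float = 80.0
    sex_ratio: float = 0.55
    birth_year_range: tuple[int, int] = (1940, 1975)
    simulate_occupation: bool = False

    def __post_init__(self) -> None:
        if self.n_per_study <= 0 or self.n_studies <= 0:
            raise ConfigurationError("n_per_study and n_studies must be positive")
        if not 0.0 <= self.p_high_edu <= 1.0:
            raise ConfigurationError("p_high_edu must lie in [0, 1]")
        if not -1.0 <= self.rho_pgs_edu <= 1.0:
            raise ConfigurationError("|rho_pgs_edu| must not exceed 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        for name in ("baseline_hazard", "mortality_hazard"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ConfigurationError(f"{name} must be a 1-d sequence")
            if np.any(arr < 0):
                raise ConfigurationError(f"{name} must be non-negative")
            setattr(self, name, tuple(float(x) for x in arr))
        if len(self.baseline_hazard) != len(self.mortality_hazard):
            raise ConfigurationError("hazard schedules must share bin structure")
        lo, hi = self.entry_age_range
        if not (0.0 <= lo <= hi <= self.admin_censor_age):
            raise ConfigurationError(
                "entry_age_range must lie within [0, admin_censor_age]"
            )
        if self.tau_study < 0:
            raise ConfigurationError("tau_study must be non-negative")
        n_bins = len(self.baseline_hazard)
        if n_bins * AGE_BIN_WIDTH < self.admin_censor_age:
            raise ConfigurationError(
                "hazard bins must cover [0, admin_censor_age)"
            )

    @property
    def age_edges(self) -> np.ndarray:
        """Bin edges 0, 5, ..., of the piecewise-constant hazards."""
        return np.arange(len(self.baseline_hazard) + 1) * AGE_BIN_WIDTH


@dataclass
class StratumSpec:
    """Polygenic-score grouping used for stratum hazard ratios and risk curves.

    Default five groups <20%, 20-40%, 40-60% (reference), 60-95%, >95% with
    population weights equal to the quantile mass of each group.
    """

    quantile_cuts: tuple[float, ...] = (0.20, 0.40, 0.60, 0.95)
    group_labels: tuple[str, ...] = ("<20%", "20-40%", "40-60%", "60-95%", ">95%")
    reference: str = "40-60%"
    weights: tuple[float, ...] = (0.20, 0.20, 0.20, 0.35, 0.05)

    def __post_init__(self) -> None:
        cuts = np.asarray(self.quantile_cuts, dtype=float)
        if np.any(cuts <= 0) or np.any(cuts >= 1) or np.any(np.diff(cuts) <= 0):
            raise ConfigurationError("quantile_cuts must be strictly increasing in (0,1)")
        if len(self.group_labels) != len(cuts) + 1:
            raise ConfigurationError("need one label per group")
        if self.reference not in self.group_labels:
            raise ConfigurationError("reference must be one of group_labels")
        w = np.asarray(self.weights, dtype=float)
        if w.size != len(self.group_labels) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("weights must sum to 1, one per group")

    @property
    def reference_index(self) -> int:
        return self.group_labels.index(self.reference)


@dataclass
class EndpointSpec:
    """Per-disease analysis rules: sex restriction, study exclusions, max age."""

    disease_name: str = "synthetic_disease"
    sex_restriction: str = "none"  # none | female_only | male_only
    excluded_studies: frozenset[str] = frozenset()
    analysis_max_age: float = 80.0

    def __post_init__(self) -> None:
        if self.sex_restriction not in ("none", "female_only", "male_only"):
            raise ConfigurationError(f"unknown sex_restriction {self.sex_restriction!r}")
        if self.analysis_max_age <= 0:
            raise ConfigurationError("analysis_max_age must be positive")
        self.excluded_studies = frozenset(self.excluded_studies)


@dataclass
class ModelSpec:
    """Which Cox/logistic model of the battery to fit.

    model_id selects the risk-factor terms; ``adjust`` adds the standard
    covariates (sex, birth decade, genetic PCs).  The PC rule is 10 PCs
    whenever a PGS term is present, 5 otherwise, unless n_pcs is forced.
    """

    model_id: str = "joint"
    adjust: bool = True
    n_pcs: int | None = None

    _VALID = ("pgs_only", "edu_only", "joint", "interaction")

    def __post_init__(self) -> None:
        if self.model_id not in self._VALID:
            raise ConfigurationError(f"unknown model_id {self.model_id!r}")
        if self.n_pcs is not None and self.n_pcs not in (0, 5, 10):
            raise ConfigurationError("n_pcs must be one of 0, 5, 10")

    @property
    def has_pgs(self) -> bool:
        return self.model_id in ("pgs_only", "joint", "interaction")

    @property
    def has_education(self) -> bool:
        return self.model_id in ("edu_only", "joint", "interaction")

    @property
    def effective_n_pcs(self) -> int:
        if self.n_pcs is not None:
            return self.n_pcs
        if not self.adjust:
            return 0
        return 10 if self.has_pgs else 5


@dataclass
class RunConfig:
    """Top-level configuration for an end-to-end pipeline run."""

    simulate: SimConfig = field(default_factory=SimConfig)
    endpoints: list[EndpointSpec] = field(default_factory=lambda: [EndpointSpec()])
    strata: StratumSpec = field(default_factory=StratumSpec)
    bootstrap_b: int = 200
    prediction_fraction: float = 0.8
    multiplicity_m: int = 19
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicity_m < 1:
            raise ConfigurationError("multiplicity_m must be >= 1")
        if not 0.0 < self.prediction_fraction < 1.0:
            raise ConfigurationError("prediction_fraction must lie in (0, 1)")
        if self.bootstrap_b < 1:
            raise ConfigurationError("bootstrap_b must be >= 1")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**raw.get("simulate", {}))
    endpoints = [EndpointSpec(**e) for e in raw.get("endpoints", [{}])]
    strata_raw = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in raw.get("strata", {}).items()
    }
    strata = StratumSpec(**strata_raw)
    analysis = raw.get("analysis", {})
    return RunConfig(
        simulate=sim,
        endpoints=endpoints,
        strata=strata,
        bootstrap_b=int(analysis.get("bootstrap_b", 200)),
        prediction_fraction=float(analysis.get("prediction_fraction", 0.8)),
        multiplicity_m=int(analysis.get("multiplicity_m", 19)),
        alpha=float(analysis.get("alpha", 0.05)),
        seed=int(raw.get("seed", 0)),
    )


def config_hash(cfg) -> str:
    """Short deterministic hash of a configuration dataclass, for file headers."""
    import hashlib
    import json

    def _default(obj):
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return str(obj)

    payload = json.dumps(asdict(cfg), sort_keys=True, default=_default).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
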