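"""Configuration objects for cohort simulation and pipeline runs.

Two dataclasses drive everything: :class:`SimConfig` holds the data-generating
assumptions of the synthetic biobank cohort (genetic architecture, exposure
scales, exposure→hazard maps, censoring, missingness), and :class:`RunConfig`
holds the analysis switches (covariate schemes, quantile count, thresholds)
plus file paths for non-synthetic runs.  Both round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

#: The three adiposity exposures compared throughout the package.
EXPOSURES = ("bmi", "fmi", "whr")

#: Natural-unit (mean, SD) used to place standardized latent exposures on
#: realistic scales: BMI in kg/m^2, FMI in kg/m^2 of fat mass, WHR unitless.
#: These are fixture constants, overridable through ``SimConfig.exposure_scales``.
EXPOSURE_SCALES = {"bmi": (27.0, 4.7), "fmi": (8.0, 3.0), "whr": (0.87, 0.09)}

#: Cause-of-death categories used for cause-specific mortality.
CAUSES = ("cancer", "cvd", "respiratory", "other")


class ConfigError(ValueError):
    """Raised when a configuration object fails validation."""


@dataclass
class HazardShape:
    """Exposure→log-hazard map.

    ``quadratic`` gives a J-shape ``a * (X - c)^2`` in natural exposure units
    (curvature ``a`` >= 0, nadir ``c``); ``linear`` gives ``b * X_sd`` with the
    exposure in SD units; ``none`` contributes nothing.
    """

    kind: str = "none"
    curvature: float = 0.0
    nadir: Optional[float] = None
    slope: float = 0.0

    def validate(self, name: str = "hazard_shape") -> None:
        if self.kind not in {"quadratic", "linear", "none"}:
            raise ConfigError(f"{name}: unknown kind {self.kind!r}")
        if self.kind == "quadratic":
            if self.curvature < 0:
                raise ConfigError(f"{name}: quadratic curvature must be >= 0")
            if self.nadir is None:
                raise ConfigError(f"{name}: quadratic shape requires a nadir")

    def log_hazard(self, x_natural: np.ndarray, x_sd: np.ndarray) -> np.ndarray:
        """Evaluate the map's contribution to the log hazard."""
        if self.kind == "quadratic":
            return self.curvature * (np.asarray(x_natural) - self.nadir) ** 2
        if self.kind == "linear":
            return self.slope * np.asarray(x_sd)
        return np.zeros_like(np.asarray(x_natural, dtype=float))

    def per_sd_log_effect(self, sd: float) -> Optional[float]:
        """True per-SD log effect for a linear map; None for a J-shape."""
        if self.kind == "linear":
            return self.slope
        if self.kind == "none":
            return 0.0
        return None


def _default_exposure_corr() -> list:
    # Environmental-component correlations; BMI/FMI track closely, WHR loosely.
    return [[1.0, 0.85, 0.45], [0.85, 1.0, 0.40], [0.45, 0.40, 1.0]]


def _default_hazard_shapes() -> dict:
    return {
        "bmi": HazardShape(kind="quadratic", curvature=0.005, nadir=24.9),
        "fmi": HazardShape(kind="quadratic", curvature=0.012, nadir=6.15),
        "whr": HazardShape(kind="linear", slope=0.34),
    }


def _default_cause_mix() -> dict:
    return {"cancer": 0.48, "cvd": 0.20, "respiratory": 0.06, "other": 0.26}


@dataclass
class SimConfig:
    """Data-generating assumptions for a synthetic biobank-like cohort.

    Defaults emulate a middle-aged population cohort: ~5% annual-scale
    mortality pressure rising with age, three correlated adiposity exposures
    each with a polygenic score explaining 10% of variance, J-shaped
    BMI/FMI hazard maps with nadirs at 24.9 and 6.15 natural units, a
    monotone WHR map, ~4.9% missing phenotypes, and ~0.1% extreme BMI.
    """

    n_participants: int = 50_000
    n_variants: int = 100
    maf_range: tuple = (0.05, 0.5)
    prs_variance_explained: float = 0.1
    exposure_corr: list = field(default_factory=_default_exposure_corr)
    hazard_shape: dict = field(default_factory=_default_hazard_shapes)
    baseline_log_hazard: float = -5.5
    age_log_hazard: float = 0.09
    sex_log_hazard: float = 0.45
    followup_years: float = 12.5
    cause_mix: dict = field(default_factory=_default_cause_mix)
    missing_rate: float = 0.049
    extreme_bmi_rate: float = 0.001
    exposure_scales: dict = field(default_factory=lambda: dict(EXPOSURE_SCALES))
    seed: int = 0

    def __post_init__(self) -> None:
        self.hazard_shape = {
            k: (v if isinstance(v, HazardShape) else HazardShape(**v))
            for k, v in self.hazard_shape.items()
        }
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be positive")
        if self.n_variants < 0:
            raise ConfigError("n_variants must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0 <= self.prs_variance_explained < 1):
            raise ConfigError("prs_variance_explained must be in [0, 1)")
        corr = np.asarray(self.exposure_corr, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ConfigError("exposure_corr must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ConfigError("exposure_corr is not positive-definite")
        for name, shape in self.hazard_shape.items():
            shape.validate(f"hazard_shape[{name}]")
        if self.followup_years <= 0:
            raise ConfigError("followup_years must be positive")
        mix = dict(self.cause_mix)
        probs = np.array([mix.get(c, 0.0) for c in CAUSES], dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ConfigError("cause_mix probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigError(f"cause_mix must sum to 1, got {probs.sum()!r}")
        for nm in ("missing_rate", "extreme_bmi_rate"):
            v = getattr(self, nm)
            if not (0 <= v <= 1):
                raise ConfigError(f"{nm} must be in [0, 1]")

    def corr_matrix(self) -> np.ndarray:
        return np.asarray(self.exposure_corr, dtype=float)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class RunConfig:
    """Analysis configuration for a full pipeline run.

    Thresholds mirror the study design: PRS variants retained at association
    p < .01, nonlinearity flagged at F > 10, significance at p < .05, 20
    exposure quantiles in the stratified nonlinear MR.
    """

    out_dir: str = "adipomr_out"
    phenotype_path: Optional[str] = None
    dosage_path: Optional[str] = None
    weights_paths: Optional[dict] = None  # exposure -> weights TSV
    sim: Optional[SimConfig] = None
    schemes: tuple = ("adjusted",)
    n_quantiles: int = 20
    p_threshold: float = 0.01
    f_threshold: float = 10.0
    alpha: float = 0.05
    bootstrap_reps: int = 200
    nadir_bootstrap: int = 0
    min_events: int = 50
    weak_t: float = 2.0
    bmi_bounds: tuple = (15.0, 50.0)
    exclude_prevalent_for: Optional[str] = "any"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is not None and not isinstance(self.sim, SimConfig):
            self.sim = SimConfig.from_dict(self.sim)
        self.validate()

    def validate(self) -> None:
        if self.sim is None:
            for nm in ("phenotype_path", "dosage_path", "weights_paths"):
                if getattr(self, nm) is None:
                    raise ConfigError(f"non-synthetic run requires {nm}")
            for nm in ("phenotype_path", "dosage_path"):
                if not Path(getattr(self, nm)).exists():
                    raise ConfigError(f"{nm} does not exist: {getattr(self, nm)}")
            for exp, p in dict(self.weights_paths).items():
                if not Path(p).exists():
                    raise ConfigError(f"weights path for {exp} does not exist: {p}")
        if self.n_quantiles < 1:
            raise ConfigError("n_quantiles must be >= 1")
        if not (0 < self.p_threshold <= 1):
            raise ConfigError("p_threshold must be in (0, 1]")
        lo, hi = self.bmi_bounds
        if lo > hi:
            raise ConfigError("bmi_bounds must be ordered")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["schemes"] = list(d["schemes"])
        d["bmi_bounds"] = list(d["bmi_bounds"])
        if d["sim"] is not None:
            d["sim"]["maf_range"] = list(d["sim"]["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
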