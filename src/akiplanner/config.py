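"""Configuration models for the cohort generator, planners and risk pipeline.

All tunable knobs live here as pydantic models so that a whole pipeline run
is reproducible from a single JSON document.  The default ``CohortConfig``
encodes the published marginal distributions of a 998-patient adult cardiac
surgery cohort (preoperative demographics/labs, intraoperative anesthesia
parameters, and a 52.71% postoperative AKI prevalence).
"""

from __future__ import annotations

from typing import Dict, Literal, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

# Canonical column names -----------------------------------------------------

#: The eight preoperative features used as planner inputs.
PREOP_FEATURES = ["Age", "BMI", "CCB", "Cr", "Alb", "BS", "HbA1C", "Hct"]

#: The six intraoperative anesthesia parameters predicted by the planners.
PLAN_PARAMS = [
    "AnesthesiaTime",
    "CPBTime",
    "DiureticDose",
    "CrystalloidDose",
    "PC",
    "FFP",
]

#: Binary members of :data:`PLAN_PARAMS`.
BINARY_PLAN_PARAMS = ["PC", "FFP"]

#: Extended preoperative columns carried through as pass-through noise so the
#: feature-selection stage sees the full 27-column preoperative table.
EXTENDED_FEATURES = [
    "Gender",
    "Surgery",
    "Type",
    "HTN",
    "DM",
    "CKD",
    "PHTN",
    "COPD",
    "Stenting",
    "CVA",
    "ThreeVD",
    "ACEI",
    "ARB",
    "BB",
    "Diuretics",
    "Statin",
    "ASA",
    "NSAIDs",
    "EF",
]

CREATININE_COLUMNS = ["Cr", "Cr_day1", "Cr_day7"]

GROUP_POS = "AKI+"
GROUP_NEG = "AKI-"


class FeatureSpec(BaseModel):
    """Marginal distribution of one generated column.

    ``truncnorm`` / ``trunclognorm`` draw from a truncated distribution whose
    *truncated* mean and SD are moment-matched to ``mean``/``sd`` (the parent
    parameters are solved numerically, so clipping introduces no bias).
    ``bernoulli`` draws 0/1 with probability ``p``; ``categorical`` draws
    integer codes with probabilities ``probs``.
    """

    kind: Literal["truncnorm", "trunclognorm", "bernoulli", "categorical"]
    mean: Optional[float] = None
    sd: Optional[float] = None
    lo: Optional[float] = None
    hi: Optional[float] = None
    p: Optional[float] = None
    probs: Optional[Tuple[float, ...]] = None

    @model_validator(mode="after")
    def _check(self) -> "FeatureSpec":
        if self.kind in ("truncnorm", "trunclognorm"):
            if self.mean is None or self.sd is None or self.lo is None or self.hi is None:
                raise ValueError(f"{self.kind} spec requires mean, sd, lo, hi")
            if self.sd < 0:
                raise ValueError("sd must be >= 0")
            if self.lo >= self.hi:
                raise ValueError("clip-min must be < clip-max")
        elif self.kind == "bernoulli":
            if self.p is None or not (0.0 <= self.p <= 1.0):
                raise ValueError("bernoulli spec requires p in [0, 1]")
        elif self.kind == "categorical":
            if not self.probs or abs(sum(self.probs) - 1.0) > 1e-6:
                raise ValueError("categorical spec requires probs summing to 1")
        return self


def _default_preop_specs() -> Dict[str, FeatureSpec]:
    # Printed cohort marginals: mean +/- SD (range).  Serum creatinine is
    # strongly right-skewed (range 0.5-12 around mean 1.24) and uses a
    # truncated log-normal instead of a truncated normal.
    return {
        "Age": FeatureSpec(kind="truncnorm", mean=57.44, sd=11.40, lo=18, hi=85),
        "BMI": FeatureSpec(kind="truncnorm", mean=26.76, sd=3.04, lo=17, hi=41),
        "CCB": FeatureSpec(kind="bernoulli", p=0.2915),
        "Cr": FeatureSpec(kind="trunclognorm", mean=1.24, sd=0.80, lo=0.5, hi=12),
        "Alb": FeatureSpec(kind="truncnorm", mean=3.85, sd=0.66, lo=1.8, hi=6.8),
        "BS": FeatureSpec(kind="truncnorm", mean=162.03, sd=53.4, lo=77, hi=425),
        "HbA1C": FeatureSpec(kind="truncnorm", mean=6.16, sd=1.19, lo=3.7, hi=12),
        "Hct": FeatureSpec(kind="truncnorm", mean=39.34, sd=4.10, lo=23, hi=56),
    }


def _default_extended_specs() -> Dict[str, FeatureSpec]:
    # Pass-through columns at their printed marginal rates; independent of the
    # AKI label by construction (pure noise for feature selection).
    return {
        "Gender": FeatureSpec(kind="bernoulli", p=0.5992),  # 1 = male
        "Surgery": FeatureSpec(
            kind="categorical", probs=(0.6582, 0.1784, 0.0161, 0.0554, 0.0010, 0.0909)
        ),
        "Type": FeatureSpec(kind="bernoulli", p=0.8283),  # 1 = elective
        "HTN": FeatureSpec(kind="bernoulli", p=0.7164),
        "DM": FeatureSpec(kind="bernoulli", p=0.5105),
        "CKD": FeatureSpec(kind="bernoulli", p=0.1545),
        "PHTN": FeatureSpec(kind="bernoulli", p=0.4258),
        "COPD": FeatureSpec(kind="bernoulli", p=0.1713),
        "Stenting": FeatureSpec(kind="bernoulli", p=0.3236),
        "CVA": FeatureSpec(kind="bernoulli", p=0.1203),
        "ThreeVD": FeatureSpec(kind="bernoulli", p=0.6513),
        "ACEI": FeatureSpec(kind="bernoulli", p=0.4398),
        "ARB": FeatureSpec(kind="bernoulli", p=0.3958),
        "BB": FeatureSpec(kind="bernoulli", p=0.8176),
        "Diuretics": FeatureSpec(kind="bernoulli", p=0.6092),
        "Statin": FeatureSpec(kind="bernoulli", p=0.8817),
        "ASA": FeatureSpec(kind="bernoulli", p=0.8949),
        "NSAIDs": FeatureSpec(kind="bernoulli", p=0.0961),
        "EF": FeatureSpec(kind="truncnorm", mean=48.05, sd=9.54, lo=10, hi=66),
    }


def _default_plan_specs() -> Dict[str, FeatureSpec]:
    # Anesthesia-parameter marginals.  Where the printed range contradicts the
    # printed mean +/- SD (anesthesia time), or the SD is implausible
    # (crystalloid 0.03 L; the diuretic row repeats the BMI statistics),
    # plausible clip ranges / moments consistent with the printed range are
    # substituted; see docs/methods.md.
    return {
        "AnesthesiaTime": FeatureSpec(kind="truncnorm", mean=346.81, sd=71.29, lo=120, hi=700),
        "CPBTime": FeatureSpec(kind="truncnorm", mean=112.44, sd=32.33, lo=53, hi=350),
        "DiureticDose": FeatureSpec(kind="trunclognorm", mean=40.0, sd=25.0, lo=20, hi=180),
        "CrystalloidDose": FeatureSpec(kind="truncnorm", mean=1.49, sd=0.5, lo=1, hi=3),
        "PC": FeatureSpec(kind="bernoulli", p=0.5873),
        "FFP": FeatureSpec(kind="bernoulli", p=0.4904),
    }


def _default_risk_coefs() -> Dict[str, float]:
    # Log-odds of AKI per 1 SD of each preoperative feature: renal reserve
    # (Cr up, Alb down, Hct down), glycemic burden (BS, HbA1C up), and age.
    return {
        "Age": 0.6,
        "BMI": 0.3,
        "CCB": 0.3,
        "Cr": 1.2,
        "Alb": -0.5,
        "BS": 0.5,
        "HbA1C": 0.5,
        "Hct": -0.4,
    }


def _default_plan_coefs() -> Dict[str, Dict[str, float]]:
    # Linear dependence of plan means on standardized preoperative features,
    # in SD units of each parameter (for binaries, in log-odds units).  Gives
    # the planners learnable patient-specific structure on top of the group
    # shift.
    return {
        "AnesthesiaTime": {"BMI": 0.2, "Age": 0.15, "BS": 0.1},
        "CPBTime": {"Cr": 0.25, "Age": 0.2, "BMI": 0.15},
        "DiureticDose": {"Cr": 0.3, "Alb": -0.15},
        "CrystalloidDose": {"BMI": 0.2, "Hct": -0.1},
        "PC": {"Hct": -0.3},
        "FFP": {"Cr": 0.3},
    }


class SignalConfig(BaseModel):
    """Planted signal linking preoperative features to AKI risk and to plans."""

    risk_coefs: Dict[str, float] = Field(default_factory=_default_risk_coefs)
    plan_coefs: Dict[str, Dict[str, float]] = Field(default_factory=_default_plan_coefs)


def _default_plan_shift() -> Dict[str, float]:
    # Group separation between AKI+ and AKI- conditional plan means: 1 SD per
    # continuous parameter, +0.30 event probability per binary parameter.
    # Allocated symmetrically about the marginal mean so cohort-level
    # marginals stay at their printed values.
    return {
        "AnesthesiaTime": 1.0,
        "CPBTime": 1.0,
        "DiureticDose": 1.0,
        "CrystalloidDose": 1.0,
        "PC": 0.3,
        "FFP": 0.3,
    }


class CohortConfig(BaseModel):
    """Full specification of a synthetic cardiac-surgery cohort."""

    n_patients: int = Field(default=998, gt=0)
    prevalence_target: float = Field(default=0.5271, gt=0.0, lt=1.0)
    seed: int = 7
    include_extended: bool = True
    preop_specs: Dict[str, FeatureSpec] = Field(default_factory=_default_preop_specs)
    extended_specs: Dict[str, FeatureSpec] = Field(default_factory=_default_extended_specs)
    plan_specs: Dict[str, FeatureSpec] = Field(default_factory=_default_plan_specs)
    plan_shift: Dict[str, float] = Field(default_factory=_default_plan_shift)
    signal: SignalConfig = Field(default_factory=SignalConfig)
    plan_noise_frac: float = Field(default=0.6, gt=0.0)
    missingness_rates: Dict[str, float] = Field(default_factory=dict)
    #: AKI+ stage mix on the qualifying day (stages 1, 2, 3).
    stage_probs: Tuple[float, float, float] = (0.6, 0.25, 0.15)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        for name, rate in self.missingness_rates.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missingness rate for {name!r} must be in [0, 1)")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")
        return self

    def with_plan_shift(self, factor: float) -> "CohortConfig":
        """Return a copy with every plan-shift entry scaled by ``factor``.

        Continuous shifts scale in SD units; binary shifts scale in
        probability units (clipped later during generation).
        """
        cfg = self.model_copy(deep=True)
        base = _default_plan_shift()
        cfg.plan_shift = {k: base[k] * factor for k in base}
        return cfg


class ArchConfig(BaseModel):
    """Architecture and optimizer settings for a planner network.

    A three-layer feed-forward regression net: 8 inputs, two rectified hidden
    layers, 6 linear outputs on standardized targets.
    """

    hidden_sizes: Tuple[int, ...] = (16, 8)
    activation: Literal["relu", "tanh", "logistic"] = "relu"
    learning_rate: float = 1e-3
    max_epochs: int = Field(default=2000, gt=0)
    patience: int = Field(default=50, gt=0)
    validation_fraction: float = Field(default=0.1, gt=0.0, lt=0.5)
    batch_size: int = Field(default=64, gt=0)


class RiskConfig(BaseModel):
    """Settings for the risk geometry and its reports."""

    rounding_mode: Literal["truncate", "round"] = "truncate"
    n_clusters: int = Field(default=3, gt=0)
    grid_density: int = Field(default=2000, gt=0)
    #: Candidate-plan box for the recommender, per continuous parameter.
    slider_ranges: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: {
            "AnesthesiaTime": (120.0, 700.0),
            "CPBTime": (53.0, 350.0),
            "DiureticDose": (20.0, 180.0),
            "CrystalloidDose": (1.0, 3.0),
        }
    )


class PipelineConfig(BaseModel):
    """End-to-end pipeline configuration (generate -> label -> split ->
    train -> evaluate -> cluster -> export)."""

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    input_csv: Optional[str] = None  # when set, ingest instead of generate
    train_fraction: float = Field(default=0.85, gt=0.0, lt=1.0)
    seed: int = 7
    arch: ArchConfig = Field(default_factory=ArchConfig)
    risk: RiskConfig = Field(default_factory=RiskConfig)
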