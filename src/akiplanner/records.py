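"""Light-weight record types shared across modules.

The cohort itself travels as a pandas DataFrame; these dataclasses serve
the single-patient surfaces (plan prediction, the recommender, JSON I/O).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .config import BINARY_PLAN_PARAMS, PLAN_PARAMS, PREOP_FEATURES

__all__ = ["AnesthesiaPlan", "PatientRecord"]


@dataclass
class AnesthesiaPlan:
    """One intraoperative anesthesia plan.

    Continuous parameters are in their clinical units (minutes, mg, liters).
    The two transfusion parameters are stored as values in [0, 1]: hard 0/1
    for administered plans, continuous probabilities for model outputs
    (thresholded at 0.5 only for display).
    """

    anesthesia_time: float
    cpb_time: float
    diuretic_dose: float
    crystalloid_dose: float
    pc_transfusion: float
    ffp_transfusion: float

    _FIELDS = {
        "AnesthesiaTime": "anesthesia_time",
        "CPBTime": "cpb_time",
        "DiureticDose": "diuretic_dose",
        "CrystalloidDose": "crystalloid_dose",
        "PC": "pc_transfusion",
        "FFP": "ffp_transfusion",
    }

    def __post_init__(self) -> None:
        if self.anesthesia_time <= 0 or self.cpb_time <= 0:
            raise ValueError("times must be positive")
        if self.diuretic_dose < 0 or self.crystalloid_dose < 0:
            raise ValueError("doses must be non-negative")
        if not (0 <= self.pc_transfusion <= 1 and 0 <= self.ffp_transfusion <= 1):
            raise ValueError("transfusion values must lie in [0, 1]")
        if self.cpb_time > self.anesthesia_time:
            raise ValueError("cpb_time cannot exceed anesthesia_time")

    def to_array(self) -> np.ndarray:
        """Vector in canonical parameter order (binaries as stored values)."""
        return np.array([getattr(self, self._FIELDS[p]) for p in PLAN_PARAMS])

    @classmethod
    def from_array(cls, values) -> "AnesthesiaPlan":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PLAN_PARAMS),):
            raise ValueError(f"expected {len(PLAN_PARAMS)} plan values")
        return cls(**{cls._FIELDS[p]: float(v) for p, v in zip(PLAN_PARAMS, values)})

    def to_dict(self, threshold_binaries: bool = False) -> Dict[str, float]:
        out = {p: float(getattr(self, self._FIELDS[p])) for p in PLAN_PARAMS}
        if threshold_binaries:
            for p in BINARY_PLAN_PARAMS:
                out[p] = float(out[p] >= 0.5)
        return out


@dataclass
class PatientRecord:
    """One patient: preoperative features, administered plan, trajectory."""

    patient_id: str
    preop: Dict[str, float]
    plan_administered: Optional[AnesthesiaPlan] = None
    cr_baseline: Optional[float] = None
    cr_day1: Optional[float] = None
    cr_day7: Optional[float] = None
    group_truth: str = "unlabeled"
    full_preop: Dict[str, float] = field(default_factory=dict)

    def preop_vector(self) -> np.ndarray:
        missing = [f for f in PREOP_FEATURES if f not in self.preop]
        if missing:
            raise KeyError(f"missing preoperative features: {missing}")
        return np.array([float(self.preop[f]) for f in PREOP_FEATURES])
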