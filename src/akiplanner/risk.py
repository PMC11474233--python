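"""Distance-based AKI risk geometry, evaluation and plan recommendation.

A proposed anesthesia plan is located by the pair of Euclidean distances,
in z-scored plan space, to the two planner prototypes for the same patient:

* ``d_minus`` — distance to the AKI- Planner's prediction (horizontal axis);
* ``d_plus``  — distance to the AKI+ Planner's prediction (vertical axis).

Points above the y = x line (``d_plus > d_minus``) sit closer to the
low-risk prototype and are classified AKI-; points on or below the line
are classified AKI+ (ties are flagged risky — the clinically conservative
choice).  The *safety margin* of a plan is ``d_plus - d_minus``: the
recommender ranks candidate plans by this margin.

Plan space is standardized by a :class:`PlanScaler` fitted on the pooled
training plans so minutes, milligrams and liters weigh comparably; binary
transfusion parameters enter the metric as continuous values (the
planners' predicted probabilities are used as-is, never thresholded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .config import GROUP_NEG, GROUP_POS, PLAN_PARAMS, BINARY_PLAN_PARAMS, RiskConfig
from .planners import AffineScaler, PlannerModel
from .records import AnesthesiaPlan

__all__ = [
    "RiskPoint",
    "PlanScaler",
    "EvalReport",
    "TreatmentCluster",
    "risk_point",
    "risk_points",
    "classify",
    "evaluate",
    "compute_metrics",
    "kmeans_treatments",
    "majority_vote",
    "plan_shift",
    "recommend",
]


@dataclass(frozen=True)
class RiskPoint:
    """Location of one plan relative to the two planner prototypes."""

    d_minus: float
    d_plus: float

    def __post_init__(self):
        if self.d_minus < 0 or self.d_plus < 0:
            raise ValueError("distances must be non-negative")

    @property
    def margin(self) -> float:
        """Safety margin: positive when the plan sits nearer the low-risk
        prototype (above the y = x line)."""
        return self.d_plus - self.d_minus


@dataclass
class PlanScaler(AffineScaler):
    """Plan-space standardizer fitted on the pooled training plans."""

    param_names: List[str] = field(default_factory=lambda: list(PLAN_PARAMS))

    @classmethod
    def fit_plans(cls, plans: pd.DataFrame, param_names: Optional[Sequence[str]] = None):
        names = list(param_names) if param_names is not None else list(PLAN_PARAMS)
        base = AffineScaler.fit(plans[names].to_numpy(dtype=float))
        return cls(mean=base.mean, sd=base.sd, param_names=names)


def _as_vec(plan, names: Sequence[str]) -> np.ndarray:
    if isinstance(plan, AnesthesiaPlan):
        return plan.to_array()
    v = np.asarray(plan, dtype=float)
    if v.shape[-1] != len(names):
        raise ValueError(f"plan has {v.shape[-1]} components, expected {len(names)}")
    return v


def risk_points(
    plans, pred_minus, pred_plus, scaler: PlanScaler
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized distance pairs for (n, p) arrays of plans and prototypes."""
    if scaler is None or scaler.sd is None:
        raise ValueError("scaler must be fitted")
    P = scaler.transform(np.atleast_2d(np.asarray(plans, dtype=float)))
    Qm = scaler.transform(np.atleast_2d(np.asarray(pred_minus, dtype=float)))
    Qp = scaler.transform(np.atleast_2d(np.asarray(pred_plus, dtype=float)))
    d_minus = np.linalg.norm(P - Qm, axis=1)
    d_plus = np.linalg.norm(P - Qp, axis=1)
    return d_minus, d_plus


def risk_point(plan, pred_minus, pred_plus, scaler: PlanScaler) -> RiskPoint:
    """Distance pair for a single plan (Euclidean in z-scored plan space)."""
    names = scaler.param_names
    dm, dp = risk_points(
        _as_vec(plan, names), _as_vec(pred_minus, names), _as_vec(pred_plus, names), scaler
    )
    return RiskPoint(d_minus=float(dm[0]), d_plus=float(dp[0]))


def classify(point: RiskPoint) -> str:
    """y = x rule: AKI+ iff the plan is on or below the line (d_plus <= d_minus)."""
    return GROUP_POS if point.d_plus <= point.d_minus else GROUP_NEG


def _round3(x: float, mode: str) -> float:
    if mode == "truncate":
        return math.floor(x * 1000 + 1e-9) / 1000.0
    if mode == "round":
        return round(x, 3)
    raise ValueError(f"unknown rounding mode {mode!r}")


def compute_metrics(
    tp: int, fp: int, fn: int, tn: int, mode: str = "truncate"
) -> Dict[str, float]:
    """Precision/recall/accuracy/F1 from a confusion matrix, at 3 decimals.

    F1 is the harmonic mean of the *already 3-decimal* precision and recall
    (matching the reporting convention of the original tables); the default
    3-decimal mode is truncation.  Degenerate denominators yield 0.
    """
    for v in (tp, fp, fn, tn):
        if v < 0 or int(v) != v:
            raise ValueError("confusion-matrix cells must be non-negative integers")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    precision = _round3(tp / (tp + fp) if tp + fp else 0.0, mode)
    recall = _round3(tp / (tp + fn) if tp + fn else 0.0, mode)
    accuracy = _round3((tp + tn) / n, mode)
    f1 = (
        _round3(2 * precision * recall / (precision + recall), mode)
        if precision + recall > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "accuracy": accuracy, "f1": f1}


@dataclass
class EvalReport:
    """Confusion matrix, summary metrics and the exported scatter points."""

    tp: int
    fp: int
    fn: int
    tn: int
    metrics: Dict[str, float]
    scatter: pd.DataFrame  # PatientID, d_minus, d_plus, truth, prediction
    rounding_mode: str = "truncate"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "confusion": {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn},
            "n": self.n,
            "rounding_mode": self.rounding_mode,
            **self.metrics,
        }


def evaluate(
    model_minus: PlannerModel,
    model_plus: PlannerModel,
    records: pd.DataFrame,
    scaler: PlanScaler,
    mode: str = "truncate",
) -> EvalReport:
    """Classify each record's administered plan and tally against truth.

    AKI+ is the positive class.  Records must carry the planner features,
    the administered plan columns and a ``Group`` truth label, with missing
    features already imputed.
    """
    if len(records) == 0:
        raise ValueError("no records to evaluate")
    plans = records[scaler.param_names].to_numpy(dtype=float)
    pred_m = model_minus.predict(records)
    pred_p = model_plus.predict(records)
    dm, dp = risk_points(plans, pred_m, pred_p, scaler)
    predicted = np.where(dp <= dm, GROUP_POS, GROUP_NEG)
    truth = records["Group"].to_numpy()

    tp = int(np.sum((predicted == GROUP_POS) & (truth == GROUP_POS)))
    fp = int(np.sum((predicted == GROUP_POS) & (truth == GROUP_NEG)))
    fn = int(np.sum((predicted == GROUP_NEG) & (truth == GROUP_POS)))
    tn = int(np.sum((predicted == GROUP_NEG) & (truth == GROUP_NEG)))

    scatter = pd.DataFrame(
        {
            "PatientID": records["PatientID"].to_numpy()
            if "PatientID" in records
            else np.arange(len(records)),
            "d_minus": dm,
            "d_plus": dp,
            "truth": truth,
            "prediction": predicted,
        }
    )
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        metrics=compute_metrics(tp, fp, fn, tn, mode=mode),
        scatter=scatter,
        rounding_mode=mode,
    )


@dataclass
class TreatmentCluster:
    """One candidate treatment: a cluster center over administered plans."""

    center: Dict[str, float]  # clinical units; binaries as event fractions
    member_count: int
    label: str  # 'low-risk' | 'high-risk' by member-stratum majority
    ranges: Dict[str, Tuple[float, float]]  # center +/- within-cluster SD

    def center_plan(self) -> AnesthesiaPlan:
        return AnesthesiaPlan.from_array([self.center[p] for p in PLAN_PARAMS])


def kmeans_treatments(
    plans: pd.DataFrame,
    strata: Sequence[str],
    k: int = 3,
    seed: int = 0,
    param_names: Optional[Sequence[str]] = None,
) -> List[TreatmentCluster]:
    """Cluster administered plans into k candidate treatments.

    Lloyd iterations with k-means++ initialization run on z-scored plans;
    each cluster is labeled low- or high-risk by the majority AKI stratum
    of its members, and reported as center +/- within-cluster SD in
    clinical units.
    """
    names = list(param_names) if param_names is not None else list(PLAN_PARAMS)
    X = plans[names].to_numpy(dtype=float)
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct plans")
    scaler = PlanScaler.fit_plans(plans, names)
    Z = scaler.transform(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=300)
    assign = km.fit_predict(Z)
    strata_arr = np.asarray(strata)

    clusters: List[TreatmentCluster] = []
    for c in range(k):
        members = assign == c
        center = scaler.inverse(km.cluster_centers_[c])
        sds = X[members].std(axis=0, ddof=0) if members.sum() > 1 else np.zeros(len(names))
        n_pos = int(np.sum(strata_arr[members] == GROUP_POS))
        label = "high-risk" if n_pos * 2 > members.sum() else "low-risk"
        clusters.append(
            TreatmentCluster(
                center={p: float(v) for p, v in zip(names, center)},
                member_count=int(members.sum()),
                label=label,
                ranges={
                    p: (float(center[j] - sds[j]), float(center[j] + sds[j]))
                    for j, p in enumerate(names)
                },
            )
        )
    return clusters


def majority_vote(votes: Sequence) -> Tuple[object, bool]:
    """Modal choice of three raters; a 1-1-1 tie returns the first rater's
    vote with the tie flag set."""
    if not votes:
        raise ValueError("no votes")
    counts: Dict[object, int] = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    winners = [v for v, c in counts.items() if c == best]
    if len(winners) == 1:
        return winners[0], False
    return votes[0], True


def plan_shift(
    preop,
    plan_before,
    plan_after,
    model_minus: PlannerModel,
    model_plus: PlannerModel,
    scaler: PlanScaler,
) -> Tuple[RiskPoint, RiskPoint, bool]:
    """Compare an administered plan (R1) with a proposed one (R2).

    The proposal *improves* on the administered plan when its safety margin
    ``d_plus - d_minus`` strictly increases — the point moves toward (or
    further above) the y = x line.
    """
    pm = model_minus.predict(np.asarray(preop, dtype=float))
    pp = model_plus.predict(np.asarray(preop, dtype=float))
    r1 = risk_point(plan_before, pm, pp, scaler)
    r2 = risk_point(plan_after, pm, pp, scaler)
    return r1, r2, bool(r2.margin > r1.margin)


def recommend(
    preop,
    model_minus: PlannerModel,
    model_plus: PlannerModel,
    scaler: PlanScaler,
    risk_config: Optional[RiskConfig] = None,
    seed: int = 0,
    n_candidates: Optional[int] = None,
) -> pd.DataFrame:
    """Rank candidate plans for one patient by descending safety margin.

    Candidates are the AKI- Planner's own prediction plus a seeded random
    scan of the slider box (continuous parameters uniform in their slider
    ranges, transfusion parameters drawn 0/1).  Each row carries the plan,
    its distance pair, the margin, and a low-/high-risk tag (margin > 0
    means nearer the low-risk prototype).
    """
    cfg = risk_config or RiskConfig()
    n_cand = n_candidates if n_candidates is not None else cfg.grid_density
    names = scaler.param_names
    cont = [p for p in names if p not in BINARY_PLAN_PARAMS]
    for p in cont:
        if p not in cfg.slider_ranges:
            raise ValueError(f"no slider range for parameter {p!r}")
        lo, hi = cfg.slider_ranges[p]
        if not lo < hi:
            raise ValueError(f"empty slider range for parameter {p!r}")

    rng = np.random.default_rng(seed)
    x = np.asarray(preop, dtype=float)
    proto_m = np.atleast_2d(model_minus.predict(x))
    proto_p = np.atleast_2d(model_plus.predict(x))

    cand = np.empty((n_cand, len(names)))
    for j, p in enumerate(names):
        if p in BINARY_PLAN_PARAMS:
            cand[:, j] = (rng.random(n_cand) < 0.5).astype(float)
        else:
            lo, hi = cfg.slider_ranges[p]
            cand[:, j] = rng.uniform(lo, hi, size=n_cand)
    if "CPBTime" in names and "AnesthesiaTime" in names:
        jc, ja = names.index("CPBTime"), names.index("AnesthesiaTime")
        cand[:, jc] = np.minimum(cand[:, jc], cand[:, ja])
    cand = np.vstack([proto_m, cand])  # planner's own proposal first

    dm, dp = risk_points(cand, np.repeat(proto_m, len(cand), 0), np.repeat(proto_p, len(cand), 0), scaler)
    out = pd.DataFrame(cand, columns=names)
    out["d_minus"] = dm
    out["d_plus"] = dp
    out["margin"] = dp - dm
    out["risk_tag"] = np.where(out["margin"] > 0, "low-risk", "high-risk")
    out = out.sort_values("margin", ascending=False, kind="mergesort").reset_index(drop=True)
    return out
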