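"""Gradient-boosted-tree importance ranking of preoperative features.

The full preoperative table carries 27 columns; the planners use only the
eight most informative (Cr, BS, Alb, HbA1C, Age, BMI, Hct, CCB).  With
patient-level data in hand a user can re-rank features against the AKI
label with :func:`rank_features`; the canonical eight remain the default
selection so the rest of the pipeline is well defined even when a
re-ranking on other data disagrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

__all__ = ["RankingParams", "FeatureRanking", "rank_features", "select_columns"]

#: Canonical planner inputs, in the order they are conventionally listed.
CANONICAL_SELECTION = ["Cr", "BS", "Alb", "HbA1C", "Age", "BMI", "Hct", "CCB"]


@dataclass(frozen=True)
class RankingParams:
    """Booster hyperparameters for the importance ranking.

    Conventional small-tabular settings; overridable, and recorded in the
    ranking so a run is reproducible.
    """

    max_depth: int = 3
    n_estimators: int = 200
    learning_rate: float = 0.1
    importance_type: str = "gain"


@dataclass
class FeatureRanking:
    """Importance-ordered features with their scores and the selected top-k."""

    ranking: List[Tuple[str, float]]
    selection_k: int
    params: RankingParams = field(default_factory=RankingParams)
    seed: int = 0

    @property
    def selected(self) -> List[str]:
        return [name for name, _ in self.ranking[: self.selection_k]]

    def scores(self) -> Dict[str, float]:
        return dict(self.ranking)


def rank_features(
    X: pd.DataFrame,
    y: Sequence,
    params: Optional[RankingParams] = None,
    seed: int = 0,
    selection_k: int = 8,
) -> FeatureRanking:
    """Fit a gradient-boosted tree classifier and rank columns by gain.

    Missing cells are handled natively by the tree learner through
    default-direction splits; no imputation happens here.  Features the
    booster never splits on (including constant columns) score exactly 0.
    Ties are broken by column order.
    """
    y_arr = np.asarray(y)
    if np.unique(y_arr[~pd.isna(y_arr)]).size < 2:
        raise ValueError("labels must contain both classes")
    all_missing = [c for c in X.columns if X[c].isna().all()]
    if all_missing:
        raise ValueError(f"all-missing columns: {all_missing}")

    params = params or RankingParams()
    y_bin = pd.factorize(y_arr, sort=True)[0]
    model = XGBClassifier(
        max_depth=params.max_depth,
        n_estimators=params.n_estimators,
        learning_rate=params.learning_rate,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    model.fit(X.to_numpy(dtype=float), y_bin)
    raw = model.get_booster().get_score(importance_type=params.importance_type)
    scores = {c: float(raw.get(f"f{i}", 0.0)) for i, c in enumerate(X.columns)}

    order = sorted(
        range(len(X.columns)), key=lambda i: (-scores[X.columns[i]], i)
    )
    ranking = [(X.columns[i], scores[X.columns[i]]) for i in order]
    return FeatureRanking(ranking=ranking, selection_k=selection_k, params=params, seed=seed)


def select_columns(
    cohort: pd.DataFrame,
    ranking: Optional[FeatureRanking] = None,
    k: Optional[int] = None,
) -> pd.DataFrame:
    """Return the selected feature columns, in the table's own column order.

    Without a ranking, the canonical eight-feature selection applies.
    """
    if ranking is None:
        wanted = CANONICAL_SELECTION if k is None else CANONICAL_SELECTION[:k]
    else:
        kk = ranking.selection_k if k is None else k
        wanted = [name for name, _ in ranking.ranking[:kk]]
    missing = [c for c in wanted if c not in cohort.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    keep = [c for c in cohort.columns if c in set(wanted)]
    return cohort[keep]
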