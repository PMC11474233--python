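"""The AKI- and AKI+ Planners: stratum-specific plan-regression networks.

Each planner is a three-layer feed-forward network (8 standardized
preoperative inputs -> two rectified hidden layers -> 6 linear outputs on
standardized targets) trained by minimizing joint mean squared error on its
own stratum: the AKI- Planner on patients who stayed injury-free, the AKI+
Planner on patients who developed postoperative AKI.  The AKI- output is
the low-risk plan prototype for a patient; the AKI+ output is the high-risk
prototype the anesthesiologist should keep a margin from.

Training uses scikit-learn's Adam-based MLP with a seeded 10% validation
slice for early stopping; the fitted weights and both affine scalers are
extracted into the :class:`PlannerModel`, which performs its own forward
pass and serializes to plain JSON so a trained planner can be reloaded by
any runtime.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .config import (
    BINARY_PLAN_PARAMS,
    PLAN_PARAMS,
    PREOP_FEATURES,
    ArchConfig,
    CohortConfig,
)
from .records import AnesthesiaPlan

__all__ = ["AffineScaler", "Imputer", "PlannerModel", "train_planner"]

_ACTIVATIONS = {
    "relu": lambda x: np.maximum(x, 0.0),
    "tanh": np.tanh,
    "logistic": lambda x: 1.0 / (1.0 + np.exp(-x)),
}


def default_plan_ranges() -> Dict[str, tuple]:
    """Plausible clinical ranges used to clip planner outputs."""
    specs = CohortConfig().plan_specs
    out = {}
    for p in PLAN_PARAMS:
        if p in BINARY_PLAN_PARAMS:
            out[p] = (0.0, 1.0)
        else:
            out[p] = (specs[p].lo, specs[p].hi)
    return out


@dataclass
class AffineScaler:
    """Per-column affine standardization; degenerate SDs are replaced by 1."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "AffineScaler":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd <= 1e-12, 1.0, sd)
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineScaler":
        return cls(mean=np.asarray(d["mean"]), sd=np.asarray(d["sd"]))


@dataclass
class Imputer:
    """Median (continuous) / mode (binary) fills learned on training data."""

    fills: Dict[str, float]

    @classmethod
    def fit(
        cls, train: pd.DataFrame, columns: Optional[Sequence[str]] = None
    ) -> "Imputer":
        columns = list(columns) if columns is not None else list(train.columns)
        fills: Dict[str, float] = {}
        for c in columns:
            col = pd.to_numeric(train[c], errors="coerce")
            observed = col.dropna()
            if observed.empty:
                raise ValueError(f"feature {c!r} has no observed training values")
            values = observed.unique()
            if set(np.unique(values)).issubset({0.0, 1.0}):
                fills[c] = float(observed.mode().iloc[0])
            else:
                fills[c] = float(observed.median())
        return cls(fills=fills)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c, v in self.fills.items():
            if c in out.columns:
                out[c] = out[c].fillna(v)
        return out

    def to_dict(self) -> dict:
        return dict(self.fills)

    @classmethod
    def from_dict(cls, d: dict) -> "Imputer":
        return cls(fills={k: float(v) for k, v in d.items()})


@dataclass
class PlannerModel:
    """A trained planner: scalers + layer weights + training metadata."""

    stratum: str
    arch: ArchConfig
    input_scaler: AffineScaler
    output_scaler: AffineScaler
    weights: List[np.ndarray]  # alternating W (in x out) and b per layer
    biases: List[np.ndarray]
    seed: int
    feature_names: List[str] = field(default_factory=lambda: list(PREOP_FEATURES))
    param_names: List[str] = field(default_factory=lambda: list(PLAN_PARAMS))
    clip_ranges: Dict[str, tuple] = field(default_factory=default_plan_ranges)
    training_meta: dict = field(default_factory=dict)

    # -- forward pass -------------------------------------------------------

    def _forward(self, Z: np.ndarray) -> np.ndarray:
        act = _ACTIVATIONS[self.arch.activation]
        h = Z
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < len(self.weights) - 1:
                h = act(h)
        return h

    def predict(self, X) -> np.ndarray:
        """Predict plans for a feature table / array (rows in clinical units).

        Returns an (n, 6) array: continuous parameters inverse-scaled and
        clipped to their plausible ranges, binary parameters as
        probabilities clipped to [0, 1], and cpb_time <= anesthesia_time
        enforced.
        """
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        one = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        if not np.isfinite(X).all():
            raise ValueError("inputs must be finite (impute before predicting)")
        Y = self.output_scaler.inverse(self._forward(self.input_scaler.transform(X)))
        for j, p in enumerate(self.param_names):
            lo, hi = self.clip_ranges.get(p, (-np.inf, np.inf))
            Y[:, j] = np.clip(Y[:, j], lo, hi)
        if "CPBTime" in self.param_names and "AnesthesiaTime" in self.param_names:
            i_cpb = self.param_names.index("CPBTime")
            i_ane = self.param_names.index("AnesthesiaTime")
            Y[:, i_cpb] = np.minimum(Y[:, i_cpb], Y[:, i_ane])
        return Y[0] if one else Y

    def predict_plan(self, preop) -> AnesthesiaPlan:
        """Predict a single :class:`AnesthesiaPlan` from an 8-feature vector."""
        return AnesthesiaPlan.from_array(self.predict(np.asarray(preop, dtype=float)))

    # -- persistence --------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "stratum": self.stratum,
            "arch": self.arch.model_dump(),
            "seed": self.seed,
            "feature_names": self.feature_names,
            "param_names": self.param_names,
            "input_scaler": self.input_scaler.to_dict(),
            "output_scaler": self.output_scaler.to_dict(),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "clip_ranges": {k: list(v) for k, v in self.clip_ranges.items()},
            "training_meta": self.training_meta,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PlannerModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            stratum=doc["stratum"],
            arch=ArchConfig(**doc["arch"]),
            input_scaler=AffineScaler.from_dict(doc["input_scaler"]),
            output_scaler=AffineScaler.from_dict(doc["output_scaler"]),
            weights=[np.asarray(w) for w in doc["weights"]],
            biases=[np.asarray(b) for b in doc["biases"]],
            seed=doc["seed"],
            feature_names=doc["feature_names"],
            param_names=doc["param_names"],
            clip_ranges={k: tuple(v) for k, v in doc["clip_ranges"].items()},
            training_meta=doc.get("training_meta", {}),
        )


def train_planner(
    stratum_records: pd.DataFrame,
    stratum: str,
    arch: Optional[ArchConfig] = None,
    seed: int = 0,
    feature_names: Sequence[str] = PREOP_FEATURES,
    param_names: Sequence[str] = PLAN_PARAMS,
    clip_ranges: Optional[Mapping[str, tuple]] = None,
) -> PlannerModel:
    """Fit one planner on its stratum's (already imputed) records.

    Inputs and targets are standardized by scalers frozen from the training
    stratum; the net minimizes joint MSE with Adam, early-stopping on a
    seeded 10% validation slice.  The same seed reproduces identical
    weights.
    """
    arch = arch or ArchConfig()
    if len(stratum_records) < 20:
        raise ValueError("need at least 20 records to train a planner")
    X = stratum_records[list(feature_names)].to_numpy(dtype=float)
    Y = stratum_records[list(param_names)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("training features contain missing values; impute first")

    in_scaler = AffineScaler.fit(X)
    out_scaler = AffineScaler.fit(Y)
    Z, T = in_scaler.transform(X), out_scaler.transform(Y)

    if np.allclose(Y.std(axis=0), 0.0):
        # Degenerate stratum: every target constant.  The MSE minimizer is
        # that constant, reached exactly by a zero network on standardized
        # targets -- no gradient descent needed.
        sizes = [X.shape[1], *arch.hidden_sizes, Y.shape[1]]
        return PlannerModel(
            stratum=stratum,
            arch=arch,
            input_scaler=in_scaler,
            output_scaler=out_scaler,
            weights=[np.zeros((a, b)) for a, b in zip(sizes, sizes[1:])],
            biases=[np.zeros(b) for b in sizes[1:]],
            seed=seed,
            feature_names=list(feature_names),
            param_names=list(param_names),
            clip_ranges=dict(clip_ranges) if clip_ranges else default_plan_ranges(),
            training_meta={"n_train": int(len(Z)), "epochs": 0,
                           "degenerate_constant_targets": True},
        )

    n_fit = max(1, int(len(Z) * (1 - arch.validation_fraction)))
    net = MLPRegressor(
        hidden_layer_sizes=tuple(arch.hidden_sizes),
        activation=arch.activation,
        solver="adam",
        learning_rate_init=arch.learning_rate,
        max_iter=arch.max_epochs,
        early_stopping=True,
        validation_fraction=arch.validation_fraction,
        n_iter_no_change=arch.patience,
        batch_size=min(arch.batch_size, n_fit),
        random_state=seed,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        # patience-based early stopping is the intended stop rule; reaching
        # max_epochs first is not an error
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(Z, T)
    if not np.isfinite(net.loss_):
        raise RuntimeError(
            f"planner training diverged (loss={net.loss_}); "
            "lower the learning rate or check the inputs"
        )

    return PlannerModel(
        stratum=stratum,
        arch=arch,
        input_scaler=in_scaler,
        output_scaler=out_scaler,
        weights=[np.asarray(w) for w in net.coefs_],
        biases=[np.asarray(b) for b in net.intercepts_],
        seed=seed,
        feature_names=list(feature_names),
        param_names=list(param_names),
        clip_ranges=dict(clip_ranges) if clip_ranges else default_plan_ranges(),
        training_meta={
            "n_train": int(len(Z)),
            "epochs": int(net.n_iter_),
            "final_loss": float(net.loss_),
            "loss_curve": [float(v) for v in net.loss_curve_],
            "best_validation_score": float(net.best_validation_score_),
        },
    )
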