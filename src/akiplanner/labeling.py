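"""KDIGO creatinine staging, AKI group assignment and the stratified split.

Postoperative kidney injury is staged from serum creatinine alone (urine
output and renal-replacement criteria are out of scope: the cohort schema
carries no urine data).  Each postoperative day is compared against the
preoperative baseline:

* stage 3 — creatinine >= 3.0x baseline, or an absolute value >= 4.0 mg/dL
  reached with a qualifying rise (>= 0.3 mg/dL over baseline);
* stage 2 — creatinine >= 2.0x baseline;
* stage 1 — creatinine >= 1.5x baseline, or an absolute rise >= 0.3 mg/dL;
* stage 0 — neither trigger fires.

A patient is AKI+ when either postoperative day (1 or 7) stages >= 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import GROUP_NEG, GROUP_POS

__all__ = ["kdigo_stage", "assign_group", "label_cohort", "stratified_split"]


def kdigo_stage(cr_baseline, cr_post):
    """Stage a postoperative creatinine value against baseline (0-3).

    Accepts scalars or numpy arrays; returns int or int array.
    """
    scalar = np.ndim(cr_baseline) == 0 and np.ndim(cr_post) == 0
    base, post = np.broadcast_arrays(
        np.atleast_1d(np.asarray(cr_baseline, dtype=float)),
        np.atleast_1d(np.asarray(cr_post, dtype=float)),
    )
    if np.any(base <= 0) or np.any(post <= 0):
        raise ValueError("creatinine values must be positive")

    ratio = post / base
    rise = post - base
    stage = np.zeros(base.shape, dtype=int)
    stage[(ratio >= 1.5) | (rise >= 0.3)] = 1
    stage[ratio >= 2.0] = 2
    stage[(ratio >= 3.0) | ((post >= 4.0) & (rise >= 0.3))] = 3
    if scalar:
        return int(stage[0])
    return stage


def assign_group(cr_baseline, cr_day1, cr_day7):
    """AKI+ iff the worse of the day-1 / day-7 stages is >= 1."""
    s1 = kdigo_stage(cr_baseline, cr_day1)
    s7 = kdigo_stage(cr_baseline, cr_day7)
    worst = np.maximum(s1, s7)
    if np.ndim(worst) == 0:
        return GROUP_POS if worst >= 1 else GROUP_NEG
    return np.where(worst >= 1, GROUP_POS, GROUP_NEG)


def label_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-day stages and the Group column from the trajectory."""
    out = cohort.copy()
    out["Stage_day1"] = kdigo_stage(out["Cr"].to_numpy(), out["Cr_day1"].to_numpy())
    out["Stage_day7"] = kdigo_stage(out["Cr"].to_numpy(), out["Cr_day7"].to_numpy())
    out["Group"] = assign_group(
        out["Cr"].to_numpy(), out["Cr_day1"].to_numpy(), out["Cr_day7"].to_numpy()
    )
    return out


def stratified_split(
    cohort: pd.DataFrame,
    train_fraction: float = 0.85,
    seed: int = 0,
    group_col: str = "Group",
) -> pd.Series:
    """Assign each patient to 'train' or 'test', stratified by AKI group.

    Within each stratum, ``floor(train_fraction * stratum_size)`` patients
    go to training and the remainder to test (floor allocation keeps the
    published 848/150 bookkeeping exact: 472 -> 401/71, 526 -> 447/79).
    Membership within a stratum is randomized by ``seed``.
    """
    if group_col not in cohort.columns:
        raise KeyError(f"missing group column {group_col!r}")
    rng = np.random.default_rng(seed)
    partition = pd.Series(index=cohort.index, dtype=object, name="partition")
    for _, idx in cohort.groupby(group_col, sort=True).groups.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            warnings.warn("empty stratum in stratified split", stacklevel=2)
            continue
        n_train = int(np.floor(train_fraction * idx.size))
        perm = rng.permutation(idx.size)
        partition.loc[idx[perm[:n_train]]] = "train"
        partition.loc[idx[perm[n_train:]]] = "test"
    return partition
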