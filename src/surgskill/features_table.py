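"""Assemble recordings into labeled feature tables.

The trial-level table has one row per (subject, task, trial, muscle,
side) with the six linear EMG features and the nonlinear accelerometer
features.  Aggregation across trials within (subject, task, muscle,
side) produces the ``Mean_*`` / ``Var_MSE`` feature names used by the
selection report.  Missing values stay as NaN — the mask is explicit,
never silently imputed here.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .emg_features import EMG_FEATURE_NAMES, emg_feature_vector
from .nonlinear import ACC_TRIAL_FEATURES, NonlinearParams, acc_feature_vector
from .types import Recording, SKILLS

logger = logging.getLogger(__name__)

INDEX_COLS = ["subject_id", "skill", "task", "trial", "muscle", "side"]

#: Aggregated feature names in the selection-report convention.
AGGREGATED_NAMES = {
    "Apen": "Mean_Apen",
    "MSE": "Mean_MSE",
    "Sample_Entropy": "Mean_Sample_Entropy",
    "Var_MSE": "Var_MSE",
    "Wolf_Lye": "Mean_Wolf_Lye",
    "Short_Lye": "Mean_Short_Lye",
    "Long_Lye": "Mean_Long_Lye",
    "Rosenstein_Lye": "Mean_Rosenstein_Lye",
    "Correlation_Dimension": "Mean_Correlation_Dimension",
    "Generalized_Hurst_Exp": "Mean_Generalized_Hurst_Exp",
}


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a table that hold feature values (not keys or labels)."""
    return [c for c in table.columns if c not in INDEX_COLS]


def build_feature_table(
    recordings: Iterable[Recording],
    nonlinear_params: NonlinearParams | None = None,
    include_acc: bool = True,
    include_emg: bool = True,
) -> pd.DataFrame:
    """Trial-level feature table: one row per recording unit."""
    params = nonlinear_params or NonlinearParams()
    rows = []
    for rec in recordings:
        row: dict = {
            "subject_id": rec.subject_id,
            "skill": rec.skill,
            "task": rec.task,
            "trial": rec.trial,
            "muscle": rec.muscle,
            "side": rec.side,
        }
        if include_emg:
            row.update(emg_feature_vector(rec).as_dict())
        if include_acc:
            row.update(acc_feature_vector(rec, params))
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_trials(table: pd.DataFrame, pool_sides: bool = False) -> pd.DataFrame:
    """Average features across trials within (subject, task, muscle, side).

    Nonlinear feature names gain the ``Mean_`` prefix of the selection
    report (``Var_MSE`` keeps its name: it is already a variance, taken
    across scales within each trial before averaging across trials).
    With ``pool_sides=True`` left and right rows pool into one group.
    """
    keys = ["subject_id", "skill", "task", "muscle"]
    if not pool_sides:
        keys.append("side")
    feats = feature_columns(table)
    agg = table.groupby(keys, as_index=False, sort=True)[feats].mean()
    renames = {}
    for c in feats:
        if c in AGGREGATED_NAMES:
            renames[c] = AGGREGATED_NAMES[c]
        elif c in EMG_FEATURE_NAMES:
            renames[c] = f"Mean_{c}"
    return agg.rename(columns=renames)


def pivot_muscle_features(
    table: pd.DataFrame,
    muscles: Sequence[str],
    sides: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Wide table for classification over a muscle set.

    Rows are (subject, skill, task, trial); columns concatenate the
    per-(muscle, side) features as ``<muscle>_<side>_<feature>``.
    """
    sub = table[table["muscle"].isin(list(muscles))].copy()
    if sides is not None:
        sub = sub[sub["side"].isin(list(sides))]
    if sub.empty:
        raise ValueError(f"no rows for muscles {list(muscles)}")
    feats = feature_columns(sub)
    wide = sub.pivot_table(
        index=["subject_id", "skill", "task", "trial"],
        columns=["muscle", "side"],
        values=feats,
        sort=True,
    )
    wide.columns = [f"{m}_{s}_{f}" for (f, m, s) in wide.columns]
    wide = wide.reindex(sorted(wide.columns), axis=1)
    return wide.reset_index()
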