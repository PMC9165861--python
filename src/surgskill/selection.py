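"""Feature selection: correlation filtering and recursive elimination.

Two stages reduce a labeled feature table:

* **CFS** (correlation-based filter): for every feature pair whose
  absolute Pearson correlation meets the threshold, the member with the
  weaker absolute association to the skill label is dropped — redundancy
  goes, predictive signal stays.
* **RFE** (recursive feature elimination): a random forest is refit
  repeatedly, discarding the least important feature each round until
  the target count remains; ranks record the elimination order and the
  final fit's importances become the reported weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE

from .features_table import feature_columns
from .types import InvalidArgumentError, SKILLS

logger = logging.getLogger(__name__)

SKILL_ORDER = {s: i for i, s in enumerate(SKILLS)}


@dataclass
class SelectionResult:
    kept_features: list[str]
    ranks: dict[str, int] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    correlation_matrix: pd.DataFrame | None = None
    dropped_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def report(self) -> pd.DataFrame:
        """Two-column (feature, weight) layout ordered by priority."""
        rows = [
            {"Feature Priority": f, "Weights": self.weights.get(f, np.nan)}
            for f in self.kept_features
        ]
        return pd.DataFrame(rows)


def pearson_correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the feature columns.

    Zero-variance features produce NaN rows/columns; they are reported in
    the log, not silently dropped.
    """
    feats = feature_columns(table)
    sub = table[feats]
    degenerate = [c for c in feats if sub[c].std(skipna=True) == 0]
    if degenerate:
        logger.warning("zero-variance features with undefined correlations: %s", degenerate)
    corr = sub.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for c in degenerate:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = 1.0
    return corr


def label_association(table: pd.DataFrame) -> pd.Series:
    """|Pearson correlation| of each feature with the ordinal skill label.

    Skill is encoded novice=0, intermediate=1, expert=2 (the natural
    experience ordering), the three-class analogue of a point-biserial
    association.
    """
    y = table["skill"].map(SKILL_ORDER).astype(float)
    feats = feature_columns(table)
    assoc = {}
    for c in feats:
        x = table[c].astype(float)
        ok = x.notna()
        if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
            assoc[c] = 0.0
        else:
            assoc[c] = abs(float(np.corrcoef(x[ok], y[ok])[0, 1]))
    return pd.Series(assoc)


def cfs_filter(table: pd.DataFrame, rho_threshold: float = 0.9) -> SelectionResult:
    """Drop the weaker member of every highly correlated feature pair.

    Pairs are processed in descending |rho| order; the member with the
    weaker label association is dropped (ties drop the later column,
    logged).  Afterwards no kept pair has |rho| >= threshold.
    """
    if not (0 < rho_threshold <= 1):
        raise InvalidArgumentError("rho_threshold must lie in (0, 1]")
    corr = pearson_correlation_matrix(table)
    assoc = label_association(table)
    feats = list(corr.columns)
    kept = list(feats)
    dropped_pairs: list[tuple[str, str, float]] = []
    while True:
        sub = corr.loc[kept, kept].abs().copy()
        np.fill_diagonal(sub.values, 0.0)
        if sub.isna().all().all():
            break
        max_val = np.nanmax(sub.values)
        if not (max_val >= rho_threshold):
            break
        i, j = np.unravel_index(np.nanargmax(sub.values), sub.shape)
        a, b = kept[i], kept[j]
        if assoc[a] > assoc[b]:
            keep, drop = a, b
        elif assoc[b] > assoc[a]:
            keep, drop = b, a
        else:  # tie: drop the later column in table order
            first, second = sorted([a, b], key=feats.index)
            keep, drop = first, second
            logger.info("CFS tie between %s and %s: dropping later column %s", a, b, drop)
        kept.remove(drop)
        dropped_pairs.append((keep, drop, float(max_val)))
    return SelectionResult(
        kept_features=kept,
        correlation_matrix=corr,
        dropped_pairs=dropped_pairs,
    )


def rfe_rank(
    table: pd.DataFrame,
    n_keep: int,
    seed: int = 0,
    n_estimators: int = 100,
) -> SelectionResult:
    """Recursive feature elimination with a random-forest importance source.

    One feature is removed per iteration.  Ranks follow the elimination
    order (1 = survived to the end); weights are the final fit's feature
    importances over the kept set, normalized to sum to 1.
    """
    feats = feature_columns(table)
    if n_keep < 1:
        raise InvalidArgumentError("n_keep must be >= 1")
    if n_keep > len(feats):
        raise InvalidArgumentError(
            f"n_keep={n_keep} exceeds available features ({len(feats)})"
        )
    X = table[feats].to_numpy(dtype=float)
    # median imputation so the forest tolerates flagged-absent values
    col_med = np.nanmedian(X, axis=0)
    col_med = np.where(np.isnan(col_med), 0.0, col_med)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_med, np.nonzero(nan_mask)[1])
    y = table["skill"].to_numpy()
    est = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    if n_keep == len(feats):  # nothing to eliminate: single fit
        est.fit(X, y)
        ranks = {f: 1 for f in feats}
        kept = list(feats)
        importances = est.feature_importances_
    else:
        rfe = RFE(estimator=est, n_features_to_select=n_keep, step=1)
        rfe.fit(X, y)
        ranks = {f: int(r) for f, r in zip(feats, rfe.ranking_)}
        kept = [f for f in feats if ranks[f] == 1]
        importances = rfe.estimator_.feature_importances_
    total = importances.sum()
    weights = {f: 0.0 for f in feats}
    for f, w in zip(kept, importances):
        weights[f] = float(w / total) if total > 0 else 0.0
    return SelectionResult(kept_features=kept, ranks=ranks, weights=weights)


def reduce_dimension(
    table: pd.DataFrame,
    method: str = "cfs+rfe",
    rho_threshold: float = 0.9,
    n_keep: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, SelectionResult]:
    """Project a labeled table onto its selected features.

    ``method`` is one of ``none``, ``cfs``, ``rfe``, ``cfs+rfe`` (the
    default mirrors the reported 26 -> 10 reduction pipeline).  Returns
    the projected table (key/label columns preserved) and the combined
    selection result.
    """
    meta_cols = [c for c in table.columns if c not in feature_columns(table)]
    if method == "none":
        return table.copy(), SelectionResult(kept_features=feature_columns(table))
    result = None
    working = table
    if "cfs" in method:
        result = cfs_filter(working, rho_threshold)
        working = working[meta_cols + result.kept_features]
    if "rfe" in method:
        n = min(n_keep, len(feature_columns(working)))
        rfe_res = rfe_rank(working, n_keep=n, seed=seed)
        if result is None:
            result = rfe_res
        else:
            result = SelectionResult(
                kept_features=rfe_res.kept_features,
                ranks=rfe_res.ranks,
                weights=rfe_res.weights,
                correlation_matrix=result.correlation_matrix,
                dropped_pairs=result.dropped_pairs,
            )
        working = working[meta_cols + rfe_res.kept_features]
    if result is None:
        raise InvalidArgumentError(f"unknown selection method {method!r}")
    return working.copy(), result
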