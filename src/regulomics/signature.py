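"""Dependency-signature discovery.

Predicts a per-cell-line NRF2 dependency score (an 80:20 weighted average of
CRISPR Chronos and RNAi Demeter fitness scores; more negative = stronger
dependency) from a pan-cancer multi-omic feature matrix with random-forest
regression, attenuates each tree by its out-of-bag R², ranks features by
mean |SHAP| across the cross-validation models, and applies the three-branch
literature/knockdown rule that defines the gene signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score, roc_auc_score
from sklearn.model_selection import ShuffleSplit

from ._treeshap import forest_shap_values

logger = logging.getLogger(__name__)

CHRONOS_WEIGHT = 0.8
DEMETER_WEIGHT = 0.2

#: Production-scale forest hyperparameters; tests and desk-scale runs override
#: n_estimators / max_features_fraction (identical code path).
DEFAULT_HYPERPARAMS = {
    "max_depth": 7,
    "min_samples_leaf": 2,
    "max_features_fraction": 0.005,
    "n_estimators": 10_000,
}


def combine_dependency(
    chronos: pd.Series, demeter: Optional[pd.Series] = None
) -> pd.DataFrame:
    """80:20 Chronos:Demeter weighted average per cell line.

    Lines with missing Demeter fall back to the Chronos score alone and are
    flagged in the ``demeter_missing`` column.
    """
    chronos = chronos.dropna()
    if demeter is None:
        demeter = pd.Series(np.nan, index=chronos.index)
    lines = chronos.index
    if len(lines) == 0:
        raise ValueError("no cell lines with a Chronos score")
    demeter = demeter.reindex(lines)
    missing = demeter.isna()
    combined = CHRONOS_WEIGHT * chronos + DEMETER_WEIGHT * demeter
    combined[missing] = chronos[missing]
    out = pd.DataFrame(
        {"chronos": chronos, "demeter": demeter, "combined": combined,
         "demeter_missing": missing}
    )
    n_overlap = int((~missing).sum()) + int(missing.sum())
    if n_overlap == 0:
        raise ValueError("no overlapping cell lines between scores")
    return out


def impute_features(X: pd.DataFrame) -> pd.DataFrame:
    """Median-impute missing values, appending a missingness indicator
    column (``<feature>__missing``) for any feature with gaps."""
    X = X.copy()
    extra = {}
    for col in X.columns[X.isna().any()]:
        extra[f"{col}__missing"] = X[col].isna().astype(float)
        X[col] = X[col].fillna(X[col].median())
    if extra:
        X = pd.concat([X, pd.DataFrame(extra, index=X.index)], axis=1)
    return X


@dataclass
class ForestFit:
    """One cross-validation forest with per-tree OOB-derived weights."""

    forest: RandomForestRegressor
    oob_score_per_tree: np.ndarray
    tree_weight: np.ndarray
    fold_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    uniform_fallback: bool = False

    def __post_init__(self) -> None:
        total = self.tree_weight.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"tree weights must sum to 1, got {total}")
        if (self.tree_weight < 0).any():
            raise ValueError("tree weights must be non-negative")


def _per_tree_oob_scores(forest: RandomForestRegressor,
                         X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """R² of each tree on its out-of-bag rows (0 when OOB is degenerate)."""
    n = X.shape[0]
    scores = np.zeros(len(forest.estimators_))
    for t, (tree, sample_idx) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.ones(n, dtype=bool)
        oob[sample_idx] = False
        if oob.sum() < 2 or np.var(y[oob]) == 0:
            continue
        scores[t] = r2_score(y[oob], tree.predict(X[oob]))
    return scores


def _weights_from_oob(oob_scores: np.ndarray) -> Tuple[np.ndarray, bool]:
    clipped = np.clip(oob_scores, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        return np.full(len(oob_scores), 1.0 / len(oob_scores)), True
    return clipped / total, False


def fit_models(
    X: pd.DataFrame,
    y: pd.Series,
    hyperparams: Optional[dict] = None,
    n_folds: int = 10,
    test_size: float = 0.2,
    seed: int = 0,
) -> Tuple[List[ForestFit], pd.DataFrame]:
    """Fit ``n_folds`` forests, each on an 80:20 train:test resample.

    Returns the fits and a tidy frame of held-out predictions
    (fold, line, y_true, y_pred) where y_pred is the OOB-attenuated
    ensemble prediction on that fold's held-out lines.
    """
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    X = impute_features(X)
    y = y.loc[X.index]
    n, p = X.shape
    if n < 2 * n_folds:
        raise ValueError(f"need ≥{2 * n_folds} cell lines, got {n}")
    max_features = max(1, int(round(hp["max_features_fraction"] * p)))
    if hp["max_features_fraction"] * p < 1:
        raise ValueError(
            "max_features_fraction·n_features < 1; supply at least "
            f"{int(np.ceil(1 / hp['max_features_fraction']))} features "
            "or raise the fraction"
        )
    Xv = np.ascontiguousarray(X.to_numpy(dtype=np.float64))
    yv = y.to_numpy(dtype=np.float64)

    splitter = ShuffleSplit(n_splits=n_folds, test_size=test_size,
                            random_state=seed)
    fits: List[ForestFit] = []
    rows = []
    for fold, (tr, te) in enumerate(splitter.split(Xv)):
        forest = RandomForestRegressor(
            n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"],
            min_samples_leaf=hp["min_samples_leaf"],
            max_features=max_features,
            bootstrap=True,
            random_state=seed * n_folds + fold + 1,
            n_jobs=1,
        ).fit(Xv[tr], yv[tr])
        oob = _per_tree_oob_scores(forest, Xv[tr], yv[tr])
        weights, fallback = _weights_from_oob(oob)
        if fallback:
            logger.warning("fold %d: all per-tree OOB scores ≤ 0; "
                           "uniform tree weights", fold)
        fit = ForestFit(forest, oob, weights, fold, tr, te, fallback)
        fits.append(fit)
        preds = attenuated_predict(fit, Xv[te])
        for line, yt, yp in zip(X.index[te], yv[te], preds):
            rows.append({"fold": fold, "line": line, "y_true": yt,
                         "y_pred": yp})
    return fits, pd.DataFrame(rows)


def attenuated_predict(fit: ForestFit, X_new) -> np.ndarray:
    """OOB-attenuated ensemble prediction Σ_t w_t·tree_t(x).

    Weights are clipped OOB R² scores normalized to sum to 1, so poorly
    predicting trees are down-weighted; a weight-0 tree contributes nothing.
    """
    X_new = np.asarray(X_new, dtype=np.float64)
    out = np.zeros(X_new.shape[0])
    for tree, w in zip(fit.forest.estimators_, fit.tree_weight):
        if w == 0.0:
            continue
        out += w * tree.predict(X_new)
    return out


def shap_ranking(fits: Sequence[ForestFit], X: pd.DataFrame) -> pd.DataFrame:
    """Rank features by mean |SHAP| averaged over the CV models.

    SHAP values explain each model's attenuated prediction, so per-tree
    weights enter the attribution. Returns a frame indexed by rank with
    columns feature, importance, rank, cumulative_share.
    """
    if len(fits) == 0:
        raise ValueError("need at least one fitted model")
    X = impute_features(X)
    Xv = np.ascontiguousarray(X.to_numpy(dtype=np.float64))
    importance = np.zeros(Xv.shape[1])
    for fit in fits:
        phi = forest_shap_values(fit.forest.estimators_, Xv, fit.tree_weight)
        importance += np.abs(phi).mean(axis=0)
    importance /= len(fits)
    order = np.argsort(-importance, kind="stable")
    total = importance.sum()
    share = importance[order] / total if total > 0 else np.zeros_like(order, float)
    return pd.DataFrame(
        {
            "feature": X.columns[order],
            "importance": importance[order],
            "rank": np.arange(1, len(order) + 1),
            "cumulative_share": np.cumsum(share),
        }
    )


def top_shap_features(ranking: pd.DataFrame, cumulative_share: float = 0.15) -> set:
    """Smallest rank prefix whose cumulative importance share reaches the
    target; importance ties at the boundary are all included."""
    cum = ranking["cumulative_share"].to_numpy()
    if len(cum) == 0:
        return set()
    cutoff = int(np.searchsorted(cum, cumulative_share, side="left"))
    cutoff = min(cutoff, len(cum) - 1)
    boundary = ranking["importance"].iloc[cutoff]
    keep = (np.arange(len(cum)) <= cutoff) | (
        ranking["importance"].to_numpy() == boundary
    ) & (ranking["importance"].to_numpy() > 0)
    return set(ranking.loc[keep, "feature"])


def select_signature(
    candidates: pd.DataFrame,
    cumulative_share: float = 0.15,
    top_shap_scope: str = "all",
) -> pd.DataFrame:
    """Apply the three-branch signature rule to candidate genes.

    A candidate is selected when it is in the top-SHAP set (smallest rank
    prefix reaching ``cumulative_share`` of total importance) and satisfies
    any of: membership in ≥7 literature NRF2 gene sets; ≥5 sets with
    knockdown log2FC < 0.25 at 6 h; or ≥2 sets with knockdown log2FC < 0.
    ``top_shap_scope='first_branch'`` restricts the top-SHAP requirement to
    the first branch (the grammatical alternative reading).

    Expects columns gene, in_top_shap, literature_count, shnrf2_logfc_6h.
    """
    if top_shap_scope not in ("all", "first_branch"):
        raise ValueError("top_shap_scope must be 'all' or 'first_branch'")
    df = candidates.copy()
    if (df["literature_count"] < 0).any():
        raise ValueError("literature_count must be ≥ 0")
    lit = df["literature_count"]
    lfc = df["shnrf2_logfc_6h"]
    top = df["in_top_shap"].astype(bool)
    b1 = lit >= 7
    b2 = (lit >= 5) & (lfc < 0.25)
    b3 = (lit >= 2) & (lfc < 0)
    if top_shap_scope == "all":
        selected = top & (b1 | b2 | b3)
    else:
        selected = (top & b1) | b2 | b3
    out = df.assign(branch_lit7=b1, branch_lit5_lfc=b2, branch_lit2_lfc=b3,
                    selected=selected)
    return out


def dependency_auc(
    predictions: pd.DataFrame, threshold: float = -0.5
) -> Tuple[float, float, pd.DataFrame]:
    """Held-out performance: mean AUC and R² across folds.

    Lines are binarized as dependent when the true combined score falls
    below ``threshold`` (the Chronos < −0.5 dependency definition); the AUC
    scores how well (negated) predictions rank dependent above independent
    lines. Folds whose held-out split lacks one class are skipped with a
    warning; an error is raised if no fold is scorable.
    """
    aucs, r2s, rows = [], [], []
    for fold, grp in predictions.groupby("fold"):
        labels = (grp["y_true"] < threshold).astype(int)
        r2 = r2_score(grp["y_true"], grp["y_pred"])
        if labels.nunique() < 2:
            warnings.warn(f"fold {fold}: one dependency class empty, "
                          "AUC skipped")
            auc = np.nan
        else:
            auc = roc_auc_score(labels, -grp["y_pred"])
            aucs.append(auc)
        r2s.append(r2)
        rows.append({"fold": fold, "auc": auc, "r2": r2})
    if not aucs:
        raise ValueError("no fold had both dependency classes; "
                         "cannot compute AUC")
    return float(np.mean(aucs)), float(np.mean(r2s)), pd.DataFrame(rows)
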