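"""Class-level differential statistics for metabolomics and lipidomics.

Per-analyte differential abundance (log2 fold change and p-value, here a
Welch t-test on log2 abundances; externally computed per-analyte statistics
drop in equally) is combined per (class, fold-change direction) with
Tippett's method, P = 1 − (1 − p_min)^k, and BH-adjusted across all groups
of the assay to q-values.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chip import bh_adjust

logger = logging.getLogger(__name__)


def analyte_differential(
    abundances: pd.DataFrame,
    sample_conditions: pd.Series,
    cond_a: str,
    cond_b: str,
) -> pd.DataFrame:
    """Per-analyte log2FC (a − b) and two-sided Welch-t p on log2 abundances.

    ``abundances`` is analytes × samples (positive values) with a ``class``
    column; ``sample_conditions`` maps sample name → condition. Analytes
    with <2 replicates in either condition are skipped with a warning;
    zero-variance, zero-difference analytes get p = 1 (no evidence).
    """
    samples_a = [s for s in abundances.columns
                 if sample_conditions.get(s) == cond_a]
    samples_b = [s for s in abundances.columns
                 if sample_conditions.get(s) == cond_b]
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError("both conditions need samples")
    rows = []
    for analyte, row in abundances.iterrows():
        a = np.log2(row[samples_a].to_numpy(dtype=float))
        b = np.log2(row[samples_b].to_numpy(dtype=float))
        if len(a) < 2 or len(b) < 2:
            logger.warning("analyte %s: <2 replicates, skipped", analyte)
            continue
        log2fc = float(a.mean() - b.mean())
        if np.var(a) == 0 and np.var(b) == 0:
            p = 1.0 if log2fc == 0 else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append({"analyte": analyte, "class": row.get("class"),
                     "log2fc": log2fc, "p": p})
    return pd.DataFrame(rows)


def tippett_combine(pvalues: Iterable[float]) -> float:
    """Tippett's method: P = 1 − (1 − min p)^k over k member p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return float(1.0 - (1.0 - p.min()) ** p.size)


def class_statistics(per_analyte: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tippett-combined statistics per (class, fold-change direction).

    Analytes with log2fc exactly 0 have no direction and are excluded
    (logged). BH runs jointly across all (class, direction) groups of the
    assay. Returns class, direction, k, min_p, combined_p, q_value.
    """
    zero = per_analyte["log2fc"] == 0
    if zero.any():
        logger.info("excluding %d analytes with log2fc == 0", int(zero.sum()))
    df = per_analyte.loc[~zero].copy()
    df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
    rows = []
    for (cls, direction), grp in df.groupby(["class", "direction"]):
        rows.append(
            {
                "class": cls,
                "direction": direction,
                "k": len(grp),
                "min_p": float(grp["p"].min()),
                "combined_p": tippett_combine(grp["p"]),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["combined_p"])
        out["significant"] = out["q_value"] < alpha
        out = out.sort_values("q_value").reset_index(drop=True)
    return out
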