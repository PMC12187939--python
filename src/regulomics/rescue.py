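"""Rescue-divergence scoring.

Compares transcriptome responses to re-expression of wild-type NRF2 versus
a CBP/p300-binding-deficient mutant (Neh4/5mut) in knockdown cells. Per-gene
log2 fold changes (24 h vs 0 h) are normalized by subtracting the matched
luciferase-control log2FC, and divergence from 1:1 behaviour is the cosine
between the (WT, mutant) vector and the diagonal y = x: 1 means the mutant
rescues like wild type, smaller values mean CBP/p300-reliant expression.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

REQUIRED_LOGFC_COLUMNS = ("logfc_wt", "logfc_mut", "logfc_luc")


def expression_filter(table: pd.DataFrame, min_log2_cpm: float = -1.0) -> pd.DataFrame:
    """Keep genes with mean expression ≥ ``min_log2_cpm`` (inclusive)."""
    return table.loc[table["mean_log2_cpm"] >= min_log2_cpm].copy()


def normalize_rescue(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract the luciferase log2FC from the WT and mutant log2FCs."""
    for col in REQUIRED_LOGFC_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing required column: {col}")
    out = table.copy()
    out["norm_wt"] = out["logfc_wt"] - out["logfc_luc"]
    out["norm_mut"] = out["logfc_mut"] - out["logfc_luc"]
    return out


def cosine_to_diagonal(norm_wt: float, norm_mut: float) -> Optional[float]:
    """Cosine between (norm_wt, norm_mut) and the 1:1 diagonal.

    Equals (x + y) / (√2·‖(x, y)‖); None for the zero vector. 1 means equal
    normalized response in both conditions; 0 means orthogonal to the
    diagonal; negative values (both responses opposing the diagonal) are
    reported as computed.
    """
    norm = math.hypot(norm_wt, norm_mut)
    if norm == 0.0:
        return None
    return (norm_wt + norm_mut) / (math.sqrt(2.0) * norm)


def rescue_divergence(
    table: pd.DataFrame, min_log2_cpm: float = -1.0
) -> pd.DataFrame:
    """Full per-gene pipeline: filter, normalize, score; sorted by cosine.

    Returns the expression-filtered table with norm_wt/norm_mut/cosine
    columns, ascending cosine (most CBP/p300-divergent genes first);
    zero-vector genes carry NaN cosine and sort last.
    """
    out = normalize_rescue(expression_filter(table, min_log2_cpm))
    out["cosine"] = [
        np.nan if c is None else c
        for c in (cosine_to_diagonal(w, m)
                  for w, m in zip(out["norm_wt"], out["norm_mut"]))
    ]
    return out.sort_values("cosine", na_position="last").reset_index(drop=True)
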