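"""Promoter ChIP occupancy scoring and factor co-occupancy enrichment.

A gene's promoter ChIP score is the mean signal of all peaks overlapping the
±1 kb window around the TSS (0 when the window is empty, so a total order
exists for group classification). Signature genes split into group I (low
promoter-bound NRF2) and group II (high promoter-bound NRF2); co-occupancy
of other factors at gene-proximal NRF2 peaks is compared between groups by
Wilcoxon rank-sum, Fisher-combined across replicates, and BH-adjusted
across factors.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, Peak, Promoter, overlaps

logger = logging.getLogger(__name__)


def promoter_score(
    promoters: Sequence[Promoter],
    peaks: Sequence[Peak],
    window_bp: int = 1000,
) -> pd.DataFrame:
    """Mean peak signal within ±``window_bp`` of each promoter's TSS.

    The window is half-open ``[tss − w, tss + w)`` clipped at 0; a peak
    whose start equals the window end is excluded. A peak inside two genes'
    windows contributes to both. Genes with no peak in the window score 0.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for prom in promoters:
        win = prom.window(window_bp)
        signals = [p.signal for p in peaks if overlaps(win, p.interval)]
        rows.append(
            {
                "gene": prom.gene,
                "promoter_score": float(np.mean(signals)) if signals else 0.0,
                "n_peaks_in_window": len(signals),
            }
        )
    return pd.DataFrame(rows)


def classify_groups(
    scores: pd.DataFrame,
    method: str = "two_means",
    threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Split genes into group I (low promoter NRF2) / group II (high).

    ``two_means`` runs deterministic 1-D 2-means (Lloyd) on log1p(score)
    with centers initialized at the min and max; the lower-center cluster is
    group I. ``threshold`` assigns group I when score < threshold.
    """
    if len(scores) < 2:
        raise ValueError("need ≥2 genes to classify")
    s = scores["promoter_score"].to_numpy(dtype=float)
    if method == "threshold":
        if threshold is None:
            raise ValueError("threshold mode requires a threshold")
        group1 = s < threshold
    elif method == "two_means":
        x = np.log1p(s)
        if np.ptp(x) == 0:
            raise ValueError(
                "all promoter scores identical; use method='threshold'"
            )
        lo, hi = float(x.min()), float(x.max())
        for _ in range(100):
            assign = np.abs(x - lo) <= np.abs(x - hi)  # ties to lower center
            new_lo, new_hi = x[assign].mean(), x[~assign].mean()
            if new_lo == lo and new_hi == hi:
                break
            lo, hi = new_lo, new_hi
        group1 = assign
    else:
        raise ValueError(f"unknown method: {method}")
    return scores.assign(group=np.where(group1, "I", "II"))


def proximal_peaks(
    peaks: Sequence[Peak],
    promoters: Sequence[Promoter],
    signature_genes: set,
    gene_bodies: Optional[Mapping[str, GenomicInterval]] = None,
    qvalue_max: Optional[float] = None,
) -> List[Tuple[Peak, str]]:
    """NRF2 peaks whose closest gene (TSS distance, ties broken by gene
    name) is a signature gene, excluding peaks inside that gene's body.

    Significance filtering (``qvalue_max``) is applied before proximity
    assignment. Returns (peak, assigned gene) pairs.
    """
    if qvalue_max is not None:
        peaks = [p for p in peaks
                 if p.qvalue is not None and p.qvalue < qvalue_max]
    out: List[Tuple[Peak, str]] = []
    for peak in peaks:
        best: Optional[Tuple[int, str]] = None
        for prom in promoters:
            if prom.tss.chrom != peak.interval.chrom:
                continue
            if overlaps(peak.interval, prom.tss):
                d = 0
            elif prom.tss.start >= peak.interval.end:
                d = prom.tss.start - peak.interval.end
            else:
                d = peak.interval.start - prom.tss.end
            if best is None or (d, prom.gene) < best:
                best = (d, prom.gene)
        if best is None or best[1] not in signature_genes:
            continue
        gene = best[1]
        if gene_bodies is not None and gene in gene_bodies and overlaps(
            peak.interval, gene_bodies[gene]
        ):
            continue
        out.append((peak, gene))
    return out


def overlap_signal(query: GenomicInterval, factor_peaks: Sequence[Peak]) -> float:
    """Mean signal of factor peaks overlapping ``query``; 0 when none."""
    hits = [p.signal for p in factor_peaks if overlaps(query, p.interval)]
    return float(np.mean(hits)) if hits else 0.0


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution for combined n ≤ 20 without ties; normal
    approximation with tie and continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def fisher_combine(pvalues: Sequence[float]) -> Tuple[float, float]:
    """Fisher's method: χ² = −2Σln p on 2k df. Returns (χ², combined p)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    stat, combined = stats.combine_pvalues(p, method="fisher")
    return float(stat), float(combined)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float),
                         method="fdr_bh")[1]


def factor_enrichment(
    proximal: Sequence[Tuple[Peak, str]],
    group_by_gene: Mapping[str, str],
    factor_peaksets: Mapping[str, Sequence[Sequence[Peak]]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group I vs II co-occupancy enrichment for each factor.

    For every factor replicate, each proximal NRF2 peak receives the
    overlapping factor signal (0 when none); group I and II values are
    compared by a two-sided Wilcoxon rank-sum test, replicate p-values are
    Fisher-combined per factor, and BH adjustment runs across factors.
    """
    g1_peaks = [p for p, g in proximal if group_by_gene.get(g) == "I"]
    g2_peaks = [p for p, g in proximal if group_by_gene.get(g) == "II"]
    if not g1_peaks or not g2_peaks:
        raise ValueError("both groups must have proximal peaks")
    rows = []
    for factor, replicates in factor_peaksets.items():
        if len(replicates) == 0:
            logger.warning("factor %s has no replicates; skipped", factor)
            continue
        rep_ps, m1s, m2s = [], [], []
        for rep in replicates:
            v1 = [overlap_signal(p.interval, rep) for p in g1_peaks]
            v2 = [overlap_signal(p.interval, rep) for p in g2_peaks]
            rep_ps.append(wilcoxon_rank_sum(v1, v2))
            m1s.append(np.mean(v1))
            m2s.append(np.mean(v2))
        _, combined = fisher_combine(rep_ps)
        rows.append(
            {
                "factor": factor,
                "mean_group1": float(np.mean(m1s)),
                "mean_group2": float(np.mean(m2s)),
                "replicate_p": rep_ps,
                "combined_p": combined,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["factor", "mean_group1", "mean_group2",
                                     "replicate_p", "combined_p",
                                     "adjusted_p", "significant"])
    df = pd.DataFrame(rows)
    df["adjusted_p"] = bh_adjust(df["combined_p"])
    df["significant"] = df["adjusted_p"] < alpha
    return df
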