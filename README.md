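# regulomics

Multi-omic dependency-signature discovery and regulatory-linkage analysis
for NRF2-driven lung cancer.

KEAP1/NFE2L2-mutant non-small-cell lung cancers depend on the transcription
factor NRF2 for growth, but which NRF2 target genes carry that dependency —
and how NRF2 drives them, from promoters or from distal enhancers — is not
obvious from any single data type. `regulomics` packages the computational
stages of that analysis for genomics/computational-biology practitioners who
want to run them on their own data or validate them on synthetic data with
planted truth:

- **Dependency signature** — predict a per-cell-line dependency score
  *y* = 0.8·Chronos + 0.2·Demeter from a multi-omic feature matrix *X*
  with random-forest regression (max_depth 7, min_samples_leaf 2; 10,000
  trees and 0.5% features/split at production scale), tree predictions
  attenuated by per-tree out-of-bag R², features ranked by mean |SHAP|
  across ten 80:20 cross-validation models (exact path-dependent tree SHAP,
  implemented in-package and oracle-tested), and signature genes selected
  from the top-SHAP set (cumulative 15% of importance) by a three-branch
  literature/knockdown rule.
- **Promoter ChIP** — promoter occupancy score = mean peak signal within
  ±1 kb of the TSS; group I (low promoter NRF2) vs group II (high) by
  deterministic 1-D 2-means; factor co-occupancy enrichment at
  gene-proximal NRF2 peaks via Wilcoxon rank-sum, Fisher combination across
  replicates, and Benjamini–Hochberg across factors.
- **Enhancer linkage** — knockdown-responsive PRO-seq peaks (logFC < 0,
  p < 0.1 in ≥3 of 4 conditions), candidate chromatin links filtered to
  CCscore ≥ 1 with both arms on responsive peaks, empirical significance
  from 1000 genome-wide shuffles at 5 kb bins (significant iff the bin pair
  recurs with CCscore ≥ original in <5% of shuffles), and per-gene linkage
  types (promoter-only / single-enhancer / higher-order).
- **Rescue divergence** — per-gene cosine between luciferase-normalized
  WT-NRF2 and Neh4/5-mutant log2FC responses and the 1:1 diagonal,
  cos = (x + y)/(√2·‖(x, y)‖); values below 1 flag CBP/p300-reliant genes.
- **Class statistics** — per-analyte Welch tests on log2 abundances,
  Tippett combination P = 1 − (1 − p_min)^k per (class, direction), BH
  q-values across groups.
- **PPP flux** — relative pentose-phosphate flux from [1,2-¹³C]-glucose
  tracing: rate × Lac_M1/(Lac_M1 + Lac_M2).

A synthetic-data module generates every input (BED, BEDPE, TSV) with known
planted structure and truth tables, so the whole pipeline is testable
without external downloads. See `docs/methods.md` for models, assumptions,
and design decisions.

## Worked example

Generate a synthetic regulome, classify signature genes by promoter NRF2,
and wire enhancers to promoters through the shuffle null:

```python
from regulomics import SyntheticSpec
from regulomics.simulate import simulate_regulome
from regulomics.chip import promoter_score, classify_groups
from regulomics.linkage import (consensus_responsive_peaks, filter_links,
                                higher_order_proportions, linkage_summary,
                                peaks_to_intervals, shuffle_null)

spec = SyntheticSpec(seed=7)
reg = simulate_regulome(spec)

sig = [p for p in reg.promoters if p.gene in reg.signature_genes]
groups = classify_groups(promoter_score(sig, reg.peaks["NRF2"]))
print(groups["group"].value_counts().to_dict())

responsive = peaks_to_intervals(consensus_responsive_peaks(reg.proseq))
kept = filter_links(reg.links, responsive)
binned = shuffle_null(kept, reg.genome, n_shuffles=1000, seed=7)
print(len(reg.links), "candidates ->", len(kept), "filtered ->",
      sum(b.significant for b in binned), "significant")
summary = linkage_summary(binned, reg.promoters, reg.signature_genes)
print(higher_order_proportions(summary))
```

prints

```
{'II': 36, 'I': 24}
74 candidates -> 34 filtered -> 34 significant
{'signature': 0.16666666666666666, 'non_signature': 0.0}
```

— 24 of 60 signature genes are group I (low promoter NRF2; the generator
planted 40%), the CCscore/responsive-arm filter strips all 40 background
links while keeping the 34 planted true links, and 10 genes (16.7% of the
signature) are linked to two or more distal enhancers, exactly the planted
higher-order fraction. Non-signature genes have no linked enhancers.

Scoring the rescue transcriptome on the same seed:

```python
from regulomics.simulate import simulate_rescue_and_omics
from regulomics.rescue import rescue_divergence

rescue, tables, truth, _ = simulate_rescue_and_omics(spec)
scored = rescue_divergence(rescue).merge(truth, on="gene")
induced = scored[scored.norm_wt > 0.5]
print(induced[["gene", "norm_wt", "norm_mut", "cosine"]].head(3))
```

```
 gene  norm_wt  norm_mut   cosine
g0909 1.142275  0.329393 0.875344
g0618 1.399518  0.458306 0.892052
g0183 1.060306  0.353173 0.894327
```

The genes with the lowest cosines among induced genes are exactly the
planted CBP/p300-reliant set (mean cosine 0.919 vs 0.9998 for unaffected
genes — matching the closed form (1+a)/(√2·√(1+a²)) at attenuation
a = 0.4).

A `regulomics` console script exposes the same stages as subcommands
(`simulate`, `signature`, `chip`, `links`, `rescue`, `classstats`, `flux`)
over TSV/BED/BEDPE files with a YAML config; run `regulomics --help`.

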