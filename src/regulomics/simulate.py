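"""Synthetic inputs with planted structure for every pipeline stage.

Each generator emulates the statistical shape of the study's inputs — a
multi-omic feature matrix with a handful of informative features driving a
latent dependency score, a toy regulome where group II genes carry
promoter-proximal NRF2 peaks and group I genes carry distal enhancers wired
by true chromatin links above an exponential background, knockdown-rescue
log2FC tables with a planted CBP/p300-reliant subset, and analyte tables
with class-coherent abundance shifts — together with truth tables sufficient
to score recovery at every downstream stage.

One master seed drives everything; each generator draws from an
independently derived, stage-name-hashed substream, so adding a generator
never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Link, Peak, Promoter
from .linkage import CONDITIONS
from .signature import combine_dependency

OMIC_TYPES = ("expression", "mutation", "copy number", "pathway", "metabolite")


@dataclass(frozen=True)
class AnalyteClassSpec:
    """One planted analyte class: size, |log2FC| and shift direction."""

    name: str
    n_analytes: int
    log2fc: float
    direction: str = "down"  # "up" | "down"


DEFAULT_METABOLITE_CLASSES = (
    AnalyteClassSpec("glutathione", 8, 2.0, "down"),
    AnalyteClassSpec("nucleotide", 10, 0.0),
    AnalyteClassSpec("amino acid", 12, 0.0),
    AnalyteClassSpec("tca cycle", 8, 0.0),
    AnalyteClassSpec("pentose phosphate", 6, 0.0),
)

DEFAULT_LIPID_CLASSES = (
    AnalyteClassSpec("triglyceride", 15, 2.0, "down"),
    AnalyteClassSpec("phosphatidylcholine", 12, 0.0),
    AnalyteClassSpec("ceramide", 8, 0.0),
    AnalyteClassSpec("cholesteryl ester", 10, 0.0),
)


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic study; defaults are the study conditions.

    Dependency dataset: ``n_cell_lines`` × ``n_features`` standard-normal
    features, ``n_informative`` of which drive the latent dependency score
    with standardized effect ``effect_size``; Chronos and Demeter are two
    observations of the latent score with Gaussian noise ``noise_sd``.

    Regulome: ``n_genes`` signature genes on a toy ``genome``;
    ``frac_group1`` of them are group I (no promoter NRF2, distal enhancer
    5–50 kb away, wired by a true link at ``true_link_ccscore``);
    ``frac_higher_order`` of group I genes get a second linked enhancer.
    Background links have CCscore ``ccscore_min`` + Exp(1) (heavy-tailed so
    the shuffle null is non-degenerate).
    """

    n_cell_lines: int = 300
    n_features: int = 500
    n_informative: int = 10
    effect_size: float = 1.0
    noise_sd: float = 0.5
    n_genes: int = 60
    n_nonsignature_genes: int = 30
    frac_group1: float = 0.4
    frac_higher_order: float = 0.4
    genome: Tuple[Tuple[str, int], ...] = (("chr1", 10_000_000),
                                           ("chr2", 10_000_000))
    n_background_links: int = 40
    n_true_links: Optional[int] = None  # None: one per group I gene (+2nd
    # for the higher-order subset)
    true_link_ccscore: float = 10.0
    ccscore_min: float = 1.0
    n_rescue_genes: int = 1000
    frac_responsive: float = 0.2
    frac_reliant: float = 0.5
    attenuation: float = 0.4
    rescue_noise_sd: float = 0.05
    analyte_classes: Tuple[AnalyteClassSpec, ...] = DEFAULT_METABOLITE_CLASSES
    lipid_classes: Tuple[AnalyteClassSpec, ...] = DEFAULT_LIPID_CLASSES
    n_replicates: int = 4
    analyte_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if not (0.0 <= self.frac_group1 <= 1.0):
            raise ValueError("frac_group1 must lie in [0, 1]")
        for name in ("n_cell_lines", "n_features", "n_genes",
                     "n_rescue_genes", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-name-hashed substream of the master seed."""
        return np.random.default_rng(
            [self.seed, zlib.crc32(stage.encode())]
        )


# ---------------------------------------------------------------- dependency


def simulate_dependency_dataset(
    spec: SyntheticSpec,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Feature matrix X, dependency scores, and informative-feature truth.

    The latent dependency of line i is
    ``effect_size · Σ_j x_ij / √n_informative − 0.5`` over the informative
    features (centered so roughly half the lines fall below the −0.5
    dependency threshold); Chronos and Demeter add independent Gaussian
    noise to the latent score and combine 80:20.
    """
    rng = spec.rng("dependency")
    n, p = spec.n_cell_lines, spec.n_features
    lines = [f"line_{i:04d}" for i in range(n)]
    feats = [f"feat_{j:04d}" for j in range(p)]
    X = rng.standard_normal((n, p))
    informative = np.sort(rng.choice(p, size=spec.n_informative, replace=False))
    weight = spec.effect_size / np.sqrt(spec.n_informative)
    latent = X[:, informative].sum(axis=1) * weight - 0.5
    chronos = latent + spec.noise_sd * rng.standard_normal(n)
    demeter = latent + spec.noise_sd * rng.standard_normal(n)
    Xdf = pd.DataFrame(X, index=lines, columns=feats)
    dep = combine_dependency(pd.Series(chronos, index=lines),
                             pd.Series(demeter, index=lines))
    truth = pd.DataFrame(
        {
            "feature": feats,
            "truth_informative": [j in set(informative) for j in range(p)],
            "truth_weight": [weight if j in set(informative) else 0.0
                             for j in range(p)],
            "omic_type": [OMIC_TYPES[j % len(OMIC_TYPES)] for j in range(p)],
        }
    )
    return Xdf, dep, truth


# ------------------------------------------------------------------ regulome


@dataclass
class Regulome:
    """Everything the regulatory stages consume, plus truth tables."""

    promoters: List[Promoter]
    gene_bodies: Dict[str, GenomicInterval]
    peaks: Dict[str, List[Peak]]  # per factor
    enhancer_states: List[GenomicInterval]
    proseq: pd.DataFrame
    links: List[Link]
    truth_links: pd.DataFrame
    truth_groups: pd.DataFrame
    signature_genes: set
    genome: List[Tuple[str, int]]


def _place_genes(spec: SyntheticSpec, rng: np.random.Generator,
                 n_total: int) -> List[Tuple[str, int]]:
    """Evenly spaced TSS slots with jitter, round-robin over chromosomes."""
    genome = list(spec.genome)
    if not genome:
        raise ValueError("genome is empty")
    per_chrom = [n_total // len(genome) + (1 if i < n_total % len(genome) else 0)
                 for i in range(len(genome))]
    margin = 150_000
    positions: List[Tuple[str, int]] = []
    for (chrom, length), k in zip(genome, per_chrom):
        if k == 0:
            continue
        spacing = (length - 2 * margin) / k
        if spacing < 110_000:
            raise ValueError(
                f"chromosome {chrom} too short for {k} genes "
                "(needs ≥110 kb spacing for distal-enhancer placement)"
            )
        for i in range(k):
            tss = int(margin + i * spacing + rng.integers(-10_000, 10_001))
            positions.append((chrom, tss))
    return positions


def _peak(chrom: str, center: int, half: int, signal: float,
          name: str, qvalue: float = 0.001) -> Peak:
    return Peak(GenomicInterval(chrom, max(0, center - half), center + half),
                signal=signal, qvalue=qvalue, name=name)


def simulate_regulome(spec: SyntheticSpec) -> Regulome:
    """Toy regulome with planted group I/II structure and true links.

    Group II genes get an NRF2 peak inside the ±1 kb promoter window; group
    I genes get none at the promoter but an NRF2+H3K27ac+p300 enhancer
    15–50 kb away, annotated as a chromatin-state enhancer, transcribing a
    responsive eRNA and wired to the promoter by a true link whose CCscore
    is ``true_link_ccscore``. All link anchors are the 5 kb bin containing
    the promoter or enhancer.
    """
    rng = spec.rng("regulome")
    n_sig, n_non = spec.n_genes, spec.n_nonsignature_genes
    slots = _place_genes(spec, rng, n_sig + n_non)
    order = rng.permutation(len(slots))
    genes = []
    for i, slot in enumerate(order):
        is_sig = i < n_sig
        name = f"SIG{i:03d}" if is_sig else f"GENE{i - n_sig:03d}"
        genes.append((name, *slots[slot], is_sig))

    n_group1 = int(round(spec.frac_group1 * n_sig))
    sig_idx = [i for i, g in enumerate(genes) if g[3]]
    group1_set = set(rng.choice(sig_idx, size=n_group1, replace=False))

    promoters: List[Promoter] = []
    gene_bodies: Dict[str, GenomicInterval] = {}
    peaks: Dict[str, List[Peak]] = {"NRF2": [], "p300": [],
                                    "H3K4me3": [], "H3K27ac": []}
    enhancer_states: List[GenomicInterval] = []
    proseq_rows: List[dict] = []
    links: List[Link] = []
    truth_link_rows: List[dict] = []
    truth_group_rows: List[dict] = []
    resolution = 5000

    def bin_anchor(chrom: str, pos: int) -> GenomicInterval:
        start = (pos // resolution) * resolution
        return GenomicInterval(chrom, start, start + resolution)

    def add_proseq(chrom: str, center: int, responsive: bool, tag: str):
        row = {"peak": tag, "chrom": chrom,
               "start": max(0, center - 250), "end": center + 250}
        for cond in CONDITIONS:
            if responsive:
                row[f"logfc_{cond}"] = float(-rng.uniform(0.5, 3.0))
                row[f"p_{cond}"] = float(rng.uniform(1e-5, 0.05))
            else:
                row[f"logfc_{cond}"] = float(rng.normal(0.0, 0.4))
                row[f"p_{cond}"] = float(rng.uniform(0.0, 1.0))
        proseq_rows.append(row)

    hi_signal = lambda: float(rng.normal(50.0, 5.0))
    lo_signal = lambda: float(rng.normal(10.0, 2.0))

    planted: List[Tuple[str, str, int]] = []  # (gene, chrom, enhancer center)
    group1_genes = []
    for i, (name, chrom, tss, is_sig) in enumerate(genes):
        strand = "+" if rng.random() < 0.5 else "-"
        promoters.append(Promoter(name, GenomicInterval(chrom, tss, tss + 1,
                                                        strand)))
        body_len = int(rng.integers(2_000, 20_000))
        gene_bodies[name] = (
            GenomicInterval(chrom, tss, tss + body_len, strand)
            if strand == "+"
            else GenomicInterval(chrom, max(0, tss - body_len), tss + 1, strand)
        )
        peaks["H3K4me3"].append(_peak(chrom, tss, 400, hi_signal(),
                                      f"{name}_k4"))
        if not is_sig:
            add_proseq(chrom, tss, responsive=False, tag=f"{name}_prom")
            continue
        group = "I" if i in group1_set else "II"
        truth_group_rows.append({"gene": name, "truth_group": group})
        add_proseq(chrom, tss, responsive=True, tag=f"{name}_prom")
        peaks["H3K27ac"].append(_peak(chrom, tss, 500, hi_signal(),
                                      f"{name}_k27_prom"))
        if group == "II":
            peaks["NRF2"].append(_peak(chrom, tss + int(rng.integers(-300, 301)),
                                       300, hi_signal(), f"{name}_nrf2_prom"))
            peaks["p300"].append(_peak(chrom, tss, 300, hi_signal(),
                                       f"{name}_p300_prom"))
        else:
            group1_genes.append(name)
            sign = -1 if rng.random() < 0.5 else 1
            dist = int(rng.integers(15_000, 50_001))
            planted.append((name, chrom, tss + sign * dist))

    # second enhancer for the higher-order subset of group I genes
    n_ho = int(round(spec.frac_higher_order * len(group1_genes)))
    ho_genes = set(group1_genes[:n_ho])
    by_gene = {g: (c, t) for g, c, t in planted}
    for name in group1_genes:
        if name not in ho_genes:
            continue
        chrom, first = by_gene[name]
        tss = next(p.tss.start for p in promoters if p.gene == name)
        sign = 1 if first < tss else -1  # opposite side of the promoter
        planted.append((name, chrom, tss + sign * int(rng.integers(15_000,
                                                                   50_001))))

    if spec.n_true_links is not None:
        if spec.n_true_links > len(planted):
            # extend round-robin with further enhancers on group I genes
            k = 0
            while len(planted) < spec.n_true_links:
                if not group1_genes:
                    raise ValueError("n_true_links requested but no group I "
                                     "genes to host them")
                name = group1_genes[k % len(group1_genes)]
                chrom, _ = by_gene[name]
                tss = next(p.tss.start for p in promoters if p.gene == name)
                extra = int(rng.integers(55_000, 90_000))
                sign = -1 if rng.random() < 0.5 else 1
                planted.append((name, chrom, tss + sign * extra))
                k += 1
        planted = planted[: spec.n_true_links]

    tss_of = {p.gene: p.tss.start for p in promoters}
    for name, chrom, center in planted:
        peaks["NRF2"].append(_peak(chrom, center, 300, hi_signal(),
                                   f"{name}_nrf2_enh"))
        peaks["p300"].append(_peak(chrom, center, 300, hi_signal(),
                                   f"{name}_p300_enh"))
        peaks["H3K27ac"].append(_peak(chrom, center, 500, hi_signal(),
                                      f"{name}_k27_enh"))
        enhancer_states.append(GenomicInterval(chrom, max(0, center - 1000),
                                               center + 1000))
        add_proseq(chrom, center, responsive=True, tag=f"{name}_enh_{center}")
        link = Link(bin_anchor(chrom, tss_of[name]), bin_anchor(chrom, center),
                    ccscore=spec.true_link_ccscore, pvalue=0.001,
                    name=f"{name}_link")
        links.append(link)
        truth_link_rows.append(
            {"chrom1": link.anchor1.chrom, "start1": link.anchor1.start,
             "end1": link.anchor1.end, "chrom2": link.anchor2.chrom,
             "start2": link.anchor2.start, "end2": link.anchor2.end,
             "ccscore": link.ccscore, "truth_true": True, "truth_gene": name}
        )

    # background: random low-signal NRF2 peaks + non-responsive PRO-seq noise
    lengths = np.array([ln for _, ln in spec.genome], dtype=float)
    for b in range(spec.n_background_links):
        ci = rng.choice(len(spec.genome), p=lengths / lengths.sum())
        chrom, clen = spec.genome[ci]
        s1 = int(rng.integers(0, clen - 2_100_000))
        offset = int(rng.integers(10_000, 2_000_000))
        link = Link(bin_anchor(chrom, s1), bin_anchor(chrom, s1 + offset),
                    ccscore=float(spec.ccscore_min + rng.exponential(1.0)),
                    pvalue=float(rng.uniform(0.0, 1.0)), name=f"bg{b:03d}")
        links.append(link)
        truth_link_rows.append(
            {"chrom1": link.anchor1.chrom, "start1": link.anchor1.start,
             "end1": link.anchor1.end, "chrom2": link.anchor2.chrom,
             "start2": link.anchor2.start, "end2": link.anchor2.end,
             "ccscore": link.ccscore, "truth_true": False, "truth_gene": ""}
        )
    tss_positions = [(p.tss.chrom, p.tss.start) for p in promoters]
    for b in range(30):
        for _ in range(100):  # keep background peaks clear of promoters
            ci = rng.choice(len(spec.genome), p=lengths / lengths.sum())
            chrom, clen = spec.genome[ci]
            center = int(rng.integers(1000, clen - 1000))
            if all(c != chrom or abs(center - t) > 2000
                   for c, t in tss_positions):
                break
        peaks["NRF2"].append(_peak(chrom, center, 200, lo_signal(),
                                   f"bgpk{b:03d}", qvalue=float(rng.uniform())))
        add_proseq(chrom, center, responsive=False, tag=f"bg_peak_{b:03d}")

    return Regulome(
        promoters=promoters,
        gene_bodies=gene_bodies,
        peaks=peaks,
        enhancer_states=enhancer_states,
        proseq=pd.DataFrame(proseq_rows),
        links=links,
        truth_links=pd.DataFrame(truth_link_rows),
        truth_groups=pd.DataFrame(truth_group_rows),
        signature_genes={g for g, *_ in
                         ((n, c, t) for n, c, t, s in genes if s)},
        genome=list(spec.genome),
    )


# -------------------------------------------------------------- rescue/omics


def simulate_rescue_and_omics(
    spec: SyntheticSpec,
) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Rescue log2FC table, analyte tables per assay, and truth tables.

    A ``frac_responsive`` subset of genes responds to NRF2 re-expression;
    ``frac_reliant`` of those are CBP/p300-reliant — the mutant response is
    the wild-type response scaled by ``attenuation`` (< 1), so their
    noise-free cosine to the diagonal is (1 + a)/(√2·√(1 + a²)) < 1.
    Analyte classes shift by their planted log2FC between the treated and
    control conditions with Gaussian replicate noise on the log2 scale.

    Returns (rescue table, {"metabolite": table, "lipid": table},
    rescue truth, analyte truth).
    """
    rng = spec.rng("rescue")
    n = spec.n_rescue_genes
    gene_names = [f"g{i:04d}" for i in range(n)]
    mean_cpm = rng.normal(3.0, 2.5, size=n)
    responsive = rng.random(n) < spec.frac_responsive
    reliant = responsive & (rng.random(n) < spec.frac_reliant)
    wt_true = np.where(responsive, rng.uniform(1.0, 3.0, size=n), 0.0)
    mut_true = np.where(reliant, spec.attenuation * wt_true, wt_true)
    luc = rng.normal(0.0, 0.3, size=n)
    noise = lambda: spec.rescue_noise_sd * rng.standard_normal(n)
    rescue = pd.DataFrame(
        {
            "gene": gene_names,
            "mean_log2_cpm": mean_cpm,
            "logfc_wt": luc + wt_true + noise(),
            "logfc_mut": luc + mut_true + noise(),
            "logfc_luc": luc,
        }
    )
    with np.errstate(invalid="ignore"):
        denom = np.sqrt(2.0) * np.hypot(wt_true, mut_true)
        truth_cos = np.where(denom > 0, (wt_true + mut_true) / denom, np.nan)
    rescue_truth = pd.DataFrame(
        {"gene": gene_names, "truth_responsive": responsive,
         "truth_reliant": reliant, "truth_cosine": truth_cos}
    )

    arng = spec.rng("analytes")
    tables: Dict[str, pd.DataFrame] = {}
    truth_rows = []
    for assay, classes in (("metabolite", spec.analyte_classes),
                           ("lipid", spec.lipid_classes)):
        rows = []
        for cls in classes:
            shift = cls.log2fc if cls.direction == "up" else -cls.log2fc
            for a in range(cls.n_analytes):
                base = arng.normal(10.0, 2.0)
                row = {"analyte": f"{assay}_{cls.name}_{a:02d}".replace(" ", "_"),
                       "class": cls.name}
                for r in range(spec.n_replicates):
                    row[f"treated_{r}"] = 2.0 ** (
                        base + shift + arng.normal(0.0, spec.analyte_noise_sd))
                    row[f"control_{r}"] = 2.0 ** (
                        base + arng.normal(0.0, spec.analyte_noise_sd))
                rows.append(row)
            truth_rows.append({"assay": assay, "class": cls.name,
                               "truth_log2fc": shift,
                               "truth_direction": cls.direction
                               if cls.log2fc != 0 else "null"})
        tables[assay] = pd.DataFrame(rows).set_index("analyte")
    analyte_truth = pd.DataFrame(truth_rows)
    return rescue, tables, rescue_truth, analyte_truth


def sample_condition_map(spec: SyntheticSpec) -> pd.Series:
    """Sample → condition map matching the simulated analyte tables."""
    data = {}
    for r in range(spec.n_replicates):
        data[f"treated_{r}"] = "treated"
        data[f"control_{r}"] = "control"
    return pd.Series(data)
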