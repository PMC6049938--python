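"""Synthetic genomes, annotations and stranded count data.

Generates toy datasets with the statistical structure the classification
pipeline assumes, so every stage runs and can be validated without any
external download:

* four gene classes — highly expressed genes attenuated in the mutant
  with an antisense XUT partner (class 1), attenuated genes without a
  partner (class 2), lowly expressed unchanged genes with a partner
  (class 3), unchanged genes without (class 4);
* antisense XUTs whose **nascent** synthesis is equal between conditions
  while their **steady-state** abundance rises in the mutant (the lncRNAs
  are stabilized, not transcribed more);
* promoter chromatin: an H3 nucleosome-depleted region at the TSS
  (deepest for class 1) and a TSS-proximal H4 acetylation peak (highest
  for the attenuated classes 1-2).

Counts follow NB(mean, dispersion alpha) with Var = mu + alpha mu^2,
matching the differential module's model. All randomness flows from the
config seed; identical (seed, config) gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotations import FeatureAnnotation, GenomicInterval
from .coverage import StrandedCoverage
from .differential import CountMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_netseq_counts",
    "simulate_rnaseq_counts",
    "simulate_chip",
]

# rng stream ids so each generator stage has an independent substream
_STREAM_ANNOT, _STREAM_NET, _STREAM_RNA, _STREAM_CHIP = 11, 23, 37, 53


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions the pipeline is validated
    against: 150 genes per class, WT class-1 mean 2000 tags vs class-3
    mean 100 (a 20:1 contrast), 3x transcriptional attenuation of
    classes 1-2 in the mutant, NB dispersion 0.05, two biological
    replicates per condition, XUT nascent synthesis equal across
    conditions with 4x steady-state stabilization in the mutant.
    """

    seed: int = 0
    n_chromosomes: int = 3
    genes_per_class: Tuple[int, int, int, int] = (150, 150, 150, 150)
    gene_length_range: Tuple[int, int] = (1000, 2000)
    intergenic_gap: int = 500
    edge_margin: int = 1200

    # expression (WT mean tags per gene, by class)
    wt_means: Tuple[float, float, float, float] = (2000.0, 1500.0, 100.0, 400.0)
    attenuation_fold: float = 3.0
    dispersion: float = 0.05
    replicates: int = 2
    size_multipliers: Optional[Tuple[float, ...]] = (1.0, 1.2, 0.9, 1.1)

    # asXUT geometry and levels
    xut_overlap_fraction: float = 0.5
    xut_tss_overlap: bool = True
    xut_upstream_extension: int = 200
    xut_nascent_mean: float = 150.0
    xut_stabilization_fold: float = 4.0

    # read-to-position scattering along features
    scatter: str = "uniform"  # or "five_prime_peaked"

    # promoter chromatin (per class 1..4)
    h3_level: float = 20.0
    ndr_depth: Tuple[float, float, float, float] = (0.8, 0.6, 0.5, 0.4)
    ndr_width: float = 100.0
    h4ac_enhancement_wt: Tuple[float, float, float, float] = (4.0, 4.0, 1.5, 1.2)
    h4ac_enhancement_mut: Tuple[float, float, float, float] = (1.5, 4.0, 1.5, 1.2)
    acetyl_peak_width: float = 150.0

    # null mode: attenuate a random gene subset, uncorrelated with asXUT
    independent_attenuation: bool = False

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.wt_means):
            raise ValueError("class means must be > 0")
        if self.attenuation_fold <= 1:
            raise ValueError("attenuation_fold must be > 1")
        if not (0 < self.xut_overlap_fraction <= 1):
            raise ValueError("xut_overlap_fraction must lie in (0, 1]")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate per condition")
        n_samples = 2 * self.replicates
        if self.size_multipliers is not None and len(self.size_multipliers) != n_samples:
            raise ValueError(f"size_multipliers must have length {n_samples}")

    @property
    def sample_names(self) -> List[str]:
        return [f"WT_{i + 1}" for i in range(self.replicates)] + [
            f"mut_{i + 1}" for i in range(self.replicates)
        ]

    @property
    def conditions(self) -> Dict[str, str]:
        return {s: ("WT" if s.startswith("WT") else "mut") for s in self.sample_names}

    def multipliers(self) -> np.ndarray:
        if self.size_multipliers is None:
            return np.ones(2 * self.replicates)
        return np.asarray(self.size_multipliers, dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """True labels and means behind a simulated dataset.

    ``genes``: per gene — true class label, attenuation flag, asXUT flag,
    WT/mutant nascent means. ``xuts``: per XUT — paired gene, nascent
    mean (shared between conditions) and steady-state means.
    """

    genes: pd.DataFrame
    xuts: pd.DataFrame


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_annotation(
    cfg: SimulationConfig,
) -> Tuple[List[FeatureAnnotation], List[FeatureAnnotation], GroundTruth]:
    """Lay out genes and their antisense XUTs on toy chromosomes.

    Genes are placed without overlap, class labels shuffled along the
    genome, strands random. Every class 1 and class 3 gene receives one
    opposite-strand XUT covering ``xut_overlap_fraction`` of the gene
    (anchored at the gene TSS and extended upstream when
    ``xut_tss_overlap``, else at the gene 3' end); classes 2 and 4
    receive none.
    """
    rng = _rng(cfg, _STREAM_ANNOT)
    n_genes = sum(cfg.genes_per_class)
    labels = np.repeat([1, 2, 3, 4], cfg.genes_per_class)
    labels = labels[rng.permutation(n_genes)]
    lengths = rng.integers(*cfg.gene_length_range, size=n_genes, endpoint=True)
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")

    per_chrom = int(np.ceil(n_genes / cfg.n_chromosomes))
    slot = cfg.gene_length_range[1] + cfg.intergenic_gap + cfg.xut_upstream_extension
    chrom_len = 2 * cfg.edge_margin + per_chrom * slot

    genes: List[FeatureAnnotation] = []
    xuts: List[FeatureAnnotation] = []
    gene_rows, xut_rows = [], []
    for i in range(n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        cursor = cfg.edge_margin + (i % per_chrom) * slot + cfg.xut_upstream_extension
        start, end = cursor, cursor + int(lengths[i])
        if end + cfg.xut_upstream_extension > chrom_len:
            raise ValueError("infeasible packing: gene exceeds chromosome length")
        strand, label = strands[i], int(labels[i])
        gid = f"gene{i + 1:04d}"
        genes.append(
            FeatureAnnotation(gid, GenomicInterval(chrom, start, end, strand), "mRNA")
        )
        has_asxut = label in (1, 3)
        if has_asxut:
            xid = f"XUT{i + 1:04d}"
            xuts.append(
                FeatureAnnotation(
                    xid,
                    _xut_interval(cfg, GenomicInterval(chrom, start, end, strand)),
                    "XUT",
                )
            )
            xut_rows.append(
                {
                    "xut_id": xid,
                    "gene_id": gid,
                    "nascent_mean": cfg.xut_nascent_mean,
                    "rna_wt_mean": cfg.xut_nascent_mean,
                    "rna_mut_mean": cfg.xut_nascent_mean * cfg.xut_stabilization_fold,
                }
            )
        gene_rows.append(
            {"gene_id": gid, "class_label": label, "strand": strand, "has_asxut": has_asxut}
        )

    gt_genes = pd.DataFrame(gene_rows).set_index("gene_id")
    if cfg.independent_attenuation:
        # null mode: both the attenuated subset and the expression level are
        # drawn independently of asXUT presence, so detection power carries
        # no information about the antisense partner
        n_att = cfg.genes_per_class[0] + cfg.genes_per_class[1]
        att = np.zeros(n_genes, dtype=bool)
        att[rng.choice(n_genes, size=n_att, replace=False)] = True
        gt_genes["attenuated_true"] = att
        wt_mean = rng.choice(np.asarray(cfg.wt_means), size=n_genes)
    else:
        gt_genes["attenuated_true"] = gt_genes["class_label"].isin([1, 2])
        wt_mean = np.asarray(cfg.wt_means)[gt_genes["class_label"].to_numpy() - 1]
    gt_genes["wt_mean"] = wt_mean
    gt_genes["mut_mean"] = np.where(
        gt_genes["attenuated_true"], wt_mean / cfg.attenuation_fold, wt_mean
    )
    gt_xuts = (
        pd.DataFrame(xut_rows).set_index("xut_id")
        if xut_rows
        else pd.DataFrame(columns=["gene_id", "nascent_mean", "rna_wt_mean", "rna_mut_mean"])
    )
    return genes, xuts, GroundTruth(gt_genes, gt_xuts)


def _xut_interval(cfg: SimulationConfig, gene: GenomicInterval) -> GenomicInterval:
    """Opposite-strand XUT covering a fraction of the gene, optionally
    spanning the gene TSS and extending upstream of it."""
    overlap = max(1, int(round(cfg.xut_overlap_fraction * len(gene))))
    ext = cfg.xut_upstream_extension
    anti = "-" if gene.strand == "+" else "+"
    if cfg.xut_tss_overlap:
        if gene.strand == "+":  # TSS at gene.start; upstream = lower coords
            start, end = gene.start - ext, gene.start + overlap
        else:  # TSS at gene.end - 1; upstream = higher coords
            start, end = gene.end - overlap, gene.end + ext
    else:  # overlap anchored at the gene 3' end
        if gene.strand == "+":
            start, end = gene.end - overlap, gene.end + ext
        else:
            start, end = gene.start - ext, gene.start + overlap
    return GenomicInterval(gene.chrom, max(0, start), end, anti)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, alpha) with Var = mu + alpha mu^2; Poisson when alpha ~ 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _chrom_sizes(features: Sequence[FeatureAnnotation], cfg: SimulationConfig) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    for f in features:
        iv = f.interval
        need = iv.end + cfg.edge_margin
        sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), need)
    return sizes


def _scatter_counts(
    rng: np.random.Generator,
    cov: StrandedCoverage,
    feature: FeatureAnnotation,
    count: int,
    mode: str,
) -> None:
    """Distribute a feature's tags along its interval on its own strand."""
    if count <= 0:
        return
    iv = feature.interval
    length = len(iv)
    if mode == "uniform":
        offsets = rng.integers(0, length, size=count)
    elif mode == "five_prime_peaked":
        offsets = np.minimum(
            rng.exponential(scale=length / 5.0, size=count).astype(int), length - 1
        )
        if iv.strand == "-":
            offsets = length - 1 - offsets
    else:
        raise ValueError(f"unknown scatter mode {mode!r}")
    np.add.at(cov.strand(iv.strand)[iv.chrom], iv.start + offsets, 1.0)


def _simulate_counts(
    cfg: SimulationConfig,
    genes: Sequence[FeatureAnnotation],
    xuts: Sequence[FeatureAnnotation],
    truth: GroundTruth,
    stream: int,
    xut_mut_col: str,
    make_coverage: bool,
) -> Tuple[CountMatrix, Optional[Dict[str, StrandedCoverage]]]:
    rng = _rng(cfg, stream)
    features = list(genes) + list(xuts)
    mult = cfg.multipliers()
    is_mut = np.array([c == "mut" for c in (cfg.conditions[s] for s in cfg.sample_names)])

    wt_mean = np.concatenate(
        [
            truth.genes.loc[[g.id for g in genes], "wt_mean"].to_numpy(),
            truth.xuts.loc[[x.id for x in xuts], "nascent_mean"].to_numpy()
            if xuts
            else np.empty(0),
        ]
    )
    mut_mean = np.concatenate(
        [
            truth.genes.loc[[g.id for g in genes], "mut_mean"].to_numpy(),
            truth.xuts.loc[[x.id for x in xuts], xut_mut_col].to_numpy()
            if xuts
            else np.empty(0),
        ]
    )
    counts = np.empty((len(features), len(cfg.sample_names)), dtype=np.int64)
    for j, _sample in enumerate(cfg.sample_names):
        base = np.where(is_mut[j], mut_mean, wt_mean) * mult[j]
        counts[:, j] = _nb_draw(rng, base, cfg.dispersion)
    cm = CountMatrix(
        pd.DataFrame(counts, index=[f.id for f in features], columns=cfg.sample_names),
        cfg.conditions,
    )
    if not make_coverage:
        return cm, None
    sizes = _chrom_sizes(features, cfg)
    coverages: Dict[str, StrandedCoverage] = {}
    for j, sample in enumerate(cfg.sample_names):
        cov = StrandedCoverage.zeros(sizes)
        for i, f in enumerate(features):
            _scatter_counts(rng, cov, f, int(counts[i, j]), cfg.scatter)
        cov.library_size = float(counts[:, j].sum())
        coverages[sample] = cov
    return cm, coverages


def simulate_netseq_counts(
    cfg: SimulationConfig,
    genes: Sequence[FeatureAnnotation],
    xuts: Sequence[FeatureAnnotation],
    truth: GroundTruth,
    make_coverage: bool = True,
) -> Tuple[CountMatrix, Optional[Dict[str, StrandedCoverage]]]:
    """Nascent-transcription counts and per-sample stranded coverage.

    Gene means follow the class structure (mutant mean divided by the
    attenuation fold for attenuated genes); XUT nascent means are equal
    between conditions. Tags are scattered along each feature on its own
    strand to produce per-nucleotide coverage.
    """
    return _simulate_counts(
        cfg, genes, xuts, truth, _STREAM_NET, "nascent_mean", make_coverage
    )


def simulate_rnaseq_counts(
    cfg: SimulationConfig,
    genes: Sequence[FeatureAnnotation],
    xuts: Sequence[FeatureAnnotation],
    truth: GroundTruth,
    make_coverage: bool = True,
) -> Tuple[CountMatrix, Optional[Dict[str, StrandedCoverage]]]:
    """Steady-state (RNA-level) counts: identical to the nascent generator
    except XUT means are multiplied by the stabilization fold in the
    mutant — the lncRNAs accumulate without being transcribed more."""
    return _simulate_counts(
        cfg, genes, xuts, truth, _STREAM_RNA, "rna_mut_mean", make_coverage
    )


def coverage_to_bed_reads(
    cov: StrandedCoverage, path, read_length: int = 30
) -> int:
    """Write a raw point-mode coverage as 6-column BED reads.

    Each tag at position p becomes one read whose 3'-most base (in
    transcript orientation) is p, so re-building coverage from the BED in
    ``point_3prime`` mode reproduces the original vectors exactly (up to
    clipping at position 0). Returns the number of reads written.
    """
    n = 0
    with open(path, "w") as fh:
        for strand, vectors in (("+", cov.plus), ("-", cov.minus)):
            for chrom in sorted(vectors):
                vec = vectors[chrom]
                positions = np.flatnonzero(vec)
                for pos in positions:
                    count = int(vec[pos])
                    if strand == "+":
                        start, end = max(0, pos - read_length + 1), pos + 1
                    else:
                        start, end = pos, min(len(vec), pos + read_length)
                    for _ in range(count):
                        fh.write(f"{chrom}\t{start}\t{end}\tread{n}\t0\t{strand}\n")
                        n += 1
    return n


def simulate_chip(
    cfg: SimulationConfig,
    genes: Sequence[FeatureAnnotation],
    truth: GroundTruth,
) -> Dict[str, Dict[str, StrandedCoverage]]:
    """Promoter chromatin tracks: H3 and H4ac coverage per condition.

    H3 is a flat baseline carved by a Gaussian nucleosome-depleted region
    at each TSS (depth by class, deepest for class 1). H4ac equals H3
    multiplied by a class-specific promoter-peaked enhancement (highest
    for the attenuated classes in WT; class-1 enhancement reduced in the
    mutant). Poisson noise is applied per nucleotide. ChIP is unstranded:
    signal is stored on the plus strand.

    Returns ``{condition: {"h3": cov, "h4ac": cov}}``.
    """
    rng = _rng(cfg, _STREAM_CHIP)
    sizes = _chrom_sizes(genes, cfg)
    out: Dict[str, Dict[str, StrandedCoverage]] = {}
    enh_by_cond = {"WT": cfg.h4ac_enhancement_wt, "mut": cfg.h4ac_enhancement_mut}
    for cond in ("WT", "mut"):
        h3_mean = {c: np.full(n, cfg.h3_level) for c, n in sizes.items()}
        enh = {c: np.ones(n) for c, n in sizes.items()}
        reach = int(6 * max(cfg.ndr_width, cfg.acetyl_peak_width))
        for g in genes:
            iv = g.interval
            label = int(truth.genes.loc[g.id, "class_label"])
            tss = iv.start if iv.strand == "+" else iv.end - 1
            lo = max(0, tss - reach)
            hi = min(sizes[iv.chrom], tss + reach + 1)
            x = np.arange(lo, hi)
            bump = np.exp(-0.5 * ((x - tss) / cfg.ndr_width) ** 2)
            h3_mean[iv.chrom][lo:hi] *= 1.0 - cfg.ndr_depth[label - 1] * bump
            peak = np.exp(-0.5 * ((x - tss) / cfg.acetyl_peak_width) ** 2)
            enh[iv.chrom][lo:hi] += (enh_by_cond[cond][label - 1] - 1.0) * peak
        h3 = StrandedCoverage.zeros(sizes)
        h4 = StrandedCoverage.zeros(sizes)
        for c in sizes:
            h3.plus[c] = rng.poisson(h3_mean[c]).astype(float)
            h4.plus[c] = rng.poisson(h3_mean[c] * enh[c]).astype(float)
        h3.library_size = h3.total()
        h4.library_size = h4.total()
        out[cond] = {"h3": h3, "h4ac": h4}
    return out
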