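"""End-to-end pipeline wiring: coverage -> quantify -> differential ->
classify -> metagene, plus configuration and run logging.

The pipeline consumes aligned stranded reads (SAM or 6-column BED) per
sample, a GFF3 annotation distinguishing mRNAs and XUTs, and a sample
sheet (condition + replicate per sample). It writes the count table, the
differential table, one class table per gene class, the antisense
pairing, the enrichment report and per-class TSS metagene profiles, with
a run log recording the config hash and seed so any run is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import (
    FeatureAnnotation,
    antisense_pairs,
    read_gff,
    write_pairing_tsv,
)
from .classify import assign_classes, enrichment_report, write_class_tables
from .coverage import (
    StrandedCoverage,
    coverage_from_alignments,
    normalize_to_library,
    read_bed_alignments,
    read_sam_alignments,
    feature_signal,
)
from .differential import CountMatrix, run_differential
from .metagene import metagene_profile

logger = logging.getLogger("xutclass")

__all__ = ["SampleSpec", "PipelineConfig", "run_classify_pipeline", "quantify_features"]


@dataclass
class SampleSpec:
    sample_id: str
    condition: str  # "WT" or "mut"
    replicate: int
    path: Optional[str] = None  # SAM/BED alignments


@dataclass
class PipelineConfig:
    """Paths, sample sheet and thresholds for a pipeline run."""

    annotation: str
    samples: List[SampleSpec]
    outdir: str
    alpha: float = 0.05
    min_overlap: int = 1
    window: int = 1000
    pseudocount: float = 1.0
    assignment_mode: str = "point_3prime"
    use_adjusted_p: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["samples"] = [SampleSpec(**s) for s in raw["samples"]]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        if not Path(self.annotation).exists():
            raise FileNotFoundError(f"annotation file not found: {self.annotation}")
        for s in self.samples:
            if s.path is not None and not Path(s.path).exists():
                raise FileNotFoundError(
                    f"alignment file for sample {s.sample_id!r} not found: {s.path}"
                )
        conds = {s.condition for s in self.samples}
        if len(conds) < 2:
            raise ValueError("sample sheet needs >= 1 sample in each of two conditions")


def _read_alignments(path: str):
    if path.endswith((".sam", ".bam")):
        return read_sam_alignments(path)
    return read_bed_alignments(path)


def quantify_features(
    coverages: Mapping[str, StrandedCoverage],
    features: Sequence[FeatureAnnotation],
    conditions: Mapping[str, str],
    orientation: str = "sense",
) -> CountMatrix:
    """Per-feature total tags per sample (raw coverage), as a CountMatrix."""
    data = {
        sample: [feature_signal(cov, f, orientation)[1] for f in features]
        for sample, cov in coverages.items()
    }
    df = pd.DataFrame(data, index=[f.id for f in features]).round().astype(int)
    return CountMatrix(df, dict(conditions))


def classify_counts(
    cm: CountMatrix,
    genes: Sequence[FeatureAnnotation],
    xuts: Sequence[FeatureAnnotation],
    alpha: float = 0.05,
    min_overlap: int = 1,
    use_adjusted: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, object]]:
    """Counts-level pipeline: differential -> pairing -> classes -> enrichment.

    Convenience path for data already quantified (e.g. simulated count
    matrices); returns ``(diff, assignments, report)``.
    """
    diff = run_differential(
        cm, wt_label="WT", mut_label="mut", test_features=[g.id for g in genes]
    )
    pairs = antisense_pairs(genes, xuts, min_overlap)
    assignments = assign_classes(diff, pairs, alpha=alpha, use_adjusted=use_adjusted)
    return diff, assignments, enrichment_report(assignments)


def run_classify_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Execute the full classification pipeline and write all outputs.

    Returns a dict with the in-memory results (``counts``, ``diff``,
    ``assignments``, ``report``, ``profiles``) after writing TSV outputs
    and ``run_log.json`` under ``cfg.outdir``.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: Dict[str, int] = {}

    # --- annotation
    feats = read_gff(cfg.annotation)
    genes = [f for f in feats if f.kind == "mRNA"]
    xuts = [f for f in feats if f.kind == "XUT"]
    stage_counts["genes"] = len(genes)
    stage_counts["xuts"] = len(xuts)
    logger.info("annotation: %d genes, %d XUTs", len(genes), len(xuts))

    # --- coverage per sample
    chrom_sizes = _infer_chrom_sizes(feats)
    raw_cov: Dict[str, StrandedCoverage] = {}
    for s in cfg.samples:
        if s.path is None:
            raise ValueError(f"sample {s.sample_id!r} has no alignment path")
        try:
            raw_cov[s.sample_id] = coverage_from_alignments(
                _read_alignments(s.path), chrom_sizes, cfg.assignment_mode
            )
        except Exception as exc:
            raise RuntimeError(f"coverage stage failed for sample {s.sample_id!r}: {exc}") from exc
    target = min(c.library_size for c in raw_cov.values())
    norm_cov = {sid: normalize_to_library(c, target) for sid, c in raw_cov.items()}
    stage_counts["min_library"] = int(target)

    # --- quantify + differential
    conditions = {s.sample_id: s.condition for s in cfg.samples}
    cm = quantify_features(raw_cov, genes + xuts, conditions)
    cm.counts.to_csv(outdir / "counts.tsv", sep="\t")
    diff = run_differential(
        cm, wt_label="WT", mut_label="mut", test_features=[g.id for g in genes]
    )
    diff.to_csv(outdir / "differential.tsv", sep="\t")
    stage_counts["tested_genes"] = int((~diff["untestable"]).sum())

    # --- pairing + classification + enrichment
    pairs = antisense_pairs(genes, xuts, cfg.min_overlap)
    write_pairing_tsv(pairs, genes, xuts, outdir / "pairing.tsv")
    assignments = assign_classes(
        diff, pairs, alpha=cfg.alpha, use_adjusted=cfg.use_adjusted_p
    )
    write_class_tables(assignments, diff, outdir)
    report = enrichment_report(assignments)
    _write_enrichment(report, outdir / "enrichment.tsv")
    stage_counts.update({f"class{k}": v for k, v in report["class_counts"].items()})
    logger.info(
        "classes: %s; chi2=%.3f p=%.4f; asXUT share of attenuated: %s%%",
        report["class_counts"],
        report["chi2"],
        report["pvalue"],
        report["proportion_asxut_pct"],
    )

    # --- metagenes: per-class WT sense/antisense nascent signal
    wt_samples = [s.sample_id for s in cfg.samples if s.condition == "WT"]
    profiles = {}
    gene_by_class = {
        k: [g for g in genes if g.id in assignments.index and assignments.loc[g.id, "class_label"] == k]
        for k in (1, 2, 3, 4)
    }
    pooled = _mean_coverage([norm_cov[s] for s in wt_samples])
    for k, class_genes in gene_by_class.items():
        if not class_genes:
            continue
        for orient in ("sense", "antisense"):
            prof = metagene_profile(
                pooled, class_genes, cfg.window, orient, cfg.pseudocount
            )
            prof.write_tsv(outdir / f"metagene_class{k}_{orient}.tsv")
            profiles[(k, orient)] = prof

    # --- run log
    log = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_counts": stage_counts,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return {
        "counts": cm,
        "diff": diff,
        "assignments": assignments,
        "report": report,
        "profiles": profiles,
        "log": log,
    }


def _infer_chrom_sizes(feats: Sequence[FeatureAnnotation], margin: int = 1500) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    for f in feats:
        sizes[f.interval.chrom] = max(sizes.get(f.interval.chrom, 0), f.interval.end + margin)
    return sizes


def _mean_coverage(covs: Sequence[StrandedCoverage]) -> StrandedCoverage:
    """Average several normalized coverages position-wise."""
    out = StrandedCoverage(
        plus={c: np.mean([cv.plus[c] for cv in covs], axis=0) for c in covs[0].plus},
        minus={c: np.mean([cv.minus[c] for cv in covs], axis=0) for c in covs[0].minus},
        library_size=float(np.mean([cv.library_size for cv in covs])),
        normalized=True,
    )
    return out


def _write_enrichment(report: Mapping[str, object], path: Path) -> None:
    counts = report["class_counts"]
    rows = [
        {
            "class1": counts[1],
            "class2": counts[2],
            "class3": counts[3],
            "class4": counts[4],
            "n_tested": report["n_tested"],
            "chi2": report["chi2"],
            "pvalue": report["pvalue"],
            "proportion_asxut_pct": report["proportion_asxut_pct"],
        }
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
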