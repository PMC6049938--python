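"""TSS-anchored metagene profiles, ratio densities and box statistics.

A metagene aggregates a per-nucleotide signal across many genes aligned
at their transcription start site (position 0), with +x always pointing
downstream: windows from minus-strand genes are coordinate-reversed
before averaging. Signals are log2-transformed with a pseudocount, and a
per-position 95% confidence band (normal-approximation SEM across genes)
accompanies the mean. Genes whose window runs off a chromosome edge are
kept, with per-position gene counts tracking the clipping.

ChIP ratio profiles (e.g. H4ac over H3) are computed strand-unspecifically:
both strands are summed before the ratio, and the log2 ratio per position
is aggregated across genes like any other metagene signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import FeatureAnnotation, tss_of
from .coverage import StrandedCoverage, feature_signal

__all__ = [
    "MetageneProfile",
    "RatioDensity",
    "metagene_profile",
    "chip_ratio_metagene",
    "ci95",
    "ratio_density",
    "signal_boxstats",
]

Z95 = 1.959963984540054  # two-sided 97.5% normal quantile


@dataclass
class MetageneProfile:
    """Mean log2 signal around the TSS with a 95% confidence band.

    ``positions`` runs -W..+W (TSS = 0, +x downstream); ``mean`` and
    ``ci_halfwidth`` are per-position across genes; ``n`` is the
    per-position number of genes contributing (smaller near chromosome
    edges for clipped genes); ``n_genes`` the number aggregated.
    """

    positions: np.ndarray
    mean: np.ndarray
    ci_halfwidth: np.ndarray
    n: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean": self.mean,
                "ci_low": self.mean - self.ci_halfwidth,
                "ci_high": self.mean + self.ci_halfwidth,
                "n": self.n,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class RatioDensity:
    """Per-feature log2(mutant/WT) ratios with a Gaussian-kernel density."""

    ratios: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    category: str

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"grid": self.grid, "density": self.density}).to_csv(
            path, sep="\t", index=False
        )


def ci95(values: Sequence[float]) -> float:
    """95% half-width: 1.96 x sample sd / sqrt(n); NaN when n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(Z95 * v.std(ddof=1) / np.sqrt(v.size))


def _window_values(
    values: np.ndarray, center: int, w: int, reverse: bool
) -> Tuple[np.ndarray, np.ndarray]:
    """Extract values over center +/- w with an in-bounds mask; reversed
    for minus-strand genes so +x is downstream."""
    size = len(values)
    pos = np.arange(center - w, center + w + 1)
    mask = (pos >= 0) & (pos < size)
    out = np.zeros(2 * w + 1)
    out[mask] = values[pos[mask]]
    if reverse:
        out, mask = out[::-1], mask[::-1]
    return out, mask


def _aggregate(
    per_gene: Iterable[Tuple[np.ndarray, np.ndarray]], w: int, n_genes: int
) -> MetageneProfile:
    """Accumulate per-gene (values, mask) windows into mean + 95% CI."""
    width = 2 * w + 1
    total = np.zeros(width)
    total_sq = np.zeros(width)
    n = np.zeros(width, dtype=int)
    for vals, mask in per_gene:
        total[mask] += vals[mask]
        total_sq[mask] += vals[mask] ** 2
        n[mask] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
        # unbiased variance from accumulated moments
        var = np.where(
            n > 1, (total_sq - n * mean**2) / np.maximum(n - 1, 1), np.nan
        )
        var = np.maximum(var, 0.0)  # guard tiny negative round-off
        half = np.where(n > 1, Z95 * np.sqrt(var / np.maximum(n, 1)), np.nan)
    return MetageneProfile(
        positions=np.arange(-w, w + 1), mean=mean, ci_halfwidth=half, n=n, n_genes=n_genes
    )


def metagene_profile(
    cov: StrandedCoverage,
    genes: Sequence[FeatureAnnotation],
    window: int = 1000,
    orientation: str = "sense",
    pseudocount: float = 1.0,
) -> MetageneProfile:
    """Strand-specific metagene of log2(coverage + pseudocount) around the TSS.

    For each gene the window TSS +/- ``window`` is read from the gene's
    own strand (``orientation="sense"``) or the opposite strand
    (``"antisense"``); minus-strand genes are reversed so +x is always
    downstream of the TSS.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not genes:
        raise ValueError("empty gene set")
    if orientation not in ("sense", "antisense"):
        raise ValueError(f"orientation must be 'sense' or 'antisense', got {orientation!r}")

    def gen():
        for g in genes:
            iv = g.interval
            strand = iv.strand if orientation == "sense" else ("-" if iv.strand == "+" else "+")
            vec = cov.strand(strand)[iv.chrom]
            vals, mask = _window_values(vec, tss_of(g), window, reverse=iv.strand == "-")
            yield np.log2(vals + pseudocount), mask

    return _aggregate(gen(), window, len(genes))


def chip_ratio_metagene(
    ip: StrandedCoverage,
    h3: StrandedCoverage,
    genes: Sequence[FeatureAnnotation],
    window: int = 1000,
    pseudocount: float = 1.0,
) -> MetageneProfile:
    """H3-normalized ChIP metagene: log2((IP + eps) / (H3 + eps)) around TSS.

    Strand-unspecific: both strands of each coverage are summed per
    position before the ratio. Both coverages should be normalized to a
    common library scale first.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not genes:
        raise ValueError("empty gene set")
    ratio = {
        c: np.log2(
            (ip.plus[c] + ip.minus[c] + pseudocount)
            / (h3.plus[c] + h3.minus[c] + pseudocount)
        )
        for c in ip.plus
    }

    def gen():
        for g in genes:
            iv = g.interval
            vals, mask = _window_values(
                ratio[iv.chrom], tss_of(g), window, reverse=iv.strand == "-"
            )
            yield vals, mask

    return _aggregate(gen(), window, len(genes))


def ratio_density(
    cov_mut: StrandedCoverage,
    cov_wt: StrandedCoverage,
    features: Sequence[FeatureAnnotation],
    category: str,
    pseudocount: float = 0.1,
    bandwidth: str | float = "scott",
    grid_points: int = 512,
) -> RatioDensity:
    """Density of per-feature log2(mutant/WT) mean tag/nt ratios.

    Ratios use sense-strand mean coverage with a pseudocount on both
    terms; the Gaussian-kernel density (bandwidth by Scott's rule unless
    given) is evaluated on a grid spanning the ratios +/- 4 bandwidths,
    so its integral over the grid is 1 up to quadrature error.
    """
    if not features:
        raise ValueError(f"empty feature category {category!r}")
    ratios = np.array(
        [
            np.log2(
                (feature_signal(cov_mut, f)[0] + pseudocount)
                / (feature_signal(cov_wt, f)[0] + pseudocount)
            )
            for f in features
        ]
    )
    spread = ratios.std()
    if spread == 0 or len(ratios) < 2:
        # degenerate sample: represent as a narrow Gaussian at the value
        h = 1e-3
        grid = np.linspace(ratios[0] - 6 * h, ratios[0] + 6 * h, grid_points)
        density = stats.norm.pdf(grid, loc=ratios[0], scale=h)
        if len(ratios) > 1:
            density = np.mean(
                [stats.norm.pdf(grid, loc=r, scale=h) for r in ratios], axis=0
            )
        return RatioDensity(ratios, grid, density, category)
    kde = stats.gaussian_kde(ratios, bw_method=bandwidth)
    h = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(ratios.min() - 4 * h, ratios.max() + 4 * h, grid_points)
    return RatioDensity(ratios, grid, kde(grid), category)


def signal_boxstats(
    values: Sequence[float], labels: Sequence[object]
) -> pd.DataFrame:
    """Five-number box summaries per group.

    Quartiles use linear interpolation (type 7); whiskers extend to the
    most extreme data point within 1.5 x IQR of the quartiles. Empty
    groups are omitted with a warning. Returns a DataFrame indexed by
    group with columns whisker_low, q1, median, q3, whisker_high, n.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if v.shape != lab.shape:
        raise ValueError("values and labels must have the same length")
    rows = {}
    for g in pd.unique(lab):
        sub = v[lab == g]
        if sub.size == 0:
            warnings.warn(f"group {g!r} is empty; omitted from box stats")
            continue
        q1, med, q3 = np.percentile(sub, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = sub[(sub >= lo_fence) & (sub <= hi_fence)]
        rows[g] = {
            "whisker_low": float(inside.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "whisker_high": float(inside.max()),
            "n": int(sub.size),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
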