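"""Negative-binomial differential test for transcriptional attenuation.

Count-based two-condition comparison in the style established for RNA-seq
count data:

1. per-sample **size factors** by the median-of-ratios estimator,
2. per-feature **dispersions** by method-of-moments on normalized counts,
   shrunk conservatively toward a fitted mean-dispersion trend by taking
   the per-feature maximum of raw and trend values,
3. a two-sided **Wald test** on the log fold-change between condition
   means under the NB variance function Var = mu + alpha * mu^2,
4. **Benjamini-Hochberg** step-up adjustment across features.

The model is NB(mean = s_j * q_c, dispersion alpha) for sample j in
condition c: size factors absorb sequencing depth, q_c is the
condition-level expression, and alpha the biological overdispersion
(variance of normalized counts = q/s_j + alpha * q^2).

The design handled here is the simple two-group layout (e.g. WT vs
deletion mutant, two biological replicates each); no covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "size_factors_median_of_ratios",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "run_differential",
    "read_counts_tsv",
    "write_counts_tsv",
]

_MIN_DISP = 1e-8
#: floor (in normalized counts) applied to a zero condition mean inside the
#: Wald statistic; equals the reporting pseudocount
_ZERO_MEAN_FLOOR = 0.5


@dataclass
class CountMatrix:
    """Feature x sample integer counts with per-sample condition labels.

    ``counts`` is a features-by-samples DataFrame; ``conditions`` maps each
    sample id (column) to its condition label. At least one sample per
    condition is required; the study design this targets is 2 vs 2.
    """

    counts: pd.DataFrame
    conditions: Mapping[str, str]

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and ((arr < 0).any() or not np.allclose(arr, np.round(arr))):
            raise ValueError("counts must be non-negative integers")
        missing = [s for s in self.counts.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        labels = {self.conditions[s] for s in self.counts.columns}
        if len(labels) < 2:
            raise ValueError("need samples from at least two conditions")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


def size_factors_median_of_ratios(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over features f of
    ``count[f, j] / geomean_over_samples(count[f, :])``, restricted to
    features with strictly positive counts in every sample.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in all samples; median-of-ratios "
            "undefined (consider a pseudo-reference fallback)"
        )
    log_arr = np.log(arr[all_pos])
    log_geomean = log_arr.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_arr - log_geomean, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def estimate_dispersions(
    cm: CountMatrix,
    factors: pd.Series,
    fit_trend: bool = True,
) -> pd.DataFrame:
    """Per-feature NB dispersion estimates with conservative trend sharing.

    Raw estimate: on normalized counts pooled within each condition with
    >= 2 replicates, alpha_c = max(0, (s^2 - xi * mu) / mu^2) where
    ``xi = mean(1/s_j)`` removes the depth-dependent shot-noise term; the
    per-condition values are averaged. A gamma-family regression of the raw
    estimates on the base mean (design: intercept + 1/mean) provides a
    trend, and the final dispersion is the per-feature **maximum** of raw
    and trend values.

    Returns a DataFrame with columns ``base_mean``, ``disp_raw``,
    ``disp_trend``, ``dispersion`` and boolean ``all_zero`` (features with
    no counts anywhere: dispersion undefined, excluded from testing).
    """
    df = cm.counts
    s = factors.reindex(df.columns).to_numpy(dtype=float)
    norm = df.to_numpy(dtype=float) / s
    base_mean = norm.mean(axis=1)
    all_zero = base_mean == 0

    cond_of = [cm.conditions[c] for c in df.columns]
    raw_per_cond = []
    for cond in sorted(set(cond_of)):
        idx = np.array([c == cond for c in cond_of])
        if idx.sum() < 2:
            continue
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        xi = np.mean(1.0 / s[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - xi * mu) / mu**2
        raw_per_cond.append(np.where(mu > 0, np.maximum(a, 0.0), np.nan))
    if not raw_per_cond:
        raise ValueError("need >= 2 replicates in at least one condition")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows (all-zero features)
        disp_raw = np.nanmean(np.vstack(raw_per_cond), axis=0)
    disp_raw = np.where(all_zero, np.nan, np.nan_to_num(disp_raw, nan=0.0))

    disp_trend = _fit_dispersion_trend(base_mean, disp_raw) if fit_trend else np.zeros_like(base_mean)
    dispersion = np.fmax(np.fmax(disp_raw, disp_trend), _MIN_DISP)
    dispersion[all_zero] = np.nan
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "disp_raw": disp_raw,
            "disp_trend": disp_trend,
            "dispersion": dispersion,
            "all_zero": all_zero,
        },
        index=df.index,
    )


def _fit_dispersion_trend(base_mean: np.ndarray, disp_raw: np.ndarray) -> np.ndarray:
    """Gamma-family fit of dispersion on mean: alpha(mu) = a0 + a1 / mu.

    Fitted on features with a usable positive raw estimate. Falls back to
    the median positive raw dispersion (flat trend) if the regression
    cannot be fit or yields negative coefficients.
    """
    ok = np.isfinite(disp_raw) & (disp_raw > _MIN_DISP) & (base_mean > 0)
    flat = float(np.median(disp_raw[ok])) if ok.any() else 0.0
    out_flat = np.full_like(base_mean, flat, dtype=float)
    if ok.sum() < 10:
        return out_flat
    import statsmodels.api as sm

    X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                disp_raw[ok], X, family=sm.families.Gamma(link=sm.families.links.Identity())
            ).fit(maxiter=100)
        a0, a1 = res.params
    except Exception:
        return out_flat
    if not np.isfinite([a0, a1]).all() or (a0 < 0 and a1 < 0):
        return out_flat
    a0, a1 = max(a0, 0.0), max(a1, 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(base_mean > 0, base_mean, np.inf)
    return trend


def _wald_arrays(
    counts: np.ndarray,
    factors: np.ndarray,
    alphas: np.ndarray,
    is_mut: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NB Wald test. Returns (log2fc, pvalue, untestable)."""
    norm = counts / factors
    s_wt, s_mut = factors[~is_mut], factors[is_mut]
    mu_wt = norm[:, ~is_mut].mean(axis=1)
    mu_mut = norm[:, is_mut].mean(axis=1)
    untestable = (mu_wt == 0) & (mu_mut == 0) | ~np.isfinite(alphas)

    # reported fold-change: pseudocount only when one mean is zero
    pc = np.where((np.minimum(mu_wt, mu_mut) == 0), _ZERO_MEAN_FLOOR, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2((mu_mut + pc) / (mu_wt + pc))
    log2fc = np.where(untestable, 0.0, log2fc)

    # Wald statistic on ln(mu_mut) - ln(mu_wt); delta method with
    # Var(normalized count) = q/s_j + alpha q^2
    a = np.where(np.isfinite(alphas), alphas, 0.0)
    q_wt = np.maximum(mu_wt, _ZERO_MEAN_FLOOR)
    q_mut = np.maximum(mu_mut, _ZERO_MEAN_FLOOR)
    var_wt = (q_wt[:, None] / s_wt + a[:, None] * q_wt[:, None] ** 2).sum(axis=1) / len(s_wt) ** 2
    var_mut = (q_mut[:, None] / s_mut + a[:, None] * q_mut[:, None] ** 2).sum(axis=1) / len(s_mut) ** 2
    var_log = var_wt / q_wt**2 + var_mut / q_mut**2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (np.log(q_mut) - np.log(q_wt)) / np.sqrt(var_log)
    pvalue = 2.0 * stats.norm.sf(np.abs(w))
    pvalue = np.where(untestable, 1.0, pvalue)
    return log2fc, np.clip(pvalue, 0.0, 1.0), untestable


def nb_wald_test(
    counts_row: Sequence[float],
    factors: Sequence[float],
    alpha: float,
    is_mut: Sequence[bool],
) -> Tuple[float, float]:
    """Wald test for a single feature; returns ``(log2fc, raw p)``.

    ``is_mut`` flags the mutant samples among the columns; the contrast is
    mutant over WT. A feature with both condition means zero is untestable
    and reported as ``(0.0, 1.0)``.
    """
    lfc, p, _ = _wald_arrays(
        np.asarray(counts_row, dtype=float)[None, :],
        np.asarray(factors, dtype=float),
        np.array([alpha], dtype=float),
        np.asarray(is_mut, dtype=bool),
    )
    return float(lfc[0]), float(p[0])


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Standard step-up with monotonicity enforcement; values capped at 1.
    Raises on p outside [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def run_differential(
    cm: CountMatrix,
    wt_label: str = "WT",
    mut_label: str = "mut",
    test_features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full differential pipeline: size factors -> dispersions -> Wald -> BH.

    Size factors and the dispersion trend are estimated from the whole
    count matrix; when ``test_features`` is given, only those rows are
    tested and BH-adjusted (e.g. test mRNAs while letting antisense-lncRNA
    rows, whose synthesis is expected unchanged, stabilize the
    normalization).

    Returns a per-feature DataFrame (over the tested features) with
    columns ``base_mean``, ``log2fc`` (mutant over WT), ``pvalue``,
    ``padj``, ``dispersion`` and ``untestable``. Untestable features (no
    counts in either condition) carry p = 1, log2fc = 0 and NaN ``padj``;
    BH is applied over the testable features only.
    """
    for label in (wt_label, mut_label):
        if not cm.samples_of(label):
            raise ValueError(f"no samples with condition {label!r}")
    factors = size_factors_median_of_ratios(cm)
    disp = estimate_dispersions(cm, factors)
    if test_features is None:
        rows = np.arange(len(cm.counts.index))
    else:
        rows = cm.counts.index.get_indexer(list(test_features))
        if (rows < 0).any():
            raise KeyError("test_features contains ids absent from the count matrix")
    is_mut = np.array([cm.conditions[c] == mut_label for c in cm.counts.columns])
    is_wt = np.array([cm.conditions[c] == wt_label for c in cm.counts.columns])
    keep = is_mut | is_wt
    lfc, p, untestable = _wald_arrays(
        cm.counts.to_numpy(dtype=float)[np.ix_(rows, keep)],
        factors.to_numpy()[keep],
        disp["dispersion"].to_numpy()[rows],
        is_mut[keep],
    )
    padj = np.full(len(p), np.nan)
    testable = ~untestable
    if testable.any():
        padj[testable] = bh_adjust(p[testable])
    return pd.DataFrame(
        {
            "base_mean": disp["base_mean"].to_numpy()[rows],
            "log2fc": lfc,
            "pvalue": p,
            "padj": padj,
            "dispersion": disp["dispersion"].to_numpy()[rows],
            "untestable": untestable,
        },
        index=cm.counts.index[rows],
    )


def read_counts_tsv(path: str | Path, conditions: Mapping[str, str]) -> CountMatrix:
    """Read a features-x-samples count table (TSV, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df, conditions)


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t")
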