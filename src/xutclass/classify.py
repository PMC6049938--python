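"""Gene classes 1-4 and the attenuation x asXUT enrichment test.

Genes are partitioned by two booleans:

* **attenuated** — significant transcriptional reduction in the mutant
  (adjusted p below the threshold AND negative log2 fold-change), and
* **has_asXUT** — at least one antisense XUT partner.

giving class 1 (attenuated, asXUT), class 2 (attenuated, none),
class 3 (unchanged, asXUT), class 4 (unchanged, none). Independence of
the two labels is tested on the 2x2 contingency table with Pearson's
chi-square (df = 1, no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "assign_classes",
    "chi_square_2x2",
    "enrichment_report",
    "asxut_proportion",
    "write_class_tables",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of genes by (attenuated, has_asXUT): rows = attenuation."""

    att_asxut: int  # class 1
    att_no: int  # class 2
    not_asxut: int  # class 3
    not_no: int  # class 4

    def __post_init__(self) -> None:
        cells = (self.att_asxut, self.att_no, self.not_asxut, self.not_no)
        if any(c < 0 for c in cells):
            raise ValueError("contingency cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.att_asxut, self.att_no], [self.not_asxut, self.not_no]], dtype=float
        )

    @property
    def total(self) -> int:
        return self.att_asxut + self.att_no + self.not_asxut + self.not_no


def assign_classes(
    diff: pd.DataFrame,
    pairs: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    use_adjusted: bool = True,
    require_reduction: bool = True,
) -> pd.DataFrame:
    """Assign each tested gene to class 1, 2, 3 or 4.

    Parameters
    ----------
    diff:
        Differential result table indexed by gene id, with columns
        ``log2fc``, ``pvalue``, ``padj`` and ``untestable``.
    pairs:
        Antisense pairing (gene id -> list of XUT ids); genes absent from
        the mapping have no asXUT.
    alpha:
        Significance threshold (default 0.05).
    use_adjusted:
        Test the BH-adjusted p (default) or the raw p.
    require_reduction:
        Demand log2fc < 0 in addition to significance, so only reduced
        transcription counts as attenuation (default True).

    Returns a DataFrame (indexed like ``diff`` minus untestable genes)
    with columns ``attenuated``, ``has_asxut``, ``class_label`` and
    ``xut_ids`` (comma-joined). Untestable genes are excluded from all
    classes.
    """
    tested = diff.loc[~diff["untestable"].astype(bool)]
    pcol = tested["padj"] if use_adjusted else tested["pvalue"]
    attenuated = pcol < alpha
    if require_reduction:
        attenuated &= tested["log2fc"] < 0
    has_asxut = pd.Series(
        [gid in pairs and len(pairs[gid]) > 0 for gid in tested.index], index=tested.index
    )
    class_label = np.select(
        [
            attenuated & has_asxut,
            attenuated & ~has_asxut,
            ~attenuated & has_asxut,
        ],
        [1, 2, 3],
        default=4,
    )
    return pd.DataFrame(
        {
            "attenuated": attenuated.astype(bool),
            "has_asxut": has_asxut.astype(bool),
            "class_label": class_label,
            "xut_ids": [",".join(pairs.get(g, [])) for g in tested.index],
        },
        index=tested.index,
    )


def class_counts(assignments: pd.DataFrame) -> Dict[int, int]:
    vc = assignments["class_label"].value_counts()
    return {k: int(vc.get(k, 0)) for k in (1, 2, 3, 4)}


def chi_square_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> Tuple[float, float, np.ndarray]:
    """Pearson chi-square test of independence on a 2x2 table.

    Expected cells are ``row total x column total / grand total``; the
    statistic is ``sum((O - E)^2 / E)`` with df = 1 and an upper-tail
    p-value. No Yates correction by default (counts here are in the
    hundreds, where it is negligible); enable via the flag.

    Returns ``(statistic, pvalue, expected)``.
    """
    obs = table.as_array()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected == 0).any():
        raise ValueError(
            "an expected cell is 0 (degenerate margin); use an exact test instead"
        )
    diff = np.abs(obs - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    pvalue = float(stats.chi2.sf(statistic, df=1))
    return statistic, pvalue, expected


def asxut_proportion(n_class1: int, n_attenuated: int) -> float:
    """Percentage of attenuated genes carrying an asXUT, one decimal.

    ``n_attenuated`` is the class 1 + class 2 total. Raises if no gene is
    attenuated (the proportion is then undefined).
    """
    if n_attenuated <= 0:
        raise ValueError("no attenuated genes: proportion undefined")
    return round(100.0 * n_class1 / n_attenuated, 1)


def enrichment_report(assignments: pd.DataFrame) -> Dict[str, object]:
    """Contingency table, chi-square result and asXUT proportion.

    Returns a dict with keys ``table`` (:class:`ContingencyTable2x2`),
    ``class_counts``, ``chi2``, ``pvalue``, ``expected``,
    ``proportion_asxut_pct`` (class1 / attenuated as a percentage, or None
    if no gene is attenuated) and ``n_tested``.
    """
    counts = class_counts(assignments)
    table = ContingencyTable2x2(counts[1], counts[2], counts[3], counts[4])
    try:
        statistic, pvalue, expected = chi_square_2x2(table)
    except ValueError:  # a zero margin: independence test undefined
        statistic = pvalue = expected = None
    n_att = counts[1] + counts[2]
    proportion = asxut_proportion(counts[1], n_att) if n_att > 0 else None
    return {
        "table": table,
        "class_counts": counts,
        "chi2": statistic,
        "pvalue": pvalue,
        "expected": expected,
        "proportion_asxut_pct": proportion,
        "n_tested": table.total,
    }


def write_class_tables(
    assignments: pd.DataFrame, diff: pd.DataFrame, outdir: str | Path
) -> List[Path]:
    """One TSV per class: gene id, log2FC, adjusted p, paired XUT ids."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label in (1, 2, 3, 4):
        sub = assignments.loc[assignments["class_label"] == label]
        out = pd.DataFrame(
            {
                "gene_id": sub.index,
                "log2fc": diff.loc[sub.index, "log2fc"].to_numpy(),
                "padj": diff.loc[sub.index, "padj"].to_numpy(),
                "xut_ids": sub["xut_ids"].to_numpy(),
            }
        )
        path = outdir / f"class{label}.tsv"
        out.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
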