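#!/usr/bin/env python
"""Differential nascent transcription, mutant vs WT.

Median-of-ratios size factors are estimated on all quantified features
(mRNAs + XUTs, the latter transcriptionally unchanged by construction);
mRNAs are then tested with the NB Wald test and BH-adjusted. Writes
results/differential.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from xutclass.annotations import read_gff
from xutclass.differential import CountMatrix, run_differential


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.split("\n")[0])
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/differential.tsv"))
    args = ap.parse_args()

    samples = pd.read_csv(args.data / "samples.tsv", sep="\t")
    conditions = dict(zip(samples["sample_id"], samples["condition"]))
    counts = pd.read_csv(args.data / "netseq_counts.tsv", sep="\t", index_col=0)
    genes = [f.id for f in read_gff(args.data / "annotation.gff3") if f.kind == "mRNA"]

    res = run_differential(CountMatrix(counts, conditions), test_features=genes)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    res.to_csv(args.out, sep="\t")

    sig = (res["padj"] < 0.05) & (res["log2fc"] < 0)
    print(
        f"tested {int((~res['untestable']).sum())} genes; "
        f"{int(sig.sum())} transcriptionally attenuated in the mutant "
        f"(adjusted p < 0.05 and log2FC < 0); "
        f"median attenuated log2FC {res.loc[sig, 'log2fc'].median():.2f}"
    )


if __name__ == "__main__":
    main()
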