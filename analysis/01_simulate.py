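#!/usr/bin/env python
"""Generate the synthetic study: annotation, ground truth and count tables.

Emulates the statistical structure of the real experiment: four gene
classes (attenuated/unchanged x with/without antisense XUT), nascent
counts for WT and mutant duplicates, and a steady-state (RNA-level)
modality in which XUTs are stabilized 4x in the mutant without any
change in their synthesis. Writes GFF3/TSV inputs for the downstream
steps under results/data/.
"""

import argparse
from pathlib import Path

import pandas as pd
import yaml

from xutclass.annotations import write_gff
from xutclass.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_netseq_counts,
    simulate_rnaseq_counts,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.split("\n")[0])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    genes, xuts, truth = simulate_annotation(cfg)
    write_gff(genes + xuts, args.out / "annotation.gff3")
    net, _ = simulate_netseq_counts(cfg, genes, xuts, truth, make_coverage=False)
    rna, _ = simulate_rnaseq_counts(cfg, genes, xuts, truth, make_coverage=False)
    net.counts.to_csv(args.out / "netseq_counts.tsv", sep="\t")
    rna.counts.to_csv(args.out / "rnaseq_counts.tsv", sep="\t")
    truth.genes.to_csv(args.out / "truth_genes.tsv", sep="\t")
    truth.xuts.to_csv(args.out / "truth_xuts.tsv", sep="\t")
    pd.DataFrame(
        {
            "sample_id": cfg.sample_names,
            "condition": [cfg.conditions[s] for s in cfg.sample_names],
            "replicate": [int(s.split("_")[1]) for s in cfg.sample_names],
        }
    ).to_csv(args.out / "samples.tsv", sep="\t", index=False)
    with open(args.out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    n_att = int(truth.genes["attenuated_true"].sum())
    print(
        f"simulated {len(genes)} genes ({n_att} attenuated in the mutant) and "
        f"{len(xuts)} antisense XUTs on {cfg.n_chromosomes} chromosomes -> {args.out}"
    )


if __name__ == "__main__":
    main()
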