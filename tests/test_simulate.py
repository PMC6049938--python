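"""Synthetic-data generator: geometry, count statistics, chromatin, determinism."""

import hashlib

import numpy as np
import pytest

from xutclass.annotations import antisense_pairs, overlap_length, write_gff
from xutclass.coverage import coverage_from_alignments, read_bed_alignments
from xutclass.metagene import chip_ratio_metagene, metagene_profile, ratio_density
from xutclass.simulate import (
    SimulationConfig,
    coverage_to_bed_reads,
    simulate_annotation,
    simulate_chip,
    simulate_netseq_counts,
    simulate_rnaseq_counts,
)


def _sha(path):
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"attenuation_fold": 1.0},
            {"xut_overlap_fraction": 0.0},
            {"xut_overlap_fraction": 1.5},
            {"wt_means": (0.0, 1, 1, 1)},
            {"size_multipliers": (1.0, 1.0)},
        ],
    )
    def test_rejects_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestAnnotationGeometry:
    def test_counts_and_pairing_recover_classes_1_and_3(self):
        cfg = SimulationConfig(seed=1, genes_per_class=(5, 5, 5, 5))
        genes, xuts, truth = simulate_annotation(cfg)
        assert len(genes) == 20 and len(xuts) == 10
        pairs = antisense_pairs(genes, xuts)
        expected = set(truth.genes.index[truth.genes["class_label"].isin([1, 3])])
        assert set(pairs) == expected
        # one XUT each, recorded in the ground truth
        for gid, xids in pairs.items():
            assert truth.xuts.loc[xids[0], "gene_id"] == gid

    def test_full_overlap_fraction_covers_gene(self):
        cfg = SimulationConfig(
            seed=2, genes_per_class=(3, 3, 3, 3), xut_overlap_fraction=1.0
        )
        genes, xuts, truth = simulate_annotation(cfg)
        by_id = {g.id: g for g in genes}
        for xid, row in truth.xuts.iterrows():
            x = next(x for x in xuts if x.id == xid)
            g = by_id[row["gene_id"]]
            assert overlap_length(g.interval, x.interval) == len(g.interval)
            assert x.interval.strand != g.interval.strand

    def test_genes_do_not_overlap_each_other(self):
        cfg = SimulationConfig(seed=3, genes_per_class=(10, 10, 10, 10))
        genes, _, _ = simulate_annotation(cfg)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_same_seed_gives_identical_gff(self, tmp_path):
        cfg = SimulationConfig(seed=4, genes_per_class=(4, 4, 4, 4))
        digests = []
        for name in ("a.gff3", "b.gff3"):
            genes, xuts, _ = simulate_annotation(cfg)
            write_gff(genes + xuts, tmp_path / name)
            digests.append(_sha(tmp_path / name))
        assert digests[0] == digests[1]
        genes, xuts, _ = simulate_annotation(SimulationConfig(seed=5, genes_per_class=(4, 4, 4, 4)))
        write_gff(genes + xuts, tmp_path / "c.gff3")
        assert _sha(tmp_path / "c.gff3") != digests[0]


class TestCounts:
    def test_class4_means_equal_between_conditions_by_construction(self):
        cfg = SimulationConfig(seed=6, genes_per_class=(2, 2, 2, 2))
        _, _, truth = simulate_annotation(cfg)
        c4 = truth.genes[truth.genes["class_label"] == 4]
        assert (c4["wt_mean"] == c4["mut_mean"]).all()
        c1 = truth.genes[truth.genes["class_label"] == 1]
        np.testing.assert_allclose(
            c1["mut_mean"], c1["wt_mean"] / cfg.attenuation_fold
        )

    def test_zero_dispersion_sample_means_near_configured(self):
        # law of large numbers: Poisson noise, means >= 1000, 4 samples
        cfg = SimulationConfig(
            seed=7,
            genes_per_class=(100, 100, 100, 100),
            dispersion=0.0,
            wt_means=(2000.0, 1500.0, 1000.0, 1200.0),
            size_multipliers=None,
        )
        genes, xuts, truth = simulate_annotation(cfg)
        cm, _ = simulate_netseq_counts(cfg, genes, xuts, truth, make_coverage=False)
        wt_cols = [s for s in cm.counts.columns if s.startswith("WT")]
        observed = cm.counts.loc[truth.genes.index, wt_cols].mean(axis=1)
        rel_err = (observed - truth.genes["wt_mean"]).abs() / truth.genes["wt_mean"]
        assert (rel_err < 0.05).mean() > 0.95

    def test_xut_nascent_counts_equal_mean_across_conditions(self):
        cfg = SimulationConfig(seed=8, genes_per_class=(50, 0, 50, 0), size_multipliers=None)
        genes, xuts, truth = simulate_annotation(cfg)
        cm, _ = simulate_netseq_counts(cfg, genes, xuts, truth, make_coverage=False)
        xut_counts = cm.counts.loc[truth.xuts.index]
        wt = xut_counts[[c for c in cm.counts.columns if c.startswith("WT")]].to_numpy().mean()
        mut = xut_counts[[c for c in cm.counts.columns if c.startswith("mut")]].to_numpy().mean()
        assert abs(wt - mut) / wt < 0.1

    def test_seed_determinism_of_counts(self):
        cfg = SimulationConfig(seed=9, genes_per_class=(5, 5, 5, 5))
        ann = simulate_annotation(cfg)
        a, _ = simulate_netseq_counts(cfg, ann[0], ann[1], ann[2], make_coverage=False)
        b, _ = simulate_netseq_counts(cfg, ann[0], ann[1], ann[2], make_coverage=False)
        assert a.counts.equals(b.counts)

    def test_coverage_totals_match_counts(self):
        cfg = SimulationConfig(seed=10, genes_per_class=(4, 4, 4, 4))
        genes, xuts, truth = simulate_annotation(cfg)
        cm, covs = simulate_netseq_counts(cfg, genes, xuts, truth, make_coverage=True)
        for sample, cov in covs.items():
            assert cov.total() == cm.counts[sample].sum() == cov.library_size


class TestRnaSeqModality:
    def test_stabilization_fold_one_matches_nascent_statistics(self):
        cfg = SimulationConfig(
            seed=11, genes_per_class=(30, 0, 30, 0), xut_stabilization_fold=1.0 + 1e-12
        )
        genes, xuts, truth = simulate_annotation(cfg)
        net, _ = simulate_netseq_counts(cfg, genes, xuts, truth, make_coverage=False)
        rna, _ = simulate_rnaseq_counts(cfg, genes, xuts, truth, make_coverage=False)
        x_net = net.counts.loc[truth.xuts.index].to_numpy().mean()
        x_rna = rna.counts.loc[truth.xuts.index].to_numpy().mean()
        assert abs(x_net - x_rna) / x_net < 0.1

    def test_fourfold_stabilization_shifts_xut_density_only(self):
        cfg = SimulationConfig(
            seed=12, genes_per_class=(8, 0, 8, 8), xut_stabilization_fold=4.0
        )
        genes, xuts, truth = simulate_annotation(cfg)
        _, covs = simulate_rnaseq_counts(cfg, genes, xuts, truth, make_coverage=True)
        wt = covs["WT_1"]
        mut = covs["mut_1"]
        d_xut = ratio_density(mut, wt, xuts, "XUT", pseudocount=0.01)
        unchanged = [
            g for g in genes
            if int(truth.genes.loc[g.id, "class_label"]) in (3, 4)
        ]
        d_mrna = ratio_density(mut, wt, unchanged, "mRNA", pseudocount=0.01)
        mult = cfg.multipliers()  # remove depth difference between samples
        depth = np.log2(mult[2] / mult[0])
        assert np.median(d_xut.ratios) - depth == pytest.approx(2.0, abs=0.4)
        assert np.median(d_mrna.ratios) - depth == pytest.approx(0.0, abs=0.4)


class TestChip:
    def _setup(self, **kw):
        cfg = SimulationConfig(seed=13, genes_per_class=(20, 20, 20, 20), **kw)
        genes, xuts, truth = simulate_annotation(cfg)
        return cfg, genes, truth

    def test_unit_enhancement_gives_flat_zero_ratio(self):
        cfg, genes, truth = self._setup(
            h4ac_enhancement_wt=(1.0, 1.0, 1.0, 1.0),
            h4ac_enhancement_mut=(1.0, 1.0, 1.0, 1.0),
        )
        chip = simulate_chip(cfg, genes, truth)
        prof = chip_ratio_metagene(
            chip["WT"]["h4ac"], chip["WT"]["h3"], genes, window=500, pseudocount=1.0
        )
        assert np.abs(prof.mean).max() < 3 * np.nanmax(prof.ci_halfwidth)

    def test_class1_acetylation_peak_at_tss(self):
        cfg, genes, truth = self._setup()
        chip = simulate_chip(cfg, genes, truth)
        c1 = [g for g in genes if truth.genes.loc[g.id, "class_label"] == 1]
        prof = chip_ratio_metagene(
            chip["WT"]["h4ac"], chip["WT"]["h3"], c1, window=800, pseudocount=0.5
        )
        peak_pos = prof.positions[np.nanargmax(prof.mean)]
        assert abs(peak_pos) <= 100

    def test_zero_ndr_depth_gives_flat_h3(self):
        cfg, genes, truth = self._setup(ndr_depth=(0.0, 0.0, 0.0, 0.0))
        chip = simulate_chip(cfg, genes, truth)
        prof = metagene_profile(chip["WT"]["h3"], genes, window=500, pseudocount=1.0)
        # flat within noise: spread across positions far below the NDR signal
        assert prof.mean.max() - prof.mean.min() < 0.2

    def test_default_ndr_is_deepest_for_class1(self):
        cfg, genes, truth = self._setup()
        chip = simulate_chip(cfg, genes, truth)
        dips = {}
        for label in (1, 4):
            sub = [g for g in genes if truth.genes.loc[g.id, "class_label"] == label]
            prof = metagene_profile(chip["WT"]["h3"], sub, window=500, pseudocount=1.0)
            dips[label] = prof.mean[500]  # value at the TSS
        assert dips[1] < dips[4]


def test_bed_reads_rebuild_point_coverage(tmp_path):
    cfg = SimulationConfig(seed=14, genes_per_class=(3, 3, 3, 3))
    genes, xuts, truth = simulate_annotation(cfg)
    _, covs = simulate_netseq_counts(cfg, genes, xuts, truth, make_coverage=True)
    cov = covs["WT_1"]
    bed = tmp_path / "wt1.bed"
    n = coverage_to_bed_reads(cov, bed)
    rebuilt = coverage_from_alignments(
        read_bed_alignments(bed), cov.chrom_sizes(), "point_3prime"
    )
    assert rebuilt.library_size == n == cov.library_size
    for chrom in cov.plus:
        np.testing.assert_array_equal(rebuilt.plus[chrom], cov.plus[chrom])
        np.testing.assert_array_equal(rebuilt.minus[chrom], cov.minus[chrom])
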