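import io

import numpy as np
import pytest

from estsnp.io_formats import (
    CALL_AB,
    CALL_BB,
    write_contig_alignment,
    write_genotype_matrix,
)
from estsnp.synthetic_data import (
    CODON_TABLE,
    SimConfig,
    _draw_depths,
    simulate_coding_snps,
    simulate_est_alignments,
    simulate_gene_set,
    simulate_genotype_panel,
)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(n_loci=17, seed=3, dup_fraction=0.25)
        p = tmp_path / "c.yaml"
        cfg.to_yaml(p)
        assert SimConfig.from_yaml(p) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_loci": 0},
            {"dup_fraction": 1.5},
            {"depth_min": 0},
            {"mean_depth": 500.0},
            {"populations": (("X", 1.0),), "diploids_per_pop": (5,)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()


class TestGeneSet:
    def test_no_duplication_means_no_psv_or_msv(self):
        truth = simulate_gene_set(SimConfig(n_loci=150, dup_fraction=0.0, seed=1))
        classes = {s.klass for s in truth.all_sites()}
        assert "psv" not in classes and "msv" not in classes

    def test_zero_fst_pins_population_frequencies_to_ancestral(self):
        cfg = SimConfig(
            n_loci=100,
            seed=2,
            populations=(("P1", 0.0), ("P2", 0.0)),
            diploids_per_pop=(10, 10),
            dh_fst=0.0,
        )
        truth = simulate_gene_set(cfg)
        for s in truth.assayed_sites():
            if s.klass in ("true_snp", "msv"):
                assert all(q == s.ancestral_q for q in s.pop_q.values())

    def test_duplicated_fraction_within_binomial_noise(self):
        n = 2000
        truth = simulate_gene_set(SimConfig(n_loci=n, seed=4))
        k = sum(locus.duplicated for locus in truth.loci)
        sd = np.sqrt(n * 0.5 * 0.5)
        assert abs(k - 0.5 * n) <= 3 * sd

    def test_dh_doses_always_homozygous(self, small_truth):
        dh = small_truth.manifest.is_dh()
        for dose in small_truth.doses.values():
            assert set(np.unique(dose[dh])) <= {0, 2}

    def test_every_assayed_site_has_one_class(self, small_truth):
        for s in small_truth.assayed_sites():
            assert s.klass in ("true_snp", "pseudo_snp", "psv", "msv")
        ids = [s.snp_id for s in small_truth.assayed_sites()]
        assert len(ids) == len(set(ids))


class TestEstAlignments:
    def test_clean_config_reproduces_consensus_exactly(self):
        cfg = SimConfig(
            n_loci=20,
            seed=5,
            dup_fraction=0.0,
            true_snp_rate=0.0,
            per_base_error_rate=0.0,
        )
        truth = simulate_gene_set(cfg)
        alignments, _ = simulate_est_alignments(truth)
        for aln in alignments:
            assert all(seq == aln.consensus for _, seq in aln.reads)

    def test_coassembled_psv_site_splits_reads_evenly(self):
        cfg = SimConfig(
            n_loci=60,
            seed=6,
            dup_fraction=1.0,
            co_assembly_prob=1.0,
            per_base_error_rate=0.0,
            true_snp_rate=0.0,
            pseudo_snp_rate=0.0,
            msv_fraction=0.0,
        )
        truth = simulate_gene_set(cfg)
        alignments, _ = simulate_est_alignments(truth)
        by_id = {a.contig_id: a for a in alignments}
        fracs = []
        for locus in truth.loci:
            aln = by_id[locus.locus_id]
            for s in locus.sites:
                if not s.assayed:
                    continue
                bases = [seq[s.pos] for _, seq in aln.reads]
                n_b = bases.count(s.allele_b)
                assert bases.count(s.allele_a) + n_b == len(bases)
                fracs.append(n_b / len(bases))
        assert abs(np.mean(fracs) - 0.5) < 0.05  # binomial half-half split

    def test_depth_distribution_matches_target(self):
        cfg = SimConfig(seed=7)
        rng = np.random.default_rng(0)
        depths = _draw_depths(5000, cfg, rng)
        assert depths.min() >= 7 and depths.max() <= 466
        assert abs(depths.mean() - 12.7) < 0.5

    def test_site_label_table_covers_all_sites(self, small_truth, small_alignments):
        _, labels = small_alignments
        assert len(labels) == len(small_truth.all_sites())
        assert set(labels["class"]) <= {"true_snp", "pseudo_snp", "psv", "msv"}

    def test_unplanned_site_defaults_to_pseudo(self, small_truth):
        assert small_truth.site_class("CTG001", 99999) == "pseudo_snp"


class TestGenotypePanel:
    def test_psv_sites_are_all_heterozygous_pre_noise(self):
        cfg = SimConfig(
            n_loci=80, seed=8, genotype_error=0.0, assay_fail_rate=0.0
        )
        truth = simulate_gene_set(cfg)
        matrix, _, table = simulate_genotype_panel(truth)
        psv_rows = np.flatnonzero((table["class"] == "psv").to_numpy())
        assert (matrix.calls[psv_rows] == CALL_AB).all()

    def test_monomorphic_truth_for_pseudo_sites(self):
        cfg = SimConfig(
            n_loci=80, seed=9, genotype_error=0.0, assay_fail_rate=0.0
        )
        truth = simulate_gene_set(cfg)
        matrix, _, table = simulate_genotype_panel(truth)
        rows = np.flatnonzero((table["class"] == "pseudo_snp").to_numpy())
        assert (matrix.calls[rows] == 0).all()

    def test_msv_assay_map_enumeration(self):
        """MSV assay: dose 0 on the segregating paralog -> AA, else AB; BB
        never occurs, and DH samples split AA/AB by the DH-group frequency."""
        cfg = SimConfig(
            n_loci=400, seed=10, genotype_error=0.0, assay_fail_rate=0.0
        )
        truth = simulate_gene_set(cfg)
        matrix, manifest, table = simulate_genotype_panel(truth)
        rows = np.flatnonzero((table["class"] == "msv").to_numpy())
        assert len(rows) > 0
        assert not (matrix.calls[rows] == CALL_BB).any()
        dh = manifest.is_dh()
        for i in rows:
            dose = truth.doses[matrix.snp_ids[i]]
            expected = np.where(dose == 0, 0, 1)
            assert (matrix.calls[i] == expected).all()
            aa_frac_dh = (matrix.calls[i][dh] == 0).mean()
            q_dh = table["q_DH"].iloc[i]
            # DH homozygous draw: P(AA) = 1 - q
            assert abs(aa_frac_dh - (1 - q_dh)) < 4 * np.sqrt(0.25 / dh.sum())

    def test_seed_determinism_is_byte_identical(self):
        outputs = []
        for _ in range(2):
            cfg = SimConfig(n_loci=40, seed=11)
            truth = simulate_gene_set(cfg)
            alignments, labels = simulate_est_alignments(truth)
            matrix, manifest, table = simulate_genotype_panel(truth)
            buf_m, buf_a = io.StringIO(), io.StringIO()
            write_genotype_matrix(matrix, buf_m)
            for aln in alignments:
                write_contig_alignment(aln, buf_a)
            outputs.append(
                (buf_m.getvalue(), buf_a.getvalue(), table.to_csv(), labels.to_csv())
            )
        assert outputs[0] == outputs[1]

    def test_different_seeds_differ(self):
        a = simulate_gene_set(SimConfig(n_loci=40, seed=1))
        b = simulate_gene_set(SimConfig(n_loci=40, seed=2))
        assert [s.snp_id for s in a.assayed_sites()] != [
            s.snp_id for s in b.assayed_sites()
        ]


class TestCodingSnps:
    def test_truth_labels_match_codon_table(self):
        for case in simulate_coding_snps(30, seed=12):
            assert case.effect == (
                "synonymous" if case.ref_aa == case.alt_aa else "nonsynonymous"
            )

    def test_window_translates_to_expected_peptide(self):
        for case in simulate_coding_snps(10, seed=13):
            lo, hi = case.contig_hit.window()
            window = case.contig_seq[lo:hi]
            if case.contig_hit.frame < 0:
                window = window.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            pep = "".join(
                CODON_TABLE[window[k : k + 3]] for k in range(0, len(window), 3)
            )
            assert "*" not in pep  # CDS built from sense codons
            assert len(pep) == case.contig_hit.aln_len
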