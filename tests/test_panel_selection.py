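import numpy as np
import pytest

from estsnp.panel_selection import (
    PanelConfig,
    design_score_filter,
    flank_length_filter,
    genomic_contiguity_filter,
    proxy_design_score,
    select_panel,
    similarity_filter,
    spacing_filter,
)
from estsnp.popgen_stats import freq_stats
from estsnp.snp_discovery import SnpCandidate


def _cand(contig: str, pos: int, major="A", minor="G") -> SnpCandidate:
    return SnpCandidate(
        contig_id=contig,
        position=pos,
        major_base=major,
        minor_base=minor,
        base_counts={major: 5, minor: 5},
        depth=10,
        left_flank="ACGT",
        right_flank="ACGT",
        stats=freq_stats(0.5),
    )


def _random_contig(rng, length=600) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


class TestSpacing:
    def test_gap_59_removes_both(self):
        kept = spacing_filter([_cand("c", 100), _cand("c", 159)])
        assert kept == set()

    def test_gap_60_keeps_both(self):
        kept = spacing_filter([_cand("c", 100), _cand("c", 160)])
        assert kept == {("c", 100), ("c", 160)}

    def test_different_contigs_do_not_interact(self):
        kept = spacing_filter([_cand("c1", 100), _cand("c2", 101)])
        assert len(kept) == 2

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(0)
        positions = sorted(rng.choice(2000, size=50, replace=False).tolist())
        cands = [_cand("c", p) for p in positions]
        kept = spacing_filter(cands)
        expected = {
            ("c", p)
            for p in positions
            if all(q == p or abs(q - p) >= 60 for q in positions)
        }
        assert kept == expected

    def test_keep_better_retains_one_of_pair(self):
        cands = [_cand("c", 100), _cand("c", 130)]
        scores = {100: 0.9, 130: 0.5}
        kept = spacing_filter(
            cands, keep_better=True, scorer=lambda c: scores[c.position]
        )
        assert kept == {("c", 100)}


class TestFlankLength:
    def test_pos_99_on_300nt_removed(self):
        kept = flank_length_filter([_cand("c", 99)], {"c": 300})
        assert kept == set()

    def test_pos_100_on_300nt_kept(self):
        kept = flank_length_filter([_cand("c", 100)], {"c": 300})
        assert kept == {("c", 100)}

    def test_right_edge(self):
        assert flank_length_filter([_cand("c", 199)], {"c": 300})
        assert not flank_length_filter([_cand("c", 200)], {"c": 300})

    def test_closed_form_interval_on_random_positions(self):
        rng = np.random.default_rng(1)
        length = 500
        cands = [_cand("c", int(p)) for p in rng.choice(length, 80, replace=False)]
        kept = flank_length_filter(cands, {"c": length})
        assert kept == {
            ("c", c.position) for c in cands if 100 <= c.position <= length - 101
        }


class TestGenomicContiguity:
    def test_verbatim_flank_kept(self):
        rng = np.random.default_rng(2)
        contig = _random_contig(rng)
        c = _cand("c", 300, major=contig[300])
        kept, warning = genomic_contiguity_filter(
            [c], {"c": contig}, {"chr1": "TTTT" + contig + "GGGG"}
        )
        assert kept == {("c", 300)} and warning is None

    def test_reverse_strand_match_kept(self):
        rng = np.random.default_rng(3)
        contig = _random_contig(rng)
        c = _cand("c", 300, major=contig[300])
        rc = contig.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        kept, _ = genomic_contiguity_filter([c], {"c": contig}, {"chr1": rc})
        assert kept == {("c", 300)}

    def test_intron_inserted_mid_flank_removed(self):
        rng = np.random.default_rng(4)
        contig = _random_contig(rng)
        c = _cand("c", 300, major=contig[300])
        intron = _random_contig(rng, 80)
        genomic = contig[:260] + intron + contig[260:]  # junction 40 nt left of site
        kept, _ = genomic_contiguity_filter([c], {"c": contig}, {"chr1": genomic})
        assert kept == set()

    def test_missing_reference_skips_with_warning(self):
        c = _cand("c", 300)
        with pytest.warns(UserWarning, match="skipped"):
            kept, warning = genomic_contiguity_filter(
                [c], {"c": "A" * 600}, None
            )
        assert kept == {("c", 300)} and "skipped" in warning

    def test_simulated_junction_truth_recovered(self, small_alignments):
        """Insert introns into half the simulated contigs; the filter must
        remove exactly the candidates whose window spans a junction."""
        alignments, _ = small_alignments
        rng = np.random.default_rng(5)
        contigs = {a.contig_id: a.consensus for a in alignments[:40]}
        cands = []
        for cid, seq in contigs.items():
            pos = int(rng.integers(110, len(seq) - 110))
            cands.append(_cand(cid, pos, major=seq[pos]))
        genomic = {}
        expected_removed = set()
        for i, c in enumerate(cands):
            seq = contigs[c.contig_id]
            if i % 2 == 0:
                cut = c.position - int(rng.integers(5, 95))  # inside left flank
                genomic[c.contig_id] = (
                    seq[:cut] + _random_contig(rng, 80) + seq[cut:]
                )
                expected_removed.add((c.contig_id, c.position))
            else:
                genomic[c.contig_id] = seq
        kept, _ = genomic_contiguity_filter(cands, contigs, genomic)
        removed = {(c.contig_id, c.position) for c in cands} - kept
        assert removed == expected_removed


class TestDesignScore:
    def test_clean_flank_scores_one(self):
        contig = ("ACGT" * 200)[:600]  # 50% GC, no homopolymer
        c = _cand("c", 300, major=contig[300])
        score = proxy_design_score(c, contig, {"c": [300]})
        assert score == 1.0

    def test_homopolymer_penalty(self):
        rng = np.random.default_rng(6)
        contig = _random_contig(rng)
        contig = contig[:310] + "AAAAAAA" + contig[317:]
        # keep GC of the +/-100 window inside [0.30, 0.70]
        c = _cand("c", 300, major=contig[300])
        score = proxy_design_score(c, contig, {"c": [300]})
        gc_window = contig[200:300] + contig[301:401]
        gc = (gc_window.count("G") + gc_window.count("C")) / 200
        expected = 0.7 if 0.30 <= gc <= 0.70 else 0.4
        assert score == pytest.approx(expected)

    def test_homopolymer_plus_bad_gc_fails_threshold(self):
        contig = "A" * 600  # GC 0 and homopolymer everywhere
        c = _cand("c", 300)
        score = proxy_design_score(c, contig, {"c": [300]})
        assert score == pytest.approx(0.4)
        assert design_score_filter([c], lambda _: score) == set()

    def test_constant_low_scorer_removes_all(self):
        cands = [_cand("c", p) for p in (100, 300, 500)]
        assert design_score_filter(cands, lambda _: 0.59) == set()

    def test_scorer_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            design_score_filter([_cand("c", 100)], lambda _: 1.2)

    def test_nearby_candidate_penalty(self):
        contig = ("ACGT" * 200)[:600]
        c = _cand("c", 300, major=contig[300])
        score = proxy_design_score(c, contig, {"c": [300, 350]})
        assert score == pytest.approx(0.8)


class TestSimilarity:
    def test_shared_kmer_across_contigs_removes_both(self):
        rng = np.random.default_rng(7)
        shared = _random_contig(rng, 40)
        c1 = _random_contig(rng, 280) + shared + _random_contig(rng, 280)
        c2 = _random_contig(rng, 280) + shared + _random_contig(rng, 280)
        cands = [
            _cand("c1", 300, major=c1[300]),
            _cand("c2", 300, major=c2[300]),
        ]
        kept = similarity_filter(cands, {"c1": c1, "c2": c2})
        assert kept == set()

    def test_same_contig_overlap_is_ignored(self):
        rng = np.random.default_rng(8)
        contig = _random_contig(rng)
        cands = [
            _cand("c", 250, major=contig[250]),
            _cand("c", 350, major=contig[350]),
        ]
        kept = similarity_filter(cands, {"c": contig})
        assert kept == {("c", 250), ("c", 350)}


class TestSelectPanel:
    def _setup(self):
        rng = np.random.default_rng(9)
        contigs = {f"c{i}": _random_contig(rng) for i in range(6)}
        cands = [
            _cand(cid, pos, major=contigs[cid][pos])
            for cid in contigs
            for pos in (150, 400)
        ]
        return contigs, cands

    def test_spacing_only_failure_recorded(self):
        contigs, _ = self._setup()
        cands = [
            _cand("c0", 150, major=contigs["c0"][150]),
            _cand("c0", 180, major=contigs["c0"][180]),
        ]
        report = select_panel(cands, contigs, reference=contigs)
        for failed in report.failed_filters:
            assert "spacing" in failed

    def test_all_pass_is_kept(self):
        contigs, cands = self._setup()
        report = select_panel(cands, contigs, reference=contigs)
        clean = [f for f in report.failed_filters if not f]
        assert len(clean) == len(report.kept) > 0

    def test_report_partitions_input(self):
        contigs, cands = self._setup()
        report = select_panel(cands, contigs, reference=contigs)
        n_failed = sum(1 for f in report.failed_filters if f)
        assert n_failed + len(report.kept) == len(cands)

    def test_kept_equals_intersection_of_predicates(self):
        """Filters are pure predicates on the pre-filter set, so the
        survivors equal the intersection of per-filter kept sets in any
        order of application."""
        contigs, cands = self._setup()
        report = select_panel(cands, contigs, reference=contigs)
        lengths = {cid: len(s) for cid, s in contigs.items()}
        per_filter = [
            spacing_filter(cands),
            flank_length_filter(cands, lengths),
            genomic_contiguity_filter(cands, contigs, contigs)[0],
            similarity_filter(cands, contigs),
        ]
        neighbour = {}
        for c in cands:
            neighbour.setdefault(c.contig_id, []).append(c.position)
        per_filter.append(
            design_score_filter(
                cands,
                lambda c: proxy_design_score(c, contigs[c.contig_id], neighbour),
            )
        )
        expected = set.intersection(*per_filter)
        assert {(c.contig_id, c.position) for c in report.kept} == expected

    def test_panel_cap_keeps_best_scoring(self):
        contigs, cands = self._setup()
        report = select_panel(
            cands,
            contigs,
            reference=contigs,
            config=PanelConfig(max_panel_size=3),
        )
        assert len(report.kept) <= 3
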