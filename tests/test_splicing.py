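import math
from itertools import combinations

import numpy as np
import pytest

from longiso.io_formats import ModelValidationError, SampleTranscriptome
from longiso.splicing import (
    ASCountTable,
    EVENT_TYPE_ORDER,
    compare_as_profiles,
    count_events,
    detect_all_events,
    detect_events,
    diversity_score,
    diversity_scores,
    group_by_gene,
    score_d,
    top_spliced_genes,
)
from longiso.fixtures import EVENT_TYPES, FixtureSpec, generate_genes
from conftest import mk_transcript, mirror_transcript
from _oracles import brute_force_event_ids

import pandas as pd


class TestGrouping:
    def test_partition_by_gene(self):
        ts = [mk_transcript(f"T{i}", [(100 * i + 10, 100 * i + 50)], gene="G1")
              for i in range(3)]
        ts += [mk_transcript(f"U{i}", [(10_000 + 100 * i, 10_000 + 100 * i + 50)],
                             gene="G2") for i in range(2)]
        groups = group_by_gene(ts)
        assert [(g.gene_id, len(g.transcripts)) for g in groups] == [("G1", 3), ("G2", 2)]

    def test_single_transcript_gene_flagged_event_free(self):
        (g,) = group_by_gene([mk_transcript("T", [(0, 10)])])
        assert g.event_free and detect_events(g) == []

    def test_mixed_strand_gene_rejected(self):
        ts = [mk_transcript("T1", [(0, 10)], "+", gene="G"),
              mk_transcript("T2", [(100, 110)], "-", gene="G")]
        with pytest.raises(ModelValidationError, match="G"):
            group_by_gene(ts)


class TestDetectEvents:
    def test_forced_se(self, simple_se_gene):
        (g,) = group_by_gene(simple_se_gene)
        (ev,) = detect_events(g)
        assert ev.event_type == "SE"
        assert ev.coordinates == (200, 300, 400, 500)
        assert ev.inclusion_transcripts == {"T1"}
        assert ev.exclusion_transcripts == {"T2"}

    def test_forced_ri(self):
        t1 = mk_transcript("T1", [(100, 400)])
        t2 = mk_transcript("T2", [(100, 200), (300, 400)])
        (g,) = group_by_gene([t1, t2])
        (ev,) = detect_events(g)
        assert ev.event_type == "RI"
        assert ev.coordinates == (100, 200, 300, 400)
        assert ev.inclusion_transcripts == {"T1"}  # retains the intron

    def test_a5_on_plus_becomes_a3_on_minus(self):
        def pair(strand):
            t1 = mk_transcript("T1", [(100, 200), (500, 600)], strand)
            t2 = mk_transcript("T2", [(100, 250), (500, 600)], strand)
            (g,) = group_by_gene([t1, t2])
            return detect_events(g)

        (plus,) = pair("+")
        (minus,) = pair("-")
        assert plus.event_type == "A5" and plus.coordinates == (200, 250, 500)
        assert minus.event_type == "A3" and minus.coordinates == (200, 250, 500)
        assert plus.inclusion_transcripts == {"T2"}  # longer exonic form

    def test_af_requires_nonoverlapping_first_exons(self):
        t1 = mk_transcript("T1", [(100, 200), (500, 600)])
        t2 = mk_transcript("T2", [(300, 400), (500, 600)])
        (g,) = group_by_gene([t1, t2])
        (ev,) = detect_events(g)
        assert ev.event_type == "AF"
        assert ev.coordinates == (100, 200, 300, 400, 500)

    def test_duplicate_structures_do_not_duplicate_events(self, simple_se_gene):
        t3 = mk_transcript("T3", [(100, 200), (500, 600)])  # same chain as T2
        (g,) = group_by_gene(simple_se_gene + [t3])
        (ev,) = detect_events(g)
        assert ev.exclusion_transcripts == {"T2", "T3"}

    def test_order_invariance(self):
        spec = FixtureSpec(seed=5, n_genes=14)
        ts, _ = generate_genes(spec)
        base = {e.event_id for e in detect_all_events(ts)}
        rng = np.random.default_rng(0)
        perm = list(ts)
        rng.shuffle(perm)
        assert {e.event_id for e in detect_all_events(perm)} == base

    def test_mirror_maps_a5_a3_and_af_al(self):
        """Mirroring coordinates with the strand kept swaps A5<->A3 and AF<->AL."""
        spec = FixtureSpec(seed=9, n_genes=21)
        ts, truth = generate_genes(spec)
        swap = {"A5": "A3", "A3": "A5", "AF": "AL", "AL": "AF",
                "SE": "SE", "RI": "RI", "MX": "MX"}
        mirrored = [mirror_transcript(t, flip_strand=False) for t in ts]
        base_types = sorted(e.event_type for e in detect_all_events(ts))
        mirror_types = sorted(e.event_type for e in detect_all_events(mirrored))
        assert mirror_types == sorted(swap[t] for t in base_types)

    def test_reverse_complement_fixes_all_types(self):
        spec = FixtureSpec(seed=9, n_genes=21)
        ts, _ = generate_genes(spec)
        rc = [mirror_transcript(t, flip_strand=True) for t in ts]
        assert sorted(e.event_type for e in detect_all_events(rc)) == \
            sorted(e.event_type for e in detect_all_events(ts))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_fixture_genes(self, seed):
        spec = FixtureSpec(seed=seed, n_genes=21)
        ts, _ = generate_genes(spec)
        for g in group_by_gene(ts):
            assert {e.event_id for e in detect_events(g)} == brute_force_event_ids(g)


class TestCountTable:
    def test_single_isoform_genes_give_zero_row(self):
        ts = [mk_transcript(f"T{i}", [(1000 * i, 1000 * i + 100)], gene=f"G{i}")
              for i in range(4)]
        table = count_events([SampleTranscriptome("s", ts)])
        assert table.counts.loc["s"].sum() == 0

    def test_fixture_counts_match_truth(self):
        spec = FixtureSpec(seed=2, n_genes=14)
        ts, truth = generate_genes(spec)
        table = count_events([SampleTranscriptome("s", ts)])
        expected = truth.event_type.value_counts()
        for etype in EVENT_TYPE_ORDER:
            assert table.counts.loc["s", etype] == expected.get(etype, 0)


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        counts = pd.DataFrame([[10] * 7, [10] * 7], index=["a", "b"],
                              columns=list(EVENT_TYPE_ORDER))
        chi2, dof, p = compare_as_profiles(ASCountTable(["a", "b"], counts))
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        counts = pd.DataFrame([[10, 20], [20, 10]], index=["a", "b"], columns=["SE", "RI"])
        chi2, dof, p = compare_as_profiles(ASCountTable(["a", "b"], counts))
        assert chi2 == pytest.approx(20 / 3)  # margins give E=15 in every cell
        assert dof == 1

    def test_zero_columns_dropped(self):
        counts = pd.DataFrame([[10, 20, 0], [20, 10, 0]], index=["a", "b"],
                              columns=["SE", "RI", "MX"])
        chi2, dof, p = compare_as_profiles(ASCountTable(["a", "b"], counts))
        assert chi2 == pytest.approx(20 / 3) and dof == 1

    def test_skewed_sample_detected(self):
        counts = pd.DataFrame([[30, 30, 30], [30, 30, 30], [80, 10, 10]],
                              index=["a", "b", "c"], columns=["SE", "RI", "MX"])
        _, _, p = compare_as_profiles(ASCountTable(["a", "b", "c"], counts))
        assert p < 0.05

    def test_degenerate_tables_rejected(self):
        counts = pd.DataFrame([[5, 5]], index=["a"], columns=["SE", "RI"])
        with pytest.raises(ValueError, match="degenerate"):
            compare_as_profiles(ASCountTable(["a"], counts))
        counts = pd.DataFrame([[5, 0], [3, 0]], index=["a", "b"], columns=["SE", "RI"])
        with pytest.raises(ValueError, match="degenerate"):
            compare_as_profiles(ASCountTable(["a", "b"], counts))


class TestDiversity:
    def _gene(self, supports):
        ts = [mk_transcript(f"T{i}", [(100 + 1000 * i, 600 + 1000 * i)], gene="G",
                            support=s) for i, s in enumerate(supports)]
        (g,) = group_by_gene(ts)
        return g

    @pytest.mark.parametrize(
        "supports,expected",
        [((7,), 0.0), ((5, 5), 1.0), ((3, 1), 0.8112781244591328), ((4, 4, 4), math.log2(3))],
    )
    def test_entropy_values(self, supports, expected):
        rec = diversity_score(self._gene(supports))
        assert rec.score == pytest.approx(expected)

    def test_zero_support_isoforms_excluded(self):
        rec = diversity_score(self._gene((5, 5, 0)))
        assert rec.score == pytest.approx(1.0) and rec.n_isoforms == 2

    def test_all_zero_supports_rejected(self):
        with pytest.raises(ValueError, match="no expressed"):
            diversity_score(self._gene((0, 0)))

    @pytest.mark.parametrize("seed", range(3))
    def test_entropy_bounds(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            supports = tuple(int(x) for x in rng.integers(1, 40, size=rng.integers(1, 6)))
            rec = diversity_score(self._gene(supports))
            assert 0 <= rec.score <= math.log2(len(supports)) + 1e-12
            if len(supports) == 1:
                assert rec.score == 0


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.integers(min_value=1, max_value=200), min_size=1, max_size=8))
def test_entropy_bounds_hold_for_any_supports(supports):
    """0 <= H <= log2(n), 0 iff one isoform, log2(n) iff uniform."""
    ts = [mk_transcript(f"T{i}", [(100 + 1000 * i, 600 + 1000 * i)], gene="G",
                        support=s) for i, s in enumerate(supports)]
    (g,) = group_by_gene(ts)
    rec = diversity_score(g)
    n = len(supports)
    assert -1e-12 <= rec.score <= math.log2(n) + 1e-9
    if n == 1:
        assert rec.score == 0.0
    if len(set(supports)) == 1:
        assert rec.score == pytest.approx(math.log2(n))


class TestScoreD:
    def _scores(self, mapping, sample):
        ts = []
        for gid, supports in mapping.items():
            base = abs(hash(gid)) % 1000 * 10_000
            ts.extend(
                mk_transcript(f"{gid}.{i}.{sample}", [(base + 1000 * i, base + 1000 * i + 200)],
                              gene=gid, support=s)
                for i, s in enumerate(supports)
            )
        return diversity_scores(SampleTranscriptome(sample, ts))

    def test_identical_scores_give_zero_d(self):
        a = self._scores({"G1": (5, 5)}, "a")
        b = self._scores({"G1": (2, 2)}, "b")
        (rec,) = score_d(a, b)
        assert rec.D == pytest.approx(0.0)

    def test_uniform_three_vs_single(self):
        a = self._scores({"G1": (4, 4, 4)}, "a")
        b = self._scores({"G1": (9,)}, "b")
        (rec,) = score_d(a, b)
        assert rec.D == pytest.approx(math.log2(3))

    def test_missing_gene_scored_zero_and_flagged(self):
        a = self._scores({"G1": (5, 5)}, "a")
        recs = score_d(a, {})
        assert recs[0].score_b == 0 and recs[0].one_sample_only

    def test_descending_order_with_gene_id_ties(self):
        a = self._scores({"G1": (5, 5), "G2": (9,), "G3": (4, 4, 4)}, "a")
        b = self._scores({"G1": (9,), "G2": (9,), "G3": (9,)}, "b")
        recs = score_d(a, b)
        assert [r.gene_id for r in recs] == ["G3", "G1", "G2"]
        assert [r.D for r in recs] == sorted([r.D for r in recs], reverse=True)

    def test_top_spliced_genes_by_k_and_threshold(self):
        a = self._scores({"G1": (5, 5), "G2": (9,), "G3": (4, 4, 4)}, "a")
        b = self._scores({"G1": (9,), "G2": (9,), "G3": (9,)}, "b")
        recs = score_d(a, b)
        assert top_spliced_genes(recs, k=2) == ["G3", "G1"]
        max_d = max(r.D for r in recs)
        assert top_spliced_genes(recs, threshold=max_d) == ["G3"]
        assert top_spliced_genes(recs, threshold=0.0) == ["G3", "G1", "G2"]
        with pytest.raises(ValueError):
            top_spliced_genes(recs, k=0)
        with pytest.raises(ValueError):
            top_spliced_genes(recs)
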