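import numpy as np
import pytest

import consbin as cb
from consbin.core import ScoringParams
from consbin.selection import dereplicate_select, select_next
from consbin.scoring import score_bin

from _oracle import brute_force_select, random_instance


def _mkbin(uid, contigs, lengths):
    b = cb.CandidateBin(uid, uid.split(".")[0], set(contigs))
    b.refresh(lengths)
    return b


def _score_stub(score):
    from consbin.scg import SCGCounts
    from consbin.scoring import BinScore
    return BinScore(score=score, domain="bacteria",
                    counts=SCGCounts("bacteria", 0, 0, 0), sub_scores={})


class TestSelectNext:
    def test_max_score_wins(self):
        lengths = {"a": 10, "b": 10}
        pool = [(_mkbin("x.A", ["a"], lengths), _score_stub(0.9)),
                (_mkbin("x.B", ["b"], lengths), _score_stub(0.7))]
        assert select_next(pool) == "x.A"

    def test_score_tie_broken_by_n50(self):
        lengths = {"a1": 30, "a2": 10, "b1": 20, "b2": 20}
        pool = [(_mkbin("x.A", ["a1", "a2"], lengths), _score_stub(0.5)),
                (_mkbin("x.B", ["b1", "b2"], lengths), _score_stub(0.5))]
        assert select_next(pool) == "x.A"  # N50 30 beats 20

    def test_score_and_n50_tie_broken_by_size(self):
        lengths = {"a1": 30, "b1": 30, "b2": 5}
        pool = [(_mkbin("x.A", ["a1"], lengths), _score_stub(0.5)),
                (_mkbin("x.B", ["b1", "b2"], lengths), _score_stub(0.5))]
        assert select_next(pool) == "x.B"  # same N50 (30), B is larger (35 > 30)

    def test_full_tie_broken_by_uid(self):
        lengths = {"a": 10, "b": 10}
        pool = [(_mkbin("x.B", ["b"], lengths), _score_stub(0.5)),
                (_mkbin("x.A", ["a"], lengths), _score_stub(0.5))]
        assert select_next(pool) == "x.A"

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            select_next([])


class TestWorkedExample:
    def test_hand_traced_loop(self, worked_example):
        lengths, bin_sets, ann, refs, params = worked_example
        cands = cb.build_candidate_set(lengths, bin_sets)
        res = dereplicate_select(cands, ann, refs, params, assembly=lengths)
        assert res.final_uids == ["X.X1"]
        assert res.final[0][1].score == 1.0
        # Y.Y1 emptied when X.X1 claimed c1-c3; Y.Y2 shrank to {c4}, rescored
        # to 1/3, extracted second but rejected (1/3 <= t)
        assert [r.extracted_uid for r in res.log] == ["X.X1", "Y.Y2"]
        assert res.log[0].emptied == ("Y.Y1",)
        assert res.log[1].score == pytest.approx(1 / 3)
        assert not res.log[1].accepted

    def test_single_perfect_candidate(self, worked_example):
        lengths, bin_sets, ann, refs, params = worked_example
        cands = cb.build_candidate_set(lengths, [bin_sets[0]])
        res = dereplicate_select(cands, ann, refs, params, assembly=lengths)
        assert res.final_uids == ["X.X1"]
        assert len(res.log) == 1

    def test_all_nonpositive_scores_stop_immediately(self, worked_example):
        lengths, bin_sets, _, refs, params = worked_example
        cands = cb.build_candidate_set(lengths, bin_sets)
        res = dereplicate_select(cands, cb.SCGAnnotation(), refs, params, assembly=lengths)
        assert res.final == []
        assert res.log == []  # zero-score bins are never extracted

    def test_threshold_one_yields_empty_final(self, worked_example):
        lengths, bin_sets, ann, refs, _ = worked_example
        cands = cb.build_candidate_set(lengths, bin_sets)
        res = dereplicate_select(cands, ann, refs, ScoringParams(0.5, 0.5, 1.0),
                                 assembly=lengths)
        assert res.final == []
        assert len(res.log) > 0  # extraction still happens


def _run_package(lengths, annotation, bins, b, c, t, release=False):
    ann = cb.SCGAnnotation()
    gene = 0
    for cid, calls in annotation.items():
        for fam, dom in calls:
            ann.add(cid, fam, dom, f"g{gene}")
            gene += 1
    refs = {
        "bacteria": cb.ReferenceSCGSet("bacteria", frozenset({"bf1", "bf2", "bf3"})),
        "archaea": cb.ReferenceSCGSet("archaea", frozenset({"af1", "af2"})),
    }
    cands = [_mkbin(uid, cs, lengths) for uid, cs in bins.items()]
    return dereplicate_select(cands, ann, refs, ScoringParams(b, c, t),
                              assembly=lengths, release_subthreshold=release)


class TestOracleEquivalence:
    def test_matches_brute_force_replay_on_random_instances(self):
        rng = np.random.default_rng(2024)
        ref_families = {"bacteria": {"bf1", "bf2", "bf3"}, "archaea": {"af1", "af2"}}
        for _ in range(150):
            lengths, annotation, bins, origins, b, c, t = random_instance(rng)
            expected = brute_force_select(bins, lengths, annotation, ref_families, b, c, t)
            got = _run_package(lengths, annotation, bins, b, c, t)
            assert [(u, frozenset(bn.contigs)) for (bn, _), (u, _) in
                    zip(got.final, expected)] == expected
            assert len(got.final) == len(expected)


class TestInvariants:
    def _random_runs(self, n):
        rng = np.random.default_rng(7)
        for _ in range(n):
            yield random_instance(rng)

    def test_disjointness_and_subset_provenance(self):
        for lengths, annotation, bins, origins, b, c, t in self._random_runs(80):
            res = _run_package(lengths, annotation, bins, b, c, t)
            seen = set()
            for bn, _ in res.final:
                assert not (seen & bn.contigs)
                seen |= bn.contigs
                assert bn.contigs <= bins[bn.uid]  # subset of its own origin bin

    def test_threshold_monotonicity(self):
        for lengths, annotation, bins, origins, b, c, _ in self._random_runs(40):
            finals = {}
            for t in (0.0, 0.3, 0.5, 0.7):
                res = _run_package(lengths, annotation, bins, b, c, t)
                finals[t] = {(bn.uid, frozenset(bn.contigs)) for bn, _ in res.final}
            assert finals[0.7] <= finals[0.5] <= finals[0.3] <= finals[0.0]

    def test_idempotence(self):
        for lengths, annotation, bins, origins, b, c, t in self._random_runs(40):
            res = _run_package(lengths, annotation, bins, b, c, t)
            again_bins = {f"final.{i}": set(bn.contigs) for i, (bn, _) in enumerate(res.final)}
            if not again_bins:
                continue
            again = _run_package(lengths, annotation, again_bins, b, c, t)
            assert {frozenset(bn.contigs) for bn, _ in again.final} == \
                   {frozenset(bn.contigs) for bn, _ in res.final}


class TestDominance:
    def test_planted_truth_bins_are_represented_at_equal_or_better_score(self, refs):
        """Every planted ground-truth bin scoring above t is either selected
        itself or overlaps a final bin whose extraction score was at least
        as high (the first claimant of any of its contigs necessarily
        outscored it at that iteration)."""
        params = ScoringParams()
        for seed in range(6):
            fx = cb.generate_benchmark(
                cb.SimConfig(seed=900 + seed, n_genomes=8, n_archaea=1,
                             genome_length_bounds=(200_000, 800_000),
                             contig_length_bounds=(5_000, 80_000)),
                n_binners=3,
            )
            planted = cb.BinSet("planted", {k: set(v) for k, v in fx.truth.bins.items()})
            cands = cb.build_candidate_set(fx.assembly, fx.binnings + [planted])
            res = dereplicate_select(cands, fx.annotation, refs, params,
                                     assembly=fx.assembly)
            final = [(bn, bs) for bn, bs in res.final]
            for truth_cand in cb.build_candidate_set(fx.assembly, [planted]):
                s = score_bin(truth_cand, fx.annotation, refs, params).score
                if s <= params.t:
                    continue
                hits = [bs.score for bn, bs in final if bn.contigs & truth_cand.contigs]
                assert hits and max(hits) >= s - 1e-12
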