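"""Joint solver: constraints, quantification, pair penalty, branch-and-bound."""

import itertools

import numpy as np
import pytest

from splicefit.graph import ObservationSet, Region, Segment, SegmentGraph
from splicefit.loss import LossModel
from splicefit.solver import (
    HyperParams,
    Quantifier,
    TranscriptSet,
    _support_pair_penalty,
    build_validity_constraints,
    pair_penalty,
    quantify_fixed,
    solve_joint,
)
from splicefit.toy import all_patterns, make_cassette_graph, pattern_to_path, simulate_samples

L2 = LossModel(kind="l2")
NB = LossModel(kind="nb", dispersion=0.1, lambda_bg=0.1)


def _obs(graph, seg_counts, intron_counts=None, pair_counts=None):
    seg_counts = np.atleast_2d(seg_counts)
    if intron_counts is None:
        intron_counts = np.zeros((seg_counts.shape[0], len(graph.edge_list)))
    return ObservationSet(
        seg_counts=seg_counts,
        intron_counts=intron_counts,
        pair_counts=pair_counts,
        seg_lengths=graph.seg_lengths,
    )


def _linear_graph(n):
    segs = [
        Segment("chr1", 100 * i, 100 * (i + 1),
                is_initial=(i == 0), is_terminal=(i == n - 1))
        for i in range(n)
    ]
    edges = {(i, i + 1): {"adjacency"} for i in range(n - 1)}
    return SegmentGraph(region=Region("chr1", 0, 100 * n), segments=segs, edges=edges)


class TestValidityConstraints:
    def test_cassette_feasible_set_by_exhaustion(self, cassette3):
        """Binary assignments satisfying the constraints are exactly the 8
        paths plus the zero row (2^7 exhaustive check against the path
        validator)."""
        vc = build_validity_constraints(cassette3)
        feasible = {
            u for u in itertools.product((0, 1), repeat=7) if vc.feasible_row(u)
        }
        valid_paths = {tuple(int(x) for x in p) for p in cassette3.enumerate_paths()}
        assert feasible == valid_paths | {(0,) * 7}

    def test_linear_chain_unique_nonzero_row(self):
        graph = _linear_graph(3)
        vc = build_validity_constraints(graph)
        feasible = [
            u for u in itertools.product((0, 1), repeat=3) if vc.feasible_row(u) and any(u)
        ]
        assert feasible == [(1, 1, 1)]

    def test_interior_segment_alone_infeasible(self):
        graph = _linear_graph(3)
        vc = build_validity_constraints(graph)
        assert not vc.feasible_row((0, 1, 0))

    def test_flagless_graph_rejected(self):
        segs = [Segment("chr1", 0, 100), Segment("chr1", 100, 200)]
        graph = SegmentGraph(region=Region("chr1", 0, 200), segments=segs,
                             edges={(0, 1): {"adjacency"}})
        with pytest.raises(ValueError, match="no initial"):
            build_validity_constraints(graph)

    def test_expand_is_block_diagonal(self, cassette3):
        vc = build_validity_constraints(cassette3, k=3)
        big_a, big_b = vc.expand()
        assert big_a.shape == (3 * vc.A.shape[0], 3 * 7)
        assert big_b.shape == (3 * len(vc.b),)


class TestQuantifyFixed:
    def test_single_transcript_constant_counts(self):
        graph = _linear_graph(4)
        tset = TranscriptSet.from_paths(graph, [np.ones(4, dtype=np.int8)])
        obs = _obs(graph, np.full((1, 4), 7.0), np.full((1, 3), 7.0))
        abund, losses = quantify_fixed(tset, obs, L2)
        # c = max count = 7, so the fitted normalized abundance is 1
        assert abund.c == 7.0
        assert abund.W[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert losses[0] == pytest.approx(0.0, abs=1e-8)

    def test_disjoint_transcripts_decouple(self):
        # two coverage islands -> two disjoint paths; the joint fit equals
        # the per-transcript individual fits
        segs = [
            Segment("chr1", 0, 100, is_initial=True, is_terminal=True),
            Segment("chr1", 500, 600, is_initial=True, is_terminal=True),
        ]
        graph = SegmentGraph(region=Region("chr1", 0, 600), segments=segs, edges={})
        rows = [np.array([1, 0], dtype=np.int8), np.array([0, 1], dtype=np.int8)]
        tset = TranscriptSet.from_paths(graph, rows)
        obs = _obs(graph, np.array([[12.0, 3.0]]))
        abund, _ = quantify_fixed(tset, obs, NB)
        single_a, _ = quantify_fixed(TranscriptSet.from_paths(graph, rows[:1]), obs, NB)
        single_b, _ = quantify_fixed(TranscriptSet.from_paths(graph, rows[1:]), obs, NB)
        assert abund.W[0, 0] == pytest.approx(single_a.W[0, 0], abs=1e-5)
        assert abund.W[1, 0] == pytest.approx(single_b.W[0, 0], abs=1e-5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_projected_gradient_oracle(self, seed):
        """The quantifier's optimum matches an independent projected
        gradient descent on the same proxy objective within 1e-4."""
        rng = np.random.default_rng(seed)
        graph = make_cassette_graph(2)
        paths = graph.enumerate_paths()
        tset = TranscriptSet.from_paths(graph, paths)
        seg_counts = rng.uniform(0, 15, size=(2, graph.n_segments))
        intron_counts = rng.uniform(0, 10, size=(2, len(graph.edge_list)))
        obs = _obs(graph, seg_counts, intron_counts)
        quantifier = Quantifier(obs, NB)
        abund, losses = quantifier.fit(tset)

        u_mat = tset.U.astype(float)
        edge_use = tset.edge_usage.astype(float)
        for r in range(2):
            w = np.full(tset.k, 0.2)
            step = 0.05
            best = quantifier.sample_loss(r, u_mat, edge_use, w)
            for _ in range(4000):
                _, grad = quantifier._sample_loss_grad(r, u_mat, edge_use, w)
                cand = np.clip(w - step * grad, 0.0, 2.0)
                val = quantifier.sample_loss(r, u_mat, edge_use, cand)
                if val <= best:
                    w, best = cand, val
                    step *= 1.05
                else:
                    step *= 0.5
                if step < 1e-12:
                    break
            assert losses[r] == pytest.approx(best, abs=1e-4)


class TestPairPenalty:
    def _tset(self, graph, rows):
        return TranscriptSet.from_paths(graph, rows)

    def test_all_pairs_covered_zero(self, cassette3):
        full = np.ones(7, dtype=np.int8)
        tset = self._tset(cassette3, [full])
        assert pair_penalty(tset, {(0, 3): 5.0, (1, 6): 2.0}) == 0.0

    def test_uncovered_pair_counts(self, cassette3):
        skip_all = pattern_to_path((0, 0, 0), 3)
        tset = self._tset(cassette3, [skip_all])
        assert pair_penalty(tset, {(1, 3): 7.0}) == 7.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_scan(self, seed, cassette3):
        rng = np.random.default_rng(seed)
        rows = [p for p in cassette3.enumerate_paths() if rng.random() < 0.5] or [
            np.ones(7, dtype=np.int8)
        ]
        tset = self._tset(cassette3, rows)
        pairs = {
            (int(a), int(b)): float(rng.integers(1, 9))
            for a, b in itertools.combinations(range(7), 2)
            if rng.random() < 0.3
        }
        expected = 0.0
        for (s1, s2), count in pairs.items():
            covered = False
            for row in rows:
                if row[s1] and row[s2]:
                    covered = True
            if not covered:
                expected += count
        assert pair_penalty(tset, pairs) == pytest.approx(expected)


def _brute_force_solve(graph, obs, loss_model, hyper, provenance=None):
    """Exhaustive oracle: minimum objective over all subsets of enumerated
    paths, each quantified by the convex fit."""
    paths = graph.enumerate_paths()
    prov = provenance or ["novel"] * len(paths)
    quantifier = Quantifier(obs, loss_model, hyper.w_intron)
    best = (np.inf, None)
    for size in range(0, min(hyper.k_max, len(paths)) + 1):
        for subset in itertools.combinations(range(len(paths)), size):
            tset = TranscriptSet.from_paths(
                graph, [paths[i] for i in subset], [prov[i] for i in subset]
            )
            _, losses = quantifier.fit(tset)
            sparsity = hyper.w_sparsity * sum(
                hyper.w_known_discount if prov[i] == "known" else 1.0 for i in subset
            )
            pair_term = hyper.w_pair * _support_pair_penalty(tset.U, obs.pair_counts)
            total = float(np.sum(losses)) + sparsity + pair_term
            if total < best[0] - 1e-12:
                best = (total, subset)
    return best


class TestSolveJoint:
    def test_noiseless_single_transcript_recovery(self):
        graph = _linear_graph(3)
        obs = _obs(graph, np.full((1, 3), 9.0), np.full((1, 2), 9.0))
        res = solve_joint(graph, obs, L2, HyperParams(w_sparsity=0.5, k_max=4))
        assert res.status == "optimal"
        assert res.transcripts.k == 1
        assert res.abundances.W[0, 0] == pytest.approx(1.0, abs=1e-6)  # a / c with c = a
        assert res.objective == pytest.approx(0.5, abs=1e-6)  # pure sparsity floor

    def test_two_of_eight_identifiable_single_sample(self, rng):
        patterns = all_patterns(3)
        idx = [1, 6]
        inst = simulate_samples(tuple(patterns[i] for i in idx), 1, rng)
        graph, obs = inst.to_observations()
        res = solve_joint(graph, obs, L2, HyperParams(w_sparsity=1e-5, k_max=8))
        chosen = sorted(tuple(int(x) for x in row) for row in res.transcripts.U)
        expected = sorted(tuple(pattern_to_path(patterns[i], 3)) for i in idx)
        assert chosen == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_mode_matches_exhaustive_oracle(self, seed):
        """On loci with few enumerable paths the branch-and-bound objective
        equals the brute-force minimum over all path subsets."""
        rng = np.random.default_rng(100 + seed)
        n_cas = int(rng.integers(2, 4))  # 4 or 8 paths
        graph = make_cassette_graph(n_cas)
        n_samples = int(rng.integers(1, 4))
        loss_model = [L2, NB][seed % 2]
        seg = rng.uniform(0, 12, size=(n_samples, graph.n_segments))
        intr = rng.uniform(0, 8, size=(n_samples, len(graph.edge_list)))
        pairs = [
            {(1, graph.n_segments - 1): float(rng.integers(0, 5))} for _ in range(n_samples)
        ]
        obs = _obs(graph, seg, intr, pairs)
        hyper = HyperParams(w_sparsity=float(rng.uniform(0.5, 5.0)), w_pair=1.0, k_max=8)
        res = solve_joint(graph, obs, loss_model, hyper)
        oracle_obj, oracle_subset = _brute_force_solve(graph, obs, loss_model, hyper)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(oracle_obj, rel=1e-6, abs=1e-6)

    def test_monotone_regularization_path(self, rng):
        patterns = all_patterns(3)
        inst = simulate_samples(tuple(patterns[i] for i in (0, 3, 5)), 2, rng)
        graph, obs = inst.to_observations()
        sizes = []
        for w in (1e-5, 1e-3, 1e-1, 10.0):
            res = solve_joint(graph, obs, L2, HyperParams(w_sparsity=w, k_max=8))
            sizes.append(res.transcripts.k)
        assert sizes == sorted(sizes, reverse=True)

    def test_joint_beats_pooled_on_multi_sample_instance(self):
        """There are instances where four samples solved jointly identify
        the true set while the same solver on summed counts does not."""
        patterns = all_patterns(3)
        found = False
        for seed in range(40):
            rng = np.random.default_rng(seed)
            idx = sorted(int(i) for i in rng.choice(8, size=3, replace=False))
            inst = simulate_samples(tuple(patterns[i] for i in idx), 4, rng)
            graph, obs = inst.to_observations()
            hyper = HyperParams(w_sparsity=1e-6, k_max=8)
            joint = solve_joint(graph, obs, L2, hyper)
            pooled = solve_joint(graph, obs.pooled(), L2, hyper)

            def chosen(res):
                return sorted(tuple(int(x) for x in row) for row in res.transcripts.U)

            expected = sorted(tuple(pattern_to_path(patterns[i], 3)) for i in idx)
            if chosen(joint) == expected and chosen(pooled) != expected:
                found = True
                break
        assert found, "no instance separating joint from pooled solving found"

    def test_known_transcripts_suppress_novel_rows(self, rng):
        patterns = all_patterns(3)
        idx = [2, 5]
        inst = simulate_samples(tuple(patterns[i] for i in idx), 2, rng)
        graph, obs = inst.to_observations()
        known = [pattern_to_path(patterns[i], 3) for i in idx]
        res = solve_joint(
            graph, obs, L2,
            HyperParams(w_sparsity=50.0, w_known_discount=1e-4, k_max=8),
            known=known,
        )
        assert set(res.transcripts.provenance) == {"known"}
        assert res.transcripts.k == 2

    def test_iterative_mode_descends_and_approximates(self, rng):
        patterns = all_patterns(3)
        inst = simulate_samples(tuple(patterns[i] for i in (1, 4, 6)), 3, rng)
        graph, obs = inst.to_observations()
        hyper = HyperParams(w_sparsity=1e-4, k_max=8)
        exact = solve_joint(graph, obs, L2, hyper, mode="exact")
        iterative = solve_joint(graph, obs, L2, hyper, mode="iterative")
        assert iterative.status == "approximate"
        assert iterative.objective >= exact.objective - 1e-9
        # on this easy identifiable instance greedy also lands on the optimum
        assert iterative.objective == pytest.approx(exact.objective, rel=1e-5, abs=1e-6)

    def test_breakdown_sums_to_objective(self, rng):
        patterns = all_patterns(2)
        inst = simulate_samples((patterns[1], patterns[2]), 2, rng)
        graph, obs = inst.to_observations()
        res = solve_joint(graph, obs, NB, HyperParams(w_sparsity=0.5, k_max=4))
        assert sum(res.breakdown.values()) == pytest.approx(res.objective, rel=1e-6)
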