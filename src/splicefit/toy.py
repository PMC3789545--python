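"""Identifiability study on cassette-exon toy graphs.

A gene with ``n`` independent cassette exons between constitutive exons
defines a splicing graph with ``2n+1`` segments and ``2^n`` source-to-sink
paths (transcripts).  When a small subset of those transcripts is expressed,
the observed segment coverages and junction counts are linear in the
(unknown) transcript abundances, so asking which transcript sets could have
produced the data reduces to linear feasibility with strictly positive
abundances.  This module simulates that setting with *exact expected*
observations (no sampling noise): it draws true transcript sets and
per-sample abundances, enumerates every minimal-cardinality transcript
subset consistent with all samples, and estimates

* the fraction of trials where exactly one consistent set remains
  (the instance is *identifiable*), and
* the expected success of the *optimal strategy* that picks uniformly at
  random among the consistent sets.

With several samples sharing the transcript set but with independently
redrawn abundances, the per-sample consistent sets are intersected, which
is what makes multi-sample data strictly more informative than pooled or
single-sample data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import linprog

from .graph import ObservationSet, Region, Segment, SegmentGraph, add_intron_edges

SEGMENT_LEN = 100

# positivity threshold for "expressed" abundances and the exact-match
# tolerance on observations
MIN_ABUNDANCE = 1e-8
MATCH_TOL = 1e-8


def make_cassette_graph(n_cassettes: int) -> SegmentGraph:
    """Splicing graph with ``n_cassettes`` independent exon skips.

    Segments alternate constitutive / cassette (2n+1 in total, each
    ``SEGMENT_LEN`` bases); every consecutive pair is joined (adjacency)
    and each cassette can be skipped by an intron edge between its
    flanking constitutive segments — 3n junction edges and ``2**n`` paths.
    ``n_cassettes == 0`` yields a single-segment graph with one path.
    """
    if n_cassettes < 0:
        raise ValueError("n_cassettes must be >= 0")
    n_seg = 2 * n_cassettes + 1
    segments = [
        Segment("toy", i * SEGMENT_LEN, (i + 1) * SEGMENT_LEN) for i in range(n_seg)
    ]
    skips = {
        (segments[2 * i].end, segments[2 * i + 2].start): 1 for i in range(n_cassettes)
    }
    region = Region("toy", 0, n_seg * SEGMENT_LEN)
    return add_intron_edges(segments, junctions=skips, region=region)


def pattern_to_path(pattern, n_cassettes: int) -> np.ndarray:
    """Binary segment vector of the transcript including cassettes where
    ``pattern`` is 1 (constitutive segments always included)."""
    u = np.ones(2 * n_cassettes + 1, dtype=np.int8)
    for i, inc in enumerate(pattern):
        u[2 * i + 1] = 1 if inc else 0
    return u


def all_patterns(n_cassettes: int):
    """All 2^n cassette inclusion patterns, lexicographic."""
    return [tuple(p) for p in itertools.product((0, 1), repeat=n_cassettes)]


@dataclass
class ToyInstance:
    """A drawn identifiability trial: true transcripts, abundances, exact
    expected observations (one row per sample)."""

    n_cassettes: int
    true_set: tuple  # tuple of cassette-inclusion patterns
    abundances: np.ndarray  # (n_samples, len(true_set)), strictly positive
    seg_cov: np.ndarray  # (n_samples, 2n+1) expected segment coverage
    junc_counts: np.ndarray  # (n_samples, 3n) expected junction support

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    def to_observations(self):
        """(graph, ObservationSet) pair for driving the full solver."""
        graph = make_cassette_graph(self.n_cassettes)
        obs = ObservationSet(
            seg_counts=self.seg_cov,
            intron_counts=self.junc_counts,
            pair_counts=None,
            seg_lengths=graph.seg_lengths,
        )
        return graph, obs


@lru_cache(maxsize=None)
def _observation_matrix(n_cassettes: int):
    """Columns = per-transcript exact observation profiles (segments then
    junction edges), for all 2^n candidate transcripts."""
    graph = make_cassette_graph(n_cassettes)
    cols = []
    for pattern in all_patterns(n_cassettes):
        u = pattern_to_path(pattern, n_cassettes)
        cols.append(np.concatenate([u, graph.path_edges(u)]).astype(float))
    return np.column_stack(cols)


def simulate_samples(true_set, n_samples: int, rng) -> ToyInstance:
    """Draw per-sample abundances for ``true_set`` and compute exact
    expected observations.

    Abundances are independent uniform(0, 1) per expressed transcript and
    per sample, renormalized to sum to one (total expression fixed), i.e.
    the total abundance is uniformly redistributed among the expressed
    transcripts in every sample.
    """
    true_set = tuple(tuple(p) for p in true_set)
    if not true_set:
        raise ValueError("true_set must be non-empty")
    n_cassettes = len(true_set[0])
    patterns = all_patterns(n_cassettes)
    idx = [patterns.index(p) for p in true_set]
    profile = _observation_matrix(n_cassettes)[:, idx]

    w = rng.uniform(size=(n_samples, len(true_set)))
    w = w / w.sum(axis=1, keepdims=True)
    expected = w @ profile.T
    n_seg = 2 * n_cassettes + 1
    return ToyInstance(
        n_cassettes=n_cassettes,
        true_set=true_set,
        abundances=w,
        seg_cov=expected[:, :n_seg],
        junc_counts=expected[:, n_seg:],
    )


# ---------------------------------------------------------------------------
# consistency enumeration
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _subset_bank(n_cassettes: int, size: int):
    """Precomputed per-subset linear systems for all transcript subsets of
    one cardinality: (subset index tuples, stacked A, stacked pinv,
    full-rank mask)."""
    profile = _observation_matrix(n_cassettes)
    n_tx = profile.shape[1]
    subsets = list(itertools.combinations(range(n_tx), size))
    mats = np.stack([profile[:, list(sub)] for sub in subsets])  # (m, rows, size)
    pinvs = np.stack([np.linalg.pinv(a) for a in mats])
    ranks = np.array([np.linalg.matrix_rank(a) for a in mats])
    return subsets, mats, pinvs, ranks == size


def _consistent_of_size(n_cassettes, size, observations, tol, min_abundance):
    """Transcript subsets of one cardinality consistent with every
    observation row (rows = concatenated segment + junction expectations)."""
    subsets, mats, pinvs, full_rank = _subset_bank(n_cassettes, size)
    ok = np.ones(len(subsets), dtype=bool)
    for b in observations:
        a = pinvs @ b  # (m, size): unique least-squares solution per subset
        resid = np.abs(np.einsum("mrk,mk->mr", mats, a) - b).max(axis=1)
        exact = (resid <= tol) & (a.min(axis=1) >= min_abundance) & full_rank
        need_lp = ok & ~full_rank
        if need_lp.any():
            exact |= _lp_feasible(mats, b, min_abundance, need_lp)
        ok &= exact
        if not ok.any():
            break
    return [frozenset(subsets[i]) for i in np.flatnonzero(ok)]


def _lp_feasible(mats, b, min_abundance, mask):
    """LP feasibility fallback for rank-deficient subset systems."""
    out = np.zeros(len(mats), dtype=bool)
    for i in np.flatnonzero(mask):
        a_mat = mats[i]
        res = linprog(
            c=np.zeros(a_mat.shape[1]),
            A_eq=a_mat,
            b_eq=b,
            bounds=(min_abundance, None),
            method="highs",
        )
        out[i] = res.status == 0
    return out


def consistent_sets(
    instance: ToyInstance,
    tol: float = MATCH_TOL,
    min_abundance: float = MIN_ABUNDANCE,
):
    """All transcript subsets of minimal cardinality consistent with every
    sample of ``instance``.

    A subset is consistent with a sample iff strictly positive abundances
    exist whose exact expected segment and junction observations equal the
    sample's.  Subsets are enumerated in increasing cardinality and the
    first non-empty level is returned, as sets of indices into
    :func:`all_patterns`.  The true set is always among the results.
    """
    observations = np.hstack([instance.seg_cov, instance.junc_counts])
    n_tx = 2**instance.n_cassettes
    for size in range(1, n_tx + 1):
        found = _consistent_of_size(
            instance.n_cassettes, size, observations, tol, min_abundance
        )
        if found:
            return found
    raise AssertionError("unreachable: the true set is always consistent")


def success_rates(
    n_cassettes: int,
    set_size: int,
    n_samples: int,
    n_trials: int,
    rng,
):
    """Monte-Carlo identifiability over random true sets and abundances.

    Returns ``(unique_fraction, optimal_strategy_fraction)``: the share of
    trials with exactly one consistent minimal-cardinality set, and the
    mean reciprocal of the number of consistent sets (the expected success
    probability of picking uniformly among them, the true set always being
    one of them).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    patterns = all_patterns(n_cassettes)
    unique = 0
    optimal = 0.0
    for _ in range(n_trials):
        chosen = rng.choice(len(patterns), size=set_size, replace=False)
        true_set = tuple(patterns[i] for i in sorted(chosen))
        inst = simulate_samples(true_set, n_samples, rng)
        sets = consistent_sets(inst)
        if len(sets) == 1:
            unique += 1
        optimal += 1.0 / len(sets)
    return unique / n_trials, optimal / n_trials


def random_guess_probability(n_transcripts: int, set_size: int) -> float:
    """Success probability (in percent) of blindly guessing the expressed
    set: 100 / C(n_transcripts, set_size)."""
    if set_size <= 0 or set_size > n_transcripts:
        raise ValueError("need 0 < set_size <= n_transcripts")
    return 100.0 / math.comb(n_transcripts, set_size)
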