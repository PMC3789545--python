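"""Multi-mapper optimization (MMO).

A read aligning equally well to several genomic locations is assigned to
the location where it best fits the expected coverage implied by the
current transcript models, i.e. the one minimizing the global count NLL.
Because the expected coverage itself depends on the assignments (through
re-quantification), assignment and model fitting alternate in an
EM-like loop.  Both steps accept only strictly improving updates against
the same exact NLL objective, so the total objective is non-increasing
and the loop terminates.

Reads are processed in fixed id order each round (deterministic); ties
between equally scoring candidate locations break toward the lowest
genomic coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import ObservationSet, SegmentGraph
from .loss import LossModel, nll_count
from .solver import HyperParams, solve_joint

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class CandidateLocation:
    """One possible origin of a multi-mapping read: which region it falls
    in, which segments it covers (and by how many bases), which intron
    edges its gaps confirm, and its coordinate for tie-breaking."""

    region_idx: int
    coordinate: int
    seg_bases: tuple  # ((segment_idx, n_bases), ...)
    intron_hits: tuple = ()  # edge indices into the region graph's edge_list


@dataclass
class MultiRead:
    read_id: str
    sample: int
    candidates: list
    assigned: int = 0

    def __post_init__(self):
        if len(self.candidates) < 2:
            raise ValueError("a multi-read needs at least two candidate locations")
        if not 0 <= self.assigned < len(self.candidates):
            raise ValueError("assigned index out of range")


class _RegionState:
    """Mutable per-region observed counts plus the current expected counts."""

    def __init__(self, graph: SegmentGraph, base_obs: ObservationSet):
        self.graph = graph
        self.seg_lengths = graph.seg_lengths
        self.base_bases = base_obs.seg_counts * self.seg_lengths  # raw aligned bases
        self.intron = base_obs.intron_counts.copy()
        self.pair_counts = base_obs.pair_counts
        self.mu_seg = np.zeros_like(self.base_bases)
        self.mu_int = np.zeros_like(self.intron)
        self.result = None

    @property
    def n_samples(self):
        return self.base_bases.shape[0]

    def observations(self) -> ObservationSet:
        return ObservationSet(
            seg_counts=self.base_bases / self.seg_lengths,
            intron_counts=self.intron,
            pair_counts=self.pair_counts,
            seg_lengths=self.seg_lengths,
        )

    def apply(self, sample: int, cand: CandidateLocation, sign: int) -> None:
        for seg_idx, n_bases in cand.seg_bases:
            self.base_bases[sample, seg_idx] += sign * n_bases
        for edge_idx in cand.intron_hits:
            self.intron[sample, edge_idx] += sign

    def total_nll(self, model: LossModel, w_intron: float) -> float:
        total = float(np.sum(nll_count(self.base_bases / self.seg_lengths, self.mu_seg, model)))
        total += w_intron * float(np.sum(nll_count(self.intron, self.mu_int, model)))
        return total


def mmo_round(multireads, states, loss_model: LossModel, w_intron: float = 1.0) -> int:
    """One sweep of read reassignment against fixed expected coverage.

    Each read moves to the candidate minimizing the summed NLL of the
    count terms it touches; only strictly improving moves are taken.
    Returns the number of changed assignments.
    """
    changed = 0
    for read in sorted(multireads, key=lambda m: (m.sample, m.read_id)):
        current = read.candidates[read.assigned]
        # fixed universe of count terms any candidate touches, so scores of
        # different placements are comparable
        seg_terms = sorted(
            {(c.region_idx, s) for c in read.candidates for s, _ in c.seg_bases}
        )
        int_terms = sorted(
            {(c.region_idx, e) for c in read.candidates for e in c.intron_hits}
        )

        def universe_nll() -> float:
            total = 0.0
            for region_idx, s in seg_terms:
                state = states[region_idx]
                v = state.base_bases[read.sample, s] / state.seg_lengths[s]
                total += float(nll_count(v, state.mu_seg[read.sample, s], loss_model))
            for region_idx, e in int_terms:
                state = states[region_idx]
                total += w_intron * float(
                    nll_count(
                        state.intron[read.sample, e], state.mu_int[read.sample, e], loss_model
                    )
                )
            return total

        scores = []
        for idx, cand in enumerate(read.candidates):
            states[current.region_idx].apply(read.sample, current, -1)
            states[cand.region_idx].apply(read.sample, cand, +1)
            scores.append((universe_nll(), cand.coordinate, idx))
            states[cand.region_idx].apply(read.sample, cand, -1)
            states[current.region_idx].apply(read.sample, current, +1)
        cur_score = scores[read.assigned][0]
        best = min(scores)
        if best[0] < cur_score - _EPS and best[2] != read.assigned:
            states[current.region_idx].apply(read.sample, current, -1)
            states[read.candidates[best[2]].region_idx].apply(
                read.sample, read.candidates[best[2]], +1
            )
            read.assigned = best[2]
            changed += 1
    return changed


def mmo_loop(
    graphs,
    base_observations,
    multireads,
    loss_model: LossModel = None,
    hyper: HyperParams = None,
    max_iters: int = 10,
    solver_mode: str = "exact",
    solver_kw: dict = None,
):
    """Alternate transcript fitting and multi-read reassignment.

    ``graphs``/``base_observations`` are parallel per-region lists, the
    observations holding the *uniquely* mapped evidence; ``multireads``
    start at their current (primary) assignment.  Returns
    ``(observation_sets, solve_results, objective_history)`` after
    convergence (no assignment changes) or ``max_iters``.
    """
    loss_model = loss_model or LossModel()
    hyper = hyper or HyperParams()
    solver_kw = solver_kw or {}
    states = [_RegionState(g, obs) for g, obs in zip(graphs, base_observations)]
    for read in multireads:
        cand = read.candidates[read.assigned]
        states[cand.region_idx].apply(read.sample, cand, +1)

    history = []
    seen_signatures = set()
    for iteration in range(max_iters):
        # model update per region, accepted only when it improves the NLL
        for state in states:
            obs = state.observations()
            result = solve_joint(
                state.graph, obs, loss_model, hyper, mode=solver_mode, **solver_kw
            )
            mu_seg = result.abundances.expected_seg_counts(result.transcripts)
            mu_int = result.abundances.expected_intron_counts(result.transcripts)
            if result.transcripts.k == 0:
                mu_seg = np.zeros_like(state.mu_seg)
                mu_int = np.zeros_like(state.mu_int)
            old_nll = state.total_nll(loss_model, hyper.w_intron)
            saved = (state.mu_seg, state.mu_int, state.result)
            state.mu_seg, state.mu_int, state.result = mu_seg, mu_int, result
            if state.total_nll(loss_model, hyper.w_intron) > old_nll + _EPS and iteration > 0:
                state.mu_seg, state.mu_int, state.result = saved

        total = sum(state.total_nll(loss_model, hyper.w_intron) for state in states)
        history.append(total)

        changed = mmo_round(multireads, states, loss_model, hyper.w_intron)
        signature = (changed, tuple(m.assigned for m in multireads))
        if changed == 0:
            break
        if signature in seen_signatures:
            logger.warning("mmo_loop: cyclic assignment signature detected; stopping")
            break
        seen_signatures.add(signature)
    history.append(sum(state.total_nll(loss_model, hyper.w_intron) for state in states))

    return [state.observations() for state in states], [state.result for state in states], history


# ---------------------------------------------------------------------------
# SAM surface
# ---------------------------------------------------------------------------


def collect_multireads_sam(path, sample: int, graphs):
    """Split a SAM/BAM (with secondary records) into unique evidence reads
    and :class:`MultiRead` objects whose candidates map onto ``graphs``."""
    import pysam

    regions = [g.region for g in graphs]
    by_name: dict = {}
    with pysam.AlignmentFile(str(path)) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            by_name.setdefault(aln.query_name, []).append(
                (aln.reference_name, tuple(aln.get_blocks()), aln.is_secondary)
            )

    unique_reads: list = []
    multis: list = []
    from .graph import Read

    for name, alns in sorted(by_name.items()):
        if len(alns) == 1:
            chrom, blocks, _ = alns[0]
            unique_reads.append(Read(name=name, chrom=chrom, blocks=blocks))
            continue
        cands = []
        primary_idx = 0
        for i, (chrom, blocks, secondary) in enumerate(alns):
            cand = _locate(chrom, blocks, graphs, regions)
            if cand is None:
                continue
            if not secondary:
                primary_idx = len(cands)
            cands.append(cand)
        if len(cands) >= 2:
            multis.append(MultiRead(read_id=name, sample=sample, candidates=cands, assigned=primary_idx))
        elif cands:
            chrom, blocks, _ = alns[0]
            unique_reads.append(Read(name=name, chrom=chrom, blocks=blocks))
    return unique_reads, multis


def _locate(chrom, blocks, graphs, regions):
    for region_idx, (graph, region) in enumerate(zip(graphs, regions)):
        if region.chrom != chrom or blocks[0][0] >= region.end or blocks[-1][1] <= region.start:
            continue
        seg_bases = []
        for s, seg in enumerate(graph.segments):
            n_bases = sum(
                max(0, min(seg.end, b_end) - max(seg.start, b_start)) for b_start, b_end in blocks
            )
            if n_bases:
                seg_bases.append((s, n_bases))
        gaps = [(blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)]
        edge_list = graph.edge_list
        intron_hits = tuple(
            e_idx
            for e_idx, (i, j) in enumerate(edge_list)
            if (graph.segments[i].end, graph.segments[j].start) in gaps
        )
        if seg_bases:
            return CandidateLocation(
                region_idx=region_idx,
                coordinate=blocks[0][0],
                seg_bases=tuple(seg_bases),
                intron_hits=intron_hits,
            )
    return None


def write_resolved_sam(in_path, out_path, multireads) -> None:
    """Copy a SAM, marking each multi-read's chosen candidate as primary
    (secondary flag set on all its other records)."""
    import pysam

    chosen = {
        m.read_id: m.candidates[m.assigned].coordinate for m in multireads
    }
    with pysam.AlignmentFile(str(in_path)) as fh, pysam.AlignmentFile(
        str(out_path), "wh", template=fh
    ) as out:
        for aln in fh:
            if aln.query_name in chosen and not aln.is_unmapped:
                aln.is_secondary = aln.reference_start != chosen[aln.query_name]
            out.write(aln)
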