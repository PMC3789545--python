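"""Splicing-graph construction from spliced alignments and/or annotation.

A genomic region is cut into *segments* at boundary events — splice sites
(SS) from spliced-read gap endpoints or annotated exon ends, and potential
transcription start/termination sites (TSS/TTS) from annotated transcript
ends or coverage-island edges.  Segments surviving the exon filter become
nodes of a directed acyclic *splicing graph*; edges are introns (from
spliced reads or annotated intron chains) plus adjacency edges between
genomically contiguous segments.  Expressed transcripts correspond to
paths from an initial to a terminal segment.

All coordinates are 0-based half-open (BAM convention); GTF conversion
happens at the I/O layer.  Graphs are built per region and per strand, in
genomic left-to-right order regardless of strand.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

SS = "SS"
TSS = "TSS"
TTS = "TTS"


class PathEnumerationOverflow(Exception):
    """Raised when a splicing graph encodes more paths than the caller's cap."""

    def __init__(self, limit: int):
        super().__init__(f"number of source-to-sink paths exceeds limit {limit}")
        self.limit = limit


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    kind: str = "exonic"
    is_initial: bool = False
    is_terminal: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("segment start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Boundary:
    pos: int
    labels: frozenset

    def __repr__(self):
        return f"Boundary({self.pos}, {{{', '.join(sorted(self.labels))}}})"


@dataclass
class Read:
    """A minimal spliced alignment: ordered aligned blocks, gaps are introns."""

    name: str
    chrom: str
    blocks: tuple
    is_read2: bool = False

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def gaps(self):
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0]) for i in range(len(self.blocks) - 1)
        )


# ---------------------------------------------------------------------------
# alignment sources
# ---------------------------------------------------------------------------


def iter_reads(source, region: Region):
    """Yield :class:`Read` objects overlapping ``region``.

    ``source`` is either an iterable of :class:`Read` or a path to a SAM/BAM
    file (read with pysam).  Raises ``ValueError`` naming the chromosome when
    the file does not know ``region.chrom``.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        import pysam

        with pysam.AlignmentFile(str(source)) as fh:
            if region.chrom not in fh.references:
                raise ValueError(f"chromosome {region.chrom!r} not present in {source}")
            try:
                records = fh.fetch(region.chrom, region.start, region.end)
            except ValueError:  # un-indexed SAM: sequential scan
                records = (
                    aln
                    for aln in fh
                    if not aln.is_unmapped
                    and aln.reference_name == region.chrom
                    and aln.reference_start < region.end
                    and aln.reference_end > region.start
                )
            for aln in records:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                blocks = _merge_touching(aln.get_blocks())
                if blocks:
                    yield Read(
                        name=aln.query_name,
                        chrom=region.chrom,
                        blocks=tuple(blocks),
                        is_read2=bool(aln.is_paired and aln.is_read2),
                    )
    else:
        for read in source:
            if read.chrom == region.chrom and read.start < region.end and read.end > region.start:
                yield read


def _merge_touching(blocks):
    """Merge abutting aligned blocks (I/D operations split pysam blocks)."""
    merged = []
    for b_start, b_end in blocks:
        if merged and b_start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b_end))
        else:
            merged.append((b_start, b_end))
    return merged


def per_base_coverage(sources, region: Region) -> np.ndarray:
    """Per-base read coverage over ``region``, summed over alignment sources."""
    cov = np.zeros(region.length, dtype=np.int64)
    for source in sources:
        for read in iter_reads(source, region):
            for b_start, b_end in read.blocks:
                lo = max(b_start, region.start) - region.start
                hi = min(b_end, region.end) - region.start
                if hi > lo:
                    cov[lo:hi] += 1
    return cov


def junction_counts(sources, region: Region):
    """Tally of spliced-read gaps (introns) within ``region`` -> count."""
    tally = defaultdict(int)
    for source in sources:
        for read in iter_reads(source, region):
            for gap in read.gaps:
                if gap[0] >= region.start and gap[1] <= region.end:
                    tally[gap] += 1
                else:
                    logger.warning("intron %s crosses region boundary; skipped", gap)
    return dict(tally)


# ---------------------------------------------------------------------------
# boundary detection (step 1)
# ---------------------------------------------------------------------------


def find_boundaries(
    alignments,
    annotation=None,
    region: Region = None,
    min_island_gap: int = 20,
):
    """Ordered, deduplicated list of segment boundaries with labels.

    SS boundaries come from spliced-read gap endpoints and internal
    annotated exon ends; TSS/TTS from annotated transcript ends and from
    coverage-island edges (a run of >= ``min_island_gap`` uncovered bases
    ends an island).  ``alignments`` is a list of per-sample sources (may
    be empty when annotation is given).
    """
    if region is None:
        raise ValueError("region is required")
    if region.length == 0:
        return []
    if not alignments and annotation is None:
        raise ValueError("need at least one of alignments or annotation")

    labels = defaultdict(set)

    # --- from annotation -------------------------------------------------
    if annotation is not None:
        for tx in annotation.overlapping(region):
            first, last = tx.exons[0], tx.exons[-1]
            start_label, end_label = (TSS, TTS) if tx.strand != "-" else (TTS, TSS)
            labels[first[0]].add(start_label)
            labels[last[1]].add(end_label)
            for i, (ex_start, ex_end) in enumerate(tx.exons):
                if i > 0:
                    labels[ex_start].add(SS)
                if i < len(tx.exons) - 1:
                    labels[ex_end].add(SS)

    # --- from reads -------------------------------------------------------
    if alignments:
        for gap in junction_counts(alignments, region):
            labels[gap[0]].add(SS)
            labels[gap[1]].add(SS)
        cov = per_base_coverage(alignments, region)
        covered = cov > 0
        # island edges: transitions bordered by >= min_island_gap zeros
        idx = np.flatnonzero(covered)
        if idx.size:
            runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            prev_end = None
            for run in runs:
                lo = int(run[0]) + region.start
                hi = int(run[-1]) + 1 + region.start
                gap_before = lo - (prev_end if prev_end is not None else -np.inf)
                if prev_end is None or gap_before >= min_island_gap:
                    labels[lo].add(TSS)
                    if prev_end is not None:
                        labels[prev_end].add(TTS)
                prev_end = hi
            labels[prev_end].add(TTS)

    in_range = {p: lab for p, lab in labels.items() if region.start <= p <= region.end}
    return [Boundary(pos, frozenset(lab)) for pos, lab in sorted(in_range.items())]


def candidate_segments(boundaries, region: Region):
    """Intervals between consecutive boundaries, as unflagged segments."""
    positions = sorted({b.pos for b in boundaries})
    return [
        Segment(region.chrom, positions[i], positions[i + 1])
        for i in range(len(positions) - 1)
    ]


# ---------------------------------------------------------------------------
# exon filter (step 2)
# ---------------------------------------------------------------------------


def filter_exonic_segments(
    candidates,
    coverage: np.ndarray,
    region: Region,
    annotation=None,
    pair_links=(),
    junctions=(),
    min_covered_frac: float = 0.05,
):
    """Keep candidate segments that look exonic.

    A segment is kept iff (i) strictly more than ``min_covered_frac`` of its
    bases are covered by at least one read, OR (ii) it lies within an exon
    of an annotated transcript, OR (iii) dropping it would disconnect two
    segments linked by paired-end fragments (indices into ``candidates``).
    ``junctions`` are intron coordinates used, together with adjacency,
    for the connectivity check.
    """
    n = len(candidates)
    annotated_exons = []
    if annotation is not None:
        for tx in annotation.overlapping(region):
            annotated_exons.extend(tx.exons)

    def covered_frac(seg: Segment) -> float:
        lo = max(seg.start, region.start) - region.start
        hi = min(seg.end, region.end) - region.start
        if hi <= lo:
            return 0.0
        return float(np.count_nonzero(coverage[lo:hi])) / seg.length

    def is_annotated(seg: Segment) -> bool:
        return any(ex[0] <= seg.start and seg.end <= ex[1] for ex in annotated_exons)

    keep = {
        i
        for i, seg in enumerate(candidates)
        if covered_frac(seg) > min_covered_frac or is_annotated(seg)
    }

    if pair_links:
        junction_pairs = _junctions_to_index_pairs(candidates, junctions)

        def connected(active, a, b):
            # BFS over adjacency (touching candidates) and junction edges
            adj = defaultdict(set)
            ordered = sorted(active)
            for x, y in zip(ordered, ordered[1:]):
                if candidates[x].end == candidates[y].start:
                    adj[x].add(y)
                    adj[y].add(x)
            for x, y in junction_pairs:
                if x in active and y in active:
                    adj[x].add(y)
                    adj[y].add(x)
            seen, stack = {a}, [a]
            while stack:
                node = stack.pop()
                if node == b:
                    return True
                for nxt in adj[node]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            return False

        changed = True
        while changed:
            changed = False
            for i in range(n):
                if i in keep:
                    continue
                for a, b in pair_links:
                    if connected(keep | {i}, a, b) and not connected(keep, a, b):
                        keep.add(i)
                        changed = True
                        break
    return [candidates[i] for i in sorted(keep)]


def _junctions_to_index_pairs(candidates, junctions):
    end_idx = {seg.end: i for i, seg in enumerate(candidates)}
    start_idx = {seg.start: i for i, seg in enumerate(candidates)}
    pairs = []
    for gs, ge in junctions:
        if gs in end_idx and ge in start_idx:
            pairs.append((end_idx[gs], start_idx[ge]))
    return pairs


# ---------------------------------------------------------------------------
# the graph (step 3)
# ---------------------------------------------------------------------------


@dataclass
class SegmentGraph:
    """DAG of exonic segments with intron and adjacency edges.

    ``edges`` maps ordered index pairs ``(i, j)``, ``i < j``, to the set of
    sources that support the connection ('read', 'annotation',
    'adjacency').  Initial/terminal flags live on the segments.
    """

    region: Region
    segments: list
    edges: dict = field(default_factory=dict)

    def __post_init__(self):
        for (i, j) in self.edges:
            if not (0 <= i < j < len(self.segments)):
                raise ValueError(f"edge ({i},{j}) must be forward-ordered within the graph")

    # -- basic queries -----------------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def edge_list(self):
        return sorted(self.edges)

    def successors(self, i: int):
        return [j for (a, j) in self.edges if a == i]

    @property
    def seg_lengths(self) -> np.ndarray:
        return np.array([seg.length for seg in self.segments], dtype=float)

    def initial_indices(self):
        return [i for i, seg in enumerate(self.segments) if seg.is_initial]

    def terminal_indices(self):
        return [i for i, seg in enumerate(self.segments) if seg.is_terminal]

    # -- path machinery ----------------------------------------------------
    def is_valid_path(self, u) -> bool:
        """True iff binary vector ``u`` selects a source-to-sink path."""
        sel = [i for i, x in enumerate(u) if x]
        if not sel:
            return False
        if not self.segments[sel[0]].is_initial or not self.segments[sel[-1]].is_terminal:
            return False
        return all((a, b) in self.edges for a, b in zip(sel, sel[1:]))

    def enumerate_paths(self, limit: int = 10000):
        """All source-to-sink paths as binary segment vectors.

        Raises :class:`PathEnumerationOverflow` when more than ``limit``
        paths exist (never silently truncates).
        """
        succ = defaultdict(list)
        for (i, j) in self.edge_list:
            succ[i].append(j)
        paths = []

        def walk(node, trail):
            if self.segments[node].is_terminal:
                if len(paths) >= limit:
                    raise PathEnumerationOverflow(limit)
                vec = np.zeros(self.n_segments, dtype=np.int8)
                vec[trail] = 1
                paths.append(vec)
            for nxt in succ[node]:
                walk(nxt, trail + [nxt])

        for s in self.initial_indices():
            walk(s, [s])
        return paths

    def count_paths(self) -> int:
        """Path count by dynamic programming (no enumeration)."""
        succ = defaultdict(list)
        for (i, j) in self.edge_list:
            succ[i].append(j)
        memo = {}

        def n_from(node):
            if node not in memo:
                total = 1 if self.segments[node].is_terminal else 0
                total += sum(n_from(nxt) for nxt in succ[node])
                memo[node] = total
            return memo[node]

        return sum(n_from(s) for s in self.initial_indices())

    def path_edges(self, u):
        """Edge indicator (over ``edge_list``) of the path selected by ``u``."""
        sel = [i for i, x in enumerate(u) if x]
        used = set(zip(sel, sel[1:]))
        return np.array([1 if e in used else 0 for e in self.edge_list], dtype=np.int8)

    # -- serialization -----------------------------------------------------
    def dump(self, path, observations=None) -> None:
        write_graph_tsv(self, path, observations)

    def __repr__(self):
        return (
            f"SegmentGraph({self.region.chrom}:{self.region.start}-{self.region.end}"
            f"{self.region.strand}, {self.n_segments} segments, {len(self.edges)} edges)"
        )


def add_intron_edges(
    segments,
    junctions=None,
    annotation=None,
    region: Region = None,
    boundaries=(),
) -> SegmentGraph:
    """Connect filtered segments into a :class:`SegmentGraph`.

    ``junctions`` maps intron coordinates (from spliced reads) to counts;
    annotated introns are added with source 'annotation'.  A junction whose
    endpoints do not coincide with segment boundaries is skipped with a
    warning.  Touching segments get an adjacency edge.  Initial/terminal
    flags are set from TSS/TTS boundary labels and island edges (a segment
    after/before a genomic gap).
    """
    if region is None:
        chrom = segments[0].chrom if segments else "?"
        lo = min((s.start for s in segments), default=0)
        hi = max((s.end for s in segments), default=0)
        region = Region(chrom, lo, hi)

    segments = sorted(segments, key=lambda s: (s.start, s.end))
    end_idx = {seg.end: i for i, seg in enumerate(segments)}
    start_idx = {seg.start: i for i, seg in enumerate(segments)}
    edges = {}

    def add_edge(i, j, source):
        if i >= j:
            logger.warning("dropping backward edge (%d,%d)", i, j)
            return
        edges.setdefault((i, j), set()).add(source)

    for i in range(len(segments) - 1):
        if segments[i].end == segments[i + 1].start:
            add_edge(i, i + 1, "adjacency")

    all_junctions = dict(junctions or {})
    for (gs, ge), _count in sorted(all_junctions.items()):
        if gs in end_idx and ge in start_idx:
            add_edge(end_idx[gs], start_idx[ge], "read")
        else:
            logger.warning("junction (%d,%d) does not match segment boundaries; skipped", gs, ge)

    if annotation is not None:
        for tx in annotation.overlapping(region):
            for intron in tx.introns():
                gs, ge = intron
                if gs in end_idx and ge in start_idx:
                    add_edge(end_idx[gs], start_idx[ge], "annotation")
                else:
                    logger.warning(
                        "annotated intron (%d,%d) does not match segment boundaries; skipped",
                        gs,
                        ge,
                    )

    label_at = defaultdict(set)
    for b in boundaries:
        label_at[b.pos] |= set(b.labels)

    # a segment may start a path when annotated/coverage evidence marks a
    # TSS at its left end, or when nothing at all leads into it (island
    # start); symmetrically for path ends
    has_incoming = {j for (_, j) in edges}
    has_outgoing = {i for (i, _) in edges}
    flagged = []
    for i, seg in enumerate(segments):
        is_initial = i not in has_incoming or TSS in label_at[seg.start]
        is_terminal = i not in has_outgoing or TTS in label_at[seg.end]
        flagged.append(replace(seg, is_initial=is_initial, is_terminal=is_terminal))

    return SegmentGraph(region=region, segments=flagged, edges=edges)


def build_graph(
    alignments,
    annotation=None,
    region: Region = None,
    min_island_gap: int = 20,
    min_covered_frac: float = 0.05,
):
    """Convenience pipeline: boundaries -> exon filter -> edges.

    Returns the graph; call :func:`count_observations` to attach counts.
    """
    boundaries = find_boundaries(alignments, annotation, region, min_island_gap)
    cands = candidate_segments(boundaries, region)
    cov = per_base_coverage(alignments, region) if alignments else np.zeros(region.length, int)
    juncs = junction_counts(alignments, region) if alignments else {}
    pair_links = _pair_links(alignments, cands, region) if alignments else ()
    connect_juncs = dict(juncs)
    if annotation is not None:
        for tx in annotation.overlapping(region):
            for intron in tx.introns():
                connect_juncs.setdefault(intron, 0)
    kept = filter_exonic_segments(
        cands,
        cov,
        region,
        annotation=annotation,
        pair_links=pair_links,
        junctions=connect_juncs,
        min_covered_frac=min_covered_frac,
    )
    return add_intron_edges(kept, juncs, annotation, region, boundaries)


def _pair_links(alignments, candidates, region: Region):
    """Candidate-index pairs linked by mates of the same fragment."""
    starts = np.array([c.start for c in candidates])
    ends = np.array([c.end for c in candidates])

    def overlapping(read):
        out = set()
        for b_start, b_end in read.blocks:
            hit = np.flatnonzero((starts < b_end) & (ends > b_start))
            out.update(int(h) for h in hit)
        return out

    links = set()
    for source in alignments:
        mates = defaultdict(list)
        for read in iter_reads(source, region):
            mates[read.name].append(read)
        for reads in mates.values():
            if len(reads) < 2:
                continue
            segs_a = overlapping(reads[0])
            segs_b = overlapping(reads[1])
            for a in segs_a:
                for b in segs_b:
                    if a != b:
                        links.add((min(a, b), max(a, b)))
    return sorted(links)


# ---------------------------------------------------------------------------
# observed counts
# ---------------------------------------------------------------------------


@dataclass
class ObservationSet:
    """Per-sample observed counts attached to a :class:`SegmentGraph`.

    ``seg_counts[r, s]`` is the average per-base read count over segment s
    in sample r; ``intron_counts[r, e]`` the spliced-read support of edge e
    (reads spanning the boundary, for adjacency edges); ``pair_counts[r]``
    maps segment-index pairs to paired-fragment counts.
    """

    seg_counts: np.ndarray
    intron_counts: np.ndarray
    pair_counts: list
    seg_lengths: np.ndarray

    def __post_init__(self):
        self.seg_counts = np.atleast_2d(np.asarray(self.seg_counts, dtype=float))
        self.intron_counts = np.atleast_2d(np.asarray(self.intron_counts, dtype=float))
        if np.any(self.seg_counts < 0) or np.any(self.intron_counts < 0):
            raise ValueError("observed counts must be non-negative")
        if self.pair_counts is None:
            self.pair_counts = [dict() for _ in range(self.n_samples)]

    @property
    def n_samples(self) -> int:
        return self.seg_counts.shape[0]

    @property
    def n_segments(self) -> int:
        return self.seg_counts.shape[1]

    @property
    def max_count(self) -> float:
        return float(np.max(self.seg_counts)) if self.seg_counts.size else 0.0

    def subset_samples(self, idx) -> "ObservationSet":
        idx = list(idx)
        return ObservationSet(
            seg_counts=self.seg_counts[idx],
            intron_counts=self.intron_counts[idx],
            pair_counts=[self.pair_counts[i] for i in idx],
            seg_lengths=self.seg_lengths,
        )

    def pooled(self) -> "ObservationSet":
        """Sum counts over samples into a single merged pseudo-sample."""
        pooled_pairs = defaultdict(float)
        for pc in self.pair_counts:
            for key, val in pc.items():
                pooled_pairs[key] += val
        return ObservationSet(
            seg_counts=self.seg_counts.sum(axis=0, keepdims=True),
            intron_counts=self.intron_counts.sum(axis=0, keepdims=True),
            pair_counts=[dict(pooled_pairs)],
            seg_lengths=self.seg_lengths,
        )


def count_observations(graph: SegmentGraph, alignments_per_sample) -> ObservationSet:
    """Observed segment, intron and pair counts for each sample.

    Segment count = total aligned bases in the segment / segment length.
    Intron count = number of spliced alignments whose gap matches the edge
    exactly; for adjacency edges, the number of alignments whose block
    spans the shared boundary.  A sample without alignments yields a zero
    row.
    """
    region = graph.region
    n_seg = graph.n_segments
    edge_list = graph.edge_list
    seg_starts = np.array([s.start for s in graph.segments])
    seg_ends = np.array([s.end for s in graph.segments])

    seg_counts = np.zeros((len(alignments_per_sample), n_seg))
    intron_counts = np.zeros((len(alignments_per_sample), len(edge_list)))
    pair_counts = []

    for r, source in enumerate(alignments_per_sample):
        base_in_seg = np.zeros(n_seg)
        junc = defaultdict(int)
        boundary_span = defaultdict(int)
        mates = defaultdict(list)
        for read in iter_reads(source, region):
            mates[read.name].append(read)
            for b_start, b_end in read.blocks:
                lo = np.maximum(seg_starts, b_start)
                hi = np.minimum(seg_ends, b_end)
                base_in_seg += np.maximum(hi - lo, 0)
                for (i, j) in edge_list:
                    if "adjacency" in graph.edges[(i, j)] or graph.segments[i].end == graph.segments[j].start:
                        p = graph.segments[i].end
                        if b_start < p and b_end > p:
                            boundary_span[(i, j)] += 1
            for gap in read.gaps:
                junc[gap] += 1

        seg_counts[r] = base_in_seg / graph.seg_lengths
        for e_idx, (i, j) in enumerate(edge_list):
            gap = (graph.segments[i].end, graph.segments[j].start)
            if gap[0] == gap[1]:  # adjacency edge
                intron_counts[r, e_idx] = boundary_span[(i, j)]
            else:
                intron_counts[r, e_idx] = junc.get(gap, 0)

        pairs = defaultdict(int)
        for reads in mates.values():
            if len(reads) < 2:
                continue
            segs = []
            for read in reads[:2]:
                hit = set()
                for b_start, b_end in read.blocks:
                    hit.update(
                        int(h)
                        for h in np.flatnonzero((seg_starts < b_end) & (seg_ends > b_start))
                    )
                segs.append(hit)
            seen = set()
            for a in segs[0]:
                for b in segs[1]:
                    if a != b:
                        key = (min(a, b), max(a, b))
                        if key not in seen:
                            seen.add(key)
                            pairs[key] += 1
        pair_counts.append(dict(pairs))

    return ObservationSet(
        seg_counts=seg_counts,
        intron_counts=intron_counts,
        pair_counts=pair_counts,
        seg_lengths=graph.seg_lengths,
    )


# ---------------------------------------------------------------------------
# TSV graph dump / load
# ---------------------------------------------------------------------------

_FORMAT_VERSION = "splicefit-graph\tv1"


def write_graph_tsv(graph: SegmentGraph, path, observations: ObservationSet = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{_FORMAT_VERSION}\n")
        reg = graph.region
        fh.write(f"#region\t{reg.chrom}\t{reg.start}\t{reg.end}\t{reg.strand}\n")
        fh.write("#segments\tidx\tstart\tend\tkind\tinitial\tterminal\n")
        for i, seg in enumerate(graph.segments):
            fh.write(
                f"S\t{i}\t{seg.start}\t{seg.end}\t{seg.kind}\t"
                f"{int(seg.is_initial)}\t{int(seg.is_terminal)}\n"
            )
        fh.write("#edges\ti\tj\tsources\n")
        for (i, j) in graph.edge_list:
            fh.write(f"E\t{i}\t{j}\t{','.join(sorted(graph.edges[(i, j)]))}\n")
        if observations is not None:
            for r in range(observations.n_samples):
                row = "\t".join(repr(float(x)) for x in observations.seg_counts[r])
                fh.write(f"VC\t{r}\t{row}\n")
            for r in range(observations.n_samples):
                row = "\t".join(repr(float(x)) for x in observations.intron_counts[r])
                fh.write(f"IC\t{r}\t{row}\n")
            for r, pc in enumerate(observations.pair_counts):
                for (a, b), val in sorted(pc.items()):
                    fh.write(f"PC\t{r}\t{a}\t{b}\t{float(val)!r}\n")


def read_graph_tsv(path):
    """Load a graph (and observations, if present) written by :func:`write_graph_tsv`.

    Returns ``(graph, observations_or_None)``.
    """
    region = None
    segments = []
    edges = {}
    seg_rows, intron_rows = {}, {}
    pair_rows = defaultdict(dict)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(f"#{_FORMAT_VERSION}"):
            raise ValueError(f"{path}: not a splicefit graph TSV (bad or missing version header)")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if line.startswith("#region"):
                region = Region(fields[1], int(fields[2]), int(fields[3]), fields[4])
            elif line.startswith("#"):
                continue
            elif fields[0] == "S":
                segments.append(
                    Segment(
                        region.chrom,
                        int(fields[2]),
                        int(fields[3]),
                        kind=fields[4],
                        is_initial=bool(int(fields[5])),
                        is_terminal=bool(int(fields[6])),
                    )
                )
            elif fields[0] == "E":
                edges[(int(fields[1]), int(fields[2]))] = set(fields[3].split(","))
            elif fields[0] == "VC":
                seg_rows[int(fields[1])] = [float(x) for x in fields[2:]]
            elif fields[0] == "IC":
                intron_rows[int(fields[1])] = [float(x) for x in fields[2:]]
            elif fields[0] == "PC":
                pair_rows[int(fields[1])][(int(fields[2]), int(fields[3]))] = float(fields[4])
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized record {fields[0]!r}")
    graph = SegmentGraph(region=region, segments=segments, edges=edges)
    obs = None
    if seg_rows:
        n_samples = max(seg_rows) + 1
        obs = ObservationSet(
            seg_counts=np.array([seg_rows[r] for r in range(n_samples)]),
            intron_counts=np.array(
                [intron_rows.get(r, [0.0] * len(graph.edge_list)) for r in range(n_samples)]
            ),
            pair_counts=[dict(pair_rows.get(r, {})) for r in range(n_samples)],
            seg_lengths=graph.seg_lengths,
        )
    return graph, obs
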