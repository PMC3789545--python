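"""Splicing-graph construction: boundaries, exon filter, edges, counts."""

import numpy as np
import pysam
import pytest

from splicefit.graph import (
    Boundary,
    PathEnumerationOverflow,
    Read,
    Region,
    Segment,
    SegmentGraph,
    add_intron_edges,
    build_graph,
    candidate_segments,
    count_observations,
    filter_exonic_segments,
    find_boundaries,
    junction_counts,
    per_base_coverage,
    read_graph_tsv,
    write_graph_tsv,
)
from splicefit.gtfio import Annotation, Transcript, read_gtf
from splicefit.toy import make_cassette_graph

REGION = Region("chr1", 0, 1000)


def _ann(*chains, strand="+"):
    ann = Annotation()
    for i, chain in enumerate(chains):
        ann.add(Transcript(f"tx{i + 1}", "g1", "chr1", strand, list(chain)))
    return ann


class TestFindBoundaries:
    def test_annotation_echo_two_exon_transcript(self):
        ann = _ann([(100, 200), (300, 400)])
        bounds = find_boundaries([], ann, REGION)
        by_pos = {b.pos: set(b.labels) for b in bounds}
        assert by_pos == {100: {"TSS"}, 200: {"SS"}, 300: {"SS"}, 400: {"TTS"}}

    def test_single_spliced_read_gap(self):
        reads = [Read("r1", "chr1", ((100, 150), (300, 350)))]
        bounds = find_boundaries([reads], None, REGION)
        ss = {b.pos for b in bounds if "SS" in b.labels}
        assert ss == {150, 300}

    def test_empty_region_gives_empty_list(self):
        assert find_boundaries([], _ann([(5, 9)]), Region("chr1", 50, 50)) == []

    def test_unknown_chromosome_named_in_error(self, cassette_fixture):
        sams, _, _ = cassette_fixture
        with pytest.raises(ValueError, match="chrMissing"):
            find_boundaries(list(sams), None, Region("chrMissing", 0, 100))

    def test_against_pileup_walk_oracle(self, cassette_fixture):
        """Island TSS/TTS edges equal the covered-run edges of an
        independently computed per-base pileup."""
        sams, _, _ = cassette_fixture
        region = Region("chrS", 0, 1000)
        depth = np.zeros(region.length, dtype=int)
        with pysam.AlignmentFile(sams[0]) as fh:
            for aln in fh:
                for pos in aln.get_reference_positions():
                    depth[pos] += 1
        runs = []
        in_run = False
        for pos, d in enumerate(depth):
            if d > 0 and not in_run:
                runs.append([pos, None])
                in_run = True
            elif d == 0 and in_run:
                runs[-1][1] = pos
                in_run = False
        if in_run:
            runs[-1][1] = region.length
        bounds = find_boundaries([sams[0]], None, region, min_island_gap=20)
        tss = {b.pos for b in bounds if "TSS" in b.labels}
        tts = {b.pos for b in bounds if "TTS" in b.labels}
        # runs separated by >= 20 zero bases must appear as island edges
        merged = [runs[0]]
        for lo, hi in runs[1:]:
            if lo - merged[-1][1] < 20:
                merged[-1][1] = hi
            else:
                merged.append([lo, hi])
        assert {lo for lo, _ in merged} <= tss
        assert {hi for _, hi in merged} <= tts


class TestExonFilter:
    def _cands(self):
        return [Segment("chr1", 0, 100), Segment("chr1", 100, 200), Segment("chr1", 200, 300)]

    def _coverage(self, covered_bases_mid):
        cov = np.zeros(1000, dtype=int)
        cov[0:100] = 1
        cov[100 : 100 + covered_bases_mid] = 1
        cov[200:300] = 1
        return cov

    def test_exactly_five_percent_dropped(self):
        kept = filter_exonic_segments(self._cands(), self._coverage(5), REGION)
        assert [s.start for s in kept] == [0, 200]

    def test_just_above_five_percent_kept(self):
        kept = filter_exonic_segments(self._cands(), self._coverage(6), REGION)
        assert [s.start for s in kept] == [0, 100, 200]

    def test_annotated_uncovered_segment_kept(self):
        ann = _ann([(100, 200)])
        kept = filter_exonic_segments(self._cands(), self._coverage(0), REGION, annotation=ann)
        assert [s.start for s in kept] == [0, 100, 200]

    def test_pair_bridge_segment_kept_by_connectivity(self):
        """An uncovered segment is kept when dropping it would disconnect
        two pair-linked segments (checked against a networkx oracle)."""
        import networkx as nx

        cands = self._cands()
        cov = self._coverage(0)
        kept = filter_exonic_segments(
            cands, cov, REGION, pair_links=[(0, 2)], junctions=()
        )
        assert [s.start for s in kept] == [0, 100, 200]

        # oracle: adjacency graph without the middle segment is disconnected
        g = nx.Graph()
        g.add_nodes_from([0, 2])
        assert not nx.has_path(g, 0, 2)
        g.add_node(1)
        g.add_edges_from([(0, 1), (1, 2)])
        assert nx.has_path(g, 0, 2)

    def test_pair_bridge_not_needed_when_junction_connects(self):
        # a junction 100->200 bypasses the uncovered middle: middle dropped
        kept = filter_exonic_segments(
            self._cands(), self._coverage(0), REGION,
            pair_links=[(0, 2)], junctions=[(100, 200)],
        )
        assert [s.start for s in kept] == [0, 200]


class TestIntronEdges:
    def test_cassette_toy_has_nine_edges(self, cassette3):
        assert len(cassette3.edges) == 9

    def test_annotation_only_edges_are_annotated_introns(self):
        ann = _ann([(100, 200), (300, 400)], [(100, 200), (500, 600)])
        region = Region("chr1", 0, 700)
        graph = build_graph([], ann, region)
        intron_edges = {
            (graph.segments[i].end, graph.segments[j].start)
            for (i, j), src in graph.edges.items()
            if "annotation" in src
        }
        assert intron_edges == {(200, 300), (200, 500)}

    def test_unmatched_junction_skipped_with_warning(self, caplog):
        segs = [Segment("chr1", 0, 100), Segment("chr1", 200, 300)]
        with caplog.at_level("WARNING"):
            graph = add_intron_edges(segs, junctions={(100, 200): 3, (100, 250): 1})
        assert (0, 1) in graph.edges
        assert len(graph.edges) == 1
        assert "does not match" in caplog.text

    def test_mixed_edges_equal_independent_junction_tally(self, cassette_fixture):
        sams, gtf, _ = cassette_fixture
        region = Region("chrS", 0, 1000)
        ann = read_gtf(gtf)
        graph = build_graph(list(sams), ann, region)
        # oracle: tally N-gaps straight from the SAM records
        tally = set()
        for sam in sams:
            with pysam.AlignmentFile(sam) as fh:
                for aln in fh:
                    blocks = aln.get_blocks()
                    for a, b in zip(blocks, blocks[1:]):
                        tally.add((a[1], b[0]))
        for tx in ann.transcripts.values():
            tally.update(tx.introns())
        built = {
            (graph.segments[i].end, graph.segments[j].start)
            for (i, j), src in graph.edges.items()
            if src - {"adjacency"}
        }
        assert built == tally


class TestCountObservations:
    def test_average_per_base_count(self):
        graph = SegmentGraph(
            region=Region("chr1", 0, 100),
            segments=[Segment("chr1", 0, 100, is_initial=True, is_terminal=True)],
        )
        reads = [Read(f"r{i}", "chr1", ((0, 50),)) for i in range(10)]
        obs = count_observations(graph, [reads])
        assert obs.seg_counts[0, 0] == pytest.approx(5.0)

    def test_no_spliced_reads_zero_intron_counts(self, cassette3):
        reads = [Read("r1", "toy", ((0, 50),))]
        obs = count_observations(cassette3, [reads])
        # junction support exists only for the adjacency edge spanned... a
        # read within segment 0 spans no boundary at all
        assert np.all(obs.intron_counts == 0)

    def test_empty_sample_gives_zero_row(self, cassette3):
        obs = count_observations(cassette3, [[], [Read("r", "toy", ((0, 700),))]])
        assert np.all(obs.seg_counts[0] == 0)
        assert np.all(obs.seg_counts[1] == 1.0)

    def test_against_pileup_oracle(self, cassette_fixture):
        """Segment counts equal per-base pileup sums computed through an
        independent pysam route (get_reference_positions)."""
        sams, gtf, _ = cassette_fixture
        region = Region("chrS", 0, 1000)
        graph = build_graph(list(sams), read_gtf(gtf), region)
        obs = count_observations(graph, list(sams))
        for r, sam in enumerate(sams):
            depth = np.zeros(region.length, dtype=int)
            with pysam.AlignmentFile(sam) as fh:
                for aln in fh:
                    for pos in aln.get_reference_positions():
                        depth[pos] += 1
            for s, seg in enumerate(graph.segments):
                expected = depth[seg.start : seg.end].sum() / seg.length
                assert obs.seg_counts[r, s] == pytest.approx(expected)

    def test_pair_counts_from_paired_fixture(self, tmp_path):
        from splicefit.simulate import FixtureSpec, make_fixture

        spec = FixtureSpec(
            chrom="chrS",
            transcripts=[[(100, 300), (600, 800)]],
            abundances=[[8.0]],
            paired=True,
            fragment_length=260,
            seed=11,
        )
        sams, gtf = make_fixture(spec, tmp_path)
        region = Region("chrS", 0, 1000)
        graph = build_graph(sams, read_gtf(gtf), region)
        obs = count_observations(graph, sams)
        # exon-spanning fragments must link a segment of the first exon
        # with a segment of the second
        def in_exon(idx, lo, hi):
            seg = graph.segments[idx]
            return lo <= seg.start and seg.end <= hi

        assert any(
            in_exon(a, 100, 300) and in_exon(b, 600, 800) for (a, b) in obs.pair_counts[0]
        )
        with pysam.AlignmentFile(sams[0]) as fh:
            n_fragments = len({aln.query_name for aln in fh})
        assert sum(obs.pair_counts[0].values()) >= n_fragments  # every mate pair linked


class TestEnumeratePaths:
    def test_three_cassettes_eight_paths(self, cassette3):
        assert len(cassette3.enumerate_paths()) == 8

    def test_linear_chain_single_path(self):
        graph = build_graph([], _ann([(100, 200), (300, 400), (500, 600)]), Region("chr1", 0, 700))
        paths = cassette3_paths = graph.enumerate_paths()
        assert len(paths) == 1
        assert paths[0].sum() == graph.n_segments

    def test_overflow_raises(self, cassette3):
        with pytest.raises(PathEnumerationOverflow):
            cassette3.enumerate_paths(limit=7)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_dag_count_matches_independent_dp(self, seed):
        """Enumerated path count equals a test-local dynamic program."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        segments = [
            Segment("chr1", 100 * i, 100 * i + 50,
                    is_initial=(i == 0 or rng.random() < 0.2),
                    is_terminal=(i == n - 1 or rng.random() < 0.2))
            for i in range(n)
        ]
        edges = {}
        for i in range(n - 1):
            edges[(i, i + 1)] = {"read"}
            for j in range(i + 2, n):
                if rng.random() < 0.3:
                    edges[(i, j)] = {"read"}
        graph = SegmentGraph(region=Region("chr1", 0, 100 * n), segments=segments, edges=edges)

        # oracle: topological DP over suffix counts
        n_paths_from = [0] * n
        for i in reversed(range(n)):
            total = 1 if segments[i].is_terminal else 0
            total += sum(n_paths_from[j] for (a, j) in edges if a == i)
            n_paths_from[i] = total
        expected = sum(n_paths_from[i] for i in range(n) if segments[i].is_initial)

        paths = graph.enumerate_paths(limit=100000)
        assert len(paths) == expected == graph.count_paths()
        validator = lambda u: graph.is_valid_path(u)
        assert all(validator(p) for p in paths)


class TestInvariants:
    def test_annotation_round_trip_reproduces_transcripts(self):
        """Annotation-only graph enumerates exactly the annotated intron
        chains (a cassette gene: no recombination possible)."""
        chains = [[(100, 300), (400, 500), (600, 800)], [(100, 300), (600, 800)]]
        ann = _ann(*chains)
        graph = build_graph([], ann, Region("chr1", 0, 900))
        paths = graph.enumerate_paths()

        def intron_chain(u):
            sel = np.flatnonzero(u)
            out = []
            for a, b in zip(sel, sel[1:]):
                gap = (graph.segments[a].end, graph.segments[b].start)
                if gap[0] != gap[1]:
                    out.append(gap)
            return tuple(out)

        enumerated = {intron_chain(p) for p in paths}
        annotated = {tuple(tx.introns()) for tx in ann.transcripts.values()}
        assert enumerated == annotated

    def test_adding_reads_never_removes_segments_or_edges(self, cassette_fixture):
        sams, gtf, _ = cassette_fixture
        ann = read_gtf(gtf)
        region = Region("chrS", 0, 1000)
        g_ann = build_graph([], ann, region)
        g_both = build_graph(list(sams), ann, region)
        segs_ann = {(s.start, s.end) for s in g_ann.segments}
        segs_both = set()
        for s in g_both.segments:
            segs_both.add((s.start, s.end))
        # every annotated segment interval is still covered (possibly split)
        for (a, b) in segs_ann:
            covered = sorted((s, e) for (s, e) in segs_both if s >= a and e <= b)
            assert covered and covered[0][0] == a and covered[-1][1] == b
        introns_ann = {
            (g_ann.segments[i].end, g_ann.segments[j].start)
            for (i, j), src in g_ann.edges.items() if src - {"adjacency"}
        }
        introns_both = {
            (g_both.segments[i].end, g_both.segments[j].start)
            for (i, j), src in g_both.edges.items() if src - {"adjacency"}
        }
        assert introns_ann <= introns_both


class TestGraphTsv:
    def test_round_trip_identity(self, cassette3, tmp_path):
        obs = count_observations(
            cassette3, [[Read("r1", "toy", ((0, 300),)), Read("r2", "toy", ((100, 150), (300, 400)))]]
        )
        path = tmp_path / "graph.tsv"
        write_graph_tsv(cassette3, path, obs)
        graph2, obs2 = read_graph_tsv(path)
        assert [(s.start, s.end, s.is_initial, s.is_terminal) for s in graph2.segments] == [
            (s.start, s.end, s.is_initial, s.is_terminal) for s in cassette3.segments
        ]
        assert graph2.edges == cassette3.edges
        np.testing.assert_array_equal(obs2.seg_counts, obs.seg_counts)
        np.testing.assert_array_equal(obs2.intron_counts, obs.intron_counts)
        assert obs2.pair_counts == obs.pair_counts

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("not a graph\n")
        with pytest.raises(ValueError, match="version header"):
            read_graph_tsv(path)
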