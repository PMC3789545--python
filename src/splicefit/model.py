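"""Model/Results facade over the graph, solver and test layers.

`TranscriptModel` bundles a splicing graph, its per-sample observed counts,
a count-loss model and the objective hyper-parameters; `fit()` runs the
joint selection/quantification and returns a `TranscriptResults` carrying
the transcript matrix, abundances, objective breakdown and the downstream
statistics (confidence, differential expression, GTF export, summary).
"""

from __future__ import annotations

import numpy as np

from . import gtfio
from .graph import ObservationSet, Region, SegmentGraph, build_graph, count_observations, read_graph_tsv
from .loss import LossModel
from .solver import HyperParams, SolveResult, TranscriptSet, solve_joint
from .stats import diff_expression_test, transcript_confidence


class TranscriptModel:
    """Joint transcript identification/quantification model for one locus.

    Parameters
    ----------
    graph : SegmentGraph
    observations : ObservationSet
        Per-sample segment/intron/pair counts on the graph.
    loss_model : LossModel, optional
        Defaults to the NB loss with shipped noise parameters.
    hyper : HyperParams, optional
    known : list of binary segment vectors, optional
        Annotated transcripts, charged a discounted sparsity price.
    """

    def __init__(self, graph, observations, loss_model=None, hyper=None, known=None):
        if observations.n_segments != graph.n_segments:
            raise ValueError("observations do not match the graph dimensions")
        self.graph = graph
        self.observations = observations
        self.loss_model = loss_model or LossModel()
        self.hyper = hyper or HyperParams()
        self.known = [np.asarray(r, dtype=np.int8) for r in (known or [])]

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_alignments(
        cls,
        sam_paths,
        region: Region,
        annotation=None,
        loss_model=None,
        hyper=None,
        use_annotation_as_known: bool = True,
        **graph_kw,
    ) -> "TranscriptModel":
        """Build graph and counts from one SAM/BAM per sample (and an
        optional :class:`~splicefit.gtfio.Annotation`)."""
        graph = build_graph(list(sam_paths), annotation, region, **graph_kw)
        obs = count_observations(graph, list(sam_paths))
        known = []
        if annotation is not None and use_annotation_as_known:
            known = [
                row
                for tx in annotation.overlapping(region)
                if (row := _transcript_to_row(tx, graph)) is not None
            ]
        return cls(graph, obs, loss_model, hyper, known)

    @classmethod
    def from_graph_file(cls, path, loss_model=None, hyper=None, known=None) -> "TranscriptModel":
        """Load a dumped graph TSV (with count sections) — the entry point
        for externally assembled graphs."""
        graph, obs = read_graph_tsv(path)
        if obs is None:
            raise ValueError(f"{path} carries no observation sections")
        return cls(graph, obs, loss_model, hyper, known)

    # -- fitting -----------------------------------------------------------
    def fit(self, mode: str = "exact", **solve_kw) -> "TranscriptResults":
        result = solve_joint(
            self.graph,
            self.observations,
            self.loss_model,
            self.hyper,
            known=self.known or None,
            mode=mode,
            **solve_kw,
        )
        return TranscriptResults(self, result)


def _transcript_to_row(tx, graph: SegmentGraph):
    """Binary segment vector of an annotated transcript, or None when the
    transcript does not map onto the graph as a valid path."""
    row = np.zeros(graph.n_segments, dtype=np.int8)
    for i, seg in enumerate(graph.segments):
        if any(ex[0] <= seg.start and seg.end <= ex[1] for ex in tx.exons):
            row[i] = 1
    return row if row.any() and graph.is_valid_path(row) else None


class TranscriptResults:
    """Fit results: selected transcripts, abundances, diagnostics."""

    def __init__(self, model: TranscriptModel, result: SolveResult):
        self.model = model
        self._result = result
        self.transcripts: TranscriptSet = result.transcripts
        self.abundances = result.abundances
        self.objective = result.objective
        self.status = result.status
        self.breakdown = result.breakdown
        self.n_nodes = result.n_nodes

    @property
    def k(self) -> int:
        return self.transcripts.k

    # -- statistics --------------------------------------------------------
    def confidence(self, df: int = None):
        """Likelihood-ratio confidence report (one row per transcript)."""
        return transcript_confidence(
            self.transcripts,
            self.model.observations,
            self.model.loss_model,
            w_intron=self.model.hyper.w_intron,
            df=df,
        )

    def diff_expression(self, sample_a: int = 0, sample_b: int = 1, subset=None):
        """Two-sample differential expression test; returns
        (statistic, df, p_value)."""
        obs2 = self.model.observations.subset_samples([sample_a, sample_b])
        return diff_expression_test(
            self.transcripts,
            obs2,
            self.model.loss_model,
            subset=subset,
            w_intron=self.model.hyper.w_intron,
        )

    # -- export ------------------------------------------------------------
    def to_transcripts(self, gene_id: str = "locus", p_values=None):
        """Selected rows as :class:`~splicefit.gtfio.Transcript` objects
        (exons = maximal runs of contiguous selected segments)."""
        graph = self.model.graph
        out = []
        c = self.abundances.c
        for t in range(self.k):
            row = self.transcripts.U[t]
            exons = []
            for i in np.flatnonzero(row):
                seg = graph.segments[i]
                if exons and exons[-1][1] == seg.start:
                    exons[-1] = (exons[-1][0], seg.end)
                else:
                    exons.append((seg.start, seg.end))
            attrs = {}
            for r in range(self.abundances.W.shape[1]):
                attrs[f"abundance_{r}"] = f"{c * self.abundances.W[t, r]:.4f}"
            if p_values is not None:
                attrs["conf_pvalue"] = f"{p_values[t]:.3e}"
            if len(exons) == 1:
                attrs["single_exon"] = "1"
            out.append(
                gtfio.Transcript(
                    transcript_id=f"{gene_id}.t{t + 1}",
                    gene_id=gene_id,
                    chrom=graph.region.chrom,
                    strand=graph.region.strand if graph.region.strand in "+-" else "+",
                    exons=exons,
                    attributes=attrs,
                )
            )
        return out

    def to_gtf(self, path, gene_id: str = "locus", with_confidence: bool = False) -> None:
        p_values = None
        if with_confidence and self.k:
            p_values = self.confidence()["p_value"].to_numpy()
        gtfio.write_gtf(self.to_transcripts(gene_id, p_values), path)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        model = self.model
        reg = model.graph.region
        lines = [
            "Transcript selection results",
            "=" * 64,
            f"Region:        {reg.chrom}:{reg.start}-{reg.end} ({reg.strand})",
            f"Segments:      {model.graph.n_segments}    Edges: {len(model.graph.edges)}",
            f"Samples:       {model.observations.n_samples}",
            f"Loss:          {model.loss_model.kind} "
            f"(alpha={model.loss_model.dispersion:g}, lambda_bg={model.loss_model.lambda_bg:g})",
            f"Status:        {self.status}    (B&B nodes: {self.n_nodes})",
            f"Objective:     {self.objective:.6g}",
            "  " + "  ".join(f"{key}={val:.4g}" for key, val in self.breakdown.items()),
            "-" * 64,
        ]
        header = f"{'transcript':<12}{'origin':<8}{'segments':<24}" + "".join(
            f"abund[{r}]".rjust(10) for r in range(model.observations.n_samples)
        )
        lines.append(header)
        c = self.abundances.c
        for t in range(self.k):
            segs = ",".join(str(i) for i in np.flatnonzero(self.transcripts.U[t]))
            abunds = "".join(
                f"{c * self.abundances.W[t, r]:>10.3f}"
                for r in range(model.observations.n_samples)
            )
            lines.append(
                f"{'t' + str(t + 1):<12}{self.transcripts.provenance[t]:<8}{segs:<24}" + abunds
            )
        if self.k == 0:
            lines.append("(no transcript selected)")
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<TranscriptResults k={self.k} objective={self.objective:.4g} "
            f"status={self.status}>"
        )
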