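"""GTF reading/writing and the annotation container.

GTF uses 1-based closed coordinates; everything internal is 0-based
half-open, so the shift happens exactly here.  Reading goes through
gffutils (in-memory database); writing is plain line formatting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list  # sorted (start, end) pairs, 0-based half-open
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self):
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    def intron_chain(self):
        return tuple(self.introns())


@dataclass
class Annotation:
    """Genes -> transcripts -> exon chains."""

    transcripts: dict = field(default_factory=dict)  # transcript_id -> Transcript

    @property
    def genes(self) -> dict:
        by_gene: dict = {}
        for tx in self.transcripts.values():
            by_gene.setdefault(tx.gene_id, []).append(tx.transcript_id)
        return by_gene

    def add(self, tx: Transcript) -> None:
        self.transcripts[tx.transcript_id] = tx

    def overlapping(self, region):
        """Transcripts intersecting ``region`` (strand-matched when both
        strands are definite)."""
        out = []
        for tx in self.transcripts.values():
            if tx.chrom != region.chrom:
                continue
            if tx.end <= region.start or tx.start >= region.end:
                continue
            if region.strand in "+-" and tx.strand in "+-" and tx.strand != region.strand:
                continue
            out.append(tx)
        return sorted(out, key=lambda t: (t.start, t.transcript_id))


def _validate_gtf_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line (expected 9 fields)")
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc


def read_gtf(path) -> Annotation:
    """Parse exon features into an :class:`Annotation`.

    Coordinates are converted from GTF (1-based closed) to internal
    0-based half-open.  Exon records without a transcript_id are skipped
    with a warning; malformed lines raise with the line number.
    """
    import gffutils

    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    ann = Annotation()
    groups: dict = {}
    extras: dict = {}
    for feat in db.features_of_type("exon"):
        tid = (feat.attributes.get("transcript_id") or [None])[0]
        if tid is None:
            logger.warning("%s: exon at %s:%d-%d lacks transcript_id; skipped",
                           path, feat.seqid, feat.start, feat.end)
            continue
        gid = (feat.attributes.get("gene_id") or [tid])[0]
        key = (tid, gid, feat.seqid, feat.strand or ".")
        groups.setdefault(key, []).append((feat.start - 1, feat.end))
        extras.setdefault(tid, {}).update(
            {
                k: vals[0]
                for k, vals in feat.attributes.items()
                if k not in ("transcript_id", "gene_id") and vals
            }
        )
    for (tid, gid, chrom, strand), exons in groups.items():
        ann.add(Transcript(tid, gid, chrom, strand, exons, attributes=extras.get(tid, {})))
    return ann


def write_gtf(transcripts, path, source: str = "splicefit") -> None:
    """Write transcripts (``Transcript`` objects, possibly carrying
    abundance/p-value attributes) as GTF exon + transcript features."""
    with open(path, "w") as fh:
        for tx in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            attrs = {"gene_id": tx.gene_id, "transcript_id": tx.transcript_id}
            attrs.update(tx.attributes)
            attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
            fh.write(
                "\t".join(
                    [
                        tx.chrom,
                        source,
                        "transcript",
                        str(tx.start + 1),
                        str(tx.end),
                        ".",
                        tx.strand,
                        ".",
                        attr_str,
                    ]
                )
                + "\n"
            )
            for (ex_start, ex_end) in tx.exons:
                fh.write(
                    "\t".join(
                        [
                            tx.chrom,
                            source,
                            "exon",
                            str(ex_start + 1),
                            str(ex_end),
                            ".",
                            tx.strand,
                            ".",
                            attr_str,
                        ]
                    )
                    + "\n"
                )
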