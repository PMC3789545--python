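"""Synthetic read/annotation fixtures for testing and demonstration.

Generates deterministic (seeded) SAM and GTF files for planted
transcripts: fragment counts are drawn per transcript and sample with NB
overdispersion matching a :class:`~splicefit.loss.LossModel`, fragment
start positions are uniform along the transcript, and reads crossing
introns get N operations in their CIGAR.  This emulates uniform
(bias-free) sampling from a known transcriptome at desk scale; it does
not model positional/sequence biases, indels or mapping errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .gtfio import Transcript, write_gtf
from .loss import LossModel

logger = logging.getLogger(__name__)


@dataclass
class FixtureSpec:
    """Planted locus: transcripts (exon chains), per-sample abundances
    (expected per-base coverage), read geometry and noise."""

    chrom: str
    transcripts: list  # list of exon-chain lists [(start, end), ...]
    abundances: np.ndarray  # (n_samples, n_transcripts) expected coverage
    read_length: int = 50
    paired: bool = False
    fragment_length: int = 160
    dispersion: float = 0.0  # NB alpha on fragment counts; 0 = Poisson-free
    seed: int = 0
    chrom_length: int = field(default=None)

    def __post_init__(self):
        self.abundances = np.atleast_2d(np.asarray(self.abundances, dtype=float))
        if self.chrom_length is None:
            self.chrom_length = max(ex[1] for chain in self.transcripts for ex in chain) + 1000


def _transcript_length(chain) -> int:
    return sum(e - s for s, e in chain)


def _to_genomic_blocks(chain, tx_start: int, tx_end: int):
    """Map a transcript-coordinate interval onto genomic blocks."""
    blocks = []
    offset = 0
    for (g_start, g_end) in chain:
        seg_len = g_end - g_start
        lo = max(tx_start - offset, 0)
        hi = min(tx_end - offset, seg_len)
        if hi > lo:
            blocks.append((g_start + lo, g_start + hi))
        offset += seg_len
    return blocks


def _cigar_from_blocks(blocks):
    parts = []
    for i, (b_start, b_end) in enumerate(blocks):
        if i > 0:
            parts.append(f"{b_start - blocks[i - 1][1]}N")
        parts.append(f"{b_end - b_start}M")
    return "".join(parts)


def make_fixture(spec: FixtureSpec, out_dir):
    """Write ``sample_<r>.sam`` per sample plus ``annotation.gtf``.

    Returns ``(sam_paths, gtf_path)``.  Reads are coordinate-sorted;
    regeneration with the same spec (same seed) is byte-identical.
    Transcripts shorter than the read length are skipped with a warning.
    """
    import os

    import pysam

    rng = np.random.default_rng(spec.seed)
    os.makedirs(out_dir, exist_ok=True)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": spec.chrom, "LN": int(spec.chrom_length)}],
    }
    n_samples, n_tx = spec.abundances.shape
    sam_paths = []
    for r in range(n_samples):
        records = []
        for t, chain in enumerate(spec.transcripts):
            tx_len = _transcript_length(chain)
            span = spec.fragment_length if spec.paired else spec.read_length
            if tx_len < span:
                warnings.warn(
                    f"transcript {t} (length {tx_len}) shorter than {span}; skipped",
                    stacklevel=2,
                )
                continue
            # expected fragments so that *interior* per-base coverage ~=
            # abundance: starts are uniform over tx_len - span + 1 positions
            bases_per_frag = 2 * spec.read_length if spec.paired else spec.read_length
            mean_frags = spec.abundances[r, t] * (tx_len - span + 1) / bases_per_frag
            if spec.dispersion > 0 and mean_frags > 0:
                n_nb = mean_frags / (spec.dispersion * mean_frags + 1e-300)
                p_nb = 1.0 / (1.0 + spec.dispersion * mean_frags)
                n_frags = int(rng.negative_binomial(max(n_nb, 1e-9), min(max(p_nb, 1e-12), 1.0)))
            else:
                n_frags = int(round(mean_frags))
            if n_frags == 0:
                continue
            starts = rng.integers(0, tx_len - span + 1, size=n_frags)
            for i, f_start in enumerate(sorted(starts)):
                name = f"s{r}_t{t}_f{i}"
                if spec.paired:
                    b1 = _to_genomic_blocks(chain, f_start, f_start + spec.read_length)
                    b2 = _to_genomic_blocks(
                        chain, f_start + spec.fragment_length - spec.read_length,
                        f_start + spec.fragment_length,
                    )
                    records.append((name, b1, b2, True))
                else:
                    b1 = _to_genomic_blocks(chain, f_start, f_start + spec.read_length)
                    records.append((name, b1, None, False))

        path = os.path.join(out_dir, f"sample_{r}.sam")
        sam_paths.append(path)
        with pysam.AlignmentFile(path, "wh", header=header) as out:
            flat = []
            for name, b1, b2, paired in records:
                if paired:
                    flat.append((b1[0][0], name, b1, 99, b2[0][0]))
                    flat.append((b2[0][0], name, b2, 147, b1[0][0]))
                else:
                    flat.append((b1[0][0], name, b1, 0, None))
            for pos, name, blocks, flag, mate_pos in sorted(flat, key=lambda x: (x[0], x[1], x[3])):
                aln = pysam.AlignedSegment()
                aln.query_name = name
                aln.reference_id = 0
                aln.reference_start = pos
                aln.flag = flag
                aln.mapping_quality = 60
                aln.cigarstring = _cigar_from_blocks(blocks)
                seq_len = sum(b_end - b_start for b_start, b_end in blocks)
                aln.query_sequence = "".join(
                    "ACGT"[b] for b in rng.integers(0, 4, size=seq_len)
                )
                if mate_pos is not None:
                    aln.next_reference_id = 0
                    aln.next_reference_start = mate_pos
                    tlen = (
                        max(blocks[-1][1], mate_pos + spec.read_length)
                        - min(pos, mate_pos)
                    )
                    aln.template_length = tlen if flag == 99 else -tlen
                out.write(aln)

    gtf_path = os.path.join(out_dir, "annotation.gtf")
    write_gtf(
        [
            Transcript(f"tx{t + 1}", "gene1", spec.chrom, "+", chain)
            for t, chain in enumerate(spec.transcripts)
        ],
        gtf_path,
    )
    return sam_paths, gtf_path
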