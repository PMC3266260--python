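"""Sequence-level primitives: splicing, intron extraction, ORFs, translation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from Bio.Seq import Seq

from .models import GenomicInterval, Intron, TranscriptModel

__all__ = [
    "spliced_sequence",
    "get_introns",
    "find_orfs",
    "translate",
    "ORF",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


def _fetch(genome: Mapping[str, str], iv: GenomicInterval) -> str:
    try:
        chrom_seq = genome[iv.chrom]
    except KeyError as exc:
        raise KeyError(f"unknown chromosome {iv.chrom!r}") from exc
    if iv.end > len(chrom_seq):
        raise ValueError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} outside chromosome "
            f"bounds (length {len(chrom_seq)})"
        )
    return chrom_seq[iv.start : iv.end]


def spliced_sequence(
    transcript: TranscriptModel, genome: Mapping[str, str], cds_only: bool = False
) -> str:
    """Concatenated exon (or CDS) sequence in transcription order.

    Minus-strand transcripts are reverse-complemented so the result always
    reads 5'->3' of the mature transcript.
    """
    parts = transcript.cds if cds_only else transcript.exons
    pieces = []
    for iv in parts:
        seg = _fetch(genome, iv)
        if iv.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        pieces.append(seg)
    return "".join(pieces)


def get_introns(transcript: TranscriptModel) -> list[Intron]:
    """Introns between consecutive exons, with CDS phase where defined.

    The phase of an intron is the number of coding nucleotides upstream of
    the junction modulo 3 (on the coding strand); ``protein_position`` is the
    0-based index of the interrupted codon.  Both are ``None`` for introns
    lying outside the CDS.
    """
    introns: list[Intron] = []
    exons = transcript.exons
    minus = transcript.strand == "-"
    # genomic CDS extent for "inside the CDS" test
    if transcript.cds:
        cds_start = min(c.start for c in transcript.cds)
        cds_end = max(c.end for c in transcript.cds)
    else:
        cds_start = cds_end = None
    for idx, (up, down) in enumerate(zip(exons, exons[1:])):
        if minus:
            g_start, g_end = down.end, up.start
        else:
            g_start, g_end = up.end, down.start
        iv = GenomicInterval(transcript.chrom, g_start, g_end, transcript.strand)
        phase = position = None
        if transcript.cds and cds_start < g_start and g_end < cds_end:
            upstream_nt = _cds_nt_upstream(transcript, iv)
            phase = upstream_nt % 3
            position = upstream_nt // 3
        introns.append(
            Intron(
                interval=iv,
                index=idx,
                transcript_id=transcript.transcript_id,
                phase=phase,
                protein_position=position,
            )
        )
    return introns


def _cds_nt_upstream(transcript: TranscriptModel, intron: GenomicInterval) -> int:
    """Coding nucleotides 5' of an intron, counted on the coding strand."""
    total = 0
    for c in transcript.cds:  # transcription order
        if transcript.strand == "+":
            if c.end <= intron.start:
                total += len(c)
        else:
            if c.start >= intron.end:
                total += len(c)
    return total


@dataclass(frozen=True)
class ORF:
    """An ATG-initiated open reading frame on a spliced transcript.

    ``start``/``end`` are 0-based half-open transcript coordinates; ``end``
    includes the stop codon when ``complete``.  ``aa_length`` excludes the
    stop.
    """

    start: int
    end: int
    frame: int
    complete: bool

    @property
    def aa_length(self) -> int:
        n = (self.end - self.start) // 3
        return n - 1 if self.complete else n

    @property
    def stop_start(self) -> Optional[int]:
        """Transcript coordinate of the first base of the stop codon."""
        return self.end - 3 if self.complete else None


def find_orfs(mrna_seq: str, min_aa: int = 30) -> list[ORF]:
    """All ATG-initiated ORFs encoding at least ``min_aa`` residues.

    An ORF runs from an ATG to the first in-frame stop; if no stop is found
    it runs to the end of the last complete codon and is flagged incomplete.
    ORFs are reported longest first, ties broken by 5'-most start.
    """
    seq = mrna_seq.upper()
    n = len(seq)
    orfs: list[ORF] = []
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        pos = start + 3
        complete = False
        while pos + 3 <= n:
            if seq[pos : pos + 3] in STOP_CODONS:
                pos += 3
                complete = True
                break
            pos += 3
        orf = ORF(start=start, end=pos, frame=start % 3, complete=complete)
        if orf.aa_length >= min_aa:
            orfs.append(orf)
    orfs.sort(key=lambda o: (-o.aa_length, o.start))
    return orfs


def translate(nt_seq: str) -> str:
    """Standard-code translation; trailing stop stripped, internal stop raises.

    Ambiguous bases (N) translate to X.
    """
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} not divisible by 3")
    if not nt_seq:
        return ""
    aa = str(Seq(nt_seq.upper()).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(f"internal stop codon at residue {aa.index('*') + 1}")
    return aa
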