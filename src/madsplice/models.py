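"""Core data structures for gene models, protein isoforms and configuration.

Coordinate conventions used throughout the package:

* genomic coordinates are 0-based half-open (``start`` inclusive, ``end``
  exclusive) on the forward strand of the chromosome;
* GFF3 input/output is converted from/to 1-based inclusive at the I/O layer;
* protein coordinates are 1-based inclusive residue intervals.

Exons of a transcript are stored in *transcription order*: for a minus-strand
transcript the first exon in the list is the one with the highest genomic
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "Intron",
    "ProteinIsoform",
    "DomainAnnotation",
    "PipelineConfig",
    "Locus",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware interval on a chromosome (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one nucleotide."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """One transcript isoform: exon (and optionally CDS) structure on a genome.

    ``exons`` and ``cds`` are kept in transcription order and must lie on a
    single chromosome and strand.  CDS intervals must be nested inside exons.
    """

    transcript_id: str
    locus_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons} | {c.chrom for c in self.cds}
        strands = {e.strand for e in self.exons} | {c.strand for c in self.cds}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons/CDS span multiple chroms/strands"
            )
        self.exons = _sort_transcription_order(self.exons)
        self.cds = _sort_transcription_order(self.cds)
        _check_non_overlapping(self.exons, self.transcript_id, "exon")
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS {c.start}-{c.end} not nested "
                    "in any exon"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)


def _sort_transcription_order(
    intervals: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    if not intervals:
        return []
    reverse = intervals[0].strand == "-"
    return sorted(intervals, key=lambda iv: iv.start, reverse=reverse)


def _check_non_overlapping(
    intervals: Sequence[GenomicInterval], tid: str, what: str
) -> None:
    by_start = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(by_start, by_start[1:]):
        if a.end > b.start:
            raise ValueError(f"{tid}: overlapping {what}s {a} / {b}")


@dataclass(frozen=True)
class Intron:
    """An intron between two consecutive exons of one transcript.

    ``phase`` is the codon offset of the intron within the CDS (0, 1 or 2
    coding nucleotides into the interrupted codon), or ``None`` when the
    intron lies outside the CDS.  ``protein_position`` is the 0-based index
    of the interrupted codon (for phase 0, the index of the first codon
    downstream of the junction).
    """

    interval: GenomicInterval
    index: int
    transcript_id: str
    phase: Optional[int] = None
    protein_position: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class ProteinIsoform:
    """A translated isoform, with the ORF's transcript-level coordinates."""

    protein_id: str
    transcript_id: str
    sequence: str
    orf_tx_start: int
    orf_tx_end: int

    def __post_init__(self) -> None:
        expected = (self.orf_tx_end - self.orf_tx_start) // 3 - 1
        if len(self.sequence) != expected:
            raise ValueError(
                f"{self.protein_id}: sequence length {len(self.sequence)} "
                f"inconsistent with ORF span ({expected} expected)"
            )
        if "*" in self.sequence:
            raise ValueError(f"{self.protein_id}: internal stop in sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueInterval:
    """1-based inclusive residue interval in protein coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid residue interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "ResidueInterval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class DomainAnnotation:
    """M/I/K/C domain boundaries of one MIKC protein (1-based inclusive).

    ``kbox_cterm`` marks the C-terminal sub-region of the K-box implicated in
    higher-order complex formation (K3 helix); by default the distal half of
    the K interval.
    """

    protein_id: str
    m: ResidueInterval
    i: ResidueInterval
    k: ResidueInterval
    c: ResidueInterval
    kbox_cterm: Optional[ResidueInterval] = None

    def __post_init__(self) -> None:
        order = [self.m, self.i, self.k, self.c]
        for a, b in zip(order, order[1:]):
            if a.end >= b.start:
                raise ValueError(
                    f"{self.protein_id}: domain intervals out of order/overlap"
                )
        if self.kbox_cterm is None:
            mid = (self.k.start + self.k.end) // 2
            object.__setattr__(
                self, "kbox_cterm", ResidueInterval(mid + 1, self.k.end)
            )
        kc = self.kbox_cterm
        if not (self.k.start <= kc.start and kc.end <= self.k.end):
            raise ValueError(f"{self.protein_id}: kbox_cterm not inside K")

    def labelled(self) -> list[tuple[str, ResidueInterval]]:
        return [("M", self.m), ("I", self.i), ("K", self.k), ("C", self.c)]

    def shifted(self, **kwargs) -> "DomainAnnotation":
        return replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """Tunable thresholds of the analysis (defaults are the published rules).

    * ``nmd_distance_nt``: a premature stop more than this many nt upstream
      of the last exon-exon junction flags an NMD target.
    * ``homolog_min_identity_pct`` / ``homolog_min_coverage_pct``: best-hit
      filter for cross-species homolog assignment.
    * ``aip_conservation_min_similarity_pct``: global-alignment similarity
      required to call an AS-induced polymorphism conserved.
    * ``flank_window_cols`` / ``flank_min_identical`` / ``flank_max_gapped``:
      quality rule on the alignment columns flanking a candidate AIP.
    * ``anchor_window_aa``: half-width of the gapless window required around
      the intron position in the isoform-to-reference alignment.
    """

    nmd_distance_nt: int = 55
    homolog_min_identity_pct: float = 40.0
    homolog_min_coverage_pct: float = 60.0
    aip_conservation_min_similarity_pct: float = 40.0
    flank_window_cols: int = 10
    flank_min_identical: int = 4
    flank_max_gapped: int = 1
    anchor_window_aa: int = 5
    aip_position_tolerance_aa: int = 3
    min_orf_aa: int = 30
    domain_transfer_min_identity_pct: float = 40.0
    # alignment scoring
    protein_matrix: str = "BLOSUM62"
    protein_gap_open: float = 10.0
    protein_gap_extend: float = 0.5
    nt_match: float = 5.0
    nt_mismatch: float = -4.0
    nt_gap_open: float = 10.0
    nt_gap_extend: float = 0.5
    exonization_min_score: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "homolog_min_identity_pct",
            "homolog_min_coverage_pct",
            "aip_conservation_min_similarity_pct",
            "domain_transfer_min_identity_pct",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        for name in (
            "nmd_distance_nt",
            "flank_window_cols",
            "flank_min_identical",
            "flank_max_gapped",
            "anchor_window_aa",
            "min_orf_aa",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Locus:
    """A gene with one or more transcript isoforms."""

    locus_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    def get(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)
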