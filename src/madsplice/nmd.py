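"""Nonsense-mediated decay classification under the 55-nt junction rule.

A transcript is a candidate NMD target when its stop codon lies more than
``nmd_distance_nt`` (default 55) nucleotides upstream of the last exon-exon
junction of the spliced transcript.  The distance is anchored at the first
base of the stop codon.  A target whose downstream ATG-initiated ORF escapes
the rule is called ambiguous: it may be degraded, or translated from the
downstream start instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .models import PipelineConfig, TranscriptModel
from .sequence import ORF, find_orfs, spliced_sequence

__all__ = ["NMDVerdict", "last_junction_tx_coord", "classify_nmd"]

CODING = "coding"
NMD_TARGET = "nmd_target"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class NMDVerdict:
    transcript_id: str
    status: str
    ptc_tx_pos: Optional[int]  # transcript coordinate of the stop codon start
    distance_to_last_junction: Optional[int]  # positive = stop upstream
    no_orf: bool = False


def last_junction_tx_coord(transcript: TranscriptModel) -> Optional[int]:
    """Spliced-transcript coordinate of the last exon-exon junction.

    ``None`` for single-exon transcripts.
    """
    if transcript.exon_count < 2:
        return None
    return sum(len(e) for e in transcript.exons[:-1])


def classify_nmd(
    transcript: TranscriptModel,
    genome: Optional[Mapping[str, str]] = None,
    orf: Optional[ORF] = None,
    all_orfs: Optional[Sequence[ORF]] = None,
    config: PipelineConfig | None = None,
) -> NMDVerdict:
    """Classify a transcript as coding, NMD target, or ambiguous.

    The evaluated ORF defaults to the longest ATG-initiated ORF of the
    spliced sequence.  Status is ``nmd_target`` iff the stop codon starts
    strictly more than the configured distance upstream of the last
    junction; it is downgraded to ``ambiguous`` when a downstream ATG ORF of
    at least ``min_orf_aa`` residues escapes the rule (possible re-initiation).
    """
    config = config or PipelineConfig()
    if orf is None or all_orfs is None:
        if genome is None:
            raise ValueError("need genome to derive ORFs, or pass them in")
        seq = spliced_sequence(transcript, genome)
        found = find_orfs(seq, config.min_orf_aa)
        all_orfs = found if all_orfs is None else all_orfs
        orf = orf or (found[0] if found else None)
    if orf is None:
        return NMDVerdict(
            transcript.transcript_id, AMBIGUOUS, None, None, no_orf=True
        )

    junction = last_junction_tx_coord(transcript)
    stop = orf.stop_start
    if junction is None or stop is None:
        # single-exon transcripts are never NMD; an ORF running off the end
        # has its stop downstream of every junction
        distance = None if junction is None or stop is None else junction - stop
        return NMDVerdict(transcript.transcript_id, CODING, stop, distance)

    distance = junction - stop
    if distance <= config.nmd_distance_nt:
        return NMDVerdict(transcript.transcript_id, CODING, stop, distance)

    # candidate target -- check for a rescuing downstream start
    for other in all_orfs or ():
        if other.start <= orf.start or other.aa_length < config.min_orf_aa:
            continue
        other_stop = other.stop_start
        if other_stop is None or junction - other_stop <= config.nmd_distance_nt:
            return NMDVerdict(transcript.transcript_id, AMBIGUOUS, stop, distance)
    return NMDVerdict(transcript.transcript_id, NMD_TARGET, stop, distance)
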