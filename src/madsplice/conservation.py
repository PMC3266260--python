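"""Cross-species conservation of AS-induced polymorphisms (AIPs).

The workflow mirrors a desk-scale homology pipeline: translate transcript
contigs in six frames, assign each fragment to its best reference (MIKC)
protein under identity/coverage thresholds, transfer intron positions onto
the homolog by global alignment, then look for indels between isoforms that
coincide with intron positions (AIPs) and test whether homologous AIPs in
other species are similar enough to call the polymorphism conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .align import PairwiseAlignmentView, align_global, align_local
from .models import Intron, PipelineConfig

__all__ = [
    "TranslatedFragment",
    "HomologHit",
    "IntronPositionMap",
    "AIP",
    "AIPConservation",
    "ExonizationReport",
    "six_frame_orfs",
    "best_homolog",
    "map_intron_positions",
    "detect_aips",
    "isoform_pair_aips",
    "call_conservation",
    "exonization_scan",
]


@dataclass(frozen=True)
class TranslatedFragment:
    """A stop-to-stop ORF from six-frame translation of a contig."""

    contig_id: str
    species: str
    frame: int  # +1..+3 forward, -1..-3 reverse
    nt_start: int  # forward-strand contig coordinates, 0-based half-open
    nt_end: int
    peptide: str


@dataclass(frozen=True)
class HomologHit:
    fragment: TranslatedFragment
    protein_id: str
    identity_pct: float
    coverage_pct: float
    score: float


@dataclass(frozen=True)
class MappedIntron:
    """One reference intron position transferred onto a subject protein."""

    intron_index: int
    subject_residue: Optional[int]  # 0-based, None when unmapped
    phase: Optional[int]
    mapped: bool
    gapless_window: bool = False


@dataclass
class IntronPositionMap:
    subject_id: str
    reference_id: str
    entries: list[MappedIntron] = field(default_factory=list)

    def mapped_positions(self) -> list[MappedIntron]:
        return [e for e in self.entries if e.mapped]


@dataclass
class AIP:
    """An indel between two isoforms coinciding with an intron position."""

    isoform_long: str
    isoform_short: str
    intron_index: int
    indel_peptide: str
    region_start_long: int  # 0-based residue on the longer isoform
    flank_identical: int
    flank_gapped: int
    passes_flank_rule: bool
    gapless_anchor: bool
    carrier_sequence: str = ""  # full sequence of the longer isoform


@dataclass(frozen=True)
class AIPConservation:
    query: AIP
    subject: AIP
    similarity_pct: float
    conserved: bool


def six_frame_orfs(
    contig: str,
    min_orf_aa: int = 30,
    contig_id: str = "contig",
    species: str = "unknown",
) -> list[TranslatedFragment]:
    """All stop-to-stop ORFs of at least ``min_orf_aa`` residues, six frames."""
    contig = contig.upper()
    n = len(contig)
    fragments: list[TranslatedFragment] = []
    for strand in (+1, -1):
        seq = contig if strand == 1 else str(Seq(contig).reverse_complement())
        for offset in range(3):
            usable = (n - offset) // 3 * 3
            if usable <= 0:
                continue
            peptide = str(Seq(seq[offset : offset + usable]).translate())
            start_aa = 0
            for segment in peptide.split("*"):
                if len(segment) >= min_orf_aa and "X" * len(segment) != segment:
                    s = offset + 3 * start_aa
                    e = s + 3 * len(segment)
                    if strand == 1:
                        nt_start, nt_end = s, e
                    else:
                        nt_start, nt_end = n - e, n - s
                    fragments.append(
                        TranslatedFragment(
                            contig_id=contig_id,
                            species=species,
                            frame=strand * (offset + 1),
                            nt_start=nt_start,
                            nt_end=nt_end,
                            peptide=segment,
                        )
                    )
                start_aa += len(segment) + 1
    return fragments


def best_homolog(
    fragment: TranslatedFragment,
    reference_proteome: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> Optional[HomologHit]:
    """Best local-alignment hit of a fragment against the reference proteome.

    The highest-scoring reference wins (ties by identity, then id); the hit
    is returned only when identity and reference coverage pass the
    configured thresholds.
    """
    config = config or PipelineConfig()
    if not reference_proteome:
        return None
    best: Optional[tuple[float, float, str, PairwiseAlignmentView]] = None
    for pid in sorted(reference_proteome):
        ref = reference_proteome[pid]
        view = align_local(fragment.peptide, ref, config)
        identity = view.identity_pct()
        key = (view.score, identity)
        if best is None or key > (best[0], best[1]):
            best = (view.score, identity, pid, view)
    score, identity, pid, view = best
    ref_len = len(reference_proteome[pid])
    covered = sum(1 for c in range(view.n_columns) if view.b_idx[c] >= 0)
    coverage = 100.0 * covered / ref_len if ref_len else 0.0
    if identity < config.homolog_min_identity_pct:
        return None
    if coverage < config.homolog_min_coverage_pct:
        return None
    return HomologHit(
        fragment=fragment,
        protein_id=pid,
        identity_pct=identity,
        coverage_pct=coverage,
        score=score,
    )


def _reference_residue(intron: Intron) -> Optional[int]:
    """0-based reference residue anchoring an intron position.

    For phase-1/2 introns this is the interrupted codon; for phase 0 the
    first codon downstream of the junction.
    """
    return intron.protein_position


def map_intron_positions(
    subject_protein: str,
    reference_protein: str,
    reference_introns: Sequence[Intron],
    config: PipelineConfig | None = None,
    subject_id: str = "subject",
    reference_id: str = "reference",
) -> IntronPositionMap:
    """Transfer reference intron positions to a subject by global alignment.

    Positions falling on columns where the subject is gapped are flagged
    unmapped; an alignment below the homolog identity threshold leaves all
    positions unmapped.  Each mapped entry also records whether the
    alignment is gap-free within +/- ``anchor_window_aa`` residues of the
    position (the anchor requirement for AIP detection).
    """
    config = config or PipelineConfig()
    view = align_global(reference_protein, subject_protein, config)
    usable = view.identity_pct() >= config.homolog_min_identity_pct
    out = IntronPositionMap(subject_id=subject_id, reference_id=reference_id)
    for intron in reference_introns:
        r = _reference_residue(intron)
        if r is None or not usable or r >= len(reference_protein):
            out.entries.append(
                MappedIntron(intron.index, None, intron.phase, False)
            )
            continue
        subject_residue = view.map_a_to_b(r)
        if subject_residue is None:
            out.entries.append(
                MappedIntron(intron.index, None, intron.phase, False)
            )
            continue
        w = config.anchor_window_aa
        lo = max(0, r - w)
        hi = min(len(reference_protein) - 1, r + w)
        cols = range(view.a_to_column(lo), view.a_to_column(hi) + 1)
        gapless = all(not view.is_gap(c) for c in cols)
        out.entries.append(
            MappedIntron(
                intron.index, subject_residue, intron.phase, True, gapless
            )
        )
    return out


def _gap_runs(view: PairwiseAlignmentView) -> list[tuple[int, int, str]]:
    """Maximal runs of columns gapped in exactly one sequence.

    Returns (start_col, end_col_exclusive, gapped_side) with side 'a' or 'b'.
    """
    runs = []
    col = 0
    n = view.n_columns
    while col < n:
        ai, bi = view.a_idx[col], view.b_idx[col]
        side = "a" if ai < 0 else ("b" if bi < 0 else None)
        if side is None:
            col += 1
            continue
        start = col
        while col < n and (view.a_idx[col] < 0 if side == "a" else view.b_idx[col] < 0):
            col += 1
        runs.append((start, col, side))
    return runs


def detect_aips(
    isoform_a: tuple[str, str],
    isoform_b: tuple[str, str],
    intron_maps: IntronPositionMap | Sequence[IntronPositionMap],
    config: PipelineConfig | None = None,
    keep_rejected: bool = False,
) -> list[AIP]:
    """Indels between two isoforms that coincide with mapped intron positions.

    ``isoform_a``/``isoform_b`` are ``(id, sequence)`` pairs; the intron
    maps give intron positions on isoform-a coordinates (one map per
    available reference alignment; the gapless-anchor requirement is met if
    any map is gap-free around the position).  A candidate is kept when the
    ten alignment columns flanking the polymorphic region contain at least
    ``flank_min_identical`` identical residue pairs and at most
    ``flank_max_gapped`` gapped positions, and the anchor holds.
    """
    config = config or PipelineConfig()
    id_a, seq_a = isoform_a
    id_b, seq_b = isoform_b
    if not seq_a or not seq_b:
        raise ValueError("empty isoform sequence")
    maps = (
        [intron_maps]
        if isinstance(intron_maps, IntronPositionMap)
        else list(intron_maps)
    )
    view = align_global(seq_a, seq_b, config)

    # alignment column of each mapped intron position; a map whose subject id
    # matches isoform b is interpreted in b coordinates, otherwise a.  The
    # gapless-anchor requirement is met if ANY isoform's reference alignment
    # is gap-free around the position.
    intron_cols: dict[int, list[int]] = {}
    anchor_ok: dict[int, bool] = {}
    for m in maps:
        on_b = m.subject_id == id_b and id_b != id_a
        seq_len = len(seq_b) if on_b else len(seq_a)
        for entry in m.mapped_positions():
            if entry.subject_residue is None or entry.subject_residue >= seq_len:
                continue
            col = (
                view.b_to_column(entry.subject_residue)
                if on_b
                else view.a_to_column(entry.subject_residue)
            )
            intron_cols.setdefault(entry.intron_index, []).append(col)
            anchor_ok[entry.intron_index] = (
                anchor_ok.get(entry.intron_index, False) or entry.gapless_window
            )

    half = config.flank_window_cols // 2
    tol = config.aip_position_tolerance_aa
    aips: list[AIP] = []
    for start, end, side in _gap_runs(view):
        # gap placement is ambiguous up to local repeats, so the intron
        # column may sit a few columns outside the run
        hit = None
        for intron_index, cols in intron_cols.items():
            if any(start - 1 - tol <= col <= end + tol for col in cols):
                hit = intron_index
                break
        if hit is None:
            continue
        intron_index = hit
        gapless = anchor_ok.get(intron_index, False)
        left = range(max(0, start - half), start)
        right = range(end, min(view.n_columns, end + half))
        flank_cols = list(left) + list(right)
        identical = int(sum(view.is_identical(c) for c in flank_cols))
        gapped = int(sum(view.is_gap(c) for c in flank_cols))
        passes = (
            identical >= config.flank_min_identical
            and gapped <= config.flank_max_gapped
        )
        # the indel peptide lives on the ungapped (longer-at-run) isoform
        if side == "b":
            long_id, short_id, long_seq = id_a, id_b, seq_a
            residues = [int(view.a_idx[c]) for c in range(start, end)]
        else:
            long_id, short_id, long_seq = id_b, id_a, seq_b
            residues = [int(view.b_idx[c]) for c in range(start, end)]
        peptide = "".join(long_seq[r] for r in residues if r >= 0)
        aip = AIP(
            isoform_long=long_id,
            isoform_short=short_id,
            intron_index=intron_index,
            indel_peptide=peptide,
            region_start_long=residues[0] if residues else 0,
            flank_identical=identical,
            flank_gapped=gapped,
            passes_flank_rule=passes,
            gapless_anchor=gapless,
            carrier_sequence=long_seq,
        )
        if (passes and gapless) or keep_rejected:
            aips.append(aip)
    return aips


def isoform_pair_aips(
    isoform_a: tuple[str, str],
    isoform_b: tuple[str, str],
    reference_protein: str,
    reference_introns: Sequence[Intron],
    config: PipelineConfig | None = None,
) -> list[AIP]:
    """AIPs between an isoform pair, with intron positions transferred from
    a reference of known gene structure via both isoforms' alignments."""
    config = config or PipelineConfig()
    maps = [
        map_intron_positions(
            seq, reference_protein, reference_introns, config, subject_id=name
        )
        for name, seq in (isoform_a, isoform_b)
    ]
    return detect_aips(isoform_a, isoform_b, maps, config)


def call_conservation(
    query_aip: AIP, subject_aip: AIP, config: PipelineConfig | None = None
) -> AIPConservation:
    """Is a subject-species AIP a conserved version of the query AIP?

    Similarity is the percentage of global-alignment columns between the two
    carrier (longer-isoform) sequences with a positive substitution-matrix
    score, gap columns counting in the denominator; conserved at >= the
    configured threshold (default 40%).
    """
    config = config or PipelineConfig()
    view = align_global(
        query_aip.carrier_sequence, subject_aip.carrier_sequence, config
    )
    similarity = view.similarity_pct()
    return AIPConservation(
        query=query_aip,
        subject=subject_aip,
        similarity_pct=similarity,
        conserved=similarity >= config.aip_conservation_min_similarity_pct,
    )


@dataclass(frozen=True)
class ExonizationReport:
    """Outcome of scanning an intron for a cryptic-exon remnant."""

    exon_id: str
    intron_id: str
    has_hit: bool
    intron_region: Optional[tuple[int, int]] = None
    exon_region: Optional[tuple[int, int]] = None
    identity_pct: float = 0.0
    acceptor_offset: Optional[int] = None
    frame_preserved: bool = False
    in_frame_stop: bool = False

    @property
    def translatable(self) -> bool:
        return self.has_hit and self.frame_preserved and not self.in_frame_stop


def exonization_scan(
    exon_nt: str,
    intron_nt: str,
    config: PipelineConfig | None = None,
    exon_id: str = "exon",
    intron_id: str = "intron",
) -> ExonizationReport:
    """Scan an intron for a homolog of a (cryptic) exon and test exonization.

    Local nucleotide alignment finds the homologous region; the nearest AG
    dinucleotide at or upstream of its 5' edge is the candidate acceptor
    site, the offset to the region determines frame preservation, and the
    region is translated in the exon's reading frame to detect in-frame
    stops.
    """
    config = config or PipelineConfig()
    exon_nt, intron_nt = exon_nt.upper(), intron_nt.upper()
    if len(exon_nt) < 20 or len(intron_nt) < 20:
        raise ValueError("exon and intron must each be >= 20 nt")
    view = align_local(exon_nt, intron_nt, config, protein=False)
    if view.score < config.exonization_min_score or view.n_columns == 0:
        return ExonizationReport(exon_id, intron_id, has_hit=False)

    q_res = [int(i) for i in view.a_idx if i >= 0]
    i_res = [int(i) for i in view.b_idx if i >= 0]
    q_start, q_end = q_res[0], q_res[-1] + 1
    i_start, i_end = i_res[0], i_res[-1] + 1
    identity = view.identity_pct()

    # nearest acceptor AG ending at or upstream of the region's 5' edge
    offset = None
    for j in range(i_start, 1, -1):
        if intron_nt[j - 2 : j] == "AG":
            offset = i_start - j
            break
    frame_preserved = offset is not None and offset % 3 == 0

    # translate the homologous intron region in the exon's codon frame
    phase = q_start % 3
    t_start = i_start - phase
    in_frame_stop = False
    if t_start >= 0:
        region = intron_nt[t_start:i_end]
        region = region[: len(region) // 3 * 3]
        if region:
            aa = str(Seq(region).translate())
            in_frame_stop = "*" in aa
    return ExonizationReport(
        exon_id=exon_id,
        intron_id=intron_id,
        has_hit=True,
        intron_region=(i_start, i_end),
        exon_region=(q_start, q_end),
        identity_pct=identity,
        acceptor_offset=offset,
        frame_preserved=frame_preserved,
        in_frame_stop=in_frame_stop,
    )
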