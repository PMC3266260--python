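"""Alternative-splicing event detection, typing, and domain-level statistics.

Event taxonomy: alternative donor, alternative acceptor, exon skipping,
intron retention, mutually exclusive exons, cryptic exon, and ``complex``
for differences that match none of the patterns.  Detection compares two
exon chains of the same locus; the first isoform is treated as the
reference, which is what distinguishes an exon skipped from the reference
(exon_skip) from a novel exon included inside a reference intron
(cryptic_exon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import fisher_exact

from .align import align_global
from .models import (
    DomainAnnotation,
    GenomicInterval,
    PipelineConfig,
    ProteinIsoform,
    ResidueInterval,
    TranscriptModel,
)
from .sequence import get_introns
from .models import Intron

__all__ = [
    "IntronCluster",
    "ASEvent",
    "ASEffect",
    "DomainASCounts",
    "cluster_introns",
    "cluster_is_as",
    "detect_events",
    "event_effect",
    "assign_domain",
    "junction_residue_interval",
    "domain_as_counts",
    "fisher_domain_enrichment",
]

EVENT_TYPES = (
    "alt_donor",
    "alt_acceptor",
    "exon_skip",
    "intron_retention",
    "mutually_exclusive",
    "cryptic_exon",
    "complex",
)


@dataclass
class IntronCluster:
    """Introns from one locus grouped by genomic overlap (single linkage)."""

    members: list[Intron]
    span: GenomicInterval
    domain_label: Optional[str] = None

    @property
    def distinct_intervals(self) -> set[tuple[int, int]]:
        return {(m.interval.start, m.interval.end) for m in self.members}

    @property
    def transcript_ids(self) -> set[str]:
        return {m.transcript_id for m in self.members}


@dataclass
class ASEffect:
    """Protein-level consequence of one AS event.

    ``aa_difference`` counts alignment columns within the event's projected
    protein region that are gapped or mismatched between the two isoforms.
    """

    region_a: Optional[ResidueInterval]
    region_b: Optional[ResidueInterval]
    aa_difference: int
    frame_shift: bool
    truncation_aa: int


@dataclass
class ASEvent:
    """A typed splicing difference between two isoforms of one locus."""

    event_type: str
    locus_id: str
    isoform_a: str
    isoform_b: str
    footprint: GenomicInterval
    effect: Optional[ASEffect] = None
    domain_label: Optional[str] = None
    intron_indices_a: tuple[int, ...] = ()
    transcript_a: Optional[TranscriptModel] = field(default=None, repr=False)
    transcript_b: Optional[TranscriptModel] = field(default=None, repr=False)


def cluster_introns(introns: Sequence[Intron]) -> list[IntronCluster]:
    """Single-linkage clustering of introns by >=1-nt genomic overlap."""
    if not introns:
        return []
    chroms = {i.interval.chrom for i in introns}
    strands = {i.interval.strand for i in introns}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("introns from multiple loci/strands cannot be clustered")
    ordered = sorted(introns, key=lambda i: (i.interval.start, i.interval.end))
    clusters: list[IntronCluster] = []
    current: list[Intron] = [ordered[0]]
    cur_end = ordered[0].interval.end
    for intron in ordered[1:]:
        if intron.interval.start < cur_end:  # >=1 nt shared
            current.append(intron)
            cur_end = max(cur_end, intron.interval.end)
        else:
            clusters.append(_make_cluster(current))
            current = [intron]
            cur_end = intron.interval.end
    clusters.append(_make_cluster(current))
    return clusters


def _make_cluster(members: list[Intron]) -> IntronCluster:
    start = min(m.interval.start for m in members)
    end = max(m.interval.end for m in members)
    iv = members[0].interval
    return IntronCluster(
        members=list(members),
        span=GenomicInterval(iv.chrom, start, end, iv.strand),
    )


def cluster_is_as(
    cluster: IntronCluster, transcripts: Sequence[TranscriptModel]
) -> bool:
    """Is this intron cluster involved in an AS event?

    True when the cluster contains multiple distinct introns, or when its
    single intron is retained (fully exonic) in another transcript of the
    locus.
    """
    if len(cluster.distinct_intervals) >= 2:
        return True
    (member,) = cluster.distinct_intervals
    iv = GenomicInterval(
        cluster.span.chrom, member[0], member[1], cluster.span.strand
    )
    carrier_ids = cluster.transcript_ids
    for t in transcripts:
        if t.transcript_id in carrier_ids:
            continue
        if any(e.contains(iv) for e in t.exons):
            return True
    return False


# ---------------------------------------------------------------------------
# event detection


def _intron_intervals(t: TranscriptModel) -> list[tuple[int, int]]:
    return sorted(
        (i.interval.start, i.interval.end) for i in get_introns(t)
    )


def detect_events(
    isoform_a: TranscriptModel, isoform_b: TranscriptModel
) -> list[ASEvent]:
    """Typed AS events between two exon chains of the same locus.

    The chains are decomposed 5'->3' into maximal local difference regions
    (single-linkage overlap over the introns unique to either chain); each
    region is classified independently and unresolved patterns are labelled
    ``complex``.  Differences at the outermost transcript ends (alternative
    transcription start/termination) are not splicing events and are ignored.
    """
    if isoform_a.locus_id != isoform_b.locus_id:
        raise ValueError("isoforms from different loci")
    if isoform_a.strand != isoform_b.strand or isoform_a.chrom != isoform_b.chrom:
        raise ValueError("isoforms on different strands/chromosomes")
    introns_a = _intron_intervals(isoform_a)
    introns_b = _intron_intervals(isoform_b)
    set_a, set_b = set(introns_a), set(introns_b)
    unique = sorted(
        [(iv, "a") for iv in set_a - set_b] + [(iv, "b") for iv in set_b - set_a]
    )
    if not unique:
        return []

    # single-linkage grouping of unique introns into difference regions
    regions: list[list[tuple[tuple[int, int], str]]] = []
    current = [unique[0]]
    cur_end = unique[0][0][1]
    for item in unique[1:]:
        if item[0][0] < cur_end:
            current.append(item)
            cur_end = max(cur_end, item[0][1])
        else:
            regions.append(current)
            current = [item]
            cur_end = item[0][1]
    regions.append(current)

    plus = isoform_a.strand == "+"
    events = []
    for region in regions:
        a_introns = sorted(iv for iv, side in region if side == "a")
        b_introns = sorted(iv for iv, side in region if side == "b")
        etype, footprint = _classify_region(
            a_introns, b_introns, isoform_a, isoform_b, plus
        )
        fp = GenomicInterval(
            isoform_a.chrom, footprint[0], footprint[1], isoform_a.strand
        )
        affected = tuple(
            i.index
            for i in get_introns(isoform_a)
            if i.interval.overlaps(fp)
        )
        events.append(
            ASEvent(
                event_type=etype,
                locus_id=isoform_a.locus_id,
                isoform_a=isoform_a.transcript_id,
                isoform_b=isoform_b.transcript_id,
                footprint=fp,
                intron_indices_a=affected,
                transcript_a=isoform_a,
                transcript_b=isoform_b,
            )
        )
    events.sort(key=lambda e: e.footprint.start)
    return events


def _span(intervals: Iterable[tuple[int, int]]) -> tuple[int, int]:
    ivs = list(intervals)
    return min(s for s, _ in ivs), max(e for _, e in ivs)


def _fully_exonic(iv: tuple[int, int], t: TranscriptModel) -> bool:
    return any(e.start <= iv[0] and iv[1] <= e.end for e in t.exons)


def _classify_region(
    a_introns: list[tuple[int, int]],
    b_introns: list[tuple[int, int]],
    ta: TranscriptModel,
    tb: TranscriptModel,
    plus: bool,
) -> tuple[str, tuple[int, int]]:
    footprint = _span(a_introns + b_introns)
    na, nb = len(a_introns), len(b_introns)

    if na == 1 and nb == 0:
        # intron of the reference retained in the alternative
        if _fully_exonic(a_introns[0], tb):
            return "intron_retention", a_introns[0]
        return "complex", footprint
    if na == 0 and nb == 1:
        if _fully_exonic(b_introns[0], ta):
            return "intron_retention", b_introns[0]
        return "complex", footprint

    if na == 1 and nb == 1:
        (s1, e1), (s2, e2) = a_introns[0], b_introns[0]
        if s1 == s2 and e1 != e2:
            # shared 5'-genomic boundary: donor on +, acceptor on -
            return ("alt_acceptor" if plus else "alt_donor"), footprint
        if e1 == e2 and s1 != s2:
            return ("alt_donor" if plus else "alt_acceptor"), footprint
        return "complex", footprint

    if na == 2 and nb == 1:
        (s1, e1), (s2, e2) = a_introns
        (S, E) = b_introns[0]
        if S == s1 and E == e2 and e1 < s2:
            # exon of the reference absent from the alternative
            return "exon_skip", footprint
        return "complex", footprint
    if na == 1 and nb == 2:
        (S, E) = a_introns[0]
        (s1, e1), (s2, e2) = b_introns
        if S == s1 and E == e2 and e1 < s2:
            # novel exon inside a reference intron, both splice sites novel
            return "cryptic_exon", footprint
        return "complex", footprint

    if na == 2 and nb == 2:
        (s1, e1), (s2, e2) = a_introns
        (s1b, e1b), (s2b, e2b) = b_introns
        exon_a = (e1, s2)
        exon_b = (e1b, s2b)
        disjoint = exon_a[1] <= exon_b[0] or exon_b[1] <= exon_a[0]
        if s1 == s1b and e2 == e2b and e1 < s2 and e1b < s2b and disjoint:
            return "mutually_exclusive", footprint
        return "complex", footprint

    return "complex", footprint


# ---------------------------------------------------------------------------
# protein-level effect


def _coding_range_in_footprint(
    t: TranscriptModel, footprint: GenomicInterval, protein_len: int
) -> tuple[Optional[ResidueInterval], int]:
    """Project a genomic footprint onto protein coordinates of one isoform.

    Returns (residue interval or None, coding nt inside the footprint).
    """
    cum = 0
    lo = hi = None
    total_nt = 0
    for c in t.cds:  # transcription order
        o_start = max(c.start, footprint.start)
        o_end = min(c.end, footprint.end)
        if o_start < o_end:
            if t.strand == "+":
                off_start = cum + (o_start - c.start)
            else:
                off_start = cum + (c.end - o_end)
            off_end = off_start + (o_end - o_start)
            total_nt += o_end - o_start
            lo = off_start if lo is None else min(lo, off_start)
            hi = off_end if hi is None else max(hi, off_end)
        cum += len(c)
    if lo is None:
        # footprint is intronic in this isoform (e.g. an insertion carried
        # only by the other isoform): anchor at the junction residues
        if protein_len == 0:
            return None, 0
        upstream = 0
        for c in t.cds:
            if t.strand == "+" and c.end <= footprint.start:
                upstream += len(c)
            elif t.strand == "-" and c.start >= footprint.end:
                upstream += len(c)
        p = upstream // 3
        if upstream == 0 or p >= protein_len:
            return None, 0
        return ResidueInterval(max(p, 1), min(p + 1, protein_len)), 0
    r1 = lo // 3 + 1
    r2 = (hi - 1) // 3 + 1
    r1 = min(max(r1, 1), protein_len) if protein_len else r1
    r2 = min(max(r2, 1), protein_len) if protein_len else r2
    if protein_len == 0:
        return None, total_nt
    return ResidueInterval(min(r1, r2), max(r1, r2)), total_nt


def event_effect(
    event: ASEvent,
    protein_a: ProteinIsoform,
    protein_b: ProteinIsoform,
    config: PipelineConfig | None = None,
) -> ASEffect:
    """Amino-acid level effect of an event on the two translated isoforms.

    The two protein sequences are globally aligned; ``aa_difference`` is the
    number of alignment columns within the event's projected region that are
    gapped or mismatched.  ``frame_shift`` is true when the coding-length
    difference inside the footprint is not a multiple of 3; ``truncation_aa``
    counts residues of the longer protein beyond the last aligned column.
    """
    if event.transcript_a is None or event.transcript_b is None:
        raise ValueError("event carries no transcript structures")
    config = config or PipelineConfig()
    region_a, nt_a = _coding_range_in_footprint(
        event.transcript_a, event.footprint, len(protein_a)
    )
    region_b, nt_b = _coding_range_in_footprint(
        event.transcript_b, event.footprint, len(protein_b)
    )
    view = align_global(protein_a.sequence, protein_b.sequence, config)

    cols = set()
    for col in range(view.n_columns):
        ai, bi = int(view.a_idx[col]), int(view.b_idx[col])
        if region_a is not None and ai >= 0 and region_a.contains_point(ai + 1):
            cols.add(col)
        if region_b is not None and bi >= 0 and region_b.contains_point(bi + 1):
            cols.add(col)
    aa_difference = 0
    if cols:
        # contiguous column window over the projected region, extended to
        # absorb gap runs the aligner shifted just outside of it
        lo, hi = min(cols), max(cols)
        while lo > 0 and view.is_gap(lo - 1):
            lo -= 1
        while hi + 1 < view.n_columns and view.is_gap(hi + 1):
            hi += 1
        aa_difference = sum(
            1
            for col in range(lo, hi + 1)
            if view.is_gap(col) or not view.is_identical(col)
        )

    frame_shift = (abs(nt_a - nt_b) % 3) != 0

    both = [
        c
        for c in range(view.n_columns)
        if view.a_idx[c] >= 0 and view.b_idx[c] >= 0
    ]
    truncation = 0
    if both:
        last = both[-1]
        longer_idx = view.a_idx if len(protein_a) >= len(protein_b) else view.b_idx
        truncation = sum(1 for c in range(last + 1, view.n_columns) if longer_idx[c] >= 0)
    return ASEffect(
        region_a=region_a,
        region_b=region_b,
        aa_difference=aa_difference,
        frame_shift=frame_shift,
        truncation_aa=truncation,
    )


def alignment_aa_difference(
    seq_a: str, seq_b: str, config: PipelineConfig | None = None
) -> int:
    """Gapped-or-mismatched columns between two isoform proteins.

    Protein-only counterpart of :func:`event_effect` for isoform pairs whose
    gene structures are unavailable: counts every internal alignment column
    that is gapped or mismatched (terminal overhangs excluded), which for a
    single clean AS difference equals the event's amino-acid difference.
    """
    config = config or PipelineConfig()
    view = align_global(seq_a, seq_b, config)
    both = [
        c
        for c in range(view.n_columns)
        if view.a_idx[c] >= 0 and view.b_idx[c] >= 0
    ]
    if not both:
        return 0
    return sum(
        1
        for c in range(both[0], both[-1] + 1)
        if view.is_gap(c) or not view.is_identical(c)
    )


# ---------------------------------------------------------------------------
# domain assignment and enrichment


_ADJACENT = (("M", "I"), ("I", "K"), ("K", "C"))


def assign_domain(
    interval: Optional[ResidueInterval], domains: DomainAnnotation
) -> str:
    """Domain label of an affected residue interval.

    The label is ``border-X/Y`` when the interval includes the last residue
    of domain X or the first residue of the following domain Y; otherwise the
    domain fully containing the interval; otherwise ``outside``.
    """
    if interval is None:
        return "outside"
    by_label = dict(domains.labelled())
    for x, y in _ADJACENT:
        if interval.contains_point(by_label[x].end) or interval.contains_point(
            by_label[y].start
        ):
            return f"border-{x}/{y}"
    for label, iv in domains.labelled():
        if iv.start <= interval.start and interval.end <= iv.end:
            return label
    return "outside"


def junction_residue_interval(intron: Intron) -> Optional[ResidueInterval]:
    """Residue interval touched by an intron junction (1-based).

    Phase-0 introns sit between two residues (both returned); phase-1/2
    introns interrupt a single codon.
    """
    if intron.protein_position is None:
        return None
    p = intron.protein_position  # 0-based codon index
    if intron.phase == 0:
        return ResidueInterval(max(p, 1), p + 1)
    return ResidueInterval(p + 1, p + 1)


@dataclass
class DomainASCounts:
    """Per-domain totals and AS-involved counts of intron clusters."""

    counts: dict[str, tuple[int, int]]  # label -> (n_total, n_as)

    def fraction(self, label: str) -> float:
        total, n_as = self.counts[label]
        return n_as / total if total else float("nan")

    def labels(self) -> list[str]:
        return sorted(self.counts)


def domain_as_counts(
    clusters: Sequence[IntronCluster], as_flags: Sequence[bool]
) -> DomainASCounts:
    """Tally clusters (total, AS-involved) per domain label."""
    if len(clusters) != len(as_flags):
        raise ValueError("clusters and flags differ in length")
    counts: dict[str, list[int]] = {}
    for cluster, flag in zip(clusters, as_flags):
        label = cluster.domain_label or "outside"
        tally = counts.setdefault(label, [0, 0])
        tally[0] += 1
        tally[1] += int(flag)
    return DomainASCounts({k: (v[0], v[1]) for k, v in counts.items()})


def fisher_domain_enrichment(
    counts: DomainASCounts | Mapping[str, tuple[int, int]]
) -> dict[str, float]:
    """Two-sided Fisher's exact test per domain versus all other domains.

    For each domain the 2x2 table is [AS, non-AS] x [this domain, all other
    domains combined]; a degenerate table (zero margin) yields p = 1.
    """
    table = counts.counts if isinstance(counts, DomainASCounts) else dict(counts)
    total_all = sum(t for t, _ in table.values())
    as_all = sum(a for _, a in table.values())
    pvalues = {}
    for label, (n_total, n_as) in table.items():
        other_total = total_all - n_total
        other_as = as_all - n_as
        tab = [
            [n_as, n_total - n_as],
            [other_as, other_total - other_as],
        ]
        if min(sum(tab[0]), sum(tab[1]), tab[0][0] + tab[1][0], tab[0][1] + tab[1][1]) == 0:
            pvalues[label] = 1.0
            continue
        _, p = fisher_exact(tab, alternative="two-sided")
        pvalues[label] = float(p)
    return pvalues
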