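"""Seeded generator of MIKC-like loci with implanted AS events and orthologs.

The generator emulates the structural habits of plant type-II MADS-box
genes: a long first exon spanning the MADS (M) domain and part of the
intervening (I) domain, short internal exons carrying the K-box across
several exons, and C-terminal exons.  On top of a reference isoform it
implants splicing variants of all six event types (alternative donor,
alternative acceptor, exon skipping, intron retention, mutually exclusive
exons, cryptic exon), premature-stop variants for decay-rule tests, and
diverged ortholog contigs with or without a conserved AS-induced
polymorphism.  Every implanted feature is recorded in a ground-truth
record so downstream detection can be scored.

All randomness flows through a single ``numpy.random.Generator``; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .models import (
    DomainAnnotation,
    GenomicInterval,
    Locus,
    ResidueInterval,
    TranscriptModel,
)

__all__ = [
    "EventSpec",
    "SpeciesSpec",
    "SimConfig",
    "EventTruth",
    "AIPTruth",
    "TruthRecord",
    "SimulatedLocus",
    "simulate_locus",
    "implant_event",
    "simulate_orthologs",
    "implant_cryptic_exon_remnant",
    "transcript_with_ptc",
    "standard_scenario",
    "write_outputs",
]

STOPS = ("TAA", "TAG", "TGA")
BASES = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# codon table: amino acid -> codons (standard code, stops excluded)
_CODONS_BY_AA: dict[str, list[str]] = {}
for b1 in BASES:
    for b2 in BASES:
        for b3 in BASES:
            codon = b1 + b2 + b3
            if codon in STOPS:
                continue
            aa = str(Seq(codon).translate())
            _CODONS_BY_AA.setdefault(aa, []).append(codon)

_NONSTOP_CODONS = sorted(c for v in _CODONS_BY_AA.values() for c in v)
# non-stop codons ending in AG (usable as the final codon before an
# alternative acceptor's AG dinucleotide)
_AG_CODONS = sorted(c for c in _NONSTOP_CODONS if c.endswith("AG"))
_GT_CODONS = sorted(c for c in _NONSTOP_CODONS if c.startswith("GT"))

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

EVENT_ANCHORS = {  # target region -> CDS junction offset (nt) in the default layout
    "I": 249,
    "border-I/K": 270,
    "K": 339,
    "K_cterm": 429,
    "C": 609,
}


@dataclass
class EventSpec:
    """One splicing variant to implant on a locus.

    ``size_nt`` is the length of the differing segment (inserted/deleted
    coding sequence; for mutually exclusive exons the size of the
    alternative exon, with ``size2_nt`` the size of the reference exon).
    ``nmd`` requests a frame-breaking variant whose premature stop makes
    the isoform a decay candidate.
    """

    event_type: str
    size_nt: int = 12
    frame_preserving: bool = True
    target_domain: str = "K"
    size2_nt: Optional[int] = None
    nmd: bool = False

    def __post_init__(self) -> None:
        if self.size_nt <= 0:
            raise ValueError("event size must be positive")
        if self.frame_preserving and not self.nmd and self.size_nt % 3 != 0:
            raise ValueError("frame-preserving events need size divisible by 3")
        if self.target_domain not in EVENT_ANCHORS:
            raise ValueError(f"unknown target domain {self.target_domain!r}")


@dataclass
class SpeciesSpec:
    """One simulated subject species for the conservation analysis."""

    name: str
    divergence: float = 0.05
    conserve_aip: bool = True
    decoy_indel: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")


@dataclass
class SimConfig:
    """Study conditions for one simulation run."""

    seed: int = 0
    n_loci: int = 1
    domain_lengths: tuple[int, int, int, int] = (60, 30, 90, 60)
    utr_length: int = 60
    intron_length: int = 102  # multiple of 3 so retained introns stay in frame
    events: list[EventSpec] = field(default_factory=list)
    species: list[SpeciesSpec] = field(default_factory=list)
    ptc_distances: list[int] = field(default_factory=list)
    random_strand: bool = True

    def __post_init__(self) -> None:
        if self.intron_length % 3 != 0 or self.intron_length < 30:
            raise ValueError("intron_length must be a multiple of 3 and >= 30")
        if any(v <= 0 for v in self.domain_lengths):
            raise ValueError("domain lengths must be positive")


@dataclass
class EventTruth:
    event_type: str
    isoform_a: str  # reference
    isoform_b: str  # implanted variant
    footprint: tuple[int, int]
    size_nt: int
    expected_aa_difference: Optional[int]
    expected_domain_label: str
    intron_index: int
    clean: bool
    nmd_status: str = "coding"
    cds_offset: Optional[int] = None  # offset of the indel segment in the CDS


@dataclass
class AIPTruth:
    species: str
    present: bool
    conserved_expected: bool
    intron_index: int
    decoy: bool = False


@dataclass
class TruthRecord:
    locus_id: str
    reference_id: str = ""
    protein: str = ""
    events: list[EventTruth] = field(default_factory=list)
    nmd: dict[str, str] = field(default_factory=dict)
    aips: list[AIPTruth] = field(default_factory=list)
    isoform_proteins: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# low-level sequence builders


def _pyrimidine_fill(rng: np.random.Generator, n: int) -> str:
    """ATG-free, stop-free background (C/T only)."""
    return "".join(rng.choice(["C", "T"], size=n)) if n > 0 else ""


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(AA_ALPHABET), size=length - 1))
    return "M" + body


def _codons_for(rng: np.random.Generator, protein: str) -> list[str]:
    return [
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein
    ]


def _random_inframe(rng: np.random.Generator, n_nt: int, first_gt: bool = False,
                    last_ag: bool = False) -> str:
    """``n_nt`` (multiple of 3) of stop-free codons with optional site ends."""
    assert n_nt % 3 == 0
    n = n_nt // 3
    codons = [
        _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))] for _ in range(n)
    ]
    if first_gt:
        codons[0] = _GT_CODONS[rng.integers(len(_GT_CODONS))]
    if last_ag:
        codons[-1] = _AG_CODONS[rng.integers(len(_AG_CODONS))]
    return "".join(codons)


def _plain_intron(rng: np.random.Generator, length: int) -> str:
    return "GT" + _pyrimidine_fill(rng, length - 4) + "AG"


# ---------------------------------------------------------------------------
# simulated locus


@dataclass
class SimulatedLocus:
    """A synthetic gene with its genome, isoforms, annotation, and truth.

    Internal structures are kept on the plus strand; when the locus is
    generated on the minus strand all public coordinates are mirrored.
    """

    locus_id: str
    chrom: str
    strand: str
    domains: DomainAnnotation
    truth: TruthRecord
    splits: list[int]  # CDS junction offsets (nt)
    # plus-strand internals
    _seq: str = ""
    _exon_sets: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    _cds_sets: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    _order: list[str] = field(default_factory=list)
    config: Optional[SimConfig] = None

    # -- public views -------------------------------------------------------

    @property
    def genome(self) -> dict[str, str]:
        seq = self._seq
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return {self.chrom: seq}

    def _flip(self, iv: tuple[int, int]) -> tuple[int, int]:
        if self.strand == "+":
            return iv
        L = len(self._seq)
        return (L - iv[1], L - iv[0])

    def transcript(self, tid: str) -> TranscriptModel:
        exons = [
            GenomicInterval(self.chrom, *self._flip(iv), self.strand)
            for iv in self._exon_sets[tid]
        ]
        cds = [
            GenomicInterval(self.chrom, *self._flip(iv), self.strand)
            for iv in self._cds_sets[tid]
        ]
        return TranscriptModel(tid, self.locus_id, exons, cds)

    @property
    def locus(self) -> Locus:
        return Locus(self.locus_id, [self.transcript(t) for t in self._order])

    @property
    def reference(self) -> TranscriptModel:
        return self.transcript(self.truth.reference_id)

    @property
    def reference_protein(self) -> str:
        return self.truth.protein

    # -- construction helpers (plus-strand coordinates) ---------------------

    def _intron_span(self, j: int) -> tuple[int, int]:
        ref = self._exon_sets[self.truth.reference_id]
        return ref[j][1], ref[j + 1][0]

    def _rewrite(self, start: int, end: int, new_seq: str) -> None:
        assert len(new_seq) == end - start
        self._seq = self._seq[:start] + new_seq + self._seq[end:]

    def _add_isoform(
        self,
        tid: str,
        exons: list[tuple[int, int]],
        utr5: int,
        utr3: int,
    ) -> None:
        """Register an isoform given plus-strand exons and UTR lengths."""
        cds = []
        first, last = 0, len(exons) - 1
        for idx, (s, e) in enumerate(exons):
            cs = s + utr5 if idx == first else s
            ce = e - utr3 if idx == last else e
            if cs < ce:
                cds.append((cs, ce))
        self._exon_sets[tid] = exons
        self._cds_sets[tid] = cds
        self._order.append(tid)

    def spliced_cds_plus(self, tid: str) -> str:
        return "".join(self._seq[s:e] for s, e in self._cds_sets[tid])


def _split_index(splits: Sequence[int], offset: int) -> int:
    return list(splits).index(offset)


def simulate_locus(
    config: SimConfig, seed: int, locus_index: int = 0
) -> SimulatedLocus:
    """Build one MIKC-like locus (reference isoform only).

    The exon layout is planned so that every event in ``config.events`` has
    a compatible junction or cassette exon in its target domain; the
    reference coding sequence is stop-free by construction and deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    m_len, i_len, k_len, c_len = config.domain_lengths
    n_aa = m_len + i_len + k_len + c_len
    cds_len = 3 * n_aa + 3

    splits = _plan_splits(config.events, cds_len)
    locus_id = f"SYN{locus_index + 1:03d}"
    chrom = f"chr_{locus_id}"
    strand = "-" if (config.random_strand and rng.random() < 0.5) else "+"

    protein = _random_protein(rng, n_aa)
    codons = _codons_for(rng, protein)
    stop = STOPS[rng.integers(3)]
    cds = "".join(codons) + stop

    utr5 = _pyrimidine_fill(rng, config.utr_length)
    utr3 = _pyrimidine_fill(rng, config.utr_length)

    # assemble genome: utr5 + chunks interleaved with introns + utr3
    bounds = [0] + list(splits) + [cds_len]
    chunks = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    introns = [_plain_intron(rng, config.intron_length) for _ in splits]

    seq_parts = [utr5]
    exons: list[tuple[int, int]] = []
    pos = 0
    pos += len(utr5)
    exon_start = 0
    for idx, chunk in enumerate(chunks):
        seq_parts.append(chunk)
        pos += len(chunk)
        if idx < len(introns):
            exons.append((exon_start, pos))
            seq_parts.append(introns[idx])
            pos += len(introns[idx])
            exon_start = pos
    seq_parts.append(utr3)
    pos += len(utr3)
    exons.append((exon_start, pos))

    domains = DomainAnnotation(
        protein_id=f"{locus_id}.1",
        m=ResidueInterval(1, m_len),
        i=ResidueInterval(m_len + 1, m_len + i_len),
        k=ResidueInterval(m_len + i_len + 1, m_len + i_len + k_len),
        c=ResidueInterval(m_len + i_len + k_len + 1, n_aa),
    )
    truth = TruthRecord(
        locus_id=locus_id,
        reference_id=f"{locus_id}.1",
        protein=protein,
        isoform_proteins={f"{locus_id}.1": protein},
    )
    truth.nmd[truth.reference_id] = "coding"
    sim = SimulatedLocus(
        locus_id=locus_id,
        chrom=chrom,
        strand=strand,
        domains=domains,
        truth=truth,
        splits=list(splits),
        _seq="".join(seq_parts),
        config=config,
    )
    sim._add_isoform(truth.reference_id, exons, len(utr5), len(utr3))
    return sim


def _plan_splits(events: Sequence[EventSpec], cds_len: int) -> list[int]:
    """CDS junction offsets: defaults plus event-specific cassette junctions."""
    splits = {249, 339, 429, 519, 609}
    for spec in events:
        anchor = EVENT_ANCHORS[spec.target_domain]
        splits.add(anchor)
        if spec.event_type == "exon_skip":
            splits.add(anchor + spec.size_nt)
        if spec.event_type == "mutually_exclusive":
            size_ref = spec.size2_nt or spec.size_nt
            splits.add(anchor + size_ref)
    splits = sorted(s for s in splits if 0 < s < cds_len - 3)
    for a, b in zip(splits, splits[1:]):
        if b - a < 12:
            raise ValueError("event layout produces an exon shorter than 12 nt")
    return splits


# ---------------------------------------------------------------------------
# event implantation


def implant_event(
    sim: SimulatedLocus, spec: EventSpec, seed: int
) -> tuple[TranscriptModel, EventTruth]:
    """Add one alternative isoform realizing ``spec`` and record its truth.

    Intron interiors are rewritten as needed (alternative splice sites,
    cassette exons, stop-free in-frame segments); reference exons are never
    touched, so previously implanted isoforms and the reference protein are
    unaffected.
    """
    rng = np.random.default_rng(seed)
    ref_id = sim.truth.reference_id
    ref_exons = sim._exon_sets[ref_id]
    utr = sim.config.utr_length if sim.config else 60
    anchor = EVENT_ANCHORS[spec.target_domain]
    j = _split_index(sim.splits, anchor)
    tid = f"{sim.locus_id}.{len(sim._order) + 1}"

    builder = {
        "alt_donor": _implant_alt_donor,
        "alt_acceptor": _implant_alt_acceptor,
        "exon_skip": _implant_exon_skip,
        "intron_retention": _implant_retention,
        "mutually_exclusive": _implant_mxe,
        "cryptic_exon": _implant_cryptic,
    }.get(spec.event_type)
    if builder is None:
        raise ValueError(f"unknown event type {spec.event_type!r}")
    exons, footprint, inserted_span = builder(sim, spec, j, rng)

    sim._add_isoform(tid, exons, utr, utr)
    alt_protein, nmd_status = _variant_truth(sim, tid)
    clean = spec.frame_preserving and not spec.nmd and nmd_status == "coding"
    expected_aa = None
    if clean and spec.event_type in (
        "alt_donor",
        "alt_acceptor",
        "exon_skip",
        "intron_retention",
        "cryptic_exon",
    ):
        size = spec.size_nt
        if spec.event_type == "intron_retention":
            size = footprint[1] - footprint[0]
        expected_aa = size // 3

    label = "border-I/K" if spec.target_domain == "border-I/K" else (
        "K" if spec.target_domain == "K_cterm" else spec.target_domain
    )
    truth = EventTruth(
        event_type=spec.event_type,
        isoform_a=ref_id,
        isoform_b=tid,
        footprint=footprint,
        size_nt=spec.size_nt,
        expected_aa_difference=expected_aa,
        expected_domain_label=label,
        intron_index=j,
        clean=clean,
        nmd_status=nmd_status,
        cds_offset=anchor,
    )
    sim.truth.events.append(truth)
    sim.truth.nmd[tid] = nmd_status
    sim.truth.isoform_proteins[tid] = alt_protein
    return sim.transcript(tid), truth


def _scan_orfs_nt(mrna: str, min_aa: int = 30) -> list[tuple[int, Optional[int], int]]:
    """All ATG-initiated ORFs as (start, stop_codon_start or None, aa_len)."""
    out = []
    for s in range(len(mrna) - 2):
        if mrna[s : s + 3] != "ATG":
            continue
        p = s + 3
        stop = None
        while p + 3 <= len(mrna):
            if mrna[p : p + 3] in STOPS:
                stop = p
                break
            p += 3
        aa_len = (stop - s) // 3 if stop is not None else (p - s) // 3
        if aa_len >= min_aa:
            out.append((s, stop, aa_len))
    out.sort(key=lambda o: (-o[2], o[0]))
    return out


def _variant_truth(sim: SimulatedLocus, tid: str) -> tuple[str, str]:
    """Protein and decay status of an isoform, by construction arithmetic.

    Translation starts at the annotated ATG.  The decay call mirrors the
    junction rule on the constructed exon lengths: target when the stop of
    the longest ORF sits more than 55 nt upstream of the last junction,
    downgraded to ambiguous when a downstream start escapes the rule.
    """
    exons = sim._exon_sets[tid]
    utr = sim.config.utr_length if sim.config else 60
    mrna = "".join(sim._seq[s:e] for s, e in exons)
    aa = []
    for p in range(utr, len(mrna) - 2, 3):
        codon = mrna[p : p + 3]
        if codon in STOPS:
            break
        aa.append(str(Seq(codon).translate()))
    protein = "".join(aa)

    orfs = _scan_orfs_nt(mrna)
    if len(exons) < 2 or not orfs:
        return protein, "coding" if orfs or len(exons) < 2 else "ambiguous"
    junction = sum(e - s for s, e in exons[:-1])
    start, stop, _ = orfs[0]
    if stop is None or junction - stop <= 55:
        return protein, "coding"
    for o_start, o_stop, _ in orfs[1:]:
        if o_start > start and (o_stop is None or junction - o_stop <= 55):
            return protein, "ambiguous"
    return protein, "nmd_target"


def _implant_alt_donor(sim, spec, j, rng):
    s = spec.size_nt
    gs, ge = sim._intron_span(j)
    L = ge - gs
    if L < s + 8:
        raise ValueError("intron too short for alternative donor shift")
    if spec.nmd:
        # in-frame early stop inside the inserted segment
        if s < 6 or s % 3 != 0:
            raise ValueError("nmd alt_donor needs size >= 6 and divisible by 3")
        segment = "GTA" + "TAA" + _pyrimidine_fill(rng, s - 6)
    elif not spec.frame_preserving:
        segment = "GT" + _pyrimidine_fill(rng, s - 2)
    else:
        segment = _random_inframe(rng, s, first_gt=True)
    tail = _pyrimidine_fill(rng, L - s - 4)
    sim._rewrite(gs, ge, segment + "GT" + tail + "AG")
    exons = [list(iv) for iv in sim._exon_sets[sim.truth.reference_id]]
    exons[j][1] += s
    return [tuple(iv) for iv in exons], (gs, ge), (gs, gs + s)


def _implant_alt_acceptor(sim, spec, j, rng):
    s = spec.size_nt
    gs, ge = sim._intron_span(j)
    L = ge - gs
    if L < s + 8:
        raise ValueError("intron too short for alternative acceptor shift")
    if spec.nmd and s % 3 == 0:
        if s < 6:
            raise ValueError("nmd alt_acceptor needs size >= 6")
        segment = "TAA" + _pyrimidine_fill(rng, s - 5) + "AG"
    elif spec.nmd or not spec.frame_preserving:
        segment = _pyrimidine_fill(rng, s - 2) + "AG"
    else:
        segment = _random_inframe(rng, s, last_ag=True)
    head = _pyrimidine_fill(rng, L - s - 4)
    sim._rewrite(gs, ge, "GT" + head + "AG" + segment)
    exons = [list(iv) for iv in sim._exon_sets[sim.truth.reference_id]]
    exons[j + 1][0] -= s
    return [tuple(iv) for iv in exons], (gs, ge), (ge - s, ge)


def _implant_exon_skip(sim, spec, j, rng):
    ref = sim._exon_sets[sim.truth.reference_id]
    if j + 1 >= len(ref) - 1:
        raise ValueError("exon skipping needs an internal exon")
    target = ref[j + 1]
    if target[1] - target[0] != spec.size_nt:
        raise ValueError(
            "locus layout lacks a cassette exon of the requested size "
            "(plan the locus with this event spec)"
        )
    exons = [iv for idx, iv in enumerate(ref) if idx != j + 1]
    gs, _ = sim._intron_span(j)
    _, ge = sim._intron_span(j + 1)
    return exons, (gs, ge), None


def _implant_retention(sim, spec, j, rng):
    gs, ge = sim._intron_span(j)
    L = ge - gs
    if spec.nmd:
        # retained intron carries an early in-frame stop
        body = _random_inframe(rng, L, first_gt=True, last_ag=True)
        body = body[:6] + "TAA" + body[9:]
        sim._rewrite(gs, ge, body)
    else:
        sim._rewrite(gs, ge, _random_inframe(rng, L, first_gt=True, last_ag=True))
    ref = sim._exon_sets[sim.truth.reference_id]
    exons = []
    for idx, iv in enumerate(ref):
        if idx == j:
            exons.append((iv[0], ref[j + 1][1]))
        elif idx == j + 1:
            continue
        else:
            exons.append(iv)
    return exons, (gs, ge), (gs, ge)


def _implant_mxe(sim, spec, j, rng):
    """Reference keeps its exon; the variant swaps in a cassette from the
    downstream intron."""
    ref = sim._exon_sets[sim.truth.reference_id]
    if j + 1 >= len(ref) - 1:
        raise ValueError("mutually exclusive exons need an internal exon")
    e1 = ref[j + 1]
    size_ref = e1[1] - e1[0]
    if spec.size2_nt is not None and size_ref != spec.size2_nt:
        raise ValueError("reference exon size does not match size2_nt")
    s2 = spec.size_nt
    gs, ge = sim._intron_span(j + 1)  # intron downstream of E1
    L = ge - gs
    min_side = 20
    if L < s2 + 2 * min_side:
        raise ValueError("intron too short to host the alternative exon")
    part1 = "GT" + _pyrimidine_fill(rng, min_side - 4) + "AG"
    cassette = _random_inframe(rng, s2)
    part2_len = L - len(part1) - s2
    part2 = "GT" + _pyrimidine_fill(rng, part2_len - 4) + "AG"
    sim._rewrite(gs, ge, part1 + cassette + part2)
    c_start = gs + len(part1)
    c_end = c_start + s2
    exons = []
    for idx, iv in enumerate(ref):
        if idx == j + 1:
            exons.append((c_start, c_end))
        else:
            exons.append(iv)
    up_gs, _ = sim._intron_span(j)
    return exons, (up_gs, ge), (c_start, c_end)


def _implant_cryptic(sim, spec, j, rng):
    """The variant includes a novel exon inside a reference intron."""
    s = spec.size_nt
    gs, ge = sim._intron_span(j)
    L = ge - gs
    min_side = 20
    if L < s + 2 * min_side:
        raise ValueError("intron too short to host a cryptic exon")
    part1 = "GT" + _pyrimidine_fill(rng, min_side - 4) + "AG"
    if spec.nmd and s % 3 == 0:
        cassette = "TAA" + _pyrimidine_fill(rng, s - 3)
    elif spec.nmd or not spec.frame_preserving:
        cassette = _pyrimidine_fill(rng, s)
    else:
        cassette = _random_inframe(rng, s)
    part2_len = L - len(part1) - s
    part2 = "GT" + _pyrimidine_fill(rng, part2_len - 4) + "AG"
    sim._rewrite(gs, ge, part1 + cassette + part2)
    c_start = gs + len(part1)
    c_end = c_start + s
    ref = sim._exon_sets[sim.truth.reference_id]
    exons = []
    for idx, iv in enumerate(ref):
        exons.append(iv)
        if iv[1] == gs:
            exons.append((c_start, c_end))
    return exons, (gs, ge), (c_start, c_end)


# ---------------------------------------------------------------------------
# orthologs


def _mutate_cds(
    cds: str, divergence: float, rng: np.random.Generator
) -> str:
    """Nucleotide substitutions with 2:1 transition bias, stop codons rejected.

    The per-site rate is calibrated so the realized protein divergence is
    approximately the requested value.
    """
    mu = divergence / 2.3
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    out = []
    for idx, codon in enumerate(codons):
        current = codon
        if idx < len(codons) - 1:  # never touch the stop codon
            for pos in range(3):
                if rng.random() >= mu:
                    continue
                base = current[pos]
                if rng.random() < 0.5:
                    new = _TRANSITION[base]
                else:
                    choices = [b for b in BASES if b not in (base, _TRANSITION[base])]
                    new = choices[rng.integers(2)]
                cand = current[:pos] + new + current[pos + 1 :]
                if cand not in STOPS:
                    current = cand
        out.append(current)
    return "".join(out)


def simulate_orthologs(
    sim: SimulatedLocus,
    species_specs: Sequence[SpeciesSpec],
    seed: int,
) -> tuple[dict[str, dict[str, str]], list[AIPTruth]]:
    """Diverged transcript contigs per species, with AIP ground truth.

    The carrier (longer) isoform of the locus's first clean indel event is
    mutated to the requested divergence with intron positions untouched.
    Species flagged ``conserve_aip`` additionally carry the short isoform
    lacking the homologous indel; ``decoy_indel`` species instead carry an
    isoform pair whose indel does NOT coincide with any intron position.
    Contigs are randomly strand-flipped to exercise six-frame translation.
    """
    rng = np.random.default_rng(seed)
    event = next(
        (
            e
            for e in sim.truth.events
            if e.clean and e.event_type in ("alt_donor", "alt_acceptor", "exon_skip")
        ),
        None,
    )
    if event is None:
        raise ValueError("locus carries no clean indel event to propagate")
    # carrier CDS: the isoform containing the indel segment
    long_id = (
        event.isoform_b
        if len(sim.truth.isoform_proteins[event.isoform_b])
        > len(sim.truth.isoform_proteins[event.isoform_a])
        else event.isoform_a
    )
    long_cds = sim.spliced_cds_plus(long_id)
    indel_off = event.cds_offset  # indel segment begins at the junction offset
    if indel_off is None:
        indel_off = sim.splits[event.intron_index]
    indel_len = event.size_nt

    contigs: dict[str, dict[str, str]] = {}
    truths: list[AIPTruth] = []
    for spec in species_specs:
        sp_rng = np.random.default_rng(rng.integers(2**31 - 1))
        mutated = _mutate_cds(long_cds, spec.divergence, sp_rng)
        entry: dict[str, str] = {}
        name_long = f"{spec.name}_{sim.locus_id}_iso1"
        entry[name_long] = _maybe_flip(mutated, sp_rng)
        if spec.conserve_aip:
            short = mutated[:indel_off] + mutated[indel_off + indel_len :]
            entry[f"{spec.name}_{sim.locus_id}_iso2"] = _maybe_flip(short, sp_rng)
        elif spec.decoy_indel:
            shift = indel_len if long_id != sim.truth.reference_id else 0
            off = _decoy_offset(sim, sp_rng, indel_off, shift, len(long_cds))
            short = mutated[:off] + mutated[off + 9 :]
            entry[f"{spec.name}_{sim.locus_id}_iso2"] = _maybe_flip(short, sp_rng)
        contigs[spec.name] = entry
        truths.append(
            AIPTruth(
                species=spec.name,
                present=spec.conserve_aip,
                conserved_expected=spec.conserve_aip,
                intron_index=event.intron_index,
                decoy=spec.decoy_indel,
            )
        )
    sim.truth.aips.extend(truths)
    return contigs, truths


def _maybe_flip(seq: str, rng: np.random.Generator) -> str:
    return str(Seq(seq).reverse_complement()) if rng.random() < 0.5 else seq


def _decoy_offset(
    sim: SimulatedLocus,
    rng: np.random.Generator,
    indel_off: int,
    shift: int,
    cds_len: int,
) -> int:
    """A codon-aligned offset on the carrier CDS >= 8 codons from any junction.

    When the carrier isoform holds an insertion relative to the reference,
    junction offsets downstream of it are shifted by the insertion length.
    """
    shifted = [s + (shift if s >= indel_off else 0) for s in sim.splits]
    for _ in range(100):
        off = int(rng.integers(30, cds_len - 42)) // 3 * 3
        if all(abs(off - s) >= 24 for s in shifted):
            return off
    raise RuntimeError("could not place decoy indel")


# ---------------------------------------------------------------------------
# cryptic-exon remnants and PTC fixtures


def implant_cryptic_exon_remnant(
    exon_nt: str,
    seed: int,
    ag_offset: int = 0,
    implant_stop: bool = False,
    intron_length: int = 400,
) -> str:
    """An intron carrying a remnant copy of ``exon_nt`` for exonization scans.

    ``ag_offset`` controls the distance between the nearest upstream AG
    acceptor dinucleotide and the 5' edge of the remnant (0 = immediately
    adjacent; 2 reproduces a frame-breaking acceptor).  ``implant_stop``
    converts one internal codon of the remnant to TAA.  The spacer between
    the planted AG and the remnant is pyrimidine-only so no closer AG can
    arise.
    """
    rng = np.random.default_rng(seed)
    copy = exon_nt.upper()
    if implant_stop:
        mid = (len(copy) // 2) // 3 * 3
        copy = copy[:mid] + "TAA" + copy[mid + 3 :]
    pad2_len = 30
    pad1_len = intron_length - 4 - 2 - ag_offset - len(copy) - pad2_len
    if pad1_len < 10:
        raise ValueError("intron_length too short for the remnant layout")
    pad1 = _pyrimidine_fill(rng, pad1_len)
    spacer = _pyrimidine_fill(rng, ag_offset)
    pad2 = _pyrimidine_fill(rng, pad2_len)
    return "GT" + pad1 + "AG" + spacer + copy + pad2 + "AG"


def transcript_with_ptc(
    distance_nt: int, seed: int = 0, n_exons: int = 3, locus_id: str = "PTC"
) -> tuple[TranscriptModel, dict[str, str]]:
    """A multi-exon transcript whose sole ORF stops ``distance_nt`` upstream
    of the last exon-exon junction (negative distances place it downstream).

    The background is pyrimidine-only so the implanted ORF is the only ORF;
    the ORF starts at transcript position 0.
    """
    if n_exons < 2:
        raise ValueError("need >=2 exons to have a junction")
    rng = np.random.default_rng(seed)
    exon_lengths = [300] + [60] * (n_exons - 2) + [120]
    junction = sum(exon_lengths[:-1])
    stop_start = junction - distance_nt
    # shift the first exon so the stop lands on a codon boundary
    shift = (-stop_start) % 3
    exon_lengths[0] += shift
    junction += shift
    stop_start += shift
    total = sum(exon_lengths)
    if not 3 <= stop_start <= total - 3:
        raise ValueError("distance incompatible with the exon layout")
    n_codons = stop_start // 3 - 1
    if n_codons < 30:
        raise ValueError("ORF would be shorter than 30 residues")
    # pyrimidine-only codons: cannot form ATG or a stop in any frame
    safe_codons = [c for c in _NONSTOP_CODONS if "A" not in c and "G" not in c]
    body = "".join(
        safe_codons[rng.integers(len(safe_codons))] for _ in range(n_codons)
    )
    mrna = "ATG" + body + "TAA" + _pyrimidine_fill(rng, total - stop_start - 3)
    assert len(mrna) == total

    chrom = f"chr_{locus_id}"
    intron = 100
    seq_parts, exons = [], []
    pos = 0
    tx_off = 0
    for idx, L in enumerate(exon_lengths):
        seq_parts.append(mrna[tx_off : tx_off + L])
        exons.append(GenomicInterval(chrom, pos, pos + L, "+"))
        pos += L
        tx_off += L
        if idx < n_exons - 1:
            seq_parts.append("GT" + "C" * (intron - 4) + "AG")
            pos += intron
    genome = {chrom: "".join(seq_parts)}
    model = TranscriptModel(f"{locus_id}.1", locus_id, exons, list(exons))
    return model, genome


# ---------------------------------------------------------------------------
# scenario assembly and output


def standard_scenario(
    seed: int,
    n_per_type: int = 1,
    species: Optional[Sequence[SpeciesSpec]] = None,
) -> list[tuple[SimulatedLocus, dict[str, dict[str, str]]]]:
    """One locus per implanted event type (x ``n_per_type``), plus orthologs
    for loci whose event can carry an AS-induced polymorphism."""
    recipes = [
        EventSpec("alt_donor", 12, target_domain="I"),
        EventSpec("alt_acceptor", 15, target_domain="K_cterm"),
        EventSpec("exon_skip", 42, target_domain="K"),
        EventSpec("intron_retention", target_domain="K"),
        EventSpec("mutually_exclusive", 45, size2_nt=90, target_domain="K"),
        EventSpec("cryptic_exon", 30, target_domain="C"),
    ]
    out = []
    rng = np.random.default_rng(seed)
    idx = 0
    for _ in range(n_per_type):
        for spec in recipes:
            config = SimConfig(seed=seed, events=[spec], species=list(species or []))
            locus_seed = int(rng.integers(2**31 - 1))
            sim = simulate_locus(config, locus_seed, locus_index=idx)
            implant_event(sim, spec, int(rng.integers(2**31 - 1)))
            contigs: dict[str, dict[str, str]] = {}
            if species and spec.event_type in (
                "alt_donor",
                "alt_acceptor",
                "exon_skip",
            ):
                contigs, _ = simulate_orthologs(
                    sim, species, int(rng.integers(2**31 - 1))
                )
            out.append((sim, contigs))
            idx += 1
    return out


def write_outputs(
    scenario: Sequence[tuple[SimulatedLocus, dict[str, dict[str, str]]]],
    outdir: str | os.PathLike,
) -> None:
    """Write genome.fa, models.gff3, per-species contigs, annotation TSVs and
    truth.json for a simulated scenario."""
    from . import io as _io

    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    genome: dict[str, str] = {}
    loci = []
    domains = {}
    truth_json = []
    per_species: dict[str, dict[str, str]] = {}
    for sim, contigs in scenario:
        genome.update(sim.genome)
        loci.append(sim.locus)
        domains[sim.domains.protein_id] = sim.domains
        truth_json.append(dataclasses.asdict(sim.truth))
        for species, seqs in contigs.items():
            per_species.setdefault(species, {}).update(seqs)
    _io.write_fasta(genome, os.path.join(outdir, "genome.fa"))
    _io.write_gff3(loci, os.path.join(outdir, "models.gff3"))
    _io.write_domains_tsv(domains, os.path.join(outdir, "domains.tsv"))
    if per_species:
        contig_dir = os.path.join(outdir, "contigs")
        os.makedirs(contig_dir, exist_ok=True)
        for species, seqs in per_species.items():
            _io.write_fasta(seqs, os.path.join(contig_dir, f"{species}.fa"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth_json, fh, indent=1)
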