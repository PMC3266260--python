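"""Functional classification of AS events against interaction-motif maps.

An event passing the NMD filter is called functional when at least one of
three independent criteria holds: (1) its protein-level effect overlaps a
predicted dimerization interaction motif; (2) it falls in the C-terminal
region of the K-box implicated in higher-order complex formation; (3) the
corresponding AS-induced polymorphism is conserved in another species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .conservation import AIPConservation
from .events import ASEffect, ASEvent
from .models import DomainAnnotation, ResidueInterval

__all__ = [
    "MotifAnnotation",
    "FunctionalCall",
    "MotifArchitecture",
    "motif_overlap",
    "classify_functional",
    "motif_architecture",
    "make_report",
]


@dataclass(frozen=True)
class MotifAnnotation:
    """A predicted interaction motif on a protein (1-based inclusive)."""

    protein_id: str
    motif_id: str
    interval: ResidueInterval


@dataclass
class FunctionalCall:
    event: ASEvent
    criterion_motif_overlap: bool
    criterion_kbox_cterm: bool
    criterion_conserved: bool
    overlapping_motifs: list[MotifAnnotation] = field(default_factory=list)
    conserved_species: list[str] = field(default_factory=list)

    @property
    def functional(self) -> bool:
        return (
            self.criterion_motif_overlap
            or self.criterion_kbox_cterm
            or self.criterion_conserved
        )


@dataclass
class MotifArchitecture:
    protein_id: str
    motifs: list[MotifAnnotation]
    junction_spanning: list[bool]


def motif_overlap(
    effect: ASEffect | ResidueInterval, motifs: Sequence[MotifAnnotation]
) -> list[MotifAnnotation]:
    """Motifs whose interval intersects the affected region by >=1 residue."""
    region = effect.region_a if isinstance(effect, ASEffect) else effect
    if region is None:
        return []
    return [m for m in motifs if m.interval.overlaps(region)]


def classify_functional(
    event: ASEvent,
    effect: ASEffect,
    domains: DomainAnnotation,
    motifs: Sequence[MotifAnnotation],
    conservation_calls: Sequence[AIPConservation] = (),
) -> FunctionalCall:
    """Apply the three functionality criteria to one (non-NMD) event.

    Criterion 3 links an event to conservation calls through the reference
    intron cluster it affects: a conserved AIP matches when its intron index
    is among the event's affected reference introns.
    """
    overlapping = motif_overlap(effect, motifs)
    region = effect.region_a
    in_kbox_cterm = region is not None and domains.kbox_cterm.overlaps(region)
    species = sorted(
        {
            getattr(call.subject, "species", call.subject.isoform_long)
            for call in conservation_calls
            if call.conserved
            and call.query.intron_index in event.intron_indices_a
        }
    )
    return FunctionalCall(
        event=event,
        criterion_motif_overlap=bool(overlapping),
        criterion_kbox_cterm=in_kbox_cterm,
        criterion_conserved=bool(species),
        overlapping_motifs=overlapping,
        conserved_species=species,
    )


def motif_architecture(
    protein_id: str,
    motifs: Sequence[MotifAnnotation],
    intron_positions: Sequence[int],
) -> MotifArchitecture:
    """Flag motifs spanning an exon-exon junction of the encoding gene.

    ``intron_positions`` are 1-based residue positions of intron junctions
    on the protein; a motif spans a junction when a position lies strictly
    inside its interval (a motif ending exactly at the junction does not).
    """
    ordered = sorted(motifs, key=lambda m: m.interval.start)
    spanning = [
        any(m.interval.start < p < m.interval.end for p in intron_positions)
        for m in ordered
    ]
    return MotifArchitecture(protein_id, ordered, spanning)


REPORT_COLUMNS = [
    "locus",
    "isoform_a",
    "isoform_b",
    "event_type",
    "domain_label",
    "aa_difference",
    "frame_shift",
    "truncation_aa",
    "criterion_motif_overlap",
    "criterion_kbox_cterm",
    "criterion_conserved",
    "functional",
    "conserved_species",
]


def make_report(calls: Sequence[FunctionalCall]) -> pd.DataFrame:
    """One row per classified event, in a fixed, deterministic column order."""
    rows = []
    for call in calls:
        ev = call.event
        eff = ev.effect
        rows.append(
            {
                "locus": ev.locus_id,
                "isoform_a": ev.isoform_a,
                "isoform_b": ev.isoform_b,
                "event_type": ev.event_type,
                "domain_label": ev.domain_label or "",
                "aa_difference": eff.aa_difference if eff else None,
                "frame_shift": eff.frame_shift if eff else None,
                "truncation_aa": eff.truncation_aa if eff else None,
                "criterion_motif_overlap": call.criterion_motif_overlap,
                "criterion_kbox_cterm": call.criterion_kbox_cterm,
                "criterion_conserved": call.criterion_conserved,
                "functional": call.functional,
                "conserved_species": ",".join(call.conserved_species),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
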