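"""End-to-end orchestration: gene models -> events -> NMD filter -> effects
-> domain labels -> functional classification -> report tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .conservation import AIPConservation
from .domains import transfer_domains
from .events import (
    ASEvent,
    DomainASCounts,
    IntronCluster,
    assign_domain,
    cluster_introns,
    cluster_is_as,
    detect_events,
    domain_as_counts,
    event_effect,
    fisher_domain_enrichment,
    junction_residue_interval,
)
from .functional import FunctionalCall, MotifAnnotation, classify_functional, make_report
from .models import (
    DomainAnnotation,
    Locus,
    PipelineConfig,
    ProteinIsoform,
    ResidueInterval,
)
from .nmd import NMDVerdict, classify_nmd
from .sequence import find_orfs, spliced_sequence, translate, get_introns

__all__ = [
    "translate_isoform",
    "LocusAnalysis",
    "analyze_locus",
    "run_analysis",
    "enrichment_table",
    "motifs_from_frame",
]


def translate_isoform(
    transcript, genome: Mapping[str, str], config: PipelineConfig | None = None
) -> Optional[ProteinIsoform]:
    """Longest ATG-initiated ORF of the spliced transcript, translated."""
    config = config or PipelineConfig()
    seq = spliced_sequence(transcript, genome)
    orfs = find_orfs(seq, config.min_orf_aa)
    if not orfs:
        return None
    orf = orfs[0]
    end = orf.end if orf.complete else orf.end + 3  # synthesize missing stop
    protein = translate(seq[orf.start : orf.end - 3] if orf.complete else seq[orf.start : orf.end])
    return ProteinIsoform(
        protein_id=transcript.transcript_id,
        transcript_id=transcript.transcript_id,
        sequence=protein,
        orf_tx_start=orf.start,
        orf_tx_end=end,
    )


def motifs_from_frame(df: pd.DataFrame) -> list[MotifAnnotation]:
    return [
        MotifAnnotation(
            protein_id=str(r.protein_id),
            motif_id=str(r.motif_id),
            interval=ResidueInterval(int(r.start), int(r.end)),
        )
        for r in df.itertuples()
    ]


@dataclass
class LocusAnalysis:
    locus: Locus
    clusters: list[IntronCluster]
    as_flags: list[bool]
    verdicts: dict[str, NMDVerdict]
    events: list[ASEvent] = field(default_factory=list)
    dropped_events: list[ASEvent] = field(default_factory=list)
    calls: list[FunctionalCall] = field(default_factory=list)


def _label_cluster(
    cluster: IntronCluster,
    reference_id: str,
    domains: Optional[DomainAnnotation],
) -> str:
    if domains is None:
        return "outside"
    member = next(
        (m for m in cluster.members if m.transcript_id == reference_id),
        None,
    ) or next((m for m in cluster.members if m.protein_position is not None), None)
    if member is None:
        return "outside"
    return assign_domain(junction_residue_interval(member), domains)


def analyze_locus(
    locus: Locus,
    genome: Mapping[str, str],
    domains: Optional[DomainAnnotation] = None,
    motifs: Sequence[MotifAnnotation] = (),
    conservation_calls: Sequence[AIPConservation] = (),
    config: PipelineConfig | None = None,
) -> LocusAnalysis:
    """Full single-locus analysis against a reference (first) isoform.

    Events whose alternative isoform is an NMD target or ambiguous are
    recorded but excluded from functional classification, mirroring the
    removal of decay candidates before protein-level interpretation.
    """
    config = config or PipelineConfig()
    reference = locus.transcripts[0]
    introns = [i for t in locus.transcripts for i in get_introns(t)]
    clusters = cluster_introns(introns) if introns else []
    as_flags = [cluster_is_as(c, locus.transcripts) for c in clusters]
    for c in clusters:
        c.domain_label = _label_cluster(c, reference.transcript_id, domains)

    verdicts = {
        t.transcript_id: classify_nmd(t, genome, config=config)
        for t in locus.transcripts
    }
    proteins = {
        t.transcript_id: translate_isoform(t, genome, config)
        for t in locus.transcripts
    }

    analysis = LocusAnalysis(locus, clusters, as_flags, verdicts)
    ref_protein = proteins[reference.transcript_id]
    for alt in locus.transcripts[1:]:
        for event in detect_events(reference, alt):
            if verdicts[alt.transcript_id].status != "coding":
                analysis.dropped_events.append(event)
                continue
            alt_protein = proteins[alt.transcript_id]
            if ref_protein is None or alt_protein is None:
                analysis.dropped_events.append(event)
                continue
            effect = event_effect(event, ref_protein, alt_protein, config)
            event.effect = effect
            event.domain_label = _event_domain_label(
                event, effect, ref_protein, alt_protein, domains, config
            )
            analysis.events.append(event)
            if domains is not None:
                analysis.calls.append(
                    classify_functional(
                        event, effect, domains, motifs, conservation_calls
                    )
                )
    return analysis


def _event_domain_label(
    event: ASEvent,
    effect,
    ref_protein: ProteinIsoform,
    alt_protein: ProteinIsoform,
    domains: Optional[DomainAnnotation],
    config: PipelineConfig,
) -> str:
    """Domain label of the affected region, annotated on the isoform that
    actually carries the differing residues (boundaries transferred when
    that is not the reference)."""
    if domains is None:
        return "outside"
    if effect.region_a is not None:
        return assign_domain(effect.region_a, domains)
    if effect.region_b is None:
        return "outside"
    alt_domains = transfer_domains(
        alt_protein.sequence, ref_protein.sequence, domains, config,
        query_id=alt_protein.protein_id,
    )
    if alt_domains is None:
        return "outside"
    return assign_domain(effect.region_b, alt_domains)


def run_analysis(
    loci: Mapping[str, Locus],
    genome: Mapping[str, str],
    domains_map: Mapping[str, DomainAnnotation] | None = None,
    motifs: Sequence[MotifAnnotation] = (),
    conservation_calls: Sequence[AIPConservation] = (),
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, list[LocusAnalysis]]:
    """Analyze every locus; returns the event report and per-locus details.

    ``domains_map`` is keyed by the reference isoform's protein id.
    """
    config = config or PipelineConfig()
    domains_map = domains_map or {}
    analyses = []
    calls: list[FunctionalCall] = []
    for locus_id in sorted(loci):
        locus = loci[locus_id]
        ref_id = locus.transcripts[0].transcript_id
        domains = domains_map.get(ref_id)
        locus_motifs = [m for m in motifs if m.protein_id == ref_id]
        analysis = analyze_locus(
            locus, genome, domains, locus_motifs, conservation_calls, config
        )
        analyses.append(analysis)
        calls.extend(analysis.calls)
    return make_report(calls), analyses


def enrichment_table(analyses: Sequence[LocusAnalysis]) -> pd.DataFrame:
    """Pooled per-domain cluster counts, AS fractions and Fisher p-values."""
    clusters = [c for a in analyses for c in a.clusters]
    flags = [f for a in analyses for f in a.as_flags]
    counts = domain_as_counts(clusters, flags)
    pvals = fisher_domain_enrichment(counts)
    rows = [
        {
            "domain": label,
            "n_clusters": counts.counts[label][0],
            "n_as": counts.counts[label][1],
            "fraction_as": counts.fraction(label),
            "fisher_p": pvals[label],
        }
        for label in counts.labels()
    ]
    return pd.DataFrame(rows)
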