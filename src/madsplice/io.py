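"""Reading and writing of the standard formats used by the pipeline.

FASTA goes through Biopython; GFF3 is restricted to the gene/mRNA/exon/CDS
feature subset that gene models need.  Domain and motif annotations travel
as TSV with 1-based inclusive residue coordinates.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    DomainAnnotation,
    GenomicInterval,
    Locus,
    ResidueInterval,
    TranscriptModel,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gff3",
    "read_domains_tsv",
    "write_domains_tsv",
    "read_motifs_tsv",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA file -> {id: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _parse_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gene_models(
    gff3_path: str | os.PathLike,
    fasta_path: Optional[str | os.PathLike] = None,
    genome: Optional[Mapping[str, str]] = None,
) -> tuple[dict[str, Locus], dict[str, str]]:
    """Load multi-isoform gene models from GFF3 (+ genome FASTA).

    Returns ``(loci, genome)`` where ``loci`` maps locus id to :class:`Locus`.
    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  Raises on unknown chromosome ids, exons
    outside chromosome bounds, and CDS features not nested in exons.
    """
    if genome is None:
        genome = read_fasta(fasta_path) if fasta_path is not None else {}

    mrna_to_gene: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    mrna_order: list[str] = []

    with open(gff3_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = fields
            if ftype not in ("gene", "mRNA", "exon", "CDS"):
                continue
            attributes = _parse_attributes(attrs)
            start, end = int(start1) - 1, int(end1)
            if genome:
                if chrom not in genome:
                    raise KeyError(f"unknown chromosome {chrom!r} in GFF3")
                if end > len(genome[chrom]):
                    raise ValueError(
                        f"feature {chrom}:{start1}-{end1} outside chromosome"
                    )
            if ftype == "mRNA":
                tid = attributes["ID"]
                mrna_to_gene[tid] = attributes.get("Parent", tid)
                mrna_order.append(tid)
            elif ftype == "exon":
                parent = attributes["Parent"]
                exons.setdefault(parent, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )
            elif ftype == "CDS":
                parent = attributes["Parent"]
                cds.setdefault(parent, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )

    loci: dict[str, Locus] = {}
    for tid in mrna_order:
        if tid not in exons:
            raise ValueError(f"mRNA {tid} has no exon features")
        model = TranscriptModel(  # validates CDS nesting, overlap, strand
            transcript_id=tid,
            locus_id=mrna_to_gene[tid],
            exons=exons[tid],
            cds=cds.get(tid, []),
        )
        loci.setdefault(model.locus_id, Locus(model.locus_id)).transcripts.append(
            model
        )
    # CDS features without any owning mRNA/exon are malformed input
    for parent in cds:
        if parent not in exons:
            raise ValueError(f"CDS features of {parent} overlap no exon")
    return loci, dict(genome)


def write_gff3(loci: Iterable[Locus], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for locus in loci:
        span_start = min(t.span.start for t in locus.transcripts)
        span_end = max(t.span.end for t in locus.transcripts)
        chrom, strand = locus.chrom, locus.strand
        lines.append(
            f"{chrom}\tmadsplice\tgene\t{span_start + 1}\t{span_end}\t.\t"
            f"{strand}\t.\tID={locus.locus_id}"
        )
        for t in locus.transcripts:
            lines.append(
                f"{chrom}\tmadsplice\tmRNA\t{t.span.start + 1}\t{t.span.end}\t.\t"
                f"{strand}\t.\tID={t.transcript_id};Parent={locus.locus_id}"
            )
            for iv in sorted(t.exons, key=lambda e: e.start):
                lines.append(
                    f"{chrom}\tmadsplice\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{strand}\t.\tParent={t.transcript_id}"
                )
            for iv in sorted(t.cds, key=lambda c: c.start):
                lines.append(
                    f"{chrom}\tmadsplice\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{strand}\t.\tParent={t.transcript_id}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_domains_tsv(path: str | os.PathLike) -> dict[str, DomainAnnotation]:
    """Domain TSV (protein_id, domain, start, end) -> annotations per protein.

    Domain labels M/I/K/C are required per protein; an optional ``kbox_cterm``
    row overrides the default higher-order-interaction sub-region.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[str, DomainAnnotation] = {}
    for pid, group in df.groupby("protein_id"):
        ivs = {
            str(row["domain"]).lower(): ResidueInterval(int(row["start"]), int(row["end"]))
            for _, row in group.iterrows()
        }
        out[str(pid)] = DomainAnnotation(
            protein_id=str(pid),
            m=ivs["m"],
            i=ivs["i"],
            k=ivs["k"],
            c=ivs["c"],
            kbox_cterm=ivs.get("kbox_cterm"),
        )
    return out


def write_domains_tsv(
    domains: Mapping[str, DomainAnnotation], path: str | os.PathLike
) -> None:
    rows = []
    for pid, ann in domains.items():
        for label, iv in ann.labelled():
            rows.append((pid, label, iv.start, iv.end))
        rows.append((pid, "kbox_cterm", ann.kbox_cterm.start, ann.kbox_cterm.end))
    pd.DataFrame(rows, columns=["protein_id", "domain", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_motifs_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Interaction-motif TSV (protein_id, motif_id, start, end)."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "motif_id", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"motif TSV needs columns {sorted(required)}")
    return df
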