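# Methods

This note documents the models, rules and numerical choices behind
`madsplice`, and what the synthetic benchmark does and does not show.

## Coordinate conventions

Genomic coordinates are 0-based half-open on the forward strand; GFF3 I/O
converts to/from 1-based inclusive; protein coordinates are 1-based
inclusive.  Transcript exons are stored in transcription order, so
minus-strand transcripts list their highest-coordinate exon first and all
intron phases are computed on the coding strand.  An intron's *phase* is the
number of coding nucleotides 5' of the junction modulo 3, and its
*protein position* the 0-based index of the interrupted codon (for phase 0,
the first codon after the junction).

## Event detection and typing

Two isoforms of a locus are compared through their intron sets.  Introns
unique to either chain are grouped into local difference regions by
single-linkage genomic overlap, and each region is classified independently;
differences at the outermost transcript ends are transcription start/stop
variation, not splicing, and are ignored.  The patterns are:

| pattern (unique introns a vs b)            | type                |
|--------------------------------------------|---------------------|
| 1 vs 0, intron exonic in the other isoform | intron_retention    |
| 1 vs 1, shared donor                       | alt_acceptor        |
| 1 vs 1, shared acceptor                    | alt_donor           |
| 2 vs 1, shared outer bounds, exon in ref   | exon_skip           |
| 1 vs 2, shared outer bounds, exon in alt   | cryptic_exon        |
| 2 vs 2, shared outer bounds, disjoint exons| mutually_exclusive  |
| anything else                              | complex             |

Donor/acceptor labels are strand-aware.  Exon skipping and cryptic-exon
inclusion are structurally identical in a pairwise comparison — an exon
present in one chain, absent in the other, with shared outer intron
boundaries — so the package distinguishes them by orientation to the first
argument, treated as the reference isoform: an exon the reference carries
and the alternative lacks is skipped; a novel exon inside a reference intron
is cryptic.  Unresolvable regions are reported `complex`, never guessed as a
specific type.

Intron clusters use the same single-linkage ≥1-nt-overlap rule.  A cluster
is AS-involved when it holds two distinct introns, or when its single intron
is retained (fully exonic) in another isoform.  Exact-coordinate grouping
would separate retention and alternative-site introns from their fully
spliced counterparts, which is why overlap linkage was chosen.

## Protein-level effects

Isoform proteins are the translations of their longest ATG-initiated ORFs.
Effects come from a global alignment (BLOSUM62, gap open 10, gap extend 0.5,
end gaps free — needle-style defaults).  The event's genomic footprint is
projected onto each isoform's residue coordinates; an insertion that has no
coding overlap on one isoform is anchored at its junction residues there.
The amino-acid difference is the number of gapped or mismatched columns in
the projected column window; because optimal gap placement is ambiguous up
to local sequence repeats, the window absorbs gap runs immediately adjacent
to it.  `frame_shift` is true when the coding-length difference inside the
footprint is not a multiple of 3; `truncation_aa` counts residues of the
longer protein beyond the last aligned column.

Domain labels follow the M/I/K/C annotation of the isoform that carries the
affected residues (boundaries transferred by alignment when that is not the
reference).  An interval containing the last residue of one domain or the
first residue of the next is a border case (`border-I/K` etc.); otherwise
the containing domain; otherwise `outside`.

## Decay rule

A transcript is a predicted NMD target when the first base of its stop codon
lies strictly more than 55 nt upstream of its last exon–exon junction in
spliced coordinates.  Which end of the stop codon anchors the distance is a
convention; the first base was chosen and the boundary tests (54/55/56 nt)
pin it.  Single-exon transcripts are never targets.  A target is downgraded
to *ambiguous* when a downstream ATG-initiated ORF of ≥ 30 residues escapes
the rule — such transcripts may be degraded or translated from the
downstream start, and both NMD targets and ambiguous cases are excluded
from protein-level interpretation.

## Per-domain enrichment

Intron clusters are labelled by the domain their junction interrupts, and
each domain is tested against all other domains combined in a 2×2 table
(AS / non-AS × domain / rest) with a two-sided Fisher's exact test — the
most conservative standard framing when the contingency construction is not
otherwise determined.  Degenerate tables (a zero margin) return p = 1.  On
the published cluster counts (I: 11/46, K: 16/147, C: 2/22) the I-domain
test gives p = 0.0277, rounding to 0.03.  The test implementation is
scipy's exact hypergeometric; the suite cross-checks it against an
independent enumeration in exact rational arithmetic.

## Homology and AIP conservation

Contigs are translated stop-to-stop in all six frames (fragments ≥ 30
residues).  Each fragment's best reference protein is the highest-scoring
Smith–Waterman hit (BLOSUM62, 10/0.5), accepted when identity ≥ 40 % over
aligned columns and when the alignment covers ≥ 60 % of the reference
residues.  Because a local alignment may clip mutated ends or skip mismatch
clusters with gaps, acceptance is sharp in the *measured* identity but soft
in ground-truth divergence; the tests assert exactly that.

Intron positions are transferred onto homologs through global alignments;
positions landing in subject gaps are unmapped.  An AIP is a maximal gap run
between two isoform proteins whose flanking columns contain a transferred
intron position.  Numerical choices, all configurable:

* **Flank window** — "ten flanking positions" is read as 5 columns on each
  side; ≥ 4 identical pairs and ≤ 1 gapped position are required.
* **Gapless anchor** — at least one of the two isoforms must align to the
  reference without gaps within ±5 residues of the intron position.  The
  isoform carrying an insertion necessarily has a gap there, so the anchor
  is evaluated on both isoforms' reference alignments.
* **Position tolerance** — optimal gap placement wobbles by up to the length
  of a local repeat, so an intron column may sit up to 3 columns outside the
  gap run and still coincide.  Decoy indels in the benchmark are placed ≥ 8
  residues from any junction, well clear of this tolerance.
* **Similarity** — two AIPs are conserved when the global alignment of their
  carrier (longer-isoform) sequences has ≥ 40 % positive-scoring columns
  under BLOSUM62, gap columns counting in the denominator; "similar" has no
  standard definition and this one is symmetric and equals 100 % on self.

E-value thresholds are replaced by raw score floors because the desk-scale
databases used here make e-value calibration meaningless.

## Exonization scan

A (cryptic) exon is searched in an intron with a local nucleotide alignment
(+5/−4, gaps 10/0.5, score floor 50 ≈ ten exact matches).  The nearest AG
dinucleotide at or upstream of the homologous region's 5' edge is the
candidate acceptor; its offset to the region decides frame preservation
(offset mod 3 = 0), and the region is translated in the exon's reading frame
to detect in-frame stops.  A remnant is translatable iff the frame is
preserved and no in-frame stop occurs — the benchmark constructs reproduce
the three outcomes: acceptor 2 nt upstream (frame-shift), implanted in-frame
stop (untranslatable), and a clean remnant (translatable).

## Synthetic data

The generator emulates MIKC gene structure with a default layout of 240
residues (M 1–60, I 61–90, K 91–180 with its distal half as the
higher-order-interaction region, C 181–240), a long first exon spanning M
and part of I, 90-nt internal exons, 102-nt introns with canonical GT..AG
sites, and 60-nt pyrimidine-only UTRs (so the annotated ORF is provably the
longest).  Junction offsets are multiples of 3 (phase 0) except where a
test constructs otherwise.  Events are implanted by rewriting intron
interiors (alternative sites, cassette exons, in-frame stop-free segments)
so the reference protein is never perturbed; every implant records its
expected type, size, amino-acid difference and domain label, and the decay
status of each isoform is derived by applying the junction rule to the
constructed exon lengths.

Orthologs are produced by nucleotide substitutions with a 2:1 transition
bias at a per-site rate calibrated so realized protein divergence
approximates the requested value (default species at d = 0.05 and 0.10);
substitutions recreating stop codons are discarded and intron positions are
untouched.  Conserving species carry the homologous indel at the homologous
intron position; decoy species carry an indel away from all junctions.
There is no indel process beyond the implanted polymorphisms, no rate
heterogeneity and no selection model — the generator tests algorithms, not
evolution.  Passing benchmarks therefore demonstrate correct recovery under
clean, single-event, moderately diverged conditions; they do not establish
performance on real EST assemblies with sequencing error, paralogy, or
compound events, where the `complex` fallback and the best-hit filter do
the guarding.

Problem sizes used by the default suite — 1,000 loci for event-type
recovery, 500 positive ortholog replicates (plus 250 decoys) for AIP
recovery, 200 random instances for the clustering oracle and 400 tables for
the Fisher oracle — keep the full run around half a minute while giving the
recovery rates two significant digits.

## Known limitations

* Pairwise domain-boundary transfer approximates the multiple-alignment
  annotation it stands in for; boundaries inside gaps snap toward the
  domain interior, preferring the downstream residue at start boundaries
  and the upstream residue at end boundaries.
* Event decomposition is greedy 5'→3'; isoform pairs differing by several
  interleaved changes may be reported `complex` where a human would
  enumerate individual events.
* The NMD model implements only the 55-nt junction rule — no uORFs, long
  3'-UTR triggers, or decay efficiency.
* Interaction motifs are consumed as annotations; the package neither
  predicts motifs nor dimerization partners.
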