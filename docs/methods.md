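# Methods

This note documents the models, conventions and design choices behind
circkit, in the order the pipeline applies them.

## Coordinates and junction identity

All internal coordinates are 0-based, half-open, on the forward genomic
strand; conversions to and from 1-based inclusive conventions happen only
in the readers and writers (GTF, CIRI2, archive dumps). A backsplice
junction is identified everywhere by the exact key
*(contig, start, end, strand)* — `start` is the leftmost genomic base of
the circle's span. Junction equality is exact: database reconciliation
must be deterministic and symmetric, so no fuzzy matching happens at this
layer; all tolerance for ragged ends lives in the transcript matcher.
Strand is mandatory (a strandless BED row is rejected rather than
guessed), because the circle's sequence depends on it.

CIRI2-style tables are filtered by junction-read support
(`min_reads`, default **2** reads). The callers themselves do not fix a
threshold; two independent junction reads is the smallest support that is
not a singleton artifact, and the flag is exposed for stricter runs.

## Representative transcript and nomenclature

A transcript matches a junction when the circle's 5' end falls within
±`tolerance` nt of some exon's transcript-5' boundary (acceptor exon *M*)
and the 3' end within ±tolerance of an exon's transcript-3' boundary
(donor exon *N*), M ≤ N. On the `-` strand, the genomic-left junction end
is the donor side. `tolerance` defaults to **2 nt**, the typical aligner
wobble at splice boundaries.

Candidates are ranked by the lexicographic key

1. total offset (|acceptor| + |donor|), ascending;
2. CCDS-tagged first (either `tag "CCDS"` or a `ccds_id` attribute);
3. commonness, descending — the number of input junctions the transcript
   matches, computed in a first pass, so that all backsplices of one gene
   are expressed on as few reference transcripts as possible;
4. exon count, descending;
5. spliced length, descending;
6. transcript id, ascending (a total order; later ties are impossible).

Junction fit is ranked first deliberately: an ill-fitting transcript
cannot define a valid exon pair, whatever its curation status. The order
is lexicographic rather than weighted because a weighted score would need
calibration data that does not exist for this task; the criterion order is
a package constant and easy to change in `reference._rank_key`.
"Conservation" is sometimes listed as a transcript-selection criterion in
this field but has no operational definition here, so it is not part of
the ranking. Commonness is grouped by `gene_id`, not symbol, because
symbols collide. Single-exon transcripts are eligible references (they can
host an M = N circle).

The display name is `SYMBOL_eM-eN` (`SYMBOL_eM` when M = N). Names encode
only (symbol, M, N); two circles assigned to *different* isoforms of one
gene can share a name, which is why the annotation table always carries
the `ref_transcript` column alongside.

## Circle assembly

The circle is the spliced sequence of exons M..N of the representative
transcript, with both ends adjusted by the signed match offsets so it
reflects the junction's actual coordinates; a positive donor offset on the
`+` strand extends the 3' end into the downstream intron. Offsets may not
consume an entire terminal exon, and intronic extensions are capped at
50 nt (`MAX_INTRONIC_EXTENSION`) as a sanity bound far above the matching
tolerance. Position 0 of the circle is the first base of the acceptor
exon; the junction sits between position L−1 and 0. Each circle keeps its
block map (circle interval → exon ordinal and genomic interval) for
back-projection.

## ORF enumeration

Start codon ATG only; stops TAA/TAG/TGA; standard genetic code — no
alternative starts, since near-cognate initiation would need
ribosome-profiling evidence this toolkit does not consume.

The circle is unrolled as four copies plus two bases and each of the three
frames is scanned with the maximal-ORF convention: the first ATG after a
stop (or after the scan origin) opens an ORF; in-frame ATGs inside an open
ORF are ignored; the first in-frame stop closes it, with the stop codon
counted inside `length_nt` — a stop straddling the junction is a
junction-dependent stop and belongs to the ORF. Records are deduplicated
on `(start mod L, length_nt)`.

After 3·L nt a reading revisits the same circle position in the same
frame, so the absence of a stop within 3·L nt of a start proves the ORF is
infinite (`edlsC`). Four unrolled copies are needed to give every start in
the first copy that full 3·L window. An endless ORF is reported with
`length_nt = 0`, `crossings = None` and one minimal period of its
repeating peptide (L/3 codons when L ≡ 0 mod 3, otherwise L codons —
the reading then visits every base before repeating). When L is not a
multiple of 3 the three scan frames are phases of one circular reading, so
a stop-free circle can surface up to three endless records, one per frame
origin; this is a property of the maximal-start convention and is shared
exactly by the brute-force oracle.

Crossing counts use the closed form
`crossings = floor((start + length_nt − 1) / L)`, which equals the number
of times the reading steps across the junction; the independent oracle
counts those passages base by base instead.

Finite peptides shorter than `min_peptide` are dropped (default **20 aa**
for pipeline runs, so micro-ORFs do not flood the tables; tests and the
fixture pipeline use 1 to exercise every record). Endless ORFs are never
dropped. ORFs with three or more crossings keep their true count in the
record but are labeled `2C` — the class vocabulary stops there.

## Novel-terminus classification

The parental CDS is projected onto the circle with per-base CDS positions
(phase-corrected from the GTF frame field). A codon of an ORF is
*parental* iff its three bases sit at consecutive CDS positions starting
at phase 0 — same sequence position *and* same reading frame as the
parental protein.

For a single-crossing ORF the complete codons strictly before/after the
junction passage form the pre/post segments (a codon straddling the
junction belongs to neither; an empty segment counts as non-parental):

- pre parental, post not → novel C terminus, `1C3'`;
- post parental, pre not → novel N terminus, `1C5'`;
- both parental (in-frame junction) → `1C3'` with qualifier
  `frame-preserving`, no novelty flags;
- neither parental, or non-coding host → `1C3'` with qualifier
  `no-parental-frame`, both flags set.

The qualifiers are not new classes; they keep the five-class vocabulary
intact while recording the two degenerate single-crossing cases. `0C` ORFs
are never novel (they are indistinguishable from the linear ORF), and
`2C`/`edlsC` are novel at both ends by construction.

`map_orf_to_protein` places the longest parental codon run on the protein
by pure coordinate arithmetic (residue = CDS position / 3 + 1 — parental
codons are exact by construction, no alignment needed); the non-parental
codons on each side become the N/C overhang lengths. An ORF with no
parental codon has no anchor that divides it, so the record carries an
empty interval and reports the full peptide length on both overhang
fields.

## Localization and reconciliation

The compartment vocabulary is fixed to the four fractionation labels
*cytoplasm, nucleoplasm, chromatin, polysome* (chromatin being the
insoluble nuclear fraction, polysome the heavy sucrose-gradient
fractions). A junction's profile is simple presence per compartment; Venn
partitions over labeled sets count every non-empty label subset and always
sum to the union size. Source labels are preserved per input file, so
reports can be built per cell line or pooled. Assembly mismatches between
resources are the caller's responsibility — the toolkit performs no
liftover.

## Synthetic data

The fixture generator emulates every input at toy scale (one ≤ 10 kb
contig, 10 transcripts, 20 junctions): Ensembl-dialect GTF, per-
compartment CIRI2 tables, circBase-like and circRNADb-like dumps (their
synthetic dialects are defined by the generator itself), a domain table,
and a ground-truth JSON. Designed content:

- one circle per crossing class, found by seeded random search and
  accepted only when the independent oracle confirms a single ORF of the
  designed class with the designed novelty geometry (CDS covers each
  scenario circle at phase 0, so frame arithmetic fixes the flags); one
  scenario gene is on the `-` strand;
- a commonness gene whose shared transcript fits all three junctions
  while a rival with more exons and greater length fits only one —
  commonness alone decides;
- a three-transcript gene hosting 9/2/1 exon pairs, reproducing the
  isoform-diversity *shape* reported for PTP4A2 (structure only, not the
  real gene);
- archive/compartment memberships populating all 7 regions of the 3-set
  Venn and a varied 4-compartment design.

Ground truth is computed from the blueprints and the oracle, never by the
engine under test. What the fixtures do **not** emulate: read-level noise,
alignment artifacts, multi-mapping, assembly differences, overlapping
genes, or realistic read-count distributions — passing tests demonstrate
correctness of the annotation logic, not robustness of upstream circRNA
calling.

Problem sizes were chosen so the whole suite and the acceptance script
each complete in seconds: 1,000 random circles with L ∈ [9, 300] for the
oracle-equivalence check (both L mod 3 classes represented), 400–600
circles for the closed-form checks, and the 20-junction fixture for
everything end-to-end.

## Determinism

Every stage is a pure function of its inputs: rankings have a total
order, tables are sorted by junction key, SVG rendering uses fixed
formatting with no timestamps or generated ids, and the generator drives
all randomness from one seed. Two runs on the same inputs produce
byte-identical output trees, which the test suite asserts literally.

## Known limitations

- No IRES prediction, ribosome-profiling integration, or translation-
  efficiency modeling; an enumerated ORF is a geometric object, not
  evidence of translation.
- The 1C5'/1C3' decision is parental-frame based; for hosts with several
  annotated CDS isoforms only the representative transcript's CDS is
  consulted.
- Archive parsing covers position-string and split-column dialects via a
  column map; exotic dumps may need a custom map.
- No GFF3 input, chromosome-alias resolution, or liftover.
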