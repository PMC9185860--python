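# circkit

Annotation and visualization toolkit for circular RNAs (circRNAs):
backsplice-junction normalization, representative-transcript nomenclature,
rolling-circle ORF classification, subcellular-localization profiling, and
deterministic SVG rendering.

## The problem

A circRNA forms when a downstream splice donor joins an upstream splice
acceptor, producing a covalently closed circle; the joint is the
*backsplice junction*. Working with circRNAs is awkward for two reasons:

1. **Naming.** Databases use incompatible accession schemes
   (`hsa_circ_…`, `circRNA_…`), so the same circle is hard to recognize
   across resources, and a junction by itself does not say which exons of
   which transcript it spans.
2. **Translation.** Because the molecule is a circle, a ribosome can read
   through the junction — possibly repeatedly — so ORF prediction on the
   linear sequence misses junction-crossing and even infinite ("endless")
   reading frames.

circkit addresses both for anyone analyzing backsplice calls from
fractionated RNA-seq or comparing database dumps: it reduces every record
to the exact key *(contig, start, end, strand)*, assigns each junction a
**representative reference transcript** and backsplice exon pair *M/N*
(naming the circle `SYMBOL_eM-eN`), and enumerates circular ORFs with a
crossing-count classification.

## Core methods

**Representative transcript.** Candidate transcripts whose exon boundaries
fit the junction ends within a small tolerance (default ±2 nt) are ranked
lexicographically by: total offset to annotated exon boundaries ↑, CCDS
status first, *commonness* ↓ (how many of the gene's junctions the
transcript fits — so one gene's circles land on a minimal number of
reference transcripts), exon count ↓, transcript length ↓, transcript id.
Assignment is a deterministic two-pass procedure (commonness is computed
over all junctions first).

**Circular ORFs.** The circle of length *L* is unrolled and every reading
frame scanned with the maximal-ORF convention (first ATG after a stop).
Each ORF's junction crossings follow the closed form
`crossings = floor((start + length − 1) / L)` and determine its class:

| class | crossings | termini vs parental protein |
|-------|-----------|------------------------------|
| `0C`   | 0         | indistinguishable from the linear ORF |
| `1C5'` | 1         | novel N terminus |
| `1C3'` | 1         | novel C terminus |
| `2C`   | ≥ 2       | novel at both ends |
| `edlsC`| ∞         | endless; peptide is a repeating period |

If no stop occurs within 3·*L* nt of a start, the reading has returned to
the same circle position and frame, which proves the ORF is infinite.
Novel-terminus calls compare each codon against the parental CDS projected
onto the circle (position *and* frame must match).

## Worked example

`python examples/02_orf_classes.py` classifies four 9–10 nt circles:

```
circle ATGAAATAA (L=9): plain linear ORF, never reaches the junction
  start=0 length_nt=9 crossings=0 class=0C peptide=MK

circle TAAATGCCC (L=9): start near the 3' end, reads once across the junction
  start=3 length_nt=9 crossings=1 class=1C3' peptide=MP

circle ATGAAAAAAA (L=10): stop only appears after two passes of the junction
  start=0 length_nt=24 crossings=2 class=2C peptide=MKKNEKK

circle ATGGCTGCT (L=9): stop-free frame: the ORF is endless (rolling circle)
  start=0 length_nt=inf crossings=inf class=edlsC peptide=MAA
```

The second circle's ORF begins 6 nt before the junction and finds its stop
only after wrapping around — a junction-dependent C terminus. The last has
a stop-free frame, so translation never terminates and the peptide repeats
the period `MAA`.

The other examples generate a synthetic input bundle (genome, GTF,
per-compartment CIRI2-style calls, circBase/circRNADb-like dumps), run the
full pipeline (`examples/01_fixture_and_annotate.py` prints the 20-row
annotation table), reconcile the three sources into a 7-region Venn
partition (`examples/03_database_reconciliation.py`), and render the SVG
views (`examples/04_plots.py`).

## Command line

```
circkit fixtures out/fixture --seed 0          # synthetic input bundle
circkit annotate --config config.yaml          # annotation/ORF/localization tables
circkit venn --config config.yaml              # Venn region table
circkit plot --config config.yaml --gene GVIZ  # SVG views
```

The YAML config lists the genome FASTA, the Ensembl-dialect GTF, labeled
junction inputs (CIRI2 TSV or BED6, optionally tagged with a subcellular
compartment), archive dumps, and the parameters `tolerance`, `min_reads`,
`min_peptide`.

## Layout

- `src/circkit/models.py` — genome + transcript models, GTF/FASTA I/O
- `src/circkit/junctions.py` — junction parsing, reconciliation, localization
- `src/circkit/reference.py` — representative-transcript ranking, nomenclature
- `src/circkit/orfs.py` — circle assembly, ORF enumeration/classification
- `src/circkit/oracle.py` — independent brute-force reference scanner
- `src/circkit/viz.py` — deterministic SVG renderers
- `src/circkit/fixtures.py` — synthetic data generator with ground truth
- `src/circkit/pipeline.py`, `cli.py` — the end-to-end pipeline and CLI

See `docs/methods.md` for the modeling choices and their rationale.
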