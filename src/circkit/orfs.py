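"""Circular-sequence assembly and rolling-circle ORF classification.

Because a circRNA is covalently closed, a ribosome entering at an AUG can
read through the backsplice junction, so candidate ORFs must be considered
beyond the circle's own length L.  Every ORF is classified by how many
times its reading passes the junction:

* ``0C``   — never crosses; indistinguishable from an ORF of the parental
  linear RNA (so it can carry no novel termini);
* ``1C5'`` — crosses once and gains a novel N-terminal sequence;
* ``1C3'`` — crosses once and gains a novel C-terminal sequence;
* ``2C``   — crosses two or more times; novel at both ends;
* ``edlsC`` — endless: the reading frame never meets a stop codon, the ORF
  is infinite and its peptide is a repeat of one minimal period.

Enumeration uses the maximal-ORF convention (the first ATG after a stop
opens an ORF; in-frame ATGs inside an open ORF are ignored) on the circle
unrolled four times.  After 3·L nt a reading revisits the same circle
position in the same frame, so the absence of a stop within 3·L nt of a
start proves the ORF is endless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .junctions import BacksplicedJunction  # noqa: F401  (typing context)
from .models import GenomeSequence, TranscriptModel, revcomp, translate
from .reference import RepAssignment

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"


@dataclass(frozen=True)
class CircleBlock:
    """One exon block of the circle: circle interval -> genomic interval."""

    circ_start: int
    circ_end: int
    exon_index: int
    contig: str
    g_start: int
    g_end: int


@dataclass
class CircularSequence:
    """The circle's sequence in 5'->3' reading orientation.

    Position 0 is the first base of the acceptor exon (the circle 5' end);
    position L-1 the last base of the donor exon; the backsplice junction
    sits between L-1 and 0.  For '-' strand sources each genomic block is
    reverse complemented and blocks appear in transcript order.
    """

    seq: str
    blocks: list[CircleBlock]
    strand: str
    transcript_id: str | None = None

    @property
    def L(self) -> int:
        return len(self.seq)

    def genomic_position(self, circ_pos: int) -> tuple[str, int]:
        """Map a circle position back to (contig, genomic position)."""
        for b in self.blocks:
            if b.circ_start <= circ_pos < b.circ_end:
                off = circ_pos - b.circ_start
                if self.strand == "+":
                    return (b.contig, b.g_start + off)
                return (b.contig, b.g_end - 1 - off)
        raise ValueError(f"circle position {circ_pos} out of range")


def build_circle(
    a: RepAssignment,
    models: list[TranscriptModel] | dict[str, TranscriptModel],
    genome: GenomeSequence,
) -> CircularSequence:
    """Assemble the circular sequence for an assigned junction.

    The circle is the spliced sequence of exons M..N of the representative
    transcript with both ends adjusted by the match offsets, so it reflects
    the junction's actual coordinates (a positive donor offset on '+'
    extends the 3' end into the downstream intron).  An offset that would
    consume an entire terminal exon is an error.
    """
    if not a.assigned:
        raise ValueError("cannot build a circle for an unassigned junction")
    models_by_id = (
        models if isinstance(models, dict)
        else {t.transcript_id: t for t in models}
    )
    t = models_by_id[a.transcript_id]
    m, n = a.exon_pair
    acc_off, don_off = a.match.acceptor_offset, a.match.donor_offset

    # Adjusted genomic bounds of the terminal exons.
    bounds = []
    for ordinal in range(m, n + 1):
        exon = t.exon(ordinal)
        g_start, g_end = exon.start, exon.end
        if t.strand == "+":
            if ordinal == m:
                g_start = exon.start + acc_off
            if ordinal == n:
                g_end = exon.end + don_off
        else:
            if ordinal == m:  # acceptor exon: transcript-5' boundary = genomic end
                g_end = exon.end + acc_off
            if ordinal == n:  # donor exon: transcript-3' boundary = genomic start
                g_start = exon.start + don_off
        if g_start >= g_end:
            raise ValueError(
                f"offset eliminates exon {ordinal} of {t.transcript_id}"
            )
        if g_start < exon.start - MAX_INTRONIC_EXTENSION or g_end > exon.end + MAX_INTRONIC_EXTENSION:
            raise ValueError(
                f"offset pushes exon {ordinal} of {t.transcript_id} "
                "outside its neighbourhood"
            )
        bounds.append((exon.index, g_start, g_end))

    blocks: list[CircleBlock] = []
    parts: list[str] = []
    pos = 0
    for exon_index, g_start, g_end in bounds:
        block_seq = genome.fetch(t.contig, g_start, g_end)
        if t.strand == "-":
            block_seq = revcomp(block_seq)
        blocks.append(
            CircleBlock(pos, pos + len(block_seq), exon_index, t.contig,
                        g_start, g_end)
        )
        parts.append(block_seq)
        pos += len(block_seq)
    return CircularSequence("".join(parts), blocks, t.strand, t.transcript_id)


#: Maximum nt an end offset may extend a terminal exon into its intron.
MAX_INTRONIC_EXTENSION = 50


@dataclass
class CircOrf:
    """One ORF on the circle.

    ``length_nt`` includes the stop codon and is 0 for endless ORFs; for an
    endless ORF ``peptide`` holds one minimal period of the repeating
    peptide and ``crossings`` is None (infinite).  A stop codon straddling
    the junction is a junction-dependent stop and counts toward crossings.
    """

    start: int
    length_nt: int
    crossings: int | None
    orf_class: str
    peptide: str
    novel_n: bool = False
    novel_c: bool = False
    qualifier: str | None = None

    @property
    def endless(self) -> bool:
        return self.length_nt == 0


def _geometry_class(crossings: int | None) -> str:
    if crossings is None:
        return "edlsC"
    if crossings == 0:
        return "0C"
    if crossings == 1:
        return "1C3'"  # provisional; classify_novelty finalizes the subtype
    return "2C"


def enumerate_orfs(c: CircularSequence, min_peptide: int = 1) -> list[CircOrf]:
    """Enumerate all maximal ORFs of a circle, with crossing counts.

    The circle is unrolled (four copies plus two bases) and each of the
    three frames is scanned with the maximal-ORF convention; records are
    deduplicated on ``(start mod L, length_nt)``.  Finite peptides shorter
    than ``min_peptide`` amino acids are dropped; endless ORFs never are.
    Crossings follow the closed form ``floor((start + length_nt - 1) / L)``.
    """
    L = c.L
    if L < 3:
        raise ValueError(f"circle length {L} < 3")
    unrolled = c.seq * 4 + c.seq[:2]
    found: dict[tuple[int, int], CircOrf] = {}

    for frame in range(3):
        open_at: int | None = None
        for p in range(frame, len(unrolled) - 2, 3):
            codon = unrolled[p : p + 3]
            if open_at is None:
                if codon == START_CODON:
                    open_at = p
            elif codon in STOP_CODONS:
                length = p + 3 - open_at
                if open_at < L:
                    key = (open_at % L, length)
                    if key not in found:
                        peptide = translate(unrolled[open_at : p])
                        crossings = (open_at + length - 1) // L
                        found[key] = CircOrf(
                            open_at, length, crossings,
                            _geometry_class(crossings), peptide,
                        )
                open_at = None
        if open_at is not None and open_at < L:
            # No stop within >= 3L nt of the start: the reading returned to
            # the same circle position and frame, so the ORF is endless.
            period = L // 3 if L % 3 == 0 else L
            key = (open_at % L, 0)
            if key not in found:
                peptide = translate(unrolled[open_at : open_at + 3 * period])
                found[key] = CircOrf(open_at, 0, None, "edlsC", peptide)

    orfs = [
        o for o in found.values()
        if o.endless or len(o.peptide) >= min_peptide
    ]
    orfs.sort(key=lambda o: (o.start, o.length_nt))
    return orfs


@dataclass
class CdsProjection:
    """The parental CDS mapped onto circle coordinates.

    ``intervals`` lists maximal circle intervals of contiguous coding
    sequence as ``(circ_start, circ_end, phase_at_start)``; ``cds_pos``
    gives, per circle position, the 0-based position within the annotated
    CDS (-1 for non-coding), phase-corrected so ``cds_pos % 3`` is the
    codon phase.
    """

    present: bool
    intervals: list[tuple[int, int, int]] = field(default_factory=list)
    cds_pos: list[int] = field(default_factory=list)


def project_cds(
    a: RepAssignment,
    c: CircularSequence,
    models: list[TranscriptModel] | dict[str, TranscriptModel],
) -> CdsProjection:
    """Intersect the representative transcript's CDS with the circle."""
    models_by_id = (
        models if isinstance(models, dict)
        else {t.transcript_id: t for t in models}
    )
    t = models_by_id[a.transcript_id]
    if not t.cds_intervals:
        return CdsProjection(present=False, cds_pos=[-1] * c.L)

    # Walk the CDS in transcript order, assigning each genomic base its
    # position within the CDS; the first interval's frame sets the phase.
    first_frame = t.cds_intervals[0][2]
    phase0 = (3 - first_frame) % 3
    genomic_cds: dict[int, int] = {}
    walk = phase0
    for s, e, _frame in t.cds_intervals:
        positions = range(s, e) if t.strand == "+" else range(e - 1, s - 1, -1)
        for g in positions:
            genomic_cds[g] = walk
            walk += 1

    cds_pos = [-1] * c.L
    for i in range(c.L):
        _contig, g = c.genomic_position(i)
        cds_pos[i] = genomic_cds.get(g, -1)

    intervals = []
    i = 0
    while i < c.L:
        if cds_pos[i] < 0:
            i += 1
            continue
        start = i
        while (
            i + 1 < c.L
            and cds_pos[i + 1] == cds_pos[i] + 1
        ):
            i += 1
        intervals.append((start, i + 1, cds_pos[start] % 3))
        i += 1
    return CdsProjection(
        present=bool(intervals), intervals=intervals, cds_pos=cds_pos
    )


def _codon_parental(u: int, L: int, cds_pos: list[int]) -> bool:
    """Is the codon starting at unrolled position u a parental codon?

    Parental means all three bases lie in the projected CDS at consecutive
    CDS positions, with the codon aligned to the parental reading frame.
    """
    v = [cds_pos[(u + i) % L] for i in range(3)]
    return (
        v[0] >= 0
        and v[1] == v[0] + 1
        and v[2] == v[0] + 2
        and v[0] % 3 == 0
    )


def _segment_flags(o: CircOrf, p: CdsProjection, L: int) -> tuple[bool, bool]:
    """(pre_parental, post_parental) for a single-crossing ORF.

    Segments are the complete translated codons strictly before / after the
    junction passage; a codon straddling the junction belongs to neither; a
    segment with no complete codon counts as non-parental.
    """
    pre, post = [], []
    for k in range(len(o.peptide)):
        u = o.start + 3 * k
        if u + 3 <= L:
            pre.append(u)
        elif u >= L:
            post.append(u)
    pre_ok = bool(pre) and all(_codon_parental(u, L, p.cds_pos) for u in pre)
    post_ok = bool(post) and all(_codon_parental(u, L, p.cds_pos) for u in post)
    return pre_ok, post_ok


def classify_novelty(o: CircOrf, p: CdsProjection, L: int) -> CircOrf:
    """Finalize the class label and novel-terminus flags of an ORF.

    A single-crossing ORF whose pre-junction codons match the parental
    reading frame gains a novel C terminus (1C3'); one whose post-junction
    codons match gains a novel N terminus (1C5').  If both segments are
    parental the junction was frame-preserving; if neither is (or the host
    is non-coding) both termini are novel and the record is qualified
    ``no-parental-frame``.  Multi-crossing ORFs are novel at both ends.
    """
    if o.endless:
        return replace(o, orf_class="edlsC", novel_n=True, novel_c=True,
                       qualifier=None)
    if o.crossings == 0:
        return replace(o, orf_class="0C", novel_n=False, novel_c=False,
                       qualifier=None)
    if o.crossings >= 2:
        return replace(o, orf_class="2C", novel_n=True, novel_c=True,
                       qualifier=None)

    pre_ok, post_ok = (
        _segment_flags(o, p, L) if p.present else (False, False)
    )
    if pre_ok and not post_ok:
        return replace(o, orf_class="1C3'", novel_n=False, novel_c=True,
                       qualifier=None)
    if post_ok and not pre_ok:
        return replace(o, orf_class="1C5'", novel_n=True, novel_c=False,
                       qualifier=None)
    if pre_ok and post_ok:
        return replace(o, orf_class="1C3'", novel_n=False, novel_c=False,
                       qualifier="frame-preserving")
    return replace(o, orf_class="1C3'", novel_n=True, novel_c=True,
                   qualifier="no-parental-frame")


@dataclass
class OrfProteinAlignment:
    """A cORF placed on its parental protein by coordinate arithmetic.

    ``residue_start``/``residue_end`` are the 1-based inclusive bounds of
    the parental residue run; overhangs count the non-parental codons on
    each side.  An ORF with no parental codons has no anchor: the interval
    is empty and both overhang fields report the full peptide length.
    """

    residue_start: int | None
    residue_end: int | None
    novel_n_aa: int
    novel_c_aa: int


def map_orf_to_protein(
    o: CircOrf, p: CdsProjection, L: int, parent_protein_length: int
) -> OrfProteinAlignment:
    """Align a finite cORF to the parental protein (no sequence alignment
    needed — parental codons are exact by construction)."""
    if o.endless:
        raise ValueError("an endless ORF has no finite protein alignment")
    if not p.present:
        n = len(o.peptide)
        return OrfProteinAlignment(None, None, n, n)

    flags = []
    residues = []
    for k in range(len(o.peptide)):
        u = o.start + 3 * k
        ok = _codon_parental(u, L, p.cds_pos)
        flags.append(ok)
        residues.append(p.cds_pos[u % L] // 3 + 1 if ok else None)

    # Longest run of parental codons (first on ties).
    best = (0, None, None)  # (run length, start index, end index)
    i = 0
    while i < len(flags):
        if flags[i]:
            jx = i
            while jx + 1 < len(flags) and flags[jx + 1]:
                jx += 1
            if jx - i + 1 > best[0]:
                best = (jx - i + 1, i, jx)
            i = jx + 1
        else:
            i += 1
    if best[0] == 0:
        n = len(o.peptide)
        return OrfProteinAlignment(None, None, n, n)
    _run, i0, i1 = best
    res = [residues[k] for k in range(i0, i1 + 1)]
    return OrfProteinAlignment(
        residue_start=min(res),
        residue_end=max(res),
        novel_n_aa=i0,
        novel_c_aa=len(flags) - 1 - i1,
    )


def analyze_circle(
    a: RepAssignment,
    models,
    genome: GenomeSequence,
    min_peptide: int = 1,
) -> tuple[CircularSequence, CdsProjection, list[CircOrf]]:
    """Convenience pipeline: circle -> CDS projection -> classified ORFs."""
    c = build_circle(a, models, genome)
    p = project_cds(a, c, models)
    orfs = [classify_novelty(o, p, c.L) for o in enumerate_orfs(c, min_peptide)]
    return c, p, orfs
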