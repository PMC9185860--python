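"""Representative-transcript assignment and circRNA nomenclature.

Each backsplice junction is matched against annotated transcripts: a match
requires the circle's 5' end to fall within a small tolerance of an exon's
transcript-5' boundary (the acceptor exon M) and its 3' end near an exon's
transcript-3' boundary (the donor exon N), with M <= N.  On the ``-``
strand the genomic-left junction end maps to the donor side.

Candidates are then ranked lexicographically:

1. total offset to the annotated exon boundaries, ascending (junction fit
   first — an ill-fitting transcript cannot define a valid exon pair);
2. CCDS-tagged transcripts first;
3. commonness, descending — how many of the input junctions the transcript
   matches, so that all backsplices of one gene land on a minimal number of
   reference transcripts;
4. exon count, descending;
5. transcript length, descending;
6. transcript_id, ascending (total order; ties are impossible beyond here).

Commonness is computed in a first pass over all junctions, making the
assignment a deterministic two-pass procedure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .junctions import BacksplicedJunction
from .models import TranscriptModel

#: Default wobble allowed between a junction end and an annotated exon
#: boundary, in nucleotides (aligner imprecision at splice sites).
DEFAULT_TOLERANCE = 2


@dataclass(frozen=True)
class TranscriptMatch:
    transcript_id: str
    acceptor_exon: int  # ordinal M
    donor_exon: int  # ordinal N
    acceptor_offset: int  # junction boundary minus exon boundary (genomic nt)
    donor_offset: int

    @property
    def total_offset(self) -> int:
        return abs(self.acceptor_offset) + abs(self.donor_offset)

    @property
    def exon_pair(self) -> tuple[int, int]:
        return (self.acceptor_exon, self.donor_exon)


@dataclass
class RepAssignment:
    junction: BacksplicedJunction
    gene_id: str | None
    gene_symbol: str | None
    transcript_id: str | None
    exon_pair: tuple[int, int] | None
    name: str | None
    competing_matches: int
    match: TranscriptMatch | None

    @property
    def assigned(self) -> bool:
        return self.transcript_id is not None


def match_transcripts(
    j: BacksplicedJunction,
    models: list[TranscriptModel],
    tolerance: int = DEFAULT_TOLERANCE,
) -> list[TranscriptMatch]:
    """All (transcript, exon pair) candidates fitting a junction.

    Offsets are signed genomic-coordinate differences (junction boundary
    minus exon boundary); each must be within ``±tolerance``.  Transcripts
    on a different contig or strand never match.  An empty list means the
    junction is unannotatable against these models.
    """
    out: list[TranscriptMatch] = []
    for t in models:
        if t.contig != j.contig or t.strand != j.strand:
            continue
        # Transcript-5' boundary of each exon is its genomic start on '+',
        # its genomic end on '-'; the circle 5' end is the genomic-left
        # junction end on '+', the genomic-right end on '-'.
        acceptors = []  # (ordinal, offset)
        donors = []
        for exon in t.exons:
            if t.strand == "+":
                acc_off = j.start - exon.start
                don_off = j.end - exon.end
            else:
                acc_off = j.end - exon.end
                don_off = j.start - exon.start
            if abs(acc_off) <= tolerance:
                acceptors.append((exon.index, acc_off))
            if abs(don_off) <= tolerance:
                donors.append((exon.index, don_off))
        for m, acc_off in acceptors:
            for n, don_off in donors:
                if m <= n:
                    out.append(
                        TranscriptMatch(t.transcript_id, m, n, acc_off, don_off)
                    )
    out.sort(key=lambda c: (c.transcript_id, c.exon_pair))
    return out


def _rank_key(match, models_by_id, commonness):
    t = models_by_id[match.transcript_id]
    return (
        match.total_offset,
        0 if t.has_ccds else 1,
        -commonness[match.transcript_id],
        -t.n_exons,
        -t.length,
        match.transcript_id,
        match.exon_pair,
        (match.acceptor_offset, match.donor_offset),
    )


def rank_and_assign(
    junctions: list[BacksplicedJunction],
    models: list[TranscriptModel],
    tolerance: int = DEFAULT_TOLERANCE,
) -> list[RepAssignment]:
    """Assign every junction its representative transcript and exon pair.

    Deterministic two-pass procedure: pass one computes the candidate
    matches and each transcript's commonness; pass two ranks candidates.
    Junctions with no candidate get an unassigned (null) record.
    """
    models_by_id = {t.transcript_id: t for t in models}
    candidates = {j.key: match_transcripts(j, models, tolerance) for j in junctions}
    commonness: Counter[str] = Counter()
    for matches in candidates.values():
        for tid in {m.transcript_id for m in matches}:
            commonness[tid] += 1

    out = []
    for j in junctions:
        matches = candidates[j.key]
        if not matches:
            out.append(
                RepAssignment(j, None, None, None, None, None, 0, None)
            )
            continue
        best = min(matches, key=lambda m: _rank_key(m, models_by_id, commonness))
        t = models_by_id[best.transcript_id]
        a = RepAssignment(
            junction=j,
            gene_id=t.gene_id,
            gene_symbol=t.gene_symbol,
            transcript_id=t.transcript_id,
            exon_pair=best.exon_pair,
            name=None,
            competing_matches=len(matches),
            match=best,
        )
        a.name = circ_name(a)
        out.append(a)
    return out


def circ_name(a: RepAssignment) -> str:
    """Display nomenclature: gene symbol tagged with the backsplice exon pair.

    Exon pair (2, 3) of gene PTP4A2 -> ``PTP4A2_e2-e3``; a single-exon
    circle (M == N) collapses to ``PTP4A2_e2``.
    """
    if a.exon_pair is None or a.gene_symbol is None:
        raise ValueError("cannot name an unassigned junction")
    m, n = a.exon_pair
    if m == n:
        return f"{a.gene_symbol}_e{m}"
    return f"{a.gene_symbol}_e{m}-e{n}"


#: Fixed column order of the annotation table (archive columns appended).
ANNOTATION_COLUMNS = [
    "name", "contig", "start", "end", "strand", "gene_symbol",
    "ref_transcript", "exon_M", "exon_N",
    "cytoplasm", "nucleoplasm", "chromatin", "polysome", "has_orf",
]


def annotation_table(
    assignments: list[RepAssignment],
    profiles_by_key: dict | None = None,
    has_orf_by_key: dict | None = None,
    archive_labels: list[str] | None = None,
):
    """Assemble the per-circRNA annotation table as a DataFrame.

    One row per junction, sorted by junction key; compartment columns are
    boolean presence flags, archive columns echo the accession under which
    the junction was archived in each database ('' if absent).  Unassigned
    junctions keep their coordinates with empty annotation fields.
    """
    import pandas as pd

    profiles_by_key = profiles_by_key or {}
    has_orf_by_key = has_orf_by_key or {}
    archive_labels = archive_labels or []
    rows = []
    for a in sorted(assignments, key=lambda a: a.junction.key):
        j = a.junction
        profile = profiles_by_key.get(j.key)
        row = {
            "name": a.name or "",
            "contig": j.contig,
            "start": j.start,
            "end": j.end,
            "strand": j.strand,
            "gene_symbol": a.gene_symbol or "",
            "ref_transcript": a.transcript_id or "",
            "exon_M": a.exon_pair[0] if a.exon_pair else "",
            "exon_N": a.exon_pair[1] if a.exon_pair else "",
        }
        for comp in ("cytoplasm", "nucleoplasm", "chromatin", "polysome"):
            row[comp] = bool(profile.present[comp]) if profile else False
        row["has_orf"] = bool(has_orf_by_key.get(j.key, False))
        for label in archive_labels:
            row[label] = j.accessions.get(label, "")
        rows.append(row)
    columns = ANNOTATION_COLUMNS + archive_labels
    return pd.DataFrame(rows, columns=columns)
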