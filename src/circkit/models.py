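"""Genome sequences and transcript models.

Coordinates are 0-based half-open on the forward genomic strand everywhere
inside the package; the GTF reader/writer is the only place the 1-based
inclusive convention appears.  Exon ordinals are 1-based and follow the
transcript's 5'->3' direction: ascending genomic start on ``+``, descending
on ``-``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome: contig name -> uppercase nucleotide string."""

    def __init__(self, contigs: dict[str, str]):
        self.contigs = contigs

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence of the half-open interval ``[start, end)``."""
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


def read_genome(path) -> GenomeSequence:
    """Load a (multi-)FASTA file; sequences are uppercased.

    Raises ``ValueError`` for an empty file or a duplicated contig name.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise ValueError(f"no records in FASTA file {path}")
    return GenomeSequence(contigs)


def write_genome(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class ExonRecord:
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    index: int  # 1-based ordinal in transcript 5'->3' order

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"exon has start {self.start} >= end {self.end}")
        if self.index < 1:
            raise ValueError("exon ordinal must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One transcript: ordered exons, CDS intervals with frame, CCDS flag.

    ``cds_intervals`` entries are ``(start, end, frame)`` in genomic
    coordinates; frame is the GTF phase (bases to skip to reach the next
    codon start), listed in transcript 5'->3' order.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    strand: str
    exons: list[ExonRecord] = field(default_factory=list)
    cds_intervals: list[tuple[int, int, int]] = field(default_factory=list)
    has_ccds: bool = False

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, ordinal: int) -> ExonRecord:
        if not 1 <= ordinal <= len(self.exons):
            raise ValueError(
                f"exon ordinal {ordinal} out of range 1..{len(self.exons)} "
                f"for {self.transcript_id}"
            )
        return self.exons[ordinal - 1]

    @property
    def span(self) -> tuple[int, int]:
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))


def build_transcript(
    transcript_id: str,
    gene_id: str,
    gene_symbol: str,
    strand: str,
    contig: str,
    exon_intervals: list[tuple[int, int]],
    cds_intervals: list[tuple[int, int, int]] | None = None,
    has_ccds: bool = False,
) -> TranscriptModel:
    """Assemble a TranscriptModel, assigning exon ordinals by strand."""
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    ordered = sorted(exon_intervals, reverse=(strand == "-"))
    exons = [
        ExonRecord(contig, s, e, i + 1) for i, (s, e) in enumerate(ordered)
    ]
    for a, b in zip(sorted(exon_intervals), sorted(exon_intervals)[1:]):
        if a[1] > b[0]:
            raise ValueError(
                f"overlapping exons {a} and {b} in {transcript_id}"
            )
    cds = list(cds_intervals or [])
    cds.sort(key=lambda iv: iv[0], reverse=(strand == "-"))
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        gene_symbol=gene_symbol,
        strand=strand,
        exons=exons,
        cds_intervals=cds,
        has_ccds=has_ccds,
    )


def _gtf_attributes(feature) -> dict[str, list[str]]:
    return dict(feature.attributes)


def read_gtf(path) -> list[TranscriptModel]:
    """Read an Ensembl-dialect GTF into transcript models.

    Only ``exon`` and ``CDS`` features are consumed; 1-based inclusive GTF
    coordinates become 0-based half-open.  A transcript is flagged
    ``has_ccds`` if any of its features carries ``tag "CCDS"`` or a
    ``ccds_id`` attribute.  Records without a ``transcript_id`` are skipped
    with a warning; strand disagreement within a transcript is an error.
    """
    from gffutils.feature import feature_from_line

    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feature = feature_from_line(line)
            if feature.featuretype not in ("exon", "CDS"):
                continue
            attrs = _gtf_attributes(feature)
            tx_ids = attrs.get("transcript_id")
            if not tx_ids:
                log.warning("line %d: missing transcript_id, skipped", lineno)
                continue
            tx_id = tx_ids[0]
            rec = per_tx.setdefault(
                tx_id,
                {
                    "gene_id": attrs.get("gene_id", [tx_id])[0],
                    "gene_symbol": attrs.get(
                        "gene_name", attrs.get("gene_id", [tx_id])
                    )[0],
                    "strand": feature.strand,
                    "contig": feature.seqid,
                    "exons": [],
                    "cds": [],
                    "has_ccds": False,
                },
            )
            if feature.strand != rec["strand"]:
                raise ValueError(
                    f"inconsistent strand within transcript {tx_id}"
                )
            start0, end0 = feature.start - 1, feature.end
            if feature.featuretype == "exon":
                rec["exons"].append((start0, end0))
            else:
                frame = int(feature.frame) if feature.frame != "." else 0
                rec["cds"].append((start0, end0, frame))
            if "CCDS" in attrs.get("tag", []) or "ccds_id" in attrs:
                rec["has_ccds"] = True

    models = []
    for tx_id, rec in per_tx.items():
        if not rec["exons"]:
            log.warning("transcript %s has no exon features, skipped", tx_id)
            continue
        models.append(
            build_transcript(
                tx_id,
                rec["gene_id"],
                rec["gene_symbol"],
                rec["strand"],
                rec["contig"],
                rec["exons"],
                rec["cds"],
                rec["has_ccds"],
            )
        )
    return models


def write_gtf(models: list[TranscriptModel], path) -> None:
    """Write transcript models back to Ensembl-dialect GTF (round-trippable)."""
    with open(path, "w") as fh:
        for t in models:
            base = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{t.gene_symbol}";'
            )
            ccds = ' tag "CCDS";' if t.has_ccds else ""
            for exon in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.contig,
                            "circkit",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            t.strand,
                            ".",
                            f'{base} exon_number "{exon.index}";{ccds}',
                        ]
                    )
                    + "\n"
                )
            for start, end, frame in t.cds_intervals:
                fh.write(
                    "\t".join(
                        [
                            t.contig,
                            "circkit",
                            "CDS",
                            str(start + 1),
                            str(end),
                            ".",
                            t.strand,
                            str(frame),
                            f"{base}{ccds}",
                        ]
                    )
                    + "\n"
                )


def spliced_sequence(
    t: TranscriptModel,
    genome: GenomeSequence,
    subset: tuple[int, int] | None = None,
) -> str:
    """Spliced transcript sequence in 5'->3' transcript orientation.

    ``subset`` is an inclusive range of exon ordinals (e.g. ``(2, 4)``); on
    the ``-`` strand each genomic block is reverse complemented and blocks
    are concatenated in transcript order.
    """
    if subset is None:
        lo, hi = 1, t.n_exons
    else:
        lo, hi = subset
    if not (1 <= lo <= hi <= t.n_exons):
        raise ValueError(
            f"exon ordinal range {lo}..{hi} invalid for transcript "
            f"{t.transcript_id} with {t.n_exons} exons"
        )
    parts = []
    for ordinal in range(lo, hi + 1):
        exon = t.exon(ordinal)
        block = genome.fetch(exon.contig, exon.start, exon.end)
        parts.append(revcomp(block) if t.strand == "-" else block)
    return "".join(parts)


def translate(seq: str) -> str:
    """Translate a codon-aligned nucleotide string (standard code)."""
    return str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
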