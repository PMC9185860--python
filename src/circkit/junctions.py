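"""Backsplice-junction records: parsing, normalization and reconciliation.

A backsplice junction is identified everywhere by its exact key
``(contig, start, end, strand)`` with 0-based half-open coordinates on the
forward genomic strand.  ``start`` is the leftmost base of the circle's
genomic span, ``end`` the exclusive right bound.  Equality is exact key
equality; any tolerance for ragged junction ends lives in the
representative-transcript matcher, not here, so that database
reconciliation stays deterministic and symmetric.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

#: Subcellular compartment vocabulary (fractionated RNA-seq labels).
COMPARTMENTS = ("cytoplasm", "nucleoplasm", "chromatin", "polysome")

JunctionKey = tuple[str, int, int, str]


@dataclass
class BacksplicedJunction:
    contig: str
    start: int
    end: int
    strand: str
    sources: set[str] = field(default_factory=set)
    read_support: dict[str, int] = field(default_factory=dict)
    accessions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"junction start {self.start} >= end {self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def key(self) -> JunctionKey:
        return (self.contig, self.start, self.end, self.strand)

    def merge(self, other: "BacksplicedJunction") -> None:
        """Union provenance of a record with an equal key into this one.

        Read support is kept per source (never summed across sources); a
        duplicate within one source keeps the larger count.
        """
        if other.key != self.key:
            raise ValueError("cannot merge junctions with different keys")
        self.sources |= other.sources
        for src, n in other.read_support.items():
            self.read_support[src] = max(self.read_support.get(src, 0), n)
        self.accessions.update(other.accessions)


def merge_junctions(*lists) -> dict[JunctionKey, BacksplicedJunction]:
    """Collapse any number of junction lists into one key-unique mapping."""
    merged: dict[JunctionKey, BacksplicedJunction] = {}
    for j in itertools.chain.from_iterable(lists):
        if j.key in merged:
            merged[j.key].merge(j)
        else:
            merged[j.key] = BacksplicedJunction(
                j.contig,
                j.start,
                j.end,
                j.strand,
                set(j.sources),
                dict(j.read_support),
                dict(j.accessions),
            )
    return merged


_CIRI_REQUIRED = ("circRNA_ID", "chr", "circRNA_start", "circRNA_end",
                  "#junction_reads", "strand")


def parse_ciri(path, source_label: str, min_reads: int = 2) -> list[BacksplicedJunction]:
    """Parse a CIRI2-dialect TSV of backsplice calls.

    CIRI2 reports 1-based inclusive coordinates; they are converted to the
    internal 0-based half-open convention.  Rows supported by fewer than
    ``min_reads`` junction reads are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _CIRI_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"CIRI2 table {path} is missing column {col!r}")
    out: dict[JunctionKey, BacksplicedJunction] = {}
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            start = int(rec["circRNA_start"])
            end = int(rec["circRNA_end"])
            reads = int(rec["#junction_reads"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"non-numeric coordinate or read count at {path} row "
                f"{row_number}: {exc}"
            ) from None
        if reads < min_reads:
            continue
        j = BacksplicedJunction(
            rec["chr"], start - 1, end, rec["strand"],
            sources={source_label},
            read_support={source_label: reads},
        )
        if j.key in out:
            out[j.key].merge(j)
        else:
            out[j.key] = j
    return list(out.values())


def parse_bed(path, source_label: str) -> list[BacksplicedJunction]:
    """Parse BED6 junctions (coordinates adopted unchanged, score = reads)."""
    out: dict[JunctionKey, BacksplicedJunction] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path} line {lineno}: BED6 requires 6 columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, _name, score, strand = fields[:6]
            if strand not in "+-":
                raise ValueError(
                    f"{path} line {lineno}: strand required ('+' or '-')"
                )
            try:
                support = int(float(score))
            except ValueError:
                support = 0
            j = BacksplicedJunction(
                chrom, int(start), int(end), strand,
                sources={source_label},
                read_support={source_label: support},
            )
            if j.key in out:
                out[j.key].merge(j)
            else:
                out[j.key] = j
    return list(out.values())


def write_bed(junctions, path) -> None:
    """Write normalized junctions to BED6 (name = accession or coordinates)."""
    rows = sorted(junctions, key=lambda j: j.key)
    with open(path, "w") as fh:
        for j in rows:
            name = next(
                (j.accessions[s] for s in sorted(j.accessions)),
                f"{j.contig}:{j.start}-{j.end}",
            )
            score = max(j.read_support.values(), default=0)
            fh.write(
                f"{j.contig}\t{j.start}\t{j.end}\t{name}\t{score}\t{j.strand}\n"
            )


#: Default semantic-field -> column-name maps for archive dumps.
ARCHIVE_DIALECTS = {
    "circbase": {
        "accession": "circRNA_ID",
        "position": "position",
        "strand": "strand",
        "zero_based": False,
    },
    "circrnadb": {
        "accession": "circRNA_ID",
        "contig": "chrom",
        "start": "start",
        "end": "end",
        "strand": "strand",
        "zero_based": False,
    },
}


def parse_archive(
    path,
    dialect: str,
    source_label: str | None = None,
    column_map: dict | None = None,
) -> list[BacksplicedJunction]:
    """Parse an archived circRNA database dump (circBase/circRNADb style).

    Coordinates are assumed 1-based inclusive unless ``column_map`` sets
    ``zero_based: True``.  The archive accession is attached to the junction
    under the source label so downstream reports can echo which database a
    circle was archived in.  Unparsable rows are skipped and counted in a
    logged warning.
    """
    if dialect not in ARCHIVE_DIALECTS:
        raise ValueError(
            f"unknown archive dialect {dialect!r}; "
            f"expected one of {sorted(ARCHIVE_DIALECTS)}"
        )
    cmap = dict(ARCHIVE_DIALECTS[dialect])
    if column_map:
        cmap.update(column_map)
    label = source_label or dialect
    offset = 0 if cmap.get("zero_based") else 1

    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[JunctionKey, BacksplicedJunction] = {}
    skipped = 0
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            if "position" in cmap and cmap["position"] in rec:
                pos = rec[cmap["position"]]
                contig, span = pos.split(":")
                start_s, end_s = span.split("-")
            else:
                contig = rec[cmap["contig"]]
                start_s, end_s = rec[cmap["start"]], rec[cmap["end"]]
            start = int(start_s) - offset
            end = int(end_s)
            strand = rec[cmap["strand"]]
            j = BacksplicedJunction(
                contig, start, end, strand,
                sources={label},
                accessions={label: rec[cmap["accession"]]},
            )
        except (KeyError, ValueError, AttributeError) as exc:
            skipped += 1
            log.warning(
                "%s row %d: unparsable archive record (%s), skipped",
                path, row_number, exc,
            )
            continue
        if j.key in out:
            out[j.key].merge(j)
        else:
            out[j.key] = j
    if skipped:
        log.warning("%s: skipped %d unparsable rows", path, skipped)
    return list(out.values())


@dataclass
class VennPartition:
    """Region counts of the Venn partition over labeled junction sets."""

    set_labels: list[str]
    region_counts: dict[tuple[str, ...], int]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def count(self, *labels: str) -> int:
        key = tuple(l for l in self.set_labels if l in set(labels))
        return self.region_counts[key]


def reconcile(sets: dict[str, list[BacksplicedJunction]]) -> VennPartition:
    """Partition the union of >= 2 labeled junction sets into Venn regions.

    Junctions are equal iff their normalized keys are equal.  Every
    non-empty subset of labels gets a region (possibly zero); region counts
    sum to the number of distinct keys in the union.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 labeled sets to reconcile")
    labels = list(sets)
    keysets = {label: {j.key for j in js} for label, js in sets.items()}
    membership: dict[JunctionKey, tuple[str, ...]] = {}
    for key in set().union(*keysets.values()):
        membership[key] = tuple(l for l in labels if key in keysets[l])
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            counts[combo] = 0
    for region in membership.values():
        counts[region] += 1
    return VennPartition(labels, counts)


@dataclass
class LocalizationProfile:
    """Per-junction presence across the four subcellular compartments."""

    junction: JunctionKey
    present: dict[str, bool]

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(c for c in COMPARTMENTS if self.present[c])


def localization_profiles(
    calls: dict[str, list[BacksplicedJunction]],
) -> list[LocalizationProfile]:
    """Build one presence profile per distinct junction key.

    ``calls`` maps compartment label -> junction calls from that cellular
    fraction; labels must come from the fixed vocabulary (cytoplasm,
    nucleoplasm, chromatin, polysome).  Empty call lists are allowed.
    """
    unknown = set(calls) - set(COMPARTMENTS)
    if unknown:
        raise ValueError(
            f"unknown compartment label(s) {sorted(unknown)}; "
            f"allowed: {list(COMPARTMENTS)}"
        )
    keysets = {c: {j.key for j in js} for c, js in calls.items()}
    all_keys = sorted(set().union(*keysets.values()) if keysets else set())
    return [
        LocalizationProfile(
            key,
            {c: key in keysets.get(c, set()) for c in COMPARTMENTS},
        )
        for key in all_keys
    ]


def compartment_venn(profiles: list[LocalizationProfile]) -> VennPartition:
    """Venn partition of profiles over the compartment vocabulary."""
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(COMPARTMENTS) + 1):
        for combo in itertools.combinations(COMPARTMENTS, r):
            counts[combo] = 0
    for p in profiles:
        counts[p.compartments] += 1
    return VennPartition(list(COMPARTMENTS), counts)
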