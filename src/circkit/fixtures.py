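"""Self-contained synthetic inputs with designed, oracle-verified properties.

The generator emulates, at toy scale, every input the annotation pipeline
consumes: a genome FASTA, an Ensembl-dialect GTF, per-compartment CIRI2
call tables, circBase-like and circRNADb-like archive dumps, and a protein
domain table — plus a ground-truth JSON of expected assignments, ORF
classes and Venn partitions.  Ground truth is computed at generation time
from the blueprints and the independent brute-force oracle
(:mod:`circkit.oracle`), never by the engine under test.

The default fixture contains:

* five single-transcript genes, each hosting one circle whose sequence is
  planted so that its sole ORF realizes one crossing scenario
  (0C, 1C5', 1C3', 2C, edlsC), one of them on the ``-`` strand;
* a "commonness" gene with a shared transcript matching all three of its
  junctions and a rival matching only one;
* a three-transcript gene hosting 9/2/1 backsplice pairs, mirroring the
  isoform-diversity shape reported for PTP4A2;
* archive/compartment memberships covering all seven regions of a 3-set
  Venn diagram and a varied 4-compartment localization design.

All randomness flows from a single seed; the same seed yields byte-
identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from . import oracle
from .junctions import COMPARTMENTS, BacksplicedJunction
from .models import (
    GenomeSequence,
    TranscriptModel,
    build_transcript,
    revcomp,
    write_genome,
    write_gtf,
)

#: Novelty flags (novel_n, novel_c) each designed scenario must produce.
SCENARIO_FLAGS = {
    "0C": (False, False),
    "1C5'": (True, False),
    "1C3'": (False, True),
    "2C": (True, True),
    "edlsC": (True, True),
}

_SAFE_CODONS = [  # no stops; used to seed stop-free frames
    "GCT", "GCC", "GCA", "GCG", "GAA", "GAG", "GGT", "GGA",
    "CTT", "CTG", "CCA", "CCG", "AAA", "AAG", "ACA", "ACC",
]


def scenario_sequence(scenario: str, L: int, seed: int) -> str:
    """A circle sequence whose single ORF realizes the given scenario.

    Candidate sequences are drawn from a seeded RNG and accepted only when
    the independent unrolled-scan oracle confirms the circle carries
    exactly one ORF of the requested crossing class, with junction/frame
    geometry that forces the scenario's designed novelty flags under a CDS
    covering the whole circle in phase 0.
    """
    if scenario not in SCENARIO_FLAGS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if L < 9:
        raise ValueError("scenario circles need L >= 9")
    if scenario == "edlsC" and L % 3 != 0:
        raise ValueError("edlsC requires L % 3 == 0 (stop-free frame cycle)")
    if scenario in ("1C5'", "1C3'", "2C") and L % 3 == 0:
        raise ValueError(f"{scenario} requires L % 3 != 0")

    rng = random.Random(f"{scenario}|{L}|{seed}")
    for _ in range(500_000):
        if scenario == "edlsC":
            codons = ["ATG"] + [
                rng.choice(_SAFE_CODONS) for _ in range(L // 3 - 1)
            ]
            seq = "".join(codons)
        else:
            seq = "".join(rng.choice("ACGT") for _ in range(L))
        if _scenario_ok(scenario, seq):
            return seq
    raise RuntimeError(
        f"no sequence found for scenario {scenario} at L={L} (seed {seed})"
    )


def _scenario_ok(scenario: str, seq: str) -> bool:
    L = len(seq)
    orfs = oracle.scan_circle(seq, min_peptide=1)
    if len(orfs) != 1:
        return False
    o = orfs[0]
    if scenario == "edlsC":
        return o.endless
    if o.endless:
        return False
    if scenario == "0C":
        return o.crossings == 0
    if scenario == "2C":
        return o.crossings == 2
    if o.crossings != 1:
        return False
    s = o.start
    pre_codons = sum(
        1 for k in range(len(o.peptide)) if s + 3 * k + 3 <= L
    )
    post_codons = sum(1 for k in range(len(o.peptide)) if s + 3 * k >= L)
    pre_aligned = pre_codons >= 1 and s % 3 == 0
    post_aligned = post_codons >= 1 and (s - L) % 3 == 0
    if scenario == "1C5'":
        return post_aligned and not pre_aligned and pre_codons >= 1
    # 1C3'
    return pre_aligned and post_codons >= 1 and not post_aligned


@dataclass
class TranscriptBlueprint:
    transcript_id: str
    exons: list[tuple[int, int]]  # absolute genomic intervals, 0-based half-open
    has_ccds: bool = False
    coding: bool = True  # CDS covers all exons, phase 0 at transcript start


@dataclass
class GeneBlueprint:
    gene_id: str
    symbol: str
    contig: str
    strand: str
    transcripts: list[TranscriptBlueprint]


@dataclass
class JunctionBlueprint:
    jid: str
    gene_id: str
    transcript_id: str  # designed representative transcript
    exon_pair: tuple[int, int]
    compartments: tuple[str, ...] = ()
    archives: dict[str, str] = field(default_factory=dict)
    scenario: str | None = None
    in_rnaseq: bool = True


@dataclass
class FixtureSpec:
    seed: int
    contig_lengths: dict[str, int]
    genes: list[GeneBlueprint]
    junctions: list[JunctionBlueprint]


def _cds_intervals(exons: list[tuple[int, int]], strand: str):
    """CDS covering the exons, transcript order, GTF frames from the walk."""
    ordered = sorted(exons, reverse=(strand == "-"))
    out = []
    cum = 0
    for s, e in ordered:
        frame = (3 - (cum % 3)) % 3
        out.append((s, e, frame))
        cum += e - s
    return out


def build_models(spec: FixtureSpec) -> list[TranscriptModel]:
    models = []
    for g in spec.genes:
        for tb in g.transcripts:
            models.append(
                build_transcript(
                    tb.transcript_id,
                    g.gene_id,
                    g.symbol,
                    g.strand,
                    g.contig,
                    tb.exons,
                    _cds_intervals(tb.exons, g.strand) if tb.coding else [],
                    tb.has_ccds,
                )
            )
    return models


def junction_coordinates(
    jb: JunctionBlueprint, models_by_id: dict[str, TranscriptModel]
) -> tuple[str, int, int, str]:
    """Genomic key of a blueprint junction (offsets are zero by design)."""
    t = models_by_id[jb.transcript_id]
    m, n = jb.exon_pair
    if not (1 <= m <= n <= t.n_exons):
        raise ValueError(
            f"blueprint {jb.jid}: exon pair {jb.exon_pair} invalid for "
            f"{jb.transcript_id}"
        )
    if t.strand == "+":
        return (t.contig, t.exon(m).start, t.exon(n).end, "+")
    return (t.contig, t.exon(n).start, t.exon(m).end, "-")


def default_spec(seed: int) -> FixtureSpec:
    """The designed default fixture (see module docstring)."""
    genes: list[GeneBlueprint] = []
    junctions: list[JunctionBlueprint] = []
    cursor = 100
    contig = "chrT"

    def lay_exons(start: int, lengths: list[int], introns: list[int]):
        exons = []
        pos = start
        for i, ln in enumerate(lengths):
            exons.append((pos, pos + ln))
            pos += ln + (introns[i] if i < len(introns) else 0)
        return exons, pos

    # --- scenario genes -------------------------------------------------
    scenario_layout = [
        ("G0C", "0C", "+", [10, 12, 20]),
        ("G1C5", "1C5'", "+", [10, 12, 20]),
        ("G1C3", "1C3'", "+", [10, 12, 20]),
        ("G2C", "2C", "-", [10, 12, 20]),
        ("GEDL", "edlsC", "+", [12, 12, 18]),
    ]
    for gid, scen, strand, lens in scenario_layout:
        exons, end = lay_exons(cursor, lens, [30, 30])
        tid = f"TX_{gid}_1"
        genes.append(
            GeneBlueprint(
                gid, gid, contig, strand,
                [TranscriptBlueprint(tid, exons, has_ccds=True, coding=True)],
            )
        )
        junctions.append(
            JunctionBlueprint(
                f"j_{gid.lower()}", gid, tid, (1, 2), scenario=scen,
            )
        )
        cursor = end + 120

    # --- commonness gene ------------------------------------------------
    shared_exons, end = lay_exons(cursor, [15] * 6, [20] * 5)
    rival_extra, _ = lay_exons(end + 7, [15] * 6, [10] * 5)
    genes.append(
        GeneBlueprint(
            "GCMN", "GCMN", contig, "+",
            [
                TranscriptBlueprint("TX_GCMN_SHARED", shared_exons,
                                    has_ccds=False, coding=True),
                TranscriptBlueprint(
                    "TX_GCMN_RIVAL",
                    [shared_exons[1], shared_exons[2]] + rival_extra,
                    has_ccds=False, coding=False,
                ),
            ],
        )
    )
    for jid, pair in (("j_cmn1", (2, 3)), ("j_cmn2", (2, 4)), ("j_cmn3", (3, 5))):
        junctions.append(
            JunctionBlueprint(jid, "GCMN", "TX_GCMN_SHARED", pair)
        )
    cursor = rival_extra[-1][1] + 150

    # --- isoform-diversity gene (9/2/1 backsplice pairs, PTP4A2-shaped) --
    tv1_exons, end1 = lay_exons(cursor, [20] * 6, [25] * 5)
    tv2_exons, end2 = lay_exons(cursor + 7, [18] * 4, [31] * 3)
    tv3_exons, end3 = lay_exons(cursor + 3, [11] * 3, [40] * 2)
    genes.append(
        GeneBlueprint(
            "GVIZ", "GVIZ", contig, "+",
            [
                TranscriptBlueprint("TX_GVIZ_1", tv1_exons, has_ccds=True,
                                    coding=True),
                TranscriptBlueprint("TX_GVIZ_2", tv2_exons, has_ccds=False,
                                    coding=False),
                TranscriptBlueprint("TX_GVIZ_3", tv3_exons, has_ccds=False,
                                    coding=False),
            ],
        )
    )
    tv1_pairs = [(1, 2), (1, 3), (2, 3), (2, 4), (3, 5), (4, 6), (1, 6),
                 (2, 6), (3, 4)]
    viz_jids = []
    for i, pair in enumerate(tv1_pairs, start=1):
        jid = f"j_viz{i}"
        viz_jids.append(jid)
        junctions.append(JunctionBlueprint(jid, "GVIZ", "TX_GVIZ_1", pair))
    for i, (tid, pair) in enumerate(
        [("TX_GVIZ_2", (1, 2)), ("TX_GVIZ_2", (2, 4)), ("TX_GVIZ_3", (1, 3))],
        start=10,
    ):
        jid = f"j_viz{i}"
        viz_jids.append(jid)
        junctions.append(JunctionBlueprint(jid, "GVIZ", tid, pair))
    cursor = max(end1, end2, end3) + 150

    # --- provenance design: compartments and archive memberships ---------
    by_id = {j.jid: j for j in junctions}
    compartment_design = {
        "j_g0c": ("cytoplasm", "polysome"),
        "j_g1c5": ("cytoplasm",),
        "j_g1c3": ("cytoplasm", "polysome"),
        "j_g2c": ("polysome",),
        "j_gedl": ("nucleoplasm", "chromatin"),
        "j_cmn1": ("cytoplasm", "nucleoplasm"),
        "j_cmn2": ("chromatin",),
        "j_cmn3": ("cytoplasm", "nucleoplasm", "chromatin", "polysome"),
        "j_viz6": ("cytoplasm",),
        "j_viz7": ("cytoplasm", "polysome"),
        "j_viz8": ("polysome",),
        "j_viz9": ("nucleoplasm",),
        "j_viz10": ("chromatin",),
        "j_viz11": ("cytoplasm", "nucleoplasm"),
        "j_viz12": ("nucleoplasm", "chromatin"),
    }
    archive_design = {  # (circbase, circrnadb) membership
        "j_g0c": (True, True),
        "j_g1c5": (True, False),
        "j_g2c": (False, True),
        "j_cmn1": (True, True),
        "j_cmn2": (True, False),
        "j_viz1": (True, False),
        "j_viz2": (True, False),
        "j_viz3": (False, True),
        "j_viz4": (False, True),
        "j_viz5": (True, True),
    }
    n_cbase = n_cdb = 0
    for jid, jb in by_id.items():
        jb.compartments = compartment_design.get(jid, ())
        in_cbase, in_cdb = archive_design.get(jid, (False, False))
        if in_cbase:
            n_cbase += 1
            jb.archives["circbase"] = f"hsa_circ_{n_cbase:07d}"
        if in_cdb:
            n_cdb += 1
            jb.archives["circrnadb"] = f"circRNA_{n_cdb:05d}"
        jb.in_rnaseq = jid not in ("j_viz1", "j_viz2", "j_viz3", "j_viz4",
                                   "j_viz5")
        if jb.in_rnaseq and not jb.compartments:
            jb.compartments = ("cytoplasm",)

    return FixtureSpec(
        seed=seed,
        contig_lengths={contig: cursor + 200},
        genes=genes,
        junctions=junctions,
    )


def validate_spec(spec: FixtureSpec, tolerance: int = 2) -> None:
    """Raise if any blueprint is internally inconsistent."""
    models_by_id = {t.transcript_id: t for t in build_models(spec)}
    for jb in spec.junctions:
        if jb.transcript_id not in models_by_id:
            raise ValueError(
                f"blueprint {jb.jid}: unknown transcript {jb.transcript_id}"
            )
        junction_coordinates(jb, models_by_id)  # checks the exon pair
        bad = set(jb.compartments) - set(COMPARTMENTS)
        if bad:
            raise ValueError(
                f"blueprint {jb.jid}: unknown compartments {sorted(bad)}"
            )
        if jb.scenario is not None and jb.scenario not in SCENARIO_FLAGS:
            raise ValueError(
                f"blueprint {jb.jid}: unknown scenario {jb.scenario!r}"
            )


def build_genome(spec: FixtureSpec) -> GenomeSequence:
    """Random contigs with scenario circle sequences planted into exons."""
    rng = random.Random(spec.seed)
    contigs = {
        name: list(
            "".join(rng.choice("ACGT") for _ in range(length))
        )
        for name, length in spec.contig_lengths.items()
    }
    models_by_id = {t.transcript_id: t for t in build_models(spec)}
    for jb in spec.junctions:
        if jb.scenario is None:
            continue
        t = models_by_id[jb.transcript_id]
        m, n = jb.exon_pair
        L = sum(t.exon(o).length for o in range(m, n + 1))
        seq = scenario_sequence(jb.scenario, L, spec.seed)
        pos = 0
        buf = contigs[t.contig]
        for o in range(m, n + 1):
            exon = t.exon(o)
            block = seq[pos : pos + exon.length]
            if t.strand == "-":
                block = revcomp(block)
            buf[exon.start : exon.end] = list(block)
            pos += exon.length
    return GenomeSequence({k: "".join(v) for k, v in contigs.items()})


def build_junctions(spec: FixtureSpec) -> list[BacksplicedJunction]:
    """All blueprint junctions as normalized records (no provenance)."""
    models_by_id = {t.transcript_id: t for t in build_models(spec)}
    out = []
    for jb in spec.junctions:
        contig, start, end, strand = junction_coordinates(jb, models_by_id)
        out.append(BacksplicedJunction(contig, start, end, strand))
    return out


def _key_str(key) -> str:
    contig, start, end, strand = key
    return f"{contig}:{start}-{end}:{strand}"


def _region_key(labels) -> str:
    return "|".join(labels)


def _venn_regions(keysets: dict[str, set]) -> dict[str, int]:
    """Hand-bookkept Venn region counts (independent of junctions.reconcile)."""
    import itertools

    labels = list(keysets)
    counts = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            counts[_region_key(combo)] = 0
    for key in set().union(*keysets.values()):
        region = tuple(l for l in labels if key in keysets[l])
        counts[_region_key(region)] += 1
    return counts


def ground_truth(spec: FixtureSpec) -> dict:
    """Expected pipeline results, derived from blueprints and the oracle."""
    models_by_id = {t.transcript_id: t for t in build_models(spec)}
    genes_by_id = {g.gene_id: g for g in spec.genes}
    genome = build_genome(spec)

    per_junction = {}
    for jb in spec.junctions:
        contig, start, end, strand = junction_coordinates(jb, models_by_id)
        t = models_by_id[jb.transcript_id]
        g = genes_by_id[jb.gene_id]
        m, n = jb.exon_pair
        name = (
            f"{g.symbol}_e{m}" if m == n else f"{g.symbol}_e{m}-e{n}"
        )
        entry = {
            "id": jb.jid,
            "gene_id": jb.gene_id,
            "gene_symbol": g.symbol,
            "transcript_id": jb.transcript_id,
            "exon_pair": [m, n],
            "name": name,
            "compartments": sorted(jb.compartments),
            "archives": dict(sorted(jb.archives.items())),
            "in_rnaseq": jb.in_rnaseq,
            "scenario": jb.scenario,
        }
        if jb.scenario is not None:
            # Circle sequence reconstructed by blueprint arithmetic and
            # scanned by the independent oracle.
            parts = []
            for o in range(m, n + 1):
                exon = t.exon(o)
                block = genome.fetch(contig, exon.start, exon.end)
                parts.append(revcomp(block) if strand == "-" else block)
            circle = "".join(parts)
            (orf,) = oracle.scan_circle(circle, min_peptide=1)
            novel_n, novel_c = SCENARIO_FLAGS[jb.scenario]
            entry["orf"] = {
                "class": jb.scenario,
                "start": orf.start,
                "length_nt": orf.length_nt,
                "crossings": orf.crossings,
                "endless": orf.endless,
                "peptide": orf.peptide,
                "novel_n": novel_n,
                "novel_c": novel_c,
            }
            entry["circle_seq"] = circle
        per_junction[_key_str((contig, start, end, strand))] = entry

    keys = {
        jb.jid: _key_str(junction_coordinates(jb, models_by_id))
        for jb in spec.junctions
    }
    archive_sets = {
        "circbase": {keys[jb.jid] for jb in spec.junctions
                     if "circbase" in jb.archives},
        "circrnadb": {keys[jb.jid] for jb in spec.junctions
                      if "circrnadb" in jb.archives},
        "rnaseq": {keys[jb.jid] for jb in spec.junctions if jb.in_rnaseq},
    }
    compartment_sets = {
        c: {keys[jb.jid] for jb in spec.junctions if c in jb.compartments}
        for c in COMPARTMENTS
    }
    return {
        "seed": spec.seed,
        "n_junctions": len(spec.junctions),
        "junctions": per_junction,
        "venn_archives": {
            "labels": list(archive_sets),
            "regions": _venn_regions(archive_sets),
        },
        "venn_compartments": {
            "labels": list(COMPARTMENTS),
            "regions": _venn_regions(compartment_sets),
        },
    }


def generate(spec: FixtureSpec, out_dir) -> dict[str, str]:
    """Write the fixture's input files and ground truth; return a manifest."""
    validate_spec(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed + 1)

    genome = build_genome(spec)
    models = build_models(spec)
    models.sort(key=lambda t: t.transcript_id)
    models_by_id = {t.transcript_id: t for t in models}

    manifest: dict[str, str] = {}
    genome_path = out / "genome.fa"
    write_genome(genome, genome_path)
    manifest["genome"] = str(genome_path)

    gtf_path = out / "annotation.gtf"
    write_gtf(models, gtf_path)
    manifest["gtf"] = str(gtf_path)

    # Per-compartment CIRI2-dialect tables; read counts are arbitrary but
    # always >= 2 so the default min_reads filter keeps every designed row.
    ciri_header = (
        "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\t"
        "SM_MS_SMS\t#non_junction_reads\tjunction_reads_ratio\t"
        "circRNA_type\tgene_id\tstrand\n"
    )
    rows_by_comp: dict[str, list[str]] = {c: [] for c in COMPARTMENTS}
    for jb in sorted(spec.junctions, key=lambda j: j.jid):
        if not jb.in_rnaseq:
            continue
        contig, start, end, strand = junction_coordinates(jb, models_by_id)
        for comp in jb.compartments:
            reads = rng.randint(2, 50)
            rows_by_comp[comp].append(
                f"{contig}:{start + 1}|{end}\t{contig}\t{start + 1}\t{end}\t"
                f"{reads}\t{reads},0,0\t{rng.randint(10, 99)}\t0.5\texon\t"
                f"{jb.gene_id}\t{strand}\n"
            )
    for comp in COMPARTMENTS:
        path = out / f"ciri_{comp}.tsv"
        with open(path, "w") as fh:
            fh.write(ciri_header)
            fh.writelines(rows_by_comp[comp])
        manifest[f"ciri_{comp}"] = str(path)

    # Archive dumps (synthetic circBase-like / circRNADb-like dialects).
    cbase_path = out / "circbase.tsv"
    with open(cbase_path, "w") as fh:
        fh.write("circRNA_ID\tposition\tstrand\n")
        for jb in sorted(spec.junctions, key=lambda j: j.jid):
            if "circbase" not in jb.archives:
                continue
            contig, start, end, strand = junction_coordinates(jb, models_by_id)
            fh.write(
                f"{jb.archives['circbase']}\t{contig}:{start + 1}-{end}\t"
                f"{strand}\n"
            )
    manifest["circbase"] = str(cbase_path)

    cdb_path = out / "circrnadb.tsv"
    with open(cdb_path, "w") as fh:
        fh.write("circRNA_ID\tchrom\tstart\tend\tstrand\n")
        for jb in sorted(spec.junctions, key=lambda j: j.jid):
            if "circrnadb" not in jb.archives:
                continue
            contig, start, end, strand = junction_coordinates(jb, models_by_id)
            fh.write(
                f"{jb.archives['circrnadb']}\t{contig}\t{start + 1}\t{end}\t"
                f"{strand}\n"
            )
    manifest["circrnadb"] = str(cdb_path)

    # Domain features for the coding isoform-diversity transcript.
    dom_path = out / "domains.tsv"
    tv1 = models_by_id["TX_GVIZ_1"]
    protein_len = sum(e - s for s, e, _f in tv1.cds_intervals) // 3
    with open(dom_path, "w") as fh:
        fh.write("protein_id\tfeature_type\tdescription\tbegin\tend\n")
        fh.write(f"TX_GVIZ_1\tDOMAIN\tzinc-finger\t5\t{protein_len // 3}\n")
        fh.write(
            f"TX_GVIZ_1\tMOTIF\tdegron\t{protein_len // 2}\t"
            f"{protein_len // 2 + 6}\n"
        )
    manifest["domains"] = str(dom_path)

    truth_path = out / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(ground_truth(spec), fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest["ground_truth"] = str(truth_path)
    return manifest


# ---------------------------------------------------------------------------
# Mirror transform: reverse complement every contig and flip all strands.
# Spliced sequences, circle sequences, ORF classes and peptides must be
# invariant under this transform; it is the strand-correctness probe.
# ---------------------------------------------------------------------------

def mirror_genome(genome: GenomeSequence) -> GenomeSequence:
    return GenomeSequence(
        {name: revcomp(seq) for name, seq in genome.contigs.items()}
    )


def mirror_models(
    models: list[TranscriptModel], genome: GenomeSequence
) -> list[TranscriptModel]:
    out = []
    for t in models:
        ln = len(genome.contigs[t.contig])
        strand = "-" if t.strand == "+" else "+"
        exons = [(ln - e.end, ln - e.start) for e in t.exons]
        cds = [(ln - e, ln - s, f) for s, e, f in t.cds_intervals]
        out.append(
            build_transcript(
                t.transcript_id, t.gene_id, t.gene_symbol, strand,
                t.contig, exons, cds, t.has_ccds,
            )
        )
    return out


def mirror_junctions(
    junctions: list[BacksplicedJunction], genome: GenomeSequence
) -> list[BacksplicedJunction]:
    out = []
    for j in junctions:
        ln = len(genome.contigs[j.contig])
        out.append(
            BacksplicedJunction(
                j.contig, ln - j.end, ln - j.start,
                "-" if j.strand == "+" else "+",
                set(j.sources), dict(j.read_support), dict(j.accessions),
            )
        )
    return out
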