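"""End-to-end pipeline: parse -> reconcile -> assign -> ORF -> report.

This is the library behind the command line: it chains the parsers, the
representative-transcript ranking, the ORF engine and the localization
profiling into deterministic tabular outputs (annotation table, ORF table,
localization matrix, normalized BED, peptide FASTA) plus optional SVG
plots.  Two runs on the same inputs produce byte-identical files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import junctions as jx
from . import viz
from .models import read_genome, read_gtf
from .orfs import analyze_circle, map_orf_to_protein
from .reference import annotation_table, rank_and_assign

log = logging.getLogger(__name__)


@dataclass
class JunctionInput:
    path: str
    dialect: str  # 'ciri' or 'bed'
    label: str
    compartment: str | None = None


@dataclass
class ArchiveInput:
    path: str
    dialect: str  # 'circbase' or 'circrnadb'
    label: str | None = None


@dataclass
class RunConfig:
    genome: str
    gtf: str
    out_dir: str
    junction_inputs: list[JunctionInput] = field(default_factory=list)
    archives: list[ArchiveInput] = field(default_factory=list)
    domains: str | None = None
    tolerance: int = 2
    min_reads: int = 2
    min_peptide: int = 20

    def validate(self) -> None:
        paths = [self.genome, self.gtf]
        paths += [j.path for j in self.junction_inputs]
        paths += [a.path for a in self.archives]
        if self.domains:
            paths.append(self.domains)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(
                f"missing input file(s): {', '.join(missing)}"
            )
        if self.tolerance < 0 or self.min_reads < 0 or self.min_peptide < 0:
            raise ValueError("tolerance/min_reads/min_peptide must be >= 0")


def from_mapping(cfg: dict) -> RunConfig:
    """Build a RunConfig from a flat mapping (parsed YAML config file)."""
    return RunConfig(
        genome=cfg["genome"],
        gtf=cfg["gtf"],
        out_dir=cfg.get("out_dir", "circkit_out"),
        junction_inputs=[
            JunctionInput(
                d["path"], d.get("dialect", "ciri"), d["label"],
                d.get("compartment"),
            )
            for d in cfg.get("junctions", [])
        ],
        archives=[
            ArchiveInput(d["path"], d["dialect"], d.get("label"))
            for d in cfg.get("archives", [])
        ],
        domains=cfg.get("domains"),
        tolerance=int(cfg.get("tolerance", 2)),
        min_reads=int(cfg.get("min_reads", 2)),
        min_peptide=int(cfg.get("min_peptide", 20)),
    )


def _parse_junction_input(ji: JunctionInput, min_reads: int):
    if ji.dialect == "ciri":
        return jx.parse_ciri(ji.path, ji.label, min_reads=min_reads)
    if ji.dialect == "bed":
        return jx.parse_bed(ji.path, ji.label)
    raise ValueError(f"unknown junction dialect {ji.dialect!r}")


def load_labeled_sets(config: RunConfig) -> dict[str, list]:
    """All labeled junction sets (caller outputs and archives)."""
    sets: dict[str, list] = {}
    for ji in config.junction_inputs:
        parsed = _parse_junction_input(ji, config.min_reads)
        sets.setdefault(ji.label, []).extend(parsed)
    for ai in config.archives:
        label = ai.label or ai.dialect
        sets.setdefault(label, []).extend(
            jx.parse_archive(ai.path, ai.dialect, source_label=label)
        )
    return sets


@dataclass
class AnnotateResult:
    assignments: list
    circles: dict  # junction key -> CircularSequence
    projections: dict  # junction key -> CdsProjection
    orfs: dict  # junction key -> list[CircOrf]
    profiles: dict  # junction key -> LocalizationProfile
    models: list
    genome: object
    archive_labels: list[str]
    tables: dict[str, str] = field(default_factory=dict)


def run_annotate(config: RunConfig) -> AnnotateResult:
    """Run the full annotation pipeline and write the output tables."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome = read_genome(config.genome)
    models = read_gtf(config.gtf)
    log.info("loaded %d contigs, %d transcripts", len(genome.contigs),
             len(models))

    compartment_calls: dict[str, list] = {}
    all_lists = []
    for ji in config.junction_inputs:
        parsed = _parse_junction_input(ji, config.min_reads)
        log.info("parsed %d junctions from %s (%s)", len(parsed), ji.path,
                 ji.label)
        all_lists.append(parsed)
        if ji.compartment:
            compartment_calls.setdefault(ji.compartment, []).extend(parsed)
    archive_labels = []
    for ai in config.archives:
        label = ai.label or ai.dialect
        archive_labels.append(label)
        parsed = jx.parse_archive(ai.path, ai.dialect, source_label=label)
        log.info("parsed %d archived records from %s (%s)", len(parsed),
                 ai.path, label)
        all_lists.append(parsed)

    merged = jx.merge_junctions(*all_lists)
    ordered = [merged[k] for k in sorted(merged)]
    log.info("merged to %d distinct junction keys", len(ordered))

    assignments = rank_and_assign(ordered, models, config.tolerance)
    n_assigned = sum(a.assigned for a in assignments)
    log.info("assigned %d junctions, %d unassigned", n_assigned,
             len(assignments) - n_assigned)

    profiles = {
        p.junction: p
        for p in jx.localization_profiles(compartment_calls)
    }

    circles, projections, orf_map = {}, {}, {}
    class_counts: dict[str, int] = {}
    for a in assignments:
        if not a.assigned:
            continue
        c, p, orfs = analyze_circle(a, models, genome, config.min_peptide)
        key = a.junction.key
        circles[key], projections[key], orf_map[key] = c, p, orfs
        for o in orfs:
            class_counts[o.orf_class] = class_counts.get(o.orf_class, 0) + 1
    log.info("ORFs per class: %s", dict(sorted(class_counts.items())))

    has_orf = {key: bool(orfs) for key, orfs in orf_map.items()}
    table = annotation_table(assignments, profiles, has_orf, archive_labels)
    tables = {}
    ann_path = out_dir / "annotation.tsv"
    table.to_csv(ann_path, sep="\t", index=False)
    tables["annotation"] = str(ann_path)

    orf_rows = []
    for a in sorted(assignments, key=lambda a: a.junction.key):
        if not a.assigned:
            continue
        for i, o in enumerate(orf_map[a.junction.key], start=1):
            orf_rows.append(
                {
                    "name": a.name,
                    "orf_index": i,
                    "start": o.start,
                    "length_nt": o.length_nt,
                    "crossings": "inf" if o.crossings is None else o.crossings,
                    "class": o.orf_class,
                    "novel_n": o.novel_n,
                    "novel_c": o.novel_c,
                    "qualifier": o.qualifier or "",
                    "peptide": o.peptide,
                }
            )
    orf_path = out_dir / "orfs.tsv"
    pd.DataFrame(
        orf_rows,
        columns=["name", "orf_index", "start", "length_nt", "crossings",
                 "class", "novel_n", "novel_c", "qualifier", "peptide"],
    ).to_csv(orf_path, sep="\t", index=False)
    tables["orfs"] = str(orf_path)

    loc_rows = [
        {"junction": f"{k[0]}:{k[1]}-{k[2]}:{k[3]}",
         **{c: p.present[c] for c in jx.COMPARTMENTS}}
        for k, p in sorted(profiles.items())
    ]
    loc_path = out_dir / "localization.tsv"
    pd.DataFrame(
        loc_rows, columns=["junction", *jx.COMPARTMENTS]
    ).to_csv(loc_path, sep="\t", index=False)
    tables["localization"] = str(loc_path)

    bed_path = out_dir / "junctions.bed"
    jx.write_bed(ordered, bed_path)
    tables["bed"] = str(bed_path)

    fasta_path = out_dir / "peptides.fa"
    with open(fasta_path, "w") as fh:
        for a in sorted(assignments, key=lambda a: a.junction.key):
            if not a.assigned:
                continue
            for i, o in enumerate(orf_map[a.junction.key], start=1):
                fh.write(f">{a.name}|{i}|{o.orf_class}\n{o.peptide}\n")
    tables["peptides"] = str(fasta_path)

    return AnnotateResult(
        assignments=assignments,
        circles=circles,
        projections=projections,
        orfs=orf_map,
        profiles=profiles,
        models=models,
        genome=genome,
        archive_labels=archive_labels,
        tables=tables,
    )


def run_venn(config: RunConfig) -> str:
    """Reconcile all labeled inputs and write the Venn region table."""
    config.validate()
    sets = load_labeled_sets(config)
    partition = jx.reconcile(sets)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "venn.tsv"
    with open(path, "w") as fh:
        fh.write("region\tcount\n")
        for region, count in partition.region_counts.items():
            fh.write(f"{'|'.join(region)}\t{count}\n")
    log.info("wrote %d Venn regions over %d junctions",
             len(partition.region_counts), partition.union_size)
    return str(path)


def run_plot(config: RunConfig, gene: str, result: AnnotateResult | None = None) -> list[str]:
    """Render the transcript plot (and protein plot when cORFs exist) for
    one gene symbol."""
    result = result or run_annotate(config)
    chosen = [
        a for a in result.assignments if a.assigned and a.gene_symbol == gene
    ]
    if not chosen:
        available = sorted(
            {a.gene_symbol for a in result.assignments if a.assigned}
        )
        raise ValueError(
            f"unknown gene {gene!r}; available: {', '.join(available)}"
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    orf_flags = {
        a.junction.key: bool(result.orfs.get(a.junction.key))
        for a in chosen
    }
    tx_path = out_dir / f"{gene}_transcripts.svg"
    viz.transcript_plot(chosen, result.models, orf_flags, tx_path)
    written.append(str(tx_path))

    domains = viz.read_domains(config.domains) if config.domains else []
    models_by_id = {t.transcript_id: t for t in result.models}
    bars_by_protein: dict[str, list[viz.OrfBar]] = {}
    for a in chosen:
        key = a.junction.key
        p = result.projections.get(key)
        if p is None or not p.present:
            continue
        t = models_by_id[a.transcript_id]
        protein_len = sum(e - s for s, e, _f in t.cds_intervals) // 3
        for i, o in enumerate(result.orfs.get(key, []), start=1):
            if o.endless:
                continue
            aln = map_orf_to_protein(o, p, result.circles[key].L, protein_len)
            bars_by_protein.setdefault(a.transcript_id, []).append(
                viz.OrfBar(
                    f"{a.name}|{i}|{o.orf_class}",
                    aln.residue_start, aln.residue_end,
                    aln.novel_n_aa, aln.novel_c_aa,
                    a.transcript_id,
                )
            )
    for protein_id in sorted(bars_by_protein):
        t = models_by_id[protein_id]
        protein_len = sum(e - s for s, e, _f in t.cds_intervals) // 3
        own_domains = [d for d in domains if d.protein_id == protein_id]
        path = out_dir / f"{gene}_{protein_id}_protein.svg"
        viz.protein_plot(protein_len, own_domains, bars_by_protein[protein_id],
                         path)
        written.append(str(path))
    return written
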