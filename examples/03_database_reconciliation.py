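"""Reconcile circRNA databases and RNA-seq calls on exact junction keys.

Different circRNA databases use incompatible accession schemes, so the
same circle is hard to recognize across resources.  Normalizing every
record to the exact key (contig, start, end, strand) makes set comparison
trivial: the Venn partition below says how many circles are unique to each
resource and how many are shared.
"""

import tempfile
from pathlib import Path

from circkit import fixtures as fx
from circkit.junctions import merge_junctions, parse_archive, parse_ciri, reconcile

with tempfile.TemporaryDirectory() as tmp:
    manifest = fx.generate(fx.default_spec(seed=0), Path(tmp) / "fixture")

    rnaseq = []
    for comp in ("cytoplasm", "nucleoplasm", "chromatin", "polysome"):
        rnaseq.extend(parse_ciri(manifest[f"ciri_{comp}"], comp, min_reads=2))
    sets = {
        "circbase": parse_archive(manifest["circbase"], "circbase"),
        "circrnadb": parse_archive(manifest["circrnadb"], "circrnadb"),
        "rnaseq": list(merge_junctions(rnaseq).values()),
    }
    partition = reconcile(sets)
    print(f"union of all three sets: {partition.union_size} junctions")
    for region, count in partition.region_counts.items():
        print(f"  {' & '.join(region):<30} {count}")
    novel = partition.count("rnaseq")
    print(f"\n{novel} junctions were found by RNA-seq but archived nowhere")
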