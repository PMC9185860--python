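"""Render the two SVG views for one gene of the synthetic fixture.

The transcript plot draws each representative transcript as a red track
(exon boxes, intron lines) with its circRNAs below — green if an ORF was
predicted, blue if not.  The protein plot aligns each circRNA-derived ORF
to the parental protein, with annotated domains on top and novel
overhangs hatched.  Both renderers are pure functions of their input, so
re-running produces byte-identical files.
"""

import tempfile
from pathlib import Path

from circkit import fixtures as fx
from circkit import pipeline

with tempfile.TemporaryDirectory() as tmp:
    manifest = fx.generate(fx.default_spec(seed=0), Path(tmp) / "fixture")
    config = pipeline.RunConfig(
        genome=manifest["genome"],
        gtf=manifest["gtf"],
        out_dir="example_plots",
        junction_inputs=[
            pipeline.JunctionInput(
                manifest[f"ciri_{c}"], "ciri", f"rnaseq_{c}", c
            )
            for c in ("cytoplasm", "nucleoplasm", "chromatin", "polysome")
        ],
        archives=[
            pipeline.ArchiveInput(manifest["circbase"], "circbase"),
            pipeline.ArchiveInput(manifest["circrnadb"], "circrnadb"),
        ],
        domains=manifest["domains"],
        min_peptide=1,
    )
    result = pipeline.run_annotate(config)
    # GVIZ hosts three isoforms carrying 9, 2 and 1 backsplice exon pairs
    for path in pipeline.run_plot(config, "GVIZ", result):
        print("wrote", path)
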