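import json

import pytest

from circkit import fixtures as fx
from circkit import pipeline

#: Seed of the shared default fixture bundle used across the suite.
BUNDLE_SEED = 7


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Generated default fixture: manifest, ground truth, spec, in-memory views."""
    out = tmp_path_factory.mktemp("fixture")
    spec = fx.default_spec(BUNDLE_SEED)
    manifest = fx.generate(spec, out)
    with open(manifest["ground_truth"]) as fh:
        truth = json.load(fh)
    return {
        "spec": spec,
        "manifest": manifest,
        "truth": truth,
        "genome": fx.build_genome(spec),
        "models": fx.build_models(spec),
        "junctions": fx.build_junctions(spec),
    }


def make_config(manifest, out_dir, min_peptide=1, **kwargs):
    """RunConfig wiring the generated bundle's files into the pipeline."""
    return pipeline.RunConfig(
        genome=manifest["genome"],
        gtf=manifest["gtf"],
        out_dir=str(out_dir),
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
        min_peptide=min_peptide,
        **kwargs,
    )


@pytest.fixture(scope="session")
def annotated(bundle, tmp_path_factory):
    """One shared full pipeline run over the default fixture."""
    out = tmp_path_factory.mktemp("annotated")
    config = make_config(bundle["manifest"], out)
    return pipeline.run_annotate(config)


def key_str(key):
    contig, start, end, strand = key
    return f"{contig}:{start}-{end}:{strand}"
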