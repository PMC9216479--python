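"""Shared fixtures: one synthetic corpus (seed 42) parsed and run once."""

import pytest
import yaml

from coiref.fixtures import CorpusParams, generate_corpus
from coiref.io_formats import read_acc2taxid, read_hmm_profile, read_taxdump
from coiref.pipeline import load_config, run_pipeline


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Synthetic corpus directory plus its ground-truth manifest."""
    outdir = tmp_path_factory.mktemp("corpus42")
    manifest = generate_corpus(42, outdir, CorpusParams())
    return outdir, manifest


@pytest.fixture(scope="session")
def store(corpus):
    outdir, _ = corpus
    with open(outdir / "nodes.dmp") as nodes, open(outdir / "names.dmp") as names, open(
        outdir / "gencode.dmp"
    ) as gencode:
        st = read_taxdump(nodes, names, gencode)
    with open(outdir / "acc2taxid.tsv") as fh:
        st.acc2taxid = read_acc2taxid(fh)
    return st


@pytest.fixture(scope="session")
def profile(corpus):
    outdir, _ = corpus
    with open(outdir / "profile.hmm") as fh:
        return read_hmm_profile(fh)


@pytest.fixture(scope="session")
def pipeline_result(corpus):
    """The full pipeline executed once on the seed-42 corpus."""
    outdir, _ = corpus
    with open(outdir / "config.yaml") as fh:
        cfg = load_config(yaml.safe_load(fh), outdir)
    return run_pipeline(cfg)
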