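import json
import pathlib

import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from actinterp.fixtures import FixtureSpec, generate
from actinterp.knowledgebase import Knowledgebase
from actinterp.paralog_map import align_isoforms, read_fasta


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle: paths, loaded knowledgebase, truth."""
    out = tmp_path_factory.mktemp("bundle")
    paths = generate(FixtureSpec(seed=7), out)
    kb = Knowledgebase().load_variants(paths["kb"])
    kb.load_population(paths["popn"])
    kb.load_annotations(paths["annot"])
    truth = json.loads(pathlib.Path(paths["truth"]).read_text())
    return {"paths": paths, "kb": kb, "truth": truth}


@pytest.fixture(scope="session")
def bundle_alignment(bundle):
    return align_isoforms(read_fasta(bundle["paths"]["fasta"]))
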