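from __future__ import annotations

import pytest

from cazyome.consensus import call_genome
from cazyome.simulate import generate_dataset, paper_flavoured_config


@pytest.fixture(scope="session")
def preset_dataset(tmp_path_factory):
    """Paper-flavoured simulated bundle, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("preset")
    bundle, truth = generate_dataset(paper_flavoured_config(seed=11), outdir=outdir)
    return bundle, truth, outdir


@pytest.fixture(scope="session")
def preset_calls(preset_dataset):
    bundle, _, _ = preset_dataset
    return {gid: call_genome(h) for gid, h in bundle.hits_by_genome.items()}
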