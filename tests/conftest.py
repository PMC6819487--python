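from __future__ import annotations

import pytest

from chipcompart.annotation import DefinitionProfile
from chipcompart.fixtures import make_fixture, minimal_plan


@pytest.fixture(scope="session")
def default_profile() -> DefinitionProfile:
    return DefinitionProfile(filter1="gene")


@pytest.fixture(scope="session")
def minimal_fixture(tmp_path_factory):
    """The minimal synthetic dataset, generated once per session."""
    outdir = tmp_path_factory.mktemp("minimal_fixture")
    return make_fixture(minimal_plan(seed=11), outdir)
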