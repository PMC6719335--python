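"""Shared fixtures: parents, loci, and small simulated genomes."""

import pytest
from hypothesis import settings

import sta1typer as st

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def parents():
    return st.generate_parent_genes(seed=7)


@pytest.fixture(scope="session")
def locus_intact(parents):
    return st.build_sta1_locus(parents, "intact")


@pytest.fixture(scope="session")
def locus_deleted(parents):
    return st.build_sta1_locus(parents, "deleted")


@pytest.fixture(scope="session")
def small_genomes(parents, locus_intact):
    """One small genome per STA1 state (fast fixtures for scans/PCR)."""
    out = {}
    for state in ("intact", "promoter_deleted", "absent"):
        spec = st.GenotypeSpec(states=(state, state), background_length=60_000,
                               seed=11)
        out[state] = st.build_genome(spec, locus_intact, parents,
                                     sample_id=state)
    return out
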