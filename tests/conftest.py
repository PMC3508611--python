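"""Shared fixtures: one modest synthetic experiment reused across the
suite (session-scoped; every test that needs reads, tags or truth draws
from it instead of re-simulating)."""

from __future__ import annotations

import pytest

from mirskin.annotate import Annotator
from mirskin.conserved import match_conserved
from mirskin.preprocess import clean_reads, collapse_tags
from mirskin.simulate import SimulationConfig, build_genome, simulate_libraries

#: annotation category for each synthetic reference set
REFSET_TO_CATEGORY = {
    "genbank_ncrna": "rRNA_etc_genbank",
    "rfam_ncrna": "rRNA_etc_rfam",
    "repeat": "repeat",
    "exon": "exon",
    "intron": "intron",
}


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(n_reads=20_000, seed=11)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    return build_genome(sim_config)


@pytest.fixture(scope="session")
def sim_reads(sim_data):
    return simulate_libraries(sim_data)


@pytest.fixture(scope="session")
def sim_clean(sim_config, sim_reads):
    return {
        lib: clean_reads(reads, sim_config.adapter3, sim_config.adapter5)
        for lib, reads in sim_reads.items()
    }


@pytest.fixture(scope="session")
def sim_tags(sim_clean):
    return collapse_tags(sim_clean)


@pytest.fixture(scope="session")
def sim_annotator(sim_data):
    refsets = {
        REFSET_TO_CATEGORY[cat]: refset
        for cat, refset in sim_data.references.items()
    }
    refsets["known_miRNA"] = sim_data.hairpin_catalog
    return Annotator(refsets)


@pytest.fixture(scope="session")
def sim_conserved_hits(sim_tags, sim_data):
    return match_conserved(sim_tags, sim_data.mature_catalog)
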