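"""Shared fixtures: a small synthetic study system with known truth."""

import numpy as np
import pytest
from hypothesis import settings

from amplihijack.synthetic_data import (
    SimConfig,
    make_16s_community,
    make_host_genome,
    simulate_pcr_reads,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    """Default study conditions, reduced depth to keep the suite quick."""
    return SimConfig(seed=7, depth=20_000)


@pytest.fixture(scope="session")
def study_system(sim_config):
    """Genome + truth, mock community, kitome, and one simulated sample."""
    rng = np.random.default_rng(sim_config.seed)
    genome, truths = make_host_genome(sim_config, rng)
    community, abund = make_16s_community(sim_config, rng)
    kitome, _ = make_16s_community(
        sim_config, rng, n_templates=sim_config.n_kitome, prefix="kit")
    sample = simulate_pcr_reads(truths, community, abund, sim_config, rng,
                                kitome=kitome)
    templates = {f"host_{t.chrom}_{t.product_start}": str(t.amplicon_seq)
                 for t in truths}
    templates.update(community)
    templates.update(kitome)
    return {
        "config": sim_config,
        "genome": genome,
        "truths": truths,
        "community": community,
        "abundances": abund,
        "kitome": kitome,
        "sample": sample,
        "templates": templates,
    }
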