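import pytest

from crossvar.chip_compare import status_by_site
from crossvar.concordance import classify_sites
from crossvar.synthetic_data import (
    SimConfig, designate_specific, simulate_chip, simulate_platform,
    simulate_reference, simulate_truth,
)

SMALL = dict(genome_length=20_000, n_contigs=1, n_variant_sites=500,
             chip_site_fraction=0.6)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    """Default-parameter simulation (n=5000 sites over 200 kb)."""
    return SimConfig(seed=11)


def make_world(config: SimConfig):
    """Simulate everything downstream stages need, in memory."""
    reference, repeats = simulate_reference(config)
    truth = simulate_truth(config, reference, repeats)
    specific = designate_specific(config, truth)
    platforms = {
        pid: simulate_platform(config, truth, reference, repeats, pid, specific)
        for pid in config.platforms
    }
    chip = simulate_chip(config, truth)
    return {
        "config": config, "reference": reference, "repeats": repeats,
        "truth": truth, "specific": specific, "platforms": platforms,
        "chip": chip,
    }


@pytest.fixture(scope="session")
def small_world(small_config):
    return make_world(small_config)


@pytest.fixture(scope="session")
def sim_world(sim_config):
    return make_world(sim_config)


@pytest.fixture(scope="session")
def sim_analysis(sim_world):
    """Concordance records and per-platform chip statuses for the default
    simulated dataset."""
    p1 = sim_world["platforms"]["p1"][0]
    p2 = sim_world["platforms"]["p2"][0]
    records = classify_sites(p1, p2)
    statuses = {
        1: status_by_site(p1, sim_world["chip"], sim_world["reference"]),
        2: status_by_site(p2, sim_world["chip"], sim_world["reference"]),
    }
    return records, statuses
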