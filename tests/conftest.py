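import numpy as np
import pytest

from exomefunnel import ScenarioConfig, annotate_variants, generate


def small_config(**overrides):
    """A desk-scale scenario: 2 chromosomes, 40 genes, ~40 kb of targets."""
    base = dict(seed=11, genome_bases=500_000, n_chroms=2, n_genes=40)
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def small_scenario():
    return generate(small_config())


@pytest.fixture(scope="session")
def small_annotated(small_scenario):
    s = small_scenario
    return annotate_variants(
        s.variants, s.genes, s.reference, catalogs=s.all_catalogs,
        map_intervals=s.map_intervals,
    )


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory):
    """A small scenario written to disk for file-based / CLI tests."""
    out = tmp_path_factory.mktemp("scenario")
    scenario = generate(small_config(seed=23), out_dir=out)
    return scenario


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
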