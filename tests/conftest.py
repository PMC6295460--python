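import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from eetsurvey.synthetic_data import SyntheticConfig, generate_proteome, seed_template_records


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark: 50 planted members, 150 decoys."""
    config = SyntheticConfig(seed=1)
    records, manifest = generate_proteome(config)
    return config, records, manifest


@pytest.fixture(scope="session")
def seed_templates():
    return seed_template_records()


@pytest.fixture(scope="session")
def benchmark_search(benchmark, seed_templates):
    """Iterative survey run once on the benchmark (shared across tests)."""
    from eetsurvey.homolog_survey import iterative_search

    _config, records, manifest = benchmark
    assignments, log = iterative_search(records, seed_templates)
    return records, manifest, assignments, log
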