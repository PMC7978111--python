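import sys
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

sys.path.insert(0, str(Path(__file__).parent))

from regusearch.search import DatasetConfig, SearchEngine
from regusearch.synth import FixtureSpec, generate


@pytest.fixture(scope="session")
def fixture_set():
    """One deterministic synthetic dataset shared by read-only tests."""
    return generate(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def engine(fixture_set):
    return SearchEngine(
        fixture_set.store,
        fixture_set.gene_table,
        mirna_registry=fixture_set.mirna_registry,
        mirna_loci=fixture_set.mirna_loci,
    )


@pytest.fixture(scope="session")
def wide_configs(fixture_set):
    """Generous windows covering every planted regulator, any-mode."""
    return {
        d: DatasetConfig(upstream_bp=50_000, downstream_bp=50_000, mode="any")
        for d in fixture_set.store.datasets()
    }
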