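import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from crossomics.pipeline import PipelineConfig, run_all
from crossomics.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A quick, fully structured bundle for unit-level pipeline tests."""
    config = SimulationConfig(
        seed=11,
        universe_size=2000,
        n_shared=30,
        n_pairwise=5,
        n_private=40,
        n_singletons=12,
        n_background=50,
        transcriptomic_studies=4,
        proteomic_studies=2,
        n_decoy_terms=20,
        decoy_size_range=(10, 60),
    )
    return simulate(config, tmp_path_factory.mktemp("small_bundle"))


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic world: 4 conditions x 10 studies, 139 shared
    genes, 50 singletons, no sign-flip noise."""
    return simulate(SimulationConfig(seed=0), tmp_path_factory.mktemp("default_bundle"))


@pytest.fixture(scope="session")
def default_report(default_bundle, tmp_path_factory):
    """Full pipeline run over the default bundle."""
    out = tmp_path_factory.mktemp("default_out")
    report = run_all(
        default_bundle.manifest_path, PipelineConfig(timestamp=False), out
    )
    return report, out
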