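import numpy as np
import pytest

from ciliamod import GeneratorConfig, PipelineConfig, small_config
from ciliamod.pipeline import run_collection, simulate_inputs


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default synthetic collection (10 datasets,
    3 tissues, 2000 genes, 60 samples, 150-gene signature, 25 markers).

    Permutation counts are scaled for test runtime; the tissue test keeps
    enough permutations for BH-significant calls at alpha 0.05.
    """
    gen = GeneratorConfig(seed=7)
    datasets, markers, evidence, atlas, truth = simulate_inputs(gen)
    cfg = PipelineConfig(seed=7, n_permutations=2 * 10**4, fdr_iterations=500)
    report = run_collection(datasets, markers, evidence, atlas, cfg)
    return {"gen": gen, "datasets": datasets, "markers": markers,
            "evidence": evidence, "atlas": atlas, "truth": truth,
            "config": cfg, "report": report}


@pytest.fixture(scope="session")
def small_collection():
    """A scaled-down collection for cheaper structural tests."""
    gen = small_config(seed=3)
    datasets, markers, evidence, atlas, truth = simulate_inputs(gen)
    return {"gen": gen, "datasets": datasets, "markers": markers,
            "evidence": evidence, "atlas": atlas, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
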