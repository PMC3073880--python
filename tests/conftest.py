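import numpy as np
import pytest

import protamide as pm

TABLE_TRUTH = {
    "salmine": {"turns": 38.0, "alpha_helix": 20.0, "random_coil": 42.0,
                "beta_sheet": 0.0},
    "squid": {"turns": 37.0, "alpha_helix": 40.0, "random_coil": 23.0,
              "beta_sheet": 0.0},
}


@pytest.fixture(scope="session")
def salmine_fixture():
    return pm.make_nucleus_fixture("salmine", dna_scale=0.7, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def squid_fixture():
    return pm.make_nucleus_fixture("squid", dna_scale=0.7, noise_sd=0.0, seed=0)


def run_pipeline(nucleus, dna_ref, outdir=""):
    cfg = pm.PipelineConfig(outdir=str(outdir) if outdir else "")
    return pm.run_decompose(cfg, nucleus=nucleus, dna_ref=dna_ref)


@pytest.fixture(scope="session")
def salmine_run(salmine_fixture):
    nucleus, dna, truth = salmine_fixture
    fit, summary, scale = run_pipeline(nucleus, dna)
    return fit, summary, scale, truth


@pytest.fixture(scope="session")
def squid_run(squid_fixture):
    nucleus, dna, truth = squid_fixture
    fit, summary, scale = run_pipeline(nucleus, dna)
    return fit, summary, scale, truth


@pytest.fixture()
def uniform_grid():
    return np.arange(1500.0, 1800.5, 0.5)
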