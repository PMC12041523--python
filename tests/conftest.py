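import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_coloc_field():
    """Noise-free, blur-free coupled field: exact identities hold."""
    from lipotrace.simulate import ColocSimParams, gen_coloc_field

    params = ColocSimParams(
        field_shape=(256, 256),
        n_cells=6,
        coloc_fraction=1.0,
        coupling_slope=0.8,
        psf_sigma=0.0,
        shot_noise=False,
        read_noise_sd=0.0,
        seed=11,
    )
    return gen_coloc_field(params)


@pytest.fixture(scope="session")
def noisy_coloc_field():
    """Realistic field: blur + Poisson/read noise, mixed coupling."""
    from lipotrace.simulate import ColocSimParams, gen_coloc_field

    params = ColocSimParams(
        field_shape=(512, 512), n_cells=20, coloc_fraction=0.7, seed=5
    )
    return gen_coloc_field(params)


@pytest.fixture(scope="session")
def raft_field():
    from lipotrace.simulate import RaftSimParams, gen_raft_field

    params = RaftSimParams(field_shape=(256, 256), n_cells=6, seed=3)
    return gen_raft_field(params)


@pytest.fixture(scope="session")
def lipid_sim():
    """Seeded lipid table with one strongly shifted species."""
    from lipotrace.simulate import LipidSimParams, gen_lipid_table

    params = LipidSimParams(
        n_samples_per_group=10, cv=0.1, group_log2fc={"PC_sp1": 3.0}, seed=21
    )
    return gen_lipid_table(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
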