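import numpy as np
import pytest

from coregrm import (
    ColumnConfig,
    ComponentParams,
    Grid,
    SchemeConfig,
    StateField,
    TimeControls,
    reference_scenario,
    simulate,
)


@pytest.fixture(scope="session")
def two_component():
    """Reference two-component configuration (the shipped scenario library)."""
    return reference_scenario("two_component")


@pytest.fixture
def mild_config():
    """A small, kinetically mild two-component column for cheap exact tests."""
    comps = (
        ComponentParams(pe=200.0, bi=5.0, eta=0.5, a1=2.0, a2=3.0,
                        b1=0.5, b2=1.0, c_inj=1.0),
        ComponentParams(pe=150.0, bi=8.0, eta=0.8, a1=4.0, a2=5.0,
                        b1=1.0, b2=2.0, c_inj=0.8),
    )
    return ColumnConfig(components=comps, eps_b=0.4, eps_p=0.5,
                        core_fraction=0.3, xi_inj=1.0)


def random_state(config, grid, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    nc = config.n_components
    return StateField(
        c_b=scale * rng.uniform(0.05, 1.0, (nc, grid.n_x)),
        c_p=scale * rng.uniform(0.05, 1.0, (nc, grid.n_x, grid.n_r)),
    )


def run_scenario(config, n_x=100, n_r=80, dxi_out=0.02, t_end=None, **ctl):
    chrom, state = simulate(
        config,
        grid=Grid(n_x, n_r),
        scheme=SchemeConfig(),
        controls=TimeControls(t_end=t_end, dxi_out=dxi_out, **ctl),
    )
    return chrom, state


@pytest.fixture(scope="session")
def concentrated_runs():
    """The four published concentrated-feed operating points (c_inj = 3) at the 100x80 grid."""
    runs = {}
    for core in (0.0, 0.5, 0.7, 0.9):
        cfg = reference_scenario("two_component", c_inj=3.0, core_fraction=core)
        runs[core] = run_scenario(cfg)[0]
    return runs


@pytest.fixture(scope="session")
def text_runs():
    """The two published dilute-feed operating points (c_inj = 1) at the 100x80 grid."""
    runs = {}
    for core in (0.0, 0.85):
        cfg = reference_scenario("two_component", core_fraction=core)
        runs[core] = run_scenario(cfg)[0]
    return runs
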