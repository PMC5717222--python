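import numpy as np
import pytest

import tqkin as tk


@pytest.fixture(scope="session")
def test_fx():
    """The benchmark enzyme: k_f = k_b = k_cat = 1 (nM, s), K_M = 2 nM."""
    return tk.enzyme_fixture("test_enzyme")


@pytest.fixture(scope="session")
def mm(test_fx):
    return test_fx.params.mm()


@pytest.fixture(scope="session")
def low_cond(test_fx):
    """E_T = S_T = 0.1 K_M = 0.2 nM, omega = 100/nM, grid to 99% conversion."""
    return test_fx.design_low


@pytest.fixture(scope="session")
def low_curves(test_fx, low_cond):
    """20 full-model progress curves at the low benchmark condition."""
    return tk.generate_datasets(test_fx.params, low_cond, 20, seed=1234)


@pytest.fixture(scope="session")
def priors():
    """Benchmark priors: means at the truth, variance 10x the mean."""
    return tk.prior_from_mean(1.0, 10.0), tk.prior_from_mean(2.0, 10.0)


def grid_condition(test_fx, E_T, S_T):
    return tk.make_condition(E_T, S_T, test_fx.omega, mm=test_fx.params.mm())


@pytest.fixture(scope="session")
def simple_curve():
    """Tiny hand-checkable curve: counts (0, 1) on t = (0, 2), E_T=1, S_T=2, omega=1."""
    cond = tk.ExperimentCondition(E_T=1.0, S_T=2.0, omega=1.0,
                                  t_obs=np.array([0.0, 2.0]))
    return tk.ProgressCurve(condition=cond, P_obs=np.array([0, 1]),
                            provenance="tQ", seed=0)
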