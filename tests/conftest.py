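import numpy as np
import pytest

from shaher.core import CorrelationMatrix, TraitPanel, compose_ugen, compose_uphen


def make_panel(w, h2, uunsh=None, uenv=None, names=None):
    """Panel whose matrices are exactly consistent with the generative model."""
    w = np.asarray(w, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    k = len(w)
    uunsh = CorrelationMatrix.identity(k) if uunsh is None else uunsh
    uenv = CorrelationMatrix.identity(k) if uenv is None else uenv
    ugen = compose_ugen(w, uunsh)
    uphen = compose_uphen(ugen, uenv, h2)
    names = tuple(f"T{i + 1}" for i in range(k)) if names is None else tuple(names)
    return TraitPanel(names=names, h2=h2, ugen=ugen, uphen=uphen)


def random_panel(rng, k=None, w_low=0.3, w_high=0.95):
    """Random model-consistent panel with noisy U_unsh and U_env."""
    from shaher.simulate import gen_env, gen_unsh

    k = int(rng.integers(3, 7)) if k is None else k
    w = rng.uniform(w_low, w_high, size=k) * rng.choice([-1.0, 1.0], size=k)
    if w.sum() < 0:
        w = -w
    h2 = rng.uniform(0.2, 0.8, size=k)
    uunsh = gen_unsh(k, 0.3, 0.5, rng)
    uenv = gen_env(k, 0.5, rng)
    return make_panel(w, h2, uunsh, uenv), w


@pytest.fixture
def worked_panel():
    """The K=3 worked example: w=(0.6,0.8,0.9), h2=0.5, identity U_unsh/U_env."""
    return make_panel([0.6, 0.8, 0.9], [0.5, 0.5, 0.5])


@pytest.fixture
def worked_w():
    return np.array([0.6, 0.8, 0.9])


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small simulated cohort (K=3, n=2000, m=600) for GWAS-level tests."""
    from shaher.cohort import simulate_cohort

    rng = np.random.default_rng(2024)
    w = np.array([0.6, 0.8, 0.9])
    h2 = np.array([0.5, 0.5, 0.5])
    eye = CorrelationMatrix.identity(3)
    return simulate_cohort(2000, 100, 500, w, h2, eye, eye, rng=rng)
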