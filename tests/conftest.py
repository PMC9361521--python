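import numpy as np
import pytest

from camdyn.io import ScatteringCurve
from camdyn import saxs, synth


def make_guinier_curve(Rg=16.8, I0=1.0, qmax=0.25, n=2000, rel_sigma=1e-3):
    """Exact Guinier-law curve I = I0 exp(-q^2 Rg^2 / 3)."""
    q = np.linspace(1e-4, qmax, n)
    I = I0 * np.exp(-(q**2) * Rg**2 / 3.0)
    return ScatteringCurve(q, I, np.maximum(rel_sigma * I, rel_sigma * I0 * 1e-3))


def make_sphere_curve(radius=20.0, qmax=0.35, n=150, rel_sigma=1e-4):
    """Analytic solid-sphere curve (independent of the Debye-sum code)."""
    q = np.linspace(5e-3, qmax, n)
    I = saxs.sphere_form_factor(q, radius)
    sig = np.maximum(rel_sigma * I.max() * np.ones_like(q), 1e-3 * I)
    return ScatteringCurve(q, I, sig)


@pytest.fixture(scope="session")
def guinier_curve():
    return make_guinier_curve()


@pytest.fixture(scope="session")
def sphere_curve():
    return make_sphere_curve()


@pytest.fixture(scope="session")
def qgrid():
    return np.linspace(1e-3, 0.45, 120)


@pytest.fixture(scope="session")
def extended_pool():
    return synth.make_two_lobe_conformers(12, compact=False, seed=11)


@pytest.fixture(scope="session")
def compact_pool():
    return synth.make_two_lobe_conformers(12, compact=True, seed=11)
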