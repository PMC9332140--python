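"""Shared fixtures: toggle-switch benchmark samples and fitted fields.

Session scope keeps the expensive fits and stochastic simulations to one run
each; all randomness is seeded.
"""

import numpy as np
import pytest

import dynofield as dy
from dynofield.simulate import GillespieParams, simulate_expression


@pytest.fixture(scope="session")
def toggle_samples():
    """5,000 uniform samples of the toggle-switch field (benchmark scale)."""
    return dy.sample_field(n=5000, seed=1)


@pytest.fixture(scope="session")
def toggle_model(toggle_samples):
    X, V = toggle_samples
    return dy.fit_vectorfield(X, V, seed=0)


@pytest.fixture(scope="session")
def toggle_model_small():
    X, V = dy.sample_field(n=600, seed=3)
    return dy.fit_vectorfield(X, V, seed=0), X, V


@pytest.fixture(scope="session")
def one_shot_sim():
    """Exact-SSA one-shot labeling data: near-constitutive promoter,
    gamma = 0.3/h, t = 2 h, 1,000 cells."""
    params = GillespieParams(k_on=10.0, k_off=1.0, alpha=30.0, gamma=0.3,
                             splicing=False, n_cells=1000, seed=7)
    return simulate_expression(params, design="one_shot", t=2.0), params


@pytest.fixture(scope="session")
def kinetics_sim():
    """Pulse-labeling series t in {0.5, 1, 2, 4} h, gamma = 0.5/h, 1,000 cells."""
    params = GillespieParams(k_on=10.0, k_off=1.0, alpha=20.0, gamma=0.5,
                             splicing=False, n_cells=1000, seed=11)
    return simulate_expression(params, design="kinetics", t=[0.5, 1, 2, 4]), params


@pytest.fixture(scope="session")
def degradation_sim():
    """Chase series t in {0, 1, 2, 4} h after saturation labeling."""
    params = GillespieParams(k_on=10.0, k_off=1.0, alpha=20.0, gamma=0.5,
                             splicing=False, n_cells=1000, seed=13)
    return simulate_expression(params, design="degradation", t=[0, 1, 2, 4]), params


@pytest.fixture(scope="session")
def splicing_sim():
    """Bursty gene with splicing: beta = 1.25, gamma = 0.5 (gamma~ = 0.4)."""
    params = GillespieParams(k_on=1.0, k_off=1.0, alpha=20.0, beta=1.25,
                             gamma=0.5, splicing=True, n_cells=2000, seed=5)
    return simulate_expression(params, design="one_shot", t=0.5), params


def toggle_attractors(model_or_field, jac=None, n_seeds=25, seed=0):
    from dynofield.topology import find_fixed_points

    dom = np.array([[0.0, 2.5], [0.0, 2.5]])
    fps = find_fixed_points(model_or_field, dom, n_seeds=n_seeds, jac=jac, seed=seed)
    return fps
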