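import numpy as np
import pytest

from tilegam import (BumpSmooth, Hyperparams, SimConfig, TileModel,
                     build_design, evaluate_basis, place_knots,
                     simulate_counts)


def make_tile_model(n_positions=200, Z=None, lam=10.0, theta=5.0, eps=1e-3,
                    seed=0, spacing=20.0, baseline=1.0, bump_height=1.0,
                    offsets=None):
    """A small simulated tile: Gaussian-bump truth, NB counts, spline design."""
    rng = np.random.default_rng(seed)
    Z = np.array([[1]]) if Z is None else np.asarray(Z)
    K = Z.shape[1]
    pos = np.arange(n_positions, dtype=float)
    knots = place_knots(0, n_positions - 1, spacing)
    basis = evaluate_basis(knots, pos)
    design = build_design(Z, basis)
    centers = rng.uniform(0.2, 0.8, K) * n_positions
    widths = rng.uniform(0.08, 0.2, K) * n_positions
    truth = np.column_stack([
        baseline + bump_height * np.exp(-0.5 * ((pos - c) / w) ** 2)
        for c, w in zip(centers, widths)])
    if K > 1:     # later smooths are fold-changes around zero
        truth[:, 1:] = truth[:, 1:] - baseline
    mu = np.exp(Z @ truth.T)
    o = np.zeros(mu.size) if offsets is None else offsets
    y = rng.negative_binomial(theta, theta / (theta + mu)).ravel()
    model = TileModel(y=y, offsets=o, design=design,
                      hyper=Hyperparams(lam=lam, theta=theta, epsilon=eps))
    return model, basis, truth


@pytest.fixture
def small_tile():
    return make_tile_model(n_positions=200, seed=1)


@pytest.fixture
def two_smooth_tile():
    return make_tile_model(n_positions=240, Z=np.array([[1, 0], [1, 1]]), seed=2)


@pytest.fixture
def sim_two_condition():
    """A 6 kb two-condition dataset with a known log fold-change smooth."""
    length = 6000
    background = BumpSmooth(centers=(1500.0, 4000.0), widths=(500.0, 700.0),
                            heights=(1.2, 0.8), baseline=1.5)
    foldchange = BumpSmooth(centers=(2800.0,), widths=(400.0,),
                            heights=(1.0,), baseline=0.0)
    config = SimConfig(length=length, smooths=(background, foldchange),
                       Z=np.array([[1, 0], [1, 1]]), theta=5.0, seed=11)
    return simulate_counts(config)
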