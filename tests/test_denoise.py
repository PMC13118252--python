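"""Shrinkage, gradients, BM3D operator, and the split-Bregman loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmatct.denoise import (BM3DParams, BregmanState, DenoiseConfig,
                            bm3d_denoise, denoise_objective,
                            estimate_noise_sigma, gradient_ops,
                            laplacian_spectrum, shrink, solve_f_subproblem,
                            total_variation, transpose_gradient,
                            tv_bm3d_denoise_step, update_bregman)
from vmatct.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="module")
def noisy_phantom():
    spec = PhantomSpec(shape=(32, 32, 32), voxel_size_mm=4.0,
                       eval_box_halfwidth_mm=6.0)
    clean, _, _ = make_phantom(spec)
    rng = np.random.default_rng(7)
    return clean.values, clean.values + rng.normal(0, 5.0, clean.values.shape)


# ---------------------------------------------------------------- shrink

@pytest.mark.parametrize("x,sigma,expected", [
    (3.0, 1.0, 2.0),      # x > sigma
    (0.5, 1.0, 0.0),      # dead zone
    (-0.5, 1.0, 0.0),     # dead zone
    (-3.0, 1.0, -2.0),    # x < -sigma
    (1.0, 0.0, 1.0),      # zero threshold is the identity
])
def test_shrink_branches(x, sigma, expected):
    assert shrink(x, sigma) == expected


def test_shrink_negative_sigma_errors():
    with pytest.raises(ValueError):
        shrink(1.0, -0.1)


@settings(derandomize=True, max_examples=50)
@given(st.floats(-100, 100), st.floats(-100, 100), st.floats(0, 10))
def test_shrink_is_odd_and_nonexpansive(x, y, sigma):
    assert shrink(-x, sigma) == pytest.approx(-shrink(x, sigma), abs=1e-12)
    assert abs(shrink(x, sigma) - shrink(y, sigma)) <= abs(x - y) + 1e-12


# ------------------------------------------------------------- gradients

def test_gradients_of_constant_are_zero():
    g = gradient_ops(np.full((6, 5, 4), 2.5))
    for a in g:
        assert np.all(a == 0.0)


def test_gradient_adjointness_dense_oracle():
    """<grad f, g> == <f, grad^T g> per axis, against dense difference
    matrices built independently from the periodic stencil."""
    rng = np.random.default_rng(9)
    shape = (8, 8, 8)
    f = rng.normal(size=shape)
    g = rng.normal(size=shape)
    grads = gradient_ops(f)
    for ax in range(3):
        lhs = float(np.sum(grads[ax] * g))
        rhs = float(np.sum(f * transpose_gradient(g, ax)))
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)
    # dense check on one axis (1D circulant difference matrix)
    n = 8
    D = -np.eye(n) + np.roll(np.eye(n), 1, axis=1)
    x = rng.normal(size=n)
    f1 = np.tile(x[:, None, None], (1, n, n))
    np.testing.assert_allclose(gradient_ops(f1)[0][:, 0, 0], D @ x,
                               rtol=1e-12, atol=1e-12)


def test_tv_of_binary_cube_is_surface_area():
    """Anisotropic TV of a k-cube of ones equals 6 k^2 (face crossings)."""
    vol = np.zeros((12, 12, 12))
    vol[3:8, 3:8, 3:8] = 1.0
    assert total_variation(vol) == pytest.approx(6 * 5 * 5)


def test_laplacian_spectrum_matches_operator():
    rng = np.random.default_rng(10)
    f = rng.normal(size=(6, 5, 4))
    lap = sum(transpose_gradient(g, a)
              for a, g in enumerate(gradient_ops(f)))
    from scipy.fft import irfftn, rfftn
    lap_fft = irfftn(rfftn(f) * laplacian_spectrum(f.shape), s=f.shape)
    np.testing.assert_allclose(lap, lap_fft, atol=1e-10)


# ------------------------------------------------------------------ BM3D

def test_bm3d_exact_on_constants():
    c = np.full((16, 16, 4), 37.2)
    out = bm3d_denoise(c, BM3DParams())
    np.testing.assert_allclose(out, c, atol=1e-10)


def test_bm3d_zero_threshold_is_identity(noisy_phantom):
    _, noisy = noisy_phantom
    params = BM3DParams(hard_threshold_multiplier=0.0, noise_sigma=5.0)
    out = bm3d_denoise(noisy, params)
    assert np.abs(out - noisy).max() <= 1e-6 * np.abs(noisy).max()


def test_bm3d_reduces_mse_on_noisy_phantom(noisy_phantom):
    clean, noisy = noisy_phantom
    out = bm3d_denoise(noisy, BM3DParams(noise_sigma=5.0))
    assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)


def test_bm3d_too_small_volume_errors():
    with pytest.raises(ValueError):
        bm3d_denoise(np.zeros((4, 4, 4)), BM3DParams(block_size=8))


def test_bm3d_params_validation():
    with pytest.raises(ValueError):
        BM3DParams(block_size=2)
    with pytest.raises(ValueError):
        BM3DParams(max_group=12)  # not a power of two
    with pytest.raises(ValueError):
        BM3DParams(search_radius=4, block_size=8)


def test_noise_sigma_estimate_tracks_truth():
    rng = np.random.default_rng(12)
    img = rng.normal(0.0, 3.0, (256, 256))
    assert estimate_noise_sigma(img) == pytest.approx(3.0, rel=0.1)


# ---------------------------------------------------------- f-subproblem

def test_f_subproblem_constant_zero_state():
    cfg = DenoiseConfig()
    c = 4.0
    state = BregmanState.zeros((8, 8, 8))
    out = solve_f_subproblem(np.full((8, 8, 8), c), state, cfg)
    np.testing.assert_allclose(out, cfg.mu * c / (cfg.mu + cfg.beta),
                               rtol=1e-12)


def test_f_subproblem_matches_dense_solve():
    """FFT solve == dense solve of (mu + alpha grad^T grad + beta) f = rhs."""
    rng = np.random.default_rng(13)
    shape = (8, 8, 8)
    n = int(np.prod(shape))
    cfg = DenoiseConfig()
    state = BregmanState(*(rng.normal(size=shape) for _ in range(8)))
    f_j = rng.normal(size=shape)
    out = solve_f_subproblem(f_j, state, cfg)

    # densely materialize the operator by applying it to basis vectors
    def op(v):
        v = v.reshape(shape)
        lap = sum(transpose_gradient(g, a)
                  for a, g in enumerate(gradient_ops(v)))
        return (cfg.mu * v + cfg.alpha * lap + cfg.beta * v).ravel()

    A = np.zeros((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        A[:, i] = op(e)
    rhs = (cfg.mu * f_j
           + cfg.alpha * sum(transpose_gradient(
               getattr(state, f"D_{ax}") - getattr(state, f"b_{ax}"), a)
               for a, ax in enumerate("xyz"))
           + cfg.beta * (state.D_w - state.b_w))
    expect = np.linalg.solve(A, rhs.ravel()).reshape(shape)
    np.testing.assert_allclose(out, expect, rtol=1e-6, atol=1e-9)


# -------------------------------------------------------- Bregman updates

def test_update_bregman_constant_input():
    cfg = DenoiseConfig()
    c = 50.0
    state = BregmanState.zeros((8, 8, 8))
    f = np.full((8, 8, 8), c)
    new = update_bregman(state, f, cfg, BM3DParams())
    for name in ("D_x", "D_y", "D_z", "b_x", "b_y", "b_z"):
        assert np.all(getattr(new, name) == 0.0)
    expect_dw = shrink(c, 1.0 / cfg.beta)
    np.testing.assert_allclose(new.D_w, expect_dw, rtol=1e-12)
    np.testing.assert_allclose(new.b_w, c - expect_dw, rtol=1e-12)


def test_update_bregman_matches_transcription():
    """One full update against an independent straight-line transcription
    of the shrinkage and multiplier formulas."""
    rng = np.random.default_rng(14)
    shape = (6, 6, 6)
    cfg = DenoiseConfig(mu=2.0, alpha=1.3, beta=0.4)
    state = BregmanState(*(rng.normal(size=shape) for _ in range(8)))
    f = rng.normal(size=shape) * 10
    w = rng.normal(size=shape) * 10  # stand-in for BM3D(f)
    new = update_bregman(state, f, cfg, bm3d_of_f=w)

    gx, gy, gz = gradient_ops(f)

    def soft(v, t):
        return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)

    Dx = soft(gx + state.b_x, 1 / cfg.alpha)
    Dy = soft(gy + state.b_y, 1 / cfg.alpha)
    Dz = soft(gz + state.b_z, 1 / cfg.alpha)
    Dw = soft(w + state.b_w, 1 / cfg.beta)
    np.testing.assert_allclose(new.D_x, Dx, rtol=1e-12)
    np.testing.assert_allclose(new.D_w, Dw, rtol=1e-12)
    np.testing.assert_allclose(new.b_x, state.b_x + gx - Dx, rtol=1e-12)
    np.testing.assert_allclose(new.b_y, state.b_y + gy - Dy, rtol=1e-12)
    np.testing.assert_allclose(new.b_z, state.b_z + gz - Dz, rtol=1e-12)
    np.testing.assert_allclose(new.b_w, state.b_w + w - Dw, rtol=1e-12)


def test_fixed_point_of_multiplier_update():
    """If grad f == D - b channelwise and shrink leaves D unchanged, the
    multiplier b is unchanged."""
    rng = np.random.default_rng(15)
    shape = (6, 6, 6)
    cfg = DenoiseConfig(alpha=1000.0)  # tiny threshold: shrink ~ identity
    f = rng.normal(size=shape)
    gx, gy, gz = gradient_ops(f)
    b = np.zeros(shape)
    state = BregmanState(gx.copy(), gy.copy(), gz.copy(), np.zeros(shape),
                         b, b, b, np.zeros(shape))
    new = update_bregman(state, f, cfg, bm3d_of_f=np.zeros(shape))
    np.testing.assert_allclose(new.b_x, b + gx - new.D_x, atol=1e-12)
    np.testing.assert_allclose(new.D_x, gx, atol=2e-3)


def test_large_alpha_gradient_channels_near_identity():
    """alpha -> inf: thresholds 1/alpha -> 0, so D tracks grad f."""
    rng = np.random.default_rng(16)
    f = rng.normal(size=(6, 6, 6)) * 10
    cfg = DenoiseConfig(alpha=1e6)
    state = BregmanState.zeros(f.shape)
    new = update_bregman(state, f, cfg, bm3d_of_f=np.zeros(f.shape))
    gx = gradient_ops(f)[0]
    np.testing.assert_allclose(new.D_x, gx, atol=2e-6)
    assert np.abs(new.b_x).max() <= 1e-6 + 1e-12


# ------------------------------------------------------------- full step

def test_denoise_step_zero_loops_is_identity(noisy_phantom):
    _, noisy = noisy_phantom
    cfg = DenoiseConfig(inner_loops=0)
    out = tv_bm3d_denoise_step(noisy, cfg, BM3DParams(noise_sigma=5.0))
    np.testing.assert_array_equal(out, noisy)


def test_denoise_step_reduces_tv_on_clean_phantom(noisy_phantom):
    clean, _ = noisy_phantom
    out = tv_bm3d_denoise_step(clean, DenoiseConfig(),
                               BM3DParams(noise_sigma=0.0))
    assert total_variation(out) <= total_variation(clean)


def test_denoise_step_reduces_mse_and_tv_on_noisy_phantom(noisy_phantom):
    clean, noisy = noisy_phantom
    out = tv_bm3d_denoise_step(noisy, DenoiseConfig(),
                               BM3DParams(noise_sigma=5.0))
    assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)
    assert total_variation(out) < total_variation(noisy)


def test_denoise_objective_decreases_over_first_loops(noisy_phantom):
    """Net decrease of the surrogate objective over the first 3 loops."""
    _, noisy = noisy_phantom
    out, hist = tv_bm3d_denoise_step(noisy, DenoiseConfig(),
                                     BM3DParams(noise_sigma=5.0),
                                     return_history=True)
    assert hist[3] <= hist[0]
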