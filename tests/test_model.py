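"""Architecture contracts and the closed-form loss identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atacdae.model import (ModelConfig, build_network, ce_loss, combined_loss,
                           mse_loss)


def _cfg(**kw):
    base = dict(input_length=64, bottom_channels=4, top_channels=8,
                classifier_hidden=8, n_populations=3, encoder_dropout=0.0,
                seed=0)
    base.update(kw)
    return ModelConfig(**base)


# ------------------------------------------------------------ architecture
def test_stride_arithmetic():
    """m=16 with two levels: one stride-2 stage gives bottom length 8, two
    more stride-2 stages give top length 2."""
    net = build_network(_cfg(input_length=16))
    x = np.zeros((1, 1, 16), dtype=np.float32)
    h1 = net.e_bottom.forward(x)
    assert h1.shape[2] == 8
    h2 = net.e_top.forward(h1)
    assert h2.shape[2] == 2


def test_one_level_variant_has_no_top_pair():
    net = build_network(_cfg(levels=1))
    assert net.e_top is None and net.d_top is None
    net3 = build_network(_cfg(levels=3))
    assert net3.e_top2 is not None and net3.d_top2 is not None


def test_same_seed_identical_parameters():
    a, b = build_network(_cfg()), build_network(_cfg())
    for pa, pb in zip(a.params(), b.params()):
        assert np.array_equal(pa.value, pb.value)


def test_input_too_small_rejected():
    with pytest.raises(ValueError):
        build_network(_cfg(input_length=8))


@pytest.mark.parametrize("m", [16, 17, 100, 1000])
@pytest.mark.parametrize("levels", [1, 2, 3])
def test_reconstruction_length_matches_input(m, levels):
    """Padding/cropping bookkeeping: output length equals input length for
    lengths that are and are not stride multiples."""
    if levels == 3 and m < 32:
        m = 33  # three levels need a longer vector
    net = build_network(_cfg(input_length=m, levels=levels))
    x = np.random.default_rng(0).random((2, m)).astype(np.float32)
    recon, probs = net.forward(x)
    assert recon.shape == (2, m)
    assert np.all((recon >= 0) & (recon <= 1))
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_zero_input_gives_finite_outputs():
    net = build_network(_cfg())
    recon, probs = net.forward(np.zeros((3, 64), dtype=np.float32))
    assert np.isfinite(recon).all() and np.isfinite(probs).all()


def test_forward_length_mismatch_rejected():
    net = build_network(_cfg())
    with pytest.raises(ValueError):
        net.forward(np.zeros((1, 63), dtype=np.float32))


def test_gradient_reaches_every_parameter_group():
    """One backward pass puts nonzero gradient into both encoders, both
    decoders, the classifier, and the two log-variances."""
    net = build_network(_cfg(encoder_dropout=0.1))
    rng = np.random.default_rng(1)
    x = rng.random((6, 64)).astype(np.float32)
    recon, probs = net.forward(x, train=True)
    y = rng.integers(0, 3, size=6)
    onehot = np.zeros_like(probs)
    onehot[np.arange(6), y] = 1
    net.s1.grad += -mse_loss(recon, x) + 1
    net.s2.grad += -ce_loss(probs, y) + 1
    net.backward((2 / 6) * (recon - x), (probs - onehot) / 6)
    for name, group in net.param_groups().items():
        assert any(np.abs(p.grad).max() > 0 for p in group), name


def test_checkpoint_round_trip(tmp_path):
    net = build_network(_cfg())
    x = np.random.default_rng(2).random((2, 64)).astype(np.float32)
    r0, p0 = net.forward(x)
    net.save(tmp_path / "ckpt")
    loaded = type(net).load(tmp_path / "ckpt")
    r1, p1 = loaded.forward(x)
    assert np.allclose(r0, r1) and np.allclose(p0, p1)


# ----------------------------------------------------------------- losses
def test_mse_loss_closed_forms():
    assert mse_loss(np.array([[0.3, 0.7]]), np.array([[0.3, 0.7]])) == 0.0
    # one cell, residuals (0.5, 0.5): 0.25 + 0.25 = 0.5
    assert np.isclose(mse_loss(np.array([[0.5, 0.5]]), np.array([[0.0, 1.0]])), 0.5)


def test_mse_loss_quadratic_homogeneity():
    rng = np.random.default_rng(3)
    t = rng.random((4, 10))
    r = rng.random((4, 10))
    base = mse_loss(r, t)
    doubled = mse_loss(t + 2 * (r - t), t)
    assert np.isclose(doubled, 4 * base)


def test_mse_loss_shape_mismatch():
    with pytest.raises(ValueError):
        mse_loss(np.zeros((1, 2)), np.zeros((1, 3)))


def test_ce_loss_closed_forms():
    perfect = np.eye(3)[[0, 1, 2]]
    assert np.isclose(ce_loss(perfect, np.array([0, 1, 2])), 0.0, atol=1e-9)
    uniform = np.full((4, 5), 0.2)
    assert np.isclose(ce_loss(uniform, np.zeros(4, dtype=int)), np.log(5), atol=1e-6)


def test_ce_loss_monotone_in_true_class_probability():
    losses = [ce_loss(np.array([[p, 1 - p]]), np.array([0]))
              for p in (0.9, 0.5, 0.1)]
    assert losses[0] < losses[1] < losses[2]


def test_ce_loss_label_out_of_range():
    with pytest.raises(ValueError):
        ce_loss(np.full((1, 2), 0.5), np.array([2]))


def test_combined_loss_closed_forms():
    # sigma1 = sigma2 = 1: log terms vanish
    assert np.isclose(combined_loss(0.3, 0.4, 0.0, 0.0).total, 0.7)
    # L_MSE = L_CE = 1, sigma1^2 = e, sigma2^2 = 1 -> e^-1 + 1 + 1
    assert np.isclose(combined_loss(1.0, 1.0, 1.0, 0.0).total,
                      2.0 + np.exp(-1.0), atol=1e-9)


@given(st.floats(0.01, 10), st.floats(0.01, 10),
       st.floats(-2, 2), st.floats(-2, 2))
@settings(max_examples=50, deadline=None)
def test_combined_loss_matches_direct_transcription(l_mse, l_ce, s1, s2):
    """The log-variance parameterization equals the printed weighting
    L/sigma1^2 + L/sigma2^2 + 2 log sigma1 + 2 log sigma2 to 1e-9."""
    sigma1 = np.sqrt(np.exp(s1))
    sigma2 = np.sqrt(np.exp(s2))
    direct = (l_mse / sigma1 ** 2 + l_ce / sigma2 ** 2
              + 2 * np.log(sigma1) + 2 * np.log(sigma2))
    assert abs(combined_loss(l_mse, l_ce, s1, s2).total - direct) < 1e-9


def test_combined_loss_optimum_at_task_variance_equal_loss():
    """For fixed L_MSE > 0 the total is minimized over sigma1^2 at
    sigma1^2 = L_MSE (stationarity of L/s + log s)."""
    l_mse = 0.37
    s_grid = np.linspace(np.log(l_mse) - 1, np.log(l_mse) + 1, 2001)
    totals = [combined_loss(l_mse, 0.0, s, 0.0).total for s in s_grid]
    s_best = s_grid[int(np.argmin(totals))]
    assert abs(np.exp(s_best) - l_mse) < 1e-3


def test_combined_loss_rejects_non_finite():
    with pytest.raises(ValueError):
        combined_loss(np.nan, 0.0, 0.0, 0.0)
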