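"""Correctness of the numpy NN engine: forward passes against scipy,
backward passes against finite differences, optimizer behaviour, and
determinism."""

import numpy as np
import pytest
from scipy.ndimage import correlate

from radiogen import nn
from radiogen.nn import functional as F
from radiogen.nn.losses import bce_loss, mse_loss, softmax_cross_entropy

from conftest import num_grad

rng0 = np.random.default_rng(0)


def _check_grads(layer, xshape, tol=2e-2):
    rng = np.random.default_rng(3)
    x = rng.standard_normal(xshape).astype(np.float32)
    y = layer.forward(x, training=True)
    t = rng.standard_normal(y.shape).astype(np.float32)

    def loss():
        return mse_loss(layer.forward(x, training=True), t)[0]

    _, g = mse_loss(layer.forward(x, training=True), t)
    gx = layer.backward(g)
    ngx = num_grad(loss, x)
    assert np.abs(gx - ngx).max() <= tol * (np.abs(ngx).max() + 1e-6)
    for name in layer.params:
        ng = num_grad(loss, layer.params[name])
        layer.forward(x, training=True)
        layer.backward(g)
        ag = layer.grads[name]
        assert np.abs(ag - ng).max() <= tol * (np.abs(ng).max() + 1e-6), name


@pytest.mark.parametrize("layer_fn,xshape", [
    (lambda: nn.Conv3d(2, 3, 3, 1, 1, rng0), (2, 2, 4, 4, 4)),
    (lambda: nn.Conv3d(2, 3, 4, 2, 1, rng0), (2, 2, 4, 6, 6)),
    (lambda: nn.ConvTranspose3d(3, 2, 4, 2, 1, rng0), (2, 3, 2, 3, 3)),
    (lambda: nn.ConvUp2(3, 2, rng0), (2, 3, 2, 2, 2)),
    (lambda: nn.ConvDown2(2, 3, rng0), (2, 2, 4, 4, 4)),
    (lambda: nn.Dense(5, 4, rng0), (3, 5)),
    (lambda: nn.InstanceNorm3d(3), (2, 3, 3, 4, 4)),
    (lambda: nn.MaxPool3d(), (2, 2, 4, 4, 4)),
    (lambda: nn.Tanh(), (2, 7)),
    (lambda: nn.Sigmoid(), (2, 7)),
    (lambda: nn.LeakyReLU(0.2), (2, 7)),
], ids=["conv_s1", "conv_s2", "convT", "up2", "down2", "dense", "inorm",
        "maxpool", "tanh", "sigmoid", "lrelu"])
def test_backward_matches_finite_differences(layer_fn, xshape):
    _check_grads(layer_fn(), xshape)


def test_conv3d_forward_matches_scipy():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((1, 1, 6, 6, 6)).astype(np.float32)
    w = rng.standard_normal((1, 1, 3, 3, 3)).astype(np.float32)
    y = F.corr3d(x, w, (1, 1, 1), (1, 1, 1))
    ref = correlate(x[0, 0].astype(float), w[0, 0].astype(float),
                    mode="constant")
    assert np.abs(y[0, 0] - ref).max() < 1e-4


def test_conv_transpose_is_adjoint_of_conv():
    """<conv(x), y> == <x, convT(y)> for matching geometry."""
    rng = np.random.default_rng(2)
    x = rng.standard_normal((1, 2, 4, 4, 4))
    w = rng.standard_normal((3, 2, 4, 4, 4))  # (O, C, k, k, k)
    y = rng.standard_normal((1, 3, 2, 2, 2))
    cx = F.corr3d(x.astype(np.float32), w.astype(np.float32),
                  (2, 2, 2), (1, 1, 1))
    # the conv weight (O, C, k...) is read by conv_transpose3d as
    # (C_in=O, C_out=C, k...), which is exactly the adjoint pairing
    ty = F.conv_transpose3d(y.astype(np.float32), w.astype(np.float32),
                            (2, 2, 2), (1, 1, 1))
    assert np.allclose((cx * y).sum(), (x * ty).sum(), rtol=1e-4)


def test_incompatible_geometry_raises():
    with pytest.raises(ValueError):
        F.out_size(5, 4, 2, 1)  # (5 + 2 - 4) odd


def test_maxpool_requires_even_dims():
    with pytest.raises(ValueError, match="even"):
        nn.MaxPool3d().forward(np.zeros((1, 1, 3, 4, 4), dtype=np.float32))


def test_dropout_scales_and_masks():
    d = nn.Dropout(0.5)
    d.rng = np.random.default_rng(0)
    x = np.ones((4, 1000), dtype=np.float32)
    y = d.forward(x, training=True)
    kept = y[y != 0]
    assert np.allclose(kept, 2.0)               # inverted dropout scaling
    assert abs((y != 0).mean() - 0.5) < 0.05
    assert np.array_equal(d.forward(x, training=False), x)


def test_adam_minimizes_quadratic():
    rng = np.random.default_rng(0)
    layer = nn.Dense(3, 1, rng)
    opt = nn.Adam([("0.w", layer, "w"), ("0.b", layer, "b")], lr=0.05)
    x = rng.standard_normal((64, 3)).astype(np.float32)
    t = (x @ np.array([[1.0], [-2.0], [0.5]]) + 0.3).astype(np.float32)
    for _ in range(300):
        y = layer.forward(x)
        loss, g = mse_loss(y, t)
        layer.backward(g)
        opt.step()
    assert loss < 1e-3


def test_plateau_scheduler_halves_lr():
    rng = np.random.default_rng(0)
    layer = nn.Dense(2, 1, rng)
    opt = nn.SGD([("0.w", layer, "w")], lr=1.0)
    sched = nn.ReduceLROnPlateau(opt, factor=0.5, patience=2)
    for _ in range(5):
        sched.step(1.0)  # no improvement
    assert opt.lr < 1.0


def test_sequential_state_dict_roundtrip():
    rng = np.random.default_rng(0)
    net = nn.Sequential(nn.Dense(4, 3, rng), nn.ReLU(), nn.Dense(3, 2, rng))
    state = net.state_dict()
    net2 = nn.Sequential(nn.Dense(4, 3, np.random.default_rng(9)), nn.ReLU(),
                         nn.Dense(3, 2, np.random.default_rng(9)))
    net2.load_state_dict(state)
    x = np.random.default_rng(1).standard_normal((5, 4)).astype(np.float32)
    assert np.array_equal(net.forward(x), net2.forward(x))


def test_losses_gradients_match_finite_differences():
    rng = np.random.default_rng(4)
    p = rng.random(6).astype(np.float64) * 0.8 + 0.1
    t = (rng.random(6) > 0.5).astype(float)
    _, g = bce_loss(p, t)
    ng = num_grad(lambda: bce_loss(p, t)[0], p, eps=1e-5)
    assert np.allclose(g, ng, rtol=1e-3)

    z = rng.standard_normal((4, 3))
    labels = np.array([0, 2, 1, 1])
    _, gz = softmax_cross_entropy(z, labels)
    ngz = num_grad(lambda: softmax_cross_entropy(z, labels)[0], z, eps=1e-5)
    assert np.allclose(gz, ngz, rtol=1e-3, atol=1e-8)
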