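"""Generative-neuron layer: vectorized forward vs independent oracle,
degenerate cases, and gradient correctness."""

import numpy as np
import pytest

from mhdnet import autodiff as ad
from mhdnet.exceptions import ContractError
from mhdnet.selfonn import (
    SelfOnn1d,
    SelfOnnParams,
    SelfOnnSpec,
    init_selfonn_params,
    selfonn_forward,
    selfonn_oracle,
)


def random_case(rng):
    spec = SelfOnnSpec(
        in_channels=int(rng.integers(1, 4)),
        out_channels=int(rng.integers(1, 5)),
        kernel_size=int(rng.choice([1, 3, 5])),
        q=int(rng.integers(1, 4)),
    )
    params = init_selfonn_params(spec, rng, dtype=np.float64)
    x = rng.normal(size=(spec.in_channels, int(rng.integers(8, 33))))
    return spec, params, x


def test_forward_matches_oracle_on_random_cases(rng):
    """50 random (shape, q, params) draws agree to < 1e-5 everywhere."""
    worst = 0.0
    for _ in range(50):
        spec, params, x = random_case(rng)
        diff = np.abs(
            selfonn_forward(x, spec, params) - selfonn_oracle(x, spec, params)
        ).max()
        worst = max(worst, diff)
    assert worst < 1e-5


def test_q1_equals_plain_convolution(rng):
    """With q=1 the layer degenerates to an ordinary convolution."""
    from scipy.signal import correlate

    spec = SelfOnnSpec(3, 2, 5, q=1)
    params = init_selfonn_params(spec, rng, dtype=np.float64)
    x = rng.normal(size=(3, 40))
    y = selfonn_forward(x, spec, params)
    expected = np.zeros_like(y)
    for o in range(2):
        acc = np.zeros(40)
        for c in range(3):
            acc += correlate(x[c], params.weights[0, o, c], mode="same")
        expected[o] = acc + params.bias[o]
    assert np.abs(y - expected).max() < 1e-6


def test_scalar_taylor_evaluation():
    """Kernel-1, q=3 neuron with unit weights maps x=2 to 2+4+8=14."""
    spec = SelfOnnSpec(1, 1, 1, q=3)
    params = SelfOnnParams(weights=np.ones((3, 1, 1, 1)), bias=np.zeros(1))
    y = selfonn_forward(np.array([[2.0]]), spec, params)
    assert y.shape == (1, 1)
    assert y[0, 0] == pytest.approx(14.0)


def test_oracle_hand_computed_q2_kernel3():
    """q=2, kernel 3 on a 1x5 input, expanded term by term by hand."""
    spec = SelfOnnSpec(1, 1, 3, q=2)
    w1 = [0.5, -1.0, 2.0]
    w2 = [0.25, 1.0, -0.5]
    b = 0.7
    params = SelfOnnParams(
        weights=np.array([w1, w2]).reshape(2, 1, 1, 3), bias=np.array([b])
    )
    x = np.array([[1.0, 2.0, 0.0, -1.0, 3.0]])
    expected = [
        b + (-1.0 * 1 + 1.0 * 1**2) + (2.0 * 2 + -0.5 * 2**2),  # left edge
        b + (0.5 * 1 + 0.25 * 1**2) + (-1.0 * 2 + 1.0 * 2**2) + 0.0,
        b + (0.5 * 2 + 0.25 * 2**2) + 0.0 + (2.0 * -1 + -0.5 * (-1) ** 2),
        b + 0.0 + (-1.0 * -1 + 1.0 * (-1) ** 2) + (2.0 * 3 + -0.5 * 3**2),
        b + (0.5 * -1 + 0.25 * (-1) ** 2) + (-1.0 * 3 + 1.0 * 3**2),  # right edge
    ]
    for fn in (selfonn_oracle, selfonn_forward):
        assert fn(x, spec, params)[0] == pytest.approx(expected)


def test_oracle_zero_input_gives_bias(rng):
    spec = SelfOnnSpec(2, 3, 3, q=3)
    params = init_selfonn_params(spec, rng, dtype=np.float64)
    params.bias[:] = [1.0, -2.0, 0.5]
    y = selfonn_oracle(np.zeros((2, 7)), spec, params)
    assert np.allclose(y, np.array([1.0, -2.0, 0.5])[:, None] * np.ones((3, 7)))


def test_additivity_in_powers(rng):
    """forward(q=3) equals the sum of its single-power contributions."""
    spec = SelfOnnSpec(2, 2, 5, q=3)
    params = init_selfonn_params(spec, rng, dtype=np.float64)
    x = rng.normal(size=(2, 24))
    full = selfonn_forward(x, spec, params)
    parts = np.zeros_like(full)
    for k in range(3):
        w_only = np.zeros_like(params.weights)
        w_only[k] = params.weights[k]
        parts += selfonn_forward(
            x, spec, SelfOnnParams(weights=w_only, bias=np.zeros(2))
        )
    parts += params.bias[:, None]
    assert np.abs(full - parts).max() <= 1e-6


def test_module_path_equals_functional_path(rng):
    """The fused training-time layer computes the same map as the API."""
    spec = SelfOnnSpec(3, 4, 5, q=3)
    layer = SelfOnn1d(spec, rng=np.random.default_rng(7), dtype=np.float64)
    x = rng.normal(size=(2, 3, 33))
    via_module = layer(ad.Tensor(x)).data
    via_api = selfonn_forward(x, spec, layer.get_params())
    assert np.abs(via_module - via_api).max() < 1e-10


@pytest.mark.parametrize("q,kernel", [(1, 3), (3, 3), (2, 1)])
def test_gradient_matches_finite_differences(q, kernel, rng):
    """Analytic gradients agree with central differences to 1e-4 relative."""
    layer = SelfOnn1d(
        SelfOnnSpec(2, 3, kernel, q=q), rng=np.random.default_rng(3), dtype=np.float64
    )
    x = rng.normal(size=(1, 2, 9))
    y = (rng.random((1, 3, 9)) < 0.3).astype(float)

    def loss_value():
        return float(ad.bce_with_logits(layer(ad.Tensor(x)), y).data)

    loss = ad.bce_with_logits(layer(ad.Tensor(x)), y)
    loss.backward()
    eps = 1e-6
    for p in layer.parameters():
        analytic = p.grad.copy()
        numeric = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = p.data[i]
            p.data[i] = orig + eps
            lp = loss_value()
            p.data[i] = orig - eps
            lm = loss_value()
            p.data[i] = orig
            numeric[i] = (lp - lm) / (2 * eps)
        rel = np.abs(analytic - numeric).max() / (np.abs(numeric).max() + 1e-12)
        assert rel < 1e-4


def test_tanh_composition_is_bounded(rng):
    """Layer + tanh stays strictly inside (-1, 1)."""
    spec = SelfOnnSpec(1, 2, 5, q=3)
    params = init_selfonn_params(spec, rng, dtype=np.float64)
    x = rng.normal(size=(1, 100))
    y = np.tanh(selfonn_forward(x, spec, params))
    assert (np.abs(y) < 1.0).all()


def test_shape_mismatch_raises(rng):
    spec = SelfOnnSpec(2, 3, 5, q=3)
    params = init_selfonn_params(SelfOnnSpec(2, 3, 5, q=2), rng)
    with pytest.raises(ContractError):
        selfonn_forward(np.zeros((2, 16)), spec, params)
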