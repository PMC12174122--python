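import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_gradient(fn, x, indices, eps=1e-6):
    """Central-difference gradient of scalar ``fn`` at selected flat indices."""
    flat = x.ravel()
    out = {}
    for i in indices:
        v0 = flat[i]
        flat[i] = v0 + eps
        lp = fn()
        flat[i] = v0 - eps
        lm = fn()
        flat[i] = v0
        out[i] = (lp - lm) / (2 * eps)
    return out


def assert_gradients_match(module, x, n_input=40, n_param=15, rtol=1e-5,
                           seed=0, forward=None, backward=None):
    """Check analytic input/parameter gradients against central differences."""
    rng = np.random.default_rng(seed)
    forward = forward or module.forward
    backward = backward or module.backward
    out = forward(x)
    r = rng.standard_normal(out.shape)

    def loss():
        return float((forward(x) * r).sum())

    module.zero_grad()
    dx = backward(r)
    idx = rng.choice(x.size, size=min(n_input, x.size), replace=False)
    num = numeric_gradient(loss, x, idx)
    for i, nv in num.items():
        assert np.isclose(dx.ravel()[i], nv, rtol=rtol, atol=1e-7), \
            f"input grad mismatch at {i}: {dx.ravel()[i]} vs {nv}"
    for name, p in module.named_params():
        idx = rng.choice(p.size, size=min(n_param, p.size), replace=False)
        num = numeric_gradient(loss, p.data, idx)
        for i, nv in num.items():
            assert np.isclose(p.grad.ravel()[i], nv, rtol=rtol, atol=1e-7), \
                f"{name} grad mismatch at {i}: {p.grad.ravel()[i]} vs {nv}"
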