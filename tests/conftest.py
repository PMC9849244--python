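"""Shared fixtures and numerical-gradient helpers."""

from __future__ import annotations

import numpy as np
import pytest

from slhardnet import nn


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def zero_parameters(module: nn.Module) -> None:
    """Zero every trainable parameter of a module (incl. BN scales)."""
    for p in module.parameters():
        p.data[...] = 0.0


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-2) -> np.ndarray:
    """Central-difference gradient of a scalar-valued fn wrt array x.

    float32 arithmetic bounds the achievable accuracy; callers compare with
    a correspondingly loose tolerance.
    """
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2.0 * eps)
    return g


def assert_grad_close(analytic: np.ndarray, numeric: np.ndarray,
                      rtol: float = 6e-2, atol: float = 6e-3):
    np.testing.assert_allclose(analytic, numeric, rtol=rtol, atol=atol)


@pytest.fixture(scope="session")
def full_model():
    """One seeded full SL-HarDNet shared across read-only tests."""
    from slhardnet.network import SLHardNet

    nn.manual_seed(7)
    model = SLHardNet()
    model.eval()
    return model


@pytest.fixture(scope="session")
def synth_96():
    """A small deterministic synthetic dataset at 96x96."""
    from slhardnet.synth import make_synthetic_dataset

    return make_synthetic_dataset(8, seed=11, canvas=(96, 96))
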