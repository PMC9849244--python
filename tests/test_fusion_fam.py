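"""FAM: projection/assignment/graph-reasoning oracles and the MEM."""

import numpy as np
import pytest

from slhardnet import nn
from slhardnet.exceptions import ConfigurationError
from slhardnet.fusion_fam import FAM, GCNUnit, MEM
from slhardnet.nn.tensor import Tensor

from conftest import zero_parameters


@pytest.fixture(scope="module")
def fam():
    nn.manual_seed(0)
    module = FAM(sem_ch=32, detail_ch=128, num_nodes=16, node_dim=16)
    module.eval()
    return module


@pytest.fixture(scope="module")
def toy_fam():
    """4 nodes, 4-dim node features, 4x4 spatial toy (16 pixels)."""
    nn.manual_seed(1)
    module = FAM(sem_ch=8, detail_ch=8, num_nodes=4, node_dim=4)
    module.eval()
    return module


def _io(rng, h=8):
    o1 = Tensor(rng.normal(size=(1, 32, h, h)).astype(np.float32))
    o2 = Tensor(rng.normal(size=(1, 128, 2 * h, 2 * h)).astype(np.float32))
    return o1, o2


def test_fam_output_shape(fam, rng):
    o1, o2 = _io(rng)
    with nn.no_grad():
        z = fam(o1, o2)
    assert z.shape == (1, 32, 8, 8)


def test_pixel_embed_two_independent_views(fam, rng):
    o1, _ = _io(rng)
    with nn.no_grad():
        q, p = fam.pixel_embed(o1)
    assert q.shape == p.shape == (1, 16, 8, 8)
    assert not np.allclose(q.data, p.data)
    saved = fam.conv_q.state_dict()
    zero_parameters(fam.conv_q)
    with nn.no_grad():
        q0, _ = fam.pixel_embed(o1)
    fam.conv_q.load_state_dict(saved)
    np.testing.assert_array_equal(q0.data, 0.0)


def test_detail_gate_softmax_normalised(fam, rng):
    _, o2 = _io(rng)
    with nn.no_grad():
        att = fam.detail_gate(o2)
        # full softmax stack, recomputed independently
        z = fam.conv_gate(o2)
        z = nn.ops.resize_bilinear(z, (8, 8)).data.astype(np.float64)
    assert att.shape == (1, 1, 8, 8)
    assert ((att.data > 0) & (att.data < 1)).all()
    e = np.exp(z - z.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(att.data[:, 0], probs[:, 1], atol=1e-6)


def test_build_nodes_gate_annihilation_and_constant(fam, rng):
    _, o2 = _io(rng)
    p = Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))
    zero_att = Tensor(np.zeros((1, 1, 8, 8), dtype=np.float32))
    with nn.no_grad():
        v = fam.build_nodes(p, zero_att)
    assert v.shape == (1, 16, 16)
    np.testing.assert_array_equal(v.data, 0.0)
    const = Tensor(np.broadcast_to(
        np.arange(16, dtype=np.float32)[None, :, None, None],
        (1, 16, 8, 8)).copy())
    ones = Tensor(np.ones((1, 1, 8, 8), dtype=np.float32))
    with nn.no_grad():
        v = fam.build_nodes(const, ones)
    np.testing.assert_allclose(
        v.data, np.tile(np.arange(16, dtype=np.float32), (1, 16, 1)),
        atol=1e-6)


def test_assign_uniform_for_zero_nodes(fam, rng):
    p = Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))
    v = Tensor(np.zeros((1, 16, 16), dtype=np.float32))
    with nn.no_grad():
        s = fam.assign(v, p)
    np.testing.assert_allclose(s.data, 1.0 / 64.0, atol=1e-7)


def test_assign_rows_stochastic(fam, rng):
    o1, o2 = _io(rng)
    with nn.no_grad():
        q, p = fam.pixel_embed(o1)
        att = fam.detail_gate(o2)
        v = fam.build_nodes(p, att)
        s = fam.assign(v, p)
    assert s.shape == (1, 16, 64)
    np.testing.assert_allclose(s.data.sum(axis=2), 1.0, atol=1e-5)


def test_projection_chain_matches_dense_oracle(toy_fam, rng):
    """Full project-reason-reproject chain vs an explicit matrix oracle on a
    4-node, 16-pixel toy."""
    o1 = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
    o2 = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
    f = toy_fam
    with nn.no_grad():
        q, p = f.pixel_embed(o1)
        o2a = nn.ops.resize_bilinear(o2, (4, 4))
        att = f.detail_gate(o2a, out_hw=(4, 4))
        v = f.build_nodes(p, att)
        s = f.assign(v, p)
        y = f.graph_reason(s, q)

    # oracle in plain numpy (float32, same operation order)
    pd = p.data[0]                       # (4, 4, 4) channels first
    qd = q.data[0]
    attd = att.data[0, 0]
    gated = pd * attd[None]
    # adaptive 2x2 pooling of 4x4 = mean over 2x2 cells
    pooled = gated.reshape(4, 2, 2, 2, 2).mean(axis=(2, 4))
    v_oracle = pooled.reshape(4, 4).T    # (K=4, Cg=4)
    np.testing.assert_allclose(v.data[0], v_oracle, atol=1e-6)

    p_flat = pd.reshape(4, 16).T         # (M, Cg)
    scores = v_oracle @ p_flat.T         # (K, M)
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    s_oracle = e / e.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(s.data[0], s_oracle, atol=1e-6)

    q_flat = qd.reshape(4, 16).T
    fn = s_oracle @ q_flat               # (K, Cg)
    unit = f.gcns[0]
    mixed = fn - unit.adjacency.data @ fn
    g = np.maximum(mixed @ unit.weight.data + unit.bias.data, 0.0)
    y_oracle = (s_oracle.T @ g).T.reshape(4, 4, 4)
    np.testing.assert_allclose(y.data[0], y_oracle, atol=1e-6)


def test_graph_reason_one_hot_broadcast(toy_fam, rng):
    """Identity GCN + one-hot assignment rows: Y broadcasts pooled node
    features back to their pixels."""
    f = toy_fam
    unit = f.gcns[0]
    saved = unit.state_dict()
    unit.adjacency.data[...] = 0.0
    unit.weight.data[...] = np.eye(4)
    unit.bias.data[...] = 0.0
    q = Tensor(np.abs(rng.normal(size=(1, 4, 4, 4))).astype(np.float32))
    s_rows = np.zeros((1, 4, 16), dtype=np.float32)
    for k in range(4):
        s_rows[0, k, 4 * k] = 1.0        # node k reads pixel 4k only
    with nn.no_grad():
        y = f.graph_reason(Tensor(s_rows), q)
    q_flat = q.data[0].reshape(4, 16)
    for k in range(4):
        np.testing.assert_allclose(y.data[0].reshape(4, 16)[:, 4 * k],
                                   q_flat[:, 4 * k], atol=1e-6)
    unit.load_state_dict(saved)


def test_gcn_unit_shape_contract(rng):
    nn.manual_seed(2)
    unit = GCNUnit(16, 16)
    fn = Tensor(rng.normal(size=(2, 16, 16)).astype(np.float32))
    assert unit(fn).shape == (2, 16, 16)


def test_mem_matches_componentwise_oracle(rng):
    nn.manual_seed(3)
    mem = MEM(128, 32)
    mem.eval()
    o1 = Tensor(rng.normal(size=(2, 32, 6, 6)).astype(np.float32))
    o2 = Tensor(rng.normal(size=(2, 128, 6, 6)).astype(np.float32))
    with nn.no_grad():
        ell, ell_p, hf, hf_p = mem.components(o1, o2)
        r = mem(o1, o2)
    # vectorised path vs explicit loops over the broadcast
    oracle = np.empty_like(r.data)
    for n in range(2):
        for c in range(32):
            oracle[n, c] = hf_p.data[n, c, 0, 0] * ell.data[n, c] \
                + hf.data[n, c] * ell_p.data[n, 0]
    np.testing.assert_allclose(r.data, oracle, atol=1e-6)
    assert r.shape == (2, 32, 6, 6)


def test_mem_zero_detail_branch(rng):
    nn.manual_seed(4)
    mem = MEM(128, 32)
    mem.eval()
    o1 = Tensor(rng.normal(size=(1, 32, 5, 5)).astype(np.float32))
    o2 = Tensor(np.zeros((1, 128, 5, 5), dtype=np.float32))
    with nn.no_grad():
        ell, ell_p, hf, hf_p = mem.components(o1, o2)
        r = mem(o1, o2)
    np.testing.assert_array_equal(ell.data, 0.0)       # bias-free 1x1
    assert np.ptp(ell_p.data) == 0.0                   # constant bias map
    np.testing.assert_allclose(r.data, hf.data * ell_p.data, atol=1e-7)


def test_zeroed_graph_branch_reduces_to_mem(fam, rng):
    o1, o2 = _io(rng)
    saved = {k: v.data.copy() for k, v in fam.conv_y.named_parameters()}
    zero_parameters(fam.conv_y)
    with nn.no_grad():
        z = fam(o1, o2)
        o2a = nn.ops.resize_bilinear(o2, (8, 8))
        r = fam.mem(o1, o2a)
    for (k, p), (_, v) in zip(fam.conv_y.named_parameters(), saved.items()):
        p.data[...] = saved[k]
    np.testing.assert_array_equal(z.data, r.data)


def test_gradient_reaches_both_inputs(rng):
    nn.manual_seed(5)
    module = FAM(sem_ch=32, detail_ch=128, num_nodes=16, node_dim=16)
    module.train()
    o1, o2 = _io(rng)
    o1.requires_grad = True
    o2.requires_grad = True
    z = module(o1, o2)
    (z * z).mean().backward()
    assert o1.grad is not None and np.any(o1.grad)
    assert o2.grad is not None and np.any(o2.grad)


def test_non_square_node_count_rejected():
    with pytest.raises(ConfigurationError, match="perfect square"):
        FAM(num_nodes=10)
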