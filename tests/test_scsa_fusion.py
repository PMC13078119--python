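"""Spatial-channel synergistic attention and the SCSA fusion block:
softmax conservation, constant-input collapse, closed-form softmax
arithmetic, a full loop-based reference forward, and weight accounting."""

import numpy as np
import pytest

from yolosda import nn
from yolosda.nn import ops
from yolosda.nn.tensor import Tensor, no_grad
from yolosda.scsa import (A2C2fSCSA, A2C2fSCSASpec, ABlockSCSA, SCSA,
                          SCSASpec)


def make_scsa(c=8, groups=4, **kw):
    return SCSA(SCSASpec(channels=c, norm_groups=groups, **kw))


# ---------------------------------------------------------------------------
# spatial pathway
# ---------------------------------------------------------------------------

def test_spatial_attention_preserves_shape_and_gate_range(rng):
    scsa = make_scsa()
    x = Tensor(rng.normal(size=(2, 8, 6, 5)))
    with no_grad():
        xs, ws = scsa.spatial_attention(x)
    assert xs.shape == x.shape
    assert (ws.data > 0).all() and (ws.data < 1).all()


def test_constant_input_collapses_to_half_gates():
    """Group-normalised constants are zero, so sigmoid gives exactly 0.5."""
    scsa = make_scsa()
    x = Tensor(np.full((1, 8, 5, 5), 3.0, np.float32))
    with no_grad():
        xs, ws = scsa.spatial_attention(x)
        xc, (_, wc) = scsa.channel_attention(x)
    np.testing.assert_array_equal(ws.data, 0.5)
    np.testing.assert_allclose(xs.data, 0.5 * x.data, atol=1e-6)
    np.testing.assert_array_equal(wc.data, 0.5)


def test_channels_not_divisible_by_groups_is_config_error():
    with pytest.raises(ValueError, match="divisible"):
        SCSASpec(channels=6, norm_groups=4)


# ---------------------------------------------------------------------------
# channel pathway
# ---------------------------------------------------------------------------

def test_single_channel_attention_matrix_is_one(rng):
    scsa = make_scsa(c=1, groups=1)
    x = Tensor(rng.normal(size=(1, 1, 4, 4)))
    with no_grad():
        _, (attn, _) = scsa.channel_attention(x)
    np.testing.assert_allclose(attn.data, 1.0, atol=1e-7)


def test_attention_rows_sum_to_one(rng):
    scsa = make_scsa(c=8)
    x = Tensor(rng.normal(size=(2, 8, 6, 6)))
    with no_grad():
        _, (attn, _) = scsa.channel_attention(x)
    np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)


def test_hand_set_logits_give_closed_form_softmax_rows():
    """QK^T rows (0, ln 3) and (0, 0) map to (1/4, 3/4) and (1/2, 1/2)."""
    q = np.array([[1.0, 0.0], [0.0, 0.0]], np.float32)
    k = np.array([[0.0, 0.0], [np.log(3.0), 0.0]], np.float32)
    attn = ops.softmax(Tensor(q) @ Tensor(k).transpose(1, 0)).data
    np.testing.assert_allclose(attn, [[0.25, 0.75], [0.5, 0.5]], atol=1e-6)


def test_zero_value_projection_reduces_to_spatial_path(rng):
    scsa = make_scsa()
    scsa.v_proj.weight.data[:] = 0.0
    scsa.v_proj.bias.data[:] = 0.0
    x = Tensor(rng.normal(size=(1, 8, 4, 4)))
    with no_grad():
        out = scsa(x)
        xs, _ = scsa.spatial_attention(x)
    np.testing.assert_allclose(out.data, xs.data, atol=1e-6)


def test_forward_preserves_shape():
    scsa = make_scsa(c=32)
    x = Tensor(np.random.default_rng(1).normal(size=(4, 32, 40, 40))
               .astype(np.float32))
    with no_grad():
        assert scsa(x).shape == (4, 32, 40, 40)


# ---------------------------------------------------------------------------
# loop-based reference of the full two-pathway forward
# ---------------------------------------------------------------------------

def _gn(x2, ngroups, gamma, beta, eps=1e-5):
    """Group norm over (C, L) in float64, looped per group."""
    C, L = x2.shape
    out = np.zeros_like(x2)
    gs = C // ngroups
    for g in range(ngroups):
        blk = x2[g * gs:(g + 1) * gs]
        mu, var = blk.mean(), blk.var()
        out[g * gs:(g + 1) * gs] = (blk - mu) / np.sqrt(var + eps)
    return gamma[:, None] * out + beta[:, None]


def _dwconv1d(seq, w):
    """Depthwise edge-padded 1-D convolution, looped. seq: (C, L)."""
    C, L = seq.shape
    k = w.shape[-1]
    pad = k // 2
    sp = np.pad(seq, ((0, 0), (pad, pad)), mode="edge")
    out = np.zeros_like(seq)
    for c in range(C):
        for i in range(L):
            out[c, i] = sum(w[c, 0, 0, t] * sp[c, i + t] for t in range(k))
    return out


def scsa_loop_reference(x, scsa):
    """Independent float64 re-derivation of the SCSA forward for one image
    when the pooled token grid equals the spatial grid (H, W <= pool size)."""
    C, H, W = x.shape
    sg = scsa.spec.norm_groups
    sigmoid = lambda z: 1.0 / (1.0 + np.exp(-z))

    def axis_gate(profile):
        feats = [_dwconv1d(profile, conv.weight.data.astype(np.float64))
                 for conv in scsa.spatial_convs]
        cat = np.concatenate(feats, axis=0)
        gn = _gn(cat, cat.shape[0],  # per-channel gate normalisation
                 scsa.spatial_norm.weight.data.astype(np.float64),
                 scsa.spatial_norm.bias.data.astype(np.float64))
        return sigmoid(gn).reshape(3, C, -1).mean(axis=0)

    ph = x.mean(axis=2)  # C, H (mean over W)
    pw = x.mean(axis=1)  # C, W (mean over H)
    gh, gw = axis_gate(ph), axis_gate(pw)
    ws = 0.5 * (gh[:, :, None] + gw[:, None, :])
    xs = x * ws

    def gn_map(m, mod):
        return _gn(m.reshape(C, -1), sg,
                   mod.weight.data.astype(np.float64),
                   mod.bias.data.astype(np.float64)).reshape(C, H, W)

    q = gn_map(x, scsa.q_norm).reshape(C, -1)
    kv = gn_map(x, scsa.kv_norm)
    kw_ = scsa.k_proj.weight.data[:, 0, 0, 0].astype(np.float64)
    kb = scsa.k_proj.bias.data.astype(np.float64)
    vw = scsa.v_proj.weight.data[:, 0, 0, 0].astype(np.float64)
    vb = scsa.v_proj.bias.data.astype(np.float64)
    k = kw_[:, None] * kv.reshape(C, -1) + kb[:, None]
    v = vw[:, None] * kv.reshape(C, -1) + vb[:, None]
    logits = q @ k.T
    attn = np.zeros_like(logits)
    for i in range(C):
        e = np.exp(logits[i] - logits[i].max())
        attn[i] = e / e.sum()
    attended = (attn @ v).reshape(C, H, W)

    def gate_scalar(profile):
        g = _dwconv1d(profile, scsa.gate_conv.weight.data.astype(np.float64))
        g = _gn(g, C, scsa.gate_norm.weight.data.astype(np.float64),
                scsa.gate_norm.bias.data.astype(np.float64))
        return sigmoid(g).mean(axis=1)

    wc = 0.5 * (gate_scalar(ph) + gate_scalar(pw))
    xc = attended * wc[:, None, None]
    return xs + xc


def test_full_forward_matches_loop_reference(rng):
    scsa = make_scsa(c=4, groups=2)
    for p in scsa.parameters():  # non-trivial affine norms
        p.data[:] = rng.normal(loc=float(p.data.mean()), scale=0.2,
                               size=p.shape).astype(np.float32)
    x = rng.normal(size=(4, 4, 4)).astype(np.float32)
    with no_grad():
        out = scsa(Tensor(x[None])).data[0]
    ref = scsa_loop_reference(x.astype(np.float64), scsa)
    np.testing.assert_allclose(out, ref, rtol=1e-4, atol=1e-5)


# ---------------------------------------------------------------------------
# the fusion block
# ---------------------------------------------------------------------------

def make_block(cin=8, cout=8, hidden=8):
    return A2C2fSCSA(A2C2fSCSASpec(in_channels=cin, out_channels=cout,
                                   hidden_channels=hidden))


def test_block_preserves_spatial_dims(rng):
    blk = make_block(cin=12, cout=8)
    x = Tensor(rng.normal(size=(1, 12, 8, 8)))
    with no_grad():
        out = blk(x)
    assert out.shape == (1, 8, 8, 8)


def test_block_rejects_wrong_input_channels():
    with pytest.raises(ValueError, match="expects 8"):
        make_block()(Tensor(np.zeros((1, 4, 8, 8), np.float32)))


def test_batch_equivariance(rng):
    blk = make_block()
    blk.eval()
    x = rng.normal(size=(3, 8, 8, 8)).astype(np.float32)
    perm = [2, 0, 1]
    with no_grad():
        out = blk(Tensor(x)).data
        out_p = blk(Tensor(x[perm])).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-5)


def _convbn_params(cin, cout, k=1, groups=1):
    return k * k * (cin // groups) * cout + 2 * cout


def _ablock_scsa_params(d, mlp_ratio=1.2, sg=4):
    h = max(4, int(d * mlp_ratio))
    attn = (_convbn_params(d, 2 * d) + _convbn_params(d, d)
            + 49 * d + _convbn_params(d, d))          # qk, v, pe, proj
    mlp = _convbn_params(d, h) + _convbn_params(h, d)
    scsa = (d * (3 + 5 + 7)          # multi-scale spatial depthwise taps
            + 2 * 3 * d              # GN over the 3C concatenation
            + 2 * d + 2 * d          # q / kv group norms
            + 2 * (d + d)            # k, v depthwise 1x1 projections + bias
            + 9 * d + 2 * d)         # 9-tap gate conv + gate norm
    return attn + mlp + scsa


def test_block_parameter_count_manual_enumeration():
    """in = out = hidden = 8 block vs the hand-summed weight inventory."""
    blk = make_block(8, 8, 8)
    unit = _ablock_scsa_params(8)
    c_mid = max(8, 8 // 2)
    expected = (_convbn_params(8, 8)           # cv1 stem projection
                + 4 * unit                     # two branches x two units
                + _convbn_params(3 * 8, c_mid)  # merge conv
                + 1                            # learnable scaling
                + _convbn_params(c_mid, 8))    # output projection
    assert blk.num_parameters() == expected


def test_shared_branch_flag_halves_branch_parameters():
    solo = make_block(8, 8, 8)
    shared = A2C2fSCSA(A2C2fSCSASpec(in_channels=8, out_channels=8,
                                     hidden_channels=8, shared_branches=True))
    assert solo.num_parameters() - shared.num_parameters() == \
        2 * _ablock_scsa_params(8)


def test_ablock_scsa_runs_and_preserves_shape(rng):
    unit = ABlockSCSA(8)
    x = Tensor(rng.normal(size=(2, 8, 4, 4)))
    with no_grad():
        assert unit(x).shape == (2, 8, 4, 4)
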