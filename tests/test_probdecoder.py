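"""ProbSparse decoder: sparsity scores, sparse/dense equivalence, norms."""

import math

import numpy as np
import pytest

import ecgrecon as er
from ecgrecon._autograd import Tensor
from ecgrecon.probdecoder import (ProbDecoder, make_attention_bundle,
                                  probsparse_attention, residual_norm,
                                  sparsity_scores)


def dense_attention(Q, K, V, scale_sqrt=True):
    """Independent dense softmax attention oracle."""
    d = Q.shape[1]
    scale = math.sqrt(d) if scale_sqrt else float(d)
    logits = Q @ K.T / scale
    w = np.exp(logits - logits.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    return w @ V


def test_sparsity_scores_orthogonal_query(rng):
    K = np.eye(8)
    Q = np.vstack([np.zeros(8), rng.standard_normal((7, 8))])
    M, idx = sparsity_scores(Q, K, np.random.default_rng(0))
    assert M[0] == 0.0  # orthogonal to every key: max = mean = 0
    assert len(idx) == math.ceil(math.log(8))
    assert len(np.unique(idx)) == len(idx)


def test_sparsity_scores_dominant_key_alignment():
    # query 0 aligned with a dominant key scores highest
    d = 6
    K = np.eye(d) * 5.0
    Q = np.eye(d)
    Q[0] *= 10.0

    class FullSampler:
        def choice(self, n, size, replace):
            return np.arange(n)

    M, _ = sparsity_scores(Q, K, FullSampler())
    assert np.argmax(M) == 0


def test_sparsity_scores_full_sampling_matches_dense_oracle(rng):
    L, d = 32, 4
    Q = rng.standard_normal((L, d))
    K = rng.standard_normal((L, d))

    class FullSampler:
        """Generator stub whose 'random' choice is every key."""

        def choice(self, n, size, replace):
            return np.arange(n)

    M, idx = sparsity_scores(Q, K, FullSampler())
    assert np.array_equal(idx, np.arange(L))
    # dense max-mean oracle over all L dot products
    x = Q @ K.T
    assert np.allclose(M, x.max(axis=1) - x.mean(axis=1))


def test_probsparse_equals_dense_when_u_covers_all(rng):
    for _ in range(50):
        L = int(rng.integers(8, 65))
        d = int(rng.integers(2, 8))
        Q = rng.standard_normal((L, d))
        K = rng.standard_normal((L, d))
        V = rng.standard_normal((L, d))
        C = L  # u = ceil(C ln L) >= L
        bundle = make_attention_bundle(Q, K, V, C, np.random.default_rng(0))
        assert len(bundle.selected_q_idx) == L
        out = probsparse_attention(bundle)
        assert np.abs(out - dense_attention(Q, K, V)).max() < 1e-5


def test_probsparse_constant_values(rng):
    L, d = 16, 3
    Q, K = rng.standard_normal((2, L, d))
    V = np.full((L, d), 2.5)
    bundle = make_attention_bundle(Q, K, V, 1.0, np.random.default_rng(0))
    out = probsparse_attention(bundle)
    assert np.abs(out - 2.5).max() < 1e-12


def test_probsparse_u_clipped_to_one():
    rng = np.random.default_rng(2)
    Q, K, V = rng.standard_normal((3, 10, 2))
    bundle = make_attention_bundle(Q, K, V, 1e-9, np.random.default_rng(0))
    assert len(bundle.selected_q_idx) == 1
    out = probsparse_attention(bundle)
    mean_rows = np.tile(V.mean(axis=0), (10, 1))
    mask = np.ones(10, bool)
    mask[bundle.selected_q_idx] = False
    assert np.allclose(out[mask], mean_rows[mask])


def test_residual_norm_cancellation_and_moments(rng):
    a = rng.standard_normal((6, 8))
    out = residual_norm(-a, a, bias=np.full(8, 1.5))
    assert np.abs(out - 1.5).max() < 1e-9  # zeros normalize to bias only

    x = rng.standard_normal((5, 16))
    y = rng.standard_normal((5, 16))
    v = residual_norm(x, y)
    assert np.abs(v.mean(axis=-1)).max() < 1e-6
    assert np.abs(v.var(axis=-1) - 1.0).max() < 1e-4

    # independent hand-coded normalization oracle
    s = x + y
    expected = (s - s.mean(-1, keepdims=True)) / np.sqrt(
        s.var(-1, keepdims=True) + 1e-5)
    assert np.allclose(v, expected)


def _tiny_decoder(**kw):
    kw.setdefault("dropout", 0.0)
    return ProbDecoder(8, np.random.default_rng(0), **kw)


def test_encode_decoder_input_zero_and_shapes():
    dec = _tiny_decoder()
    dec.token_embed.bias.data[:] = 0.0
    for proj in (dec.q_proj, dec.k_proj, dec.v_proj):
        proj.bias.data[:] = 0.0
    emb, Q, K, V = dec.encode_decoder_input(Tensor(np.zeros((1, 12, 1))))
    for t in (emb, Q, K, V):
        assert t.data.shape == (1, 12, 8)
        assert np.all(t.data == 0)
    with pytest.raises(ValueError):
        dec.encode_decoder_input(Tensor(np.zeros((1, 12, 2))))


def test_decoder_deterministic_given_seed():
    dec = _tiny_decoder()
    x = np.random.default_rng(3).standard_normal((2, 32, 1))
    enc = np.random.default_rng(4).standard_normal((2, 32, 8))
    o1 = dec(Tensor(x), Tensor(enc), np.random.default_rng(9))
    o2 = dec(Tensor(x), Tensor(enc), np.random.default_rng(9))
    assert np.array_equal(o1.data, o2.data)
    assert o1.data.shape == (2, 32, 1)


def test_cross_attention_uniform_when_encoder_zero():
    dec = _tiny_decoder(decoder_residual=False)
    dec.enc_conv.bias.data[:] = 0.0
    dec.q2_proj.bias.data[:] = 0.0
    dec.k2_proj.bias.data[:] = 0.0
    L = 10
    vhat = Tensor(np.random.default_rng(5).standard_normal((1, L, 8)))
    out = dec.cross_attention_head(Tensor(np.zeros((1, L, 8))), vhat,
                                   np.random.default_rng(0))
    # zero encoder output -> equal logits -> every row sees mean of vhat
    mean_row = vhat.data[0].mean(axis=0, keepdims=True)
    y = dec.cross_out(Tensor(np.tile(mean_row, (L, 1))[None]))
    f = dec.ffn_out(dec.ffn_in(y).gelu())
    expected = dec.head(f).data
    assert np.abs(out.data - expected).max() < 1e-10


def test_attention_rows_are_convex_combinations(rng):
    """With V entries in [a, b], attended outputs stay in [a, b]."""
    L, d = 24, 4
    Q = rng.standard_normal((L, d))
    K = rng.standard_normal((L, d))
    V = rng.uniform(-0.3, 0.9, (L, d))
    bundle = make_attention_bundle(Q, K, V, 2.0, np.random.default_rng(1))
    out = probsparse_attention(bundle)
    assert out.min() >= -0.3 - 1e-12
    assert out.max() <= 0.9 + 1e-12


def test_scale_flag_switches_denominator(rng):
    L, d = 12, 4
    Q, K, V = rng.standard_normal((3, L, d))
    bundle = make_attention_bundle(Q, K, V, L, np.random.default_rng(0))
    out_sqrt = probsparse_attention(bundle, scale_sqrt=True)
    out_lin = probsparse_attention(bundle, scale_sqrt=False)
    assert np.abs(out_sqrt - dense_attention(Q, K, V, True)).max() < 1e-10
    assert np.abs(out_lin - dense_attention(Q, K, V, False)).max() < 1e-10
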