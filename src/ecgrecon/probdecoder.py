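"""Sparse-attention decoder for single-lead reconstruction ("ProbDecoder").

The decoder receives (a) the one input lead most correlated with the target
lead and (b) the encoder output.  Its stages:

1. token embedding of the input lead (width-3 1-D convolution) and linear
   maps to query/key/value matrices Q, K, V (all L x d_model),
2. query sparsity measurement: each query is scored by the max-minus-mean
   statistic of its dot products with ceil(ln L) randomly sampled keys —
   queries attending broadly (flat score) are near-uniform and can be
   skipped,
3. ProbSparse self-attention: only the top-u queries (u = ceil(C ln L),
   C = 5 by default) receive full softmax attention over all keys; the
   remaining output rows are filled with the time-mean of V,
4. residual + layer normalization with the token embedding (the "value
   correction" step),
5. encoder-decoder attention: queries/keys derived from the encoder output
   via a convolution + linear map, values from step 4; dense softmax
   attention,
6. position-wise feed-forward and a linear head mapping d_model -> 1,
   producing the whole target lead in one step (non-autoregressive).

Softmax logits are scaled by sqrt(d_head) by default (``attn_scale_sqrt``;
set False to divide by d_head instead).  All random choices (key sampling,
dropout) flow through the generator passed to ``__call__``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _nn
from ._autograd import Tensor

__all__ = ["AttentionBundle", "encode_decoder_input", "sparsity_scores",
           "make_attention_bundle", "probsparse_attention", "residual_norm",
           "ProbDecoder"]


@dataclass
class AttentionBundle:
    """Query/key/value matrices plus the sparsity bookkeeping for one head."""

    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    sampled_key_idx: np.ndarray
    scores: np.ndarray
    selected_q_idx: np.ndarray
    C: float

    def __post_init__(self):
        L = self.Q.shape[0]
        if len(np.unique(self.sampled_key_idx)) != len(self.sampled_key_idx):
            raise ValueError("sampled key indices must be distinct")
        if (self.sampled_key_idx < 0).any() or (self.sampled_key_idx >= L).any():
            raise ValueError("sampled key indices out of range")
        if not np.isfinite(self.scores).all():
            raise ValueError("sparsity scores must be finite")


def sparsity_scores(Q: np.ndarray, K: np.ndarray, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Max-minus-mean query scores over ceil(ln L) sampled keys.

    Returns (M, sampled_key_idx) where ``M[h]`` = max_j x_hj - mean_j x_hj
    with x the dot products of query h against the sampled keys only.
    Restricting both max and mean to the sampled columns preserves the
    statistic's intent (zero-filling the unsampled columns would let the
    zeros dominate the mean) and recovers the dense score under full
    sampling.
    """
    Q = np.asarray(Q, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    L_K = K.shape[0]
    if Q.shape[0] < 2 or L_K < 2:
        raise ValueError("need at least 2 queries and keys")
    s = min(max(1, math.ceil(math.log(L_K))), L_K)
    idx = np.sort(rng.choice(L_K, size=s, replace=False))
    x = Q @ K[idx].T  # (L_Q, s)
    M = x.max(axis=1) - x.mean(axis=1)
    return M, idx


def make_attention_bundle(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                          C: float, rng: np.random.Generator) -> AttentionBundle:
    """Score queries and select the top-u = ceil(C ln L) of them."""
    L = Q.shape[0]
    M, idx = sparsity_scores(Q, K, rng)
    u = int(np.clip(math.ceil(C * math.log(L)), 1, L))
    order = np.argsort(-M, kind="stable")  # ties -> lower query index first
    selected = np.sort(order[:u])
    return AttentionBundle(Q=Q, K=K, V=V, sampled_key_idx=idx, scores=M,
                           selected_q_idx=selected, C=C)


def probsparse_attention(bundle: AttentionBundle, d_model: int | None = None,
                         scale_sqrt: bool = True) -> np.ndarray:
    """Evaluate ProbSparse attention for one (L, d) head, returning (L, d).

    Selected query rows get softmax(Q_sel K^T / scale) V over *all* keys;
    every other row is the column-wise time-mean of V.
    """
    Q, K, V = bundle.Q, bundle.K, bundle.V
    d = d_model if d_model is not None else Q.shape[1]
    if len(bundle.selected_q_idx) < 1:
        raise ValueError("at least one query must be selected")
    scale = math.sqrt(d) if scale_sqrt else float(d)
    logits = Q[bundle.selected_q_idx] @ K.T / scale
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=1, keepdims=True)
    out = np.tile(V.mean(axis=0, keepdims=True), (Q.shape[0], 1))
    out[bundle.selected_q_idx] = w @ V
    return out


def residual_norm(attn_out: np.ndarray, embedding: np.ndarray,
                  gain: np.ndarray | None = None,
                  bias: np.ndarray | None = None,
                  eps: float = 1e-5) -> np.ndarray:
    """Layer-normalized residual sum: LN(attn_out + embedding).

    Rows are normalized to zero mean / unit variance over the feature axis
    before the affine gain/bias (identity by default).
    """
    attn_out = np.asarray(attn_out, dtype=np.float64)
    embedding = np.asarray(embedding, dtype=np.float64)
    if attn_out.shape != embedding.shape:
        raise ValueError("attention output and embedding shapes must match")
    s = attn_out + embedding
    mu = s.mean(axis=-1, keepdims=True)
    var = s.var(axis=-1, keepdims=True)
    normed = (s - mu) / np.sqrt(var + eps)
    if gain is not None:
        normed = normed * gain
    if bias is not None:
        normed = normed + bias
    return normed


def _split_heads(x: Tensor, h: int) -> Tensor:
    B, L, d = x.shape
    return x.reshape(B, L, h, d // h).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    B, h, L, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, L, h * dh)


class ProbDecoder(_nn.Module):
    """Single-lead reconstruction decoder (see module docstring).

    ``sparse=False`` replaces the ProbSparse self-attention with dense
    attention (the vanilla-decoder ablations); everything else is shared.
    """

    def __init__(self, d_model: int, rng: np.random.Generator, C: float = 5.0,
                 n_heads: int = 1, ffn_hidden: int | None = None,
                 dropout: float = 0.1, sparse: bool = True,
                 attn_scale_sqrt: bool = True, decoder_residual: bool = True,
                 in_channels: int = 1):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.C = C
        self.n_heads = n_heads
        self.sparse = sparse
        self.attn_scale_sqrt = attn_scale_sqrt
        self.decoder_residual = decoder_residual
        self.in_channels = in_channels
        ffn_hidden = ffn_hidden or 4 * d_model
        self.token_embed = _nn.Conv1d(in_channels, d_model, 3, rng)
        self.q_proj = _nn.Linear(d_model, d_model, rng)
        self.k_proj = _nn.Linear(d_model, d_model, rng)
        self.v_proj = _nn.Linear(d_model, d_model, rng)
        self.self_out = _nn.Linear(d_model, d_model, rng)
        self.norm1 = _nn.LayerNorm(d_model)
        self.enc_conv = _nn.Conv1d(d_model, d_model, 3, rng)
        self.q2_proj = _nn.Linear(d_model, d_model, rng)
        self.k2_proj = _nn.Linear(d_model, d_model, rng)
        self.cross_out = _nn.Linear(d_model, d_model, rng)
        self.norm2 = _nn.LayerNorm(d_model)
        self.ffn_in = _nn.Linear(d_model, ffn_hidden, rng)
        self.ffn_out = _nn.Linear(ffn_hidden, d_model, rng)
        self.norm3 = _nn.LayerNorm(d_model)
        self.head = _nn.Linear(d_model, 1, rng)
        self.drop = _nn.Dropout(dropout)

    # -- pieces -------------------------------------------------------------

    def encode_decoder_input(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Token-embed the input lead and project to (Q, K, V).

        ``x`` is (B, L, in_channels); returns (embedding, Q, K, V), each
        (B, L, d).
        """
        if x.shape[-1] != self.in_channels:
            raise ValueError(f"decoder input must have {self.in_channels} "
                             f"channel(s), got {x.shape[-1]}")
        emb = self.token_embed(x)
        return emb, self.q_proj(emb), self.k_proj(emb), self.v_proj(emb)

    def _scale(self, dh: int) -> float:
        return math.sqrt(dh) if self.attn_scale_sqrt else float(dh)

    def _self_attention(self, Q: Tensor, K: Tensor, V: Tensor,
                        rng: np.random.Generator) -> Tensor:
        """(B, L, d) -> (B, L, d) self-attention, sparse or dense."""
        B, L, d = Q.shape
        h = self.n_heads
        dh = d // h
        Qh, Kh, Vh = (_split_heads(t, h) for t in (Q, K, V))
        # fold the softmax scale into Q (cheaper than scaling the L x L matrix)
        Qh = Qh * (1.0 / self._scale(dh))
        if not self.sparse:
            A = (Qh @ Kh.swapaxes(-1, -2)).softmax(axis=-1)
            out = A @ Vh
            return self.self_out(_merge_heads(out))
        # query scoring on detached values
        s = min(max(1, math.ceil(math.log(L))), L)
        key_idx = np.sort(rng.choice(L, size=s, replace=False))
        x = Qh.data @ np.swapaxes(Kh.data[:, :, key_idx, :], -1, -2)  # (B,h,L,s)
        M = x.max(axis=-1) - x.mean(axis=-1)  # (B, h, L)
        u = int(np.clip(math.ceil(self.C * math.log(L)), 1, L))
        order = np.argsort(-M, axis=-1, kind="stable")
        sel = np.sort(order[..., :u], axis=-1)  # (B, h, u)
        bidx = np.arange(B)[:, None, None]
        hidx = np.arange(h)[None, :, None]
        Qbar = Qh[bidx, hidx, sel]  # (B, h, u, dh)
        A = (Qbar @ Kh.swapaxes(-1, -2)).softmax(axis=-1)
        rows = A @ Vh  # (B, h, u, dh)
        base = Vh.mean(axis=2, keepdims=True) * Tensor(np.ones((1, 1, L, 1)))
        out = base.index_fill_rows((bidx, hidx, sel), rows)
        return self.self_out(_merge_heads(out))

    def _cross_body(self, enc_out: Tensor, vhat: Tensor,
                    rng: np.random.Generator, train: bool = False) -> Tensor:
        """Encoder-decoder attention + feed-forward -> (B, L, d)."""
        if enc_out.shape[:2] != vhat.shape[:2]:
            raise ValueError("encoder and decoder streams must share (B, L)")
        h = self.n_heads
        dh = self.d_model // h
        qk_base = self.enc_conv(enc_out)
        Qhat = _split_heads(self.q2_proj(qk_base), h) * (1.0 / self._scale(dh))
        Khat = _split_heads(self.k2_proj(qk_base), h)
        Vh = _split_heads(vhat, h)
        A = (Qhat @ Khat.swapaxes(-1, -2)).softmax(axis=-1)
        cross = self.cross_out(_merge_heads(A @ Vh))
        cross = self.drop(cross, rng, train)
        y = self.norm2(cross + vhat) if self.decoder_residual else cross
        f = self.ffn_out(self.ffn_in(y).gelu())
        f = self.drop(f, rng, train)
        return self.norm3(f + y) if self.decoder_residual else f

    def cross_attention_head(self, enc_out: Tensor, vhat: Tensor,
                             rng: np.random.Generator, train: bool = False) -> Tensor:
        """Encoder-decoder attention + feed-forward + linear head -> (B, L, 1)."""
        return self.head(self._cross_body(enc_out, vhat, rng, train=train))

    # -- full forward -------------------------------------------------------

    def features(self, x_dec: Tensor, enc_out: Tensor,
                 rng: np.random.Generator, train: bool = False) -> Tensor:
        """Decoder body without the output head: -> (B, L, d)."""
        emb, Q, K, V = self.encode_decoder_input(x_dec)
        attn = self._self_attention(Q, K, V, rng)
        attn = self.drop(attn, rng, train)
        vhat = self.norm1(attn + emb)
        return self._cross_body(enc_out, vhat, rng, train=train)

    def __call__(self, x_dec: Tensor, enc_out: Tensor,
                 rng: np.random.Generator, train: bool = False) -> Tensor:
        """Reconstruct the target lead: (B, L, 1), (B, L, d) -> (B, L, 1)."""
        return self.head(self.features(x_dec, enc_out, rng, train=train))
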