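"""Multi-period 2-D temporal encoder ("2D-ECGblock").

An ECG is quasi-periodic: a sinus rhythm, possibly superimposed with an
ectopic rhythm at a second inter-beat period, giving the signal multicycle
structure.  This encoder

1. embeds the 3-lead input into ``d_model`` channels with a width-3
   1-D convolution (a learned mixing of the vectorcardiographic axes),
2. ranks integer frequencies by mean FFT amplitude across channels and
   keeps the top ``m`` (DC excluded, frequencies limited to 1..L/2 by
   conjugate symmetry),
3. folds the sequence into an (period x cycle-count) 2-D tensor per kept
   frequency — columns are within-cycle traces, rows track a fixed phase
   across cycles,
4. mixes each folded tensor with a shared multi-scale (1/3/5) 2-D
   convolution bank (branches summed, GELU),
5. unfolds back to 1-D and fuses the ``m`` branches with softmax weights
   over their spectral amplitudes.

A residual connection to the embedded input plus layer normalization wrap
the block (config flag ``block_residual``); the single-layer configuration
trains poorly without it.

Frequency selection and the fusion weights are computed from the forward
values and treated as constants in the backward pass; gradients flow
through the folded signal path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _nn
from ._autograd import Tensor, stack
from .segment import EcgSegment

__all__ = ["EmbeddedSequence", "PeriodSpectrum", "dominant_periods",
           "fold_to_2d", "unfold_2d", "unfold_fuse", "EcgBlockEncoder"]


@dataclass
class EmbeddedSequence:
    """A length-L, d_model-channel embedded signal."""

    values: np.ndarray  # (L, d_model)
    fs: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if not np.isfinite(self.values).all():
            raise ValueError("embedded values must be finite")


@dataclass
class PeriodSpectrum:
    """Top-m spectral lines of a window: frequencies (cycles/window),
    periods (samples, ceil(L/f)), mean amplitudes, and softmax weights."""

    m: int
    freqs: np.ndarray
    periods: np.ndarray
    amps: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=int)
        self.periods = np.asarray(self.periods, dtype=int)
        self.amps = np.asarray(self.amps, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(set(self.freqs.tolist())) != self.m:
            raise ValueError("frequencies must be distinct")
        if (self.amps < 0).any():
            raise ValueError("amplitudes must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def _softmax(a: np.ndarray) -> np.ndarray:
    e = np.exp(a - a.max())
    return e / e.sum()


def dominant_periods(e, m: int) -> PeriodSpectrum:
    """Top-m frequencies by channel-averaged FFT amplitude.

    ``e`` is an :class:`EmbeddedSequence` or an (L, d) array.  The DC bin is
    excluded (a constant offset has no period) and only bins 1..floor(L/2)
    are considered.  Ties in amplitude break toward the lower frequency.
    """
    values = e.values if isinstance(e, EmbeddedSequence) else np.asarray(e, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    L = values.shape[0]
    if L < 4:
        raise ValueError("need at least 4 samples for period detection")
    n_bins = L // 2
    if not 1 <= m <= n_bins:
        raise ValueError(f"m must lie in [1, {n_bins}] for L={L}")
    amp = np.abs(np.fft.rfft(values, axis=0))  # (L//2+1, d)
    avg = amp.mean(axis=1)
    candidates = np.arange(1, n_bins + 1)
    cand_amp = avg[1:n_bins + 1]
    order = np.lexsort((candidates, -cand_amp))[:m]
    freqs = candidates[order]
    amps = cand_amp[order]
    periods = np.ceil(L / freqs).astype(int)
    return PeriodSpectrum(m=m, freqs=freqs, periods=periods, amps=amps,
                          weights=_softmax(amps))


def fold_to_2d(values: np.ndarray, f: int, p: int) -> np.ndarray:
    """Fold an (L, d) sequence into a (p, f, d) tensor, zero-padded.

    Column j holds contiguous segment j of length p: each column is one
    within-cycle trace, each row a fixed phase across cycles.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    L, d = values.shape
    if f < 1:
        raise ValueError("f must be >= 1")
    expected_p = math.ceil(L / f)
    if p != expected_p:
        raise ValueError(f"p must be ceil(L/f) = {expected_p}, got {p}")
    pad = p * f - L
    padded = np.pad(values, ((0, pad), (0, 0)))
    return padded.reshape(f, p, d).transpose(1, 0, 2)


def unfold_2d(slab: np.ndarray, L: int) -> np.ndarray:
    """Inverse of :func:`fold_to_2d`: (p, f, d) -> (L, d)."""
    slab = np.asarray(slab, dtype=np.float64)
    p, f, d = slab.shape
    if p * f < L:
        raise ValueError("slab too small to unfold to length L")
    return slab.transpose(1, 0, 2).reshape(p * f, d)[:L]


def unfold_fuse(slabs: list[np.ndarray], spec: PeriodSpectrum, L: int) -> np.ndarray:
    """Unfold each slab and combine with softmax-of-amplitude weights."""
    if len(slabs) != spec.m:
        raise ValueError("number of slabs must match the period spectrum")
    out = None
    for slab, f, p, w in zip(slabs, spec.freqs, spec.periods, spec.weights):
        if slab.shape[:2] != (p, f):
            raise ValueError("slab shape does not match its (p, f) entry")
        u = w * unfold_2d(slab, L)
        out = u if out is None else out + u
    return out


def _fold_tensor(x: Tensor, f: int, p: int) -> Tensor:
    """Autodiff version of :func:`fold_to_2d` for an (L, d) tensor."""
    L, d = x.shape
    pad = p * f - L
    if pad:
        x = x.pad_axis(0, 0, pad)
    return x.reshape(f, p, d).transpose(1, 0, 2)


def _unfold_tensor(slab: Tensor, L: int) -> Tensor:
    p, f, d = slab.shape
    return slab.transpose(1, 0, 2).reshape(p * f, d)[:L]


class EcgBlockEncoder(_nn.Module):
    """The multi-period 2-D encoder block (see module docstring)."""

    def __init__(self, d_model: int, m: int, rng: np.random.Generator,
                 kernel_sizes: tuple[int, ...] = (1, 3, 5),
                 block_residual: bool = True, in_leads: int = 3,
                 dropout: float = 0.0):
        self.d_model = d_model
        self.m = m
        self.block_residual = block_residual
        self.embed = _nn.Conv1d(in_leads, d_model, 3, rng)
        self.branches = [_nn.Conv2d(d_model, d_model, k, rng) for k in kernel_sizes]
        self.norm = _nn.LayerNorm(d_model)
        self.drop = _nn.Dropout(dropout)
        self.last_spectra: list[PeriodSpectrum] | None = None

    def embed_channels(self, x: Tensor) -> Tensor:
        """Width-3 multichannel fusion embedding; (B, L, leads) -> (B, L, d)."""
        return self.embed(x)

    def inception_mix(self, slab: Tensor) -> Tensor:
        """Shared multi-scale 2-D convolution, branches summed, then GELU."""
        if slab.ndim == 3:
            slab = slab.reshape(1, *slab.shape)
            squeeze = True
        else:
            squeeze = False
        out = None
        for branch in self.branches:
            y = branch(slab)
            out = y if out is None else out + y
        out = out.gelu()
        if squeeze:
            out = out.reshape(*out.shape[1:])
        return out

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 train: bool = False) -> Tensor:
        """Encode a batch (B, L, in_leads) -> (B, L, d_model)."""
        B, L, _ = x.shape
        e = self.embed_channels(x)
        m = min(self.m, L // 2)
        spectra = []
        fused_rows = []
        for b in range(B):
            eb = e[b]  # (L, d)
            spec = dominant_periods(eb.data, m)
            spectra.append(spec)
            acc = None
            for f, p, w in zip(spec.freqs, spec.periods, spec.weights):
                slab = _fold_tensor(eb, int(f), int(p))
                mixed = self.inception_mix(slab)
                u = _unfold_tensor(mixed, L) * float(w)
                acc = u if acc is None else acc + u
            fused_rows.append(acc)
        fused = stack(fused_rows, axis=0)
        self.last_spectra = spectra
        if rng is not None:
            fused = self.drop(fused, rng, train)
        if self.block_residual:
            return self.norm(fused + e)
        return fused

    # convenience for single segments -------------------------------------

    def forward_segment(self, seg: EcgSegment) -> EmbeddedSequence:
        x = Tensor(seg.samples[None, :, :])
        out = self(x)
        return EmbeddedSequence(out.data[0], fs=seg.fs)
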