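"""Per-lead reconstruction networks, training, and classical baselines.

Twelve independent single-lead networks reconstruct the standard montage:
each network sees the full 3-lead input through its encoder and the one
most-correlated input lead through its decoder.  Three architecture
variants are provided:

- ``m2eformer``     : multi-period 2-D encoder + ProbSparse decoder,
- ``t_transformer`` : multi-period 2-D encoder + dense-attention decoder,
- ``transformer``   : vanilla dense-attention encoder + dense decoder.

Classical baselines: an affine least-squares transform fitted per target
lead on pooled training samples (the LSR baseline), and application of any
externally supplied fixed 12 x (3+1) coefficient matrix (a "universal
transform" in the style of the fixed Dower matrix).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from ._autograd import Tensor, default_dtype
from .leads import LeadMapping
from .periodic2d import EcgBlockEncoder
from .probdecoder import ProbDecoder
from .segment import STANDARD_12_LEADS, EcgSegment, canonical_lead

logger = logging.getLogger(__name__)

__all__ = ["ModelConfig", "LeadModel", "TrainedLeadModel", "TransformMatrix",
           "build_model", "count_parameters", "train_lead_model",
           "reconstruct_12lead", "predict_lead", "fit_lsr", "apply_matrix",
           "split_dataset"]

ABLATIONS = ("m2eformer", "t_transformer", "transformer")


@dataclass
class ModelConfig:
    """Hyperparameters for one per-lead reconstruction network.

    Defaults follow the full-scale protocol (embedding width 512, one
    encoder and one decoder layer, dropout 0.1, Adam at 1e-4 for 100
    epochs, batches of 200); desk-scale runs shrink ``d_model``, ``epochs``
    and ``batch_size``.
    """

    d_model: int = 512
    m: int = 5
    encoder_layers: int = 1
    decoder_layers: int = 1
    C: float = 5.0
    dropout: float = 0.1
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 200
    seed: int = 0
    ablation: str = "m2eformer"
    n_heads: int = 1
    ffn_hidden: int | None = None
    kernel_sizes: tuple[int, ...] = (1, 3, 5)
    block_residual: bool = True
    attn_scale_sqrt: bool = True
    decoder_residual: bool = True
    grad_clip: float | None = 1.0
    dtype: str = "float32"

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        for name in ("d_model", "m", "encoder_layers", "decoder_layers",
                     "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


class VanillaEncoder(_nn.Module):
    """Plain transformer encoder layer: dense self-attention + FFN."""

    def __init__(self, d_model: int, rng: np.random.Generator, n_heads: int = 1,
                 ffn_hidden: int | None = None, dropout: float = 0.1,
                 in_leads: int = 3, attn_scale_sqrt: bool = True):
        self.d_model = d_model
        self.n_heads = n_heads
        self.attn_scale_sqrt = attn_scale_sqrt
        ffn_hidden = ffn_hidden or 4 * d_model
        self.embed = _nn.Conv1d(in_leads, d_model, 3, rng)
        self.q_proj = _nn.Linear(d_model, d_model, rng)
        self.k_proj = _nn.Linear(d_model, d_model, rng)
        self.v_proj = _nn.Linear(d_model, d_model, rng)
        self.attn_out = _nn.Linear(d_model, d_model, rng)
        self.norm1 = _nn.LayerNorm(d_model)
        self.ffn_in = _nn.Linear(d_model, ffn_hidden, rng)
        self.ffn_out = _nn.Linear(ffn_hidden, d_model, rng)
        self.norm2 = _nn.LayerNorm(d_model)
        self.drop = _nn.Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 train: bool = False) -> Tensor:
        from .probdecoder import _merge_heads, _split_heads
        e = self.embed(x)
        h = self.n_heads
        dh = self.d_model // h
        Q, K, V = (_split_heads(p(e), h) for p in (self.q_proj, self.k_proj, self.v_proj))
        scale = math.sqrt(dh) if self.attn_scale_sqrt else float(dh)
        Q = Q * (1.0 / scale)
        A = (Q @ K.swapaxes(-1, -2)).softmax(axis=-1)
        a = self.attn_out(_merge_heads(A @ V))
        if rng is not None:
            a = self.drop(a, rng, train)
        y = self.norm1(a + e)
        f = self.ffn_out(self.ffn_in(y).gelu())
        if rng is not None:
            f = self.drop(f, rng, train)
        return self.norm2(f + y)


class LeadModel(_nn.Module):
    """One target lead's reconstruction network: encoder stack + decoder stack."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.d_model
        self.encoders: list[_nn.Module] = []
        for layer in range(cfg.encoder_layers):
            in_leads = 3 if layer == 0 else d
            if cfg.ablation in ("m2eformer", "t_transformer"):
                self.encoders.append(EcgBlockEncoder(
                    d, cfg.m, rng, kernel_sizes=cfg.kernel_sizes,
                    block_residual=cfg.block_residual, in_leads=in_leads,
                    dropout=cfg.dropout))
            else:
                self.encoders.append(VanillaEncoder(
                    d, rng, n_heads=cfg.n_heads, ffn_hidden=cfg.ffn_hidden,
                    dropout=cfg.dropout, in_leads=in_leads,
                    attn_scale_sqrt=cfg.attn_scale_sqrt))
        sparse = cfg.ablation == "m2eformer"
        self.decoders: list[ProbDecoder] = []
        for layer in range(cfg.decoder_layers):
            self.decoders.append(ProbDecoder(
                d, rng, C=cfg.C, n_heads=cfg.n_heads, ffn_hidden=cfg.ffn_hidden,
                dropout=cfg.dropout, sparse=sparse,
                attn_scale_sqrt=cfg.attn_scale_sqrt,
                decoder_residual=cfg.decoder_residual,
                in_channels=1 if layer == 0 else d))

    def __call__(self, x3: Tensor, x_in: Tensor, rng: np.random.Generator,
                 train: bool = False) -> Tensor:
        """(B, L, 3) encoder input + (B, L, 1) decoder lead -> (B, L, 1)."""
        enc = x3
        for block in self.encoders:
            enc = block(enc, rng, train)
        y = x_in
        for dec in self.decoders[:-1]:
            y = dec.features(y, enc, rng, train=train)
        return self.decoders[-1](y, enc, rng, train=train)


def build_model(cfg: ModelConfig) -> LeadModel:
    """Assemble a per-lead network; parameter init is seeded by ``cfg.seed``."""
    with default_dtype(cfg.dtype):
        return LeadModel(cfg)


def count_parameters(model: _nn.Module) -> int:
    """Number of trainable scalars in the model."""
    return model.n_parameters()


@dataclass
class TrainedLeadModel:
    """A fitted per-lead network plus its training record."""

    target_lead: str
    input_lead: str
    model: LeadModel
    best_epoch: int
    min_val_loss: float
    config: ModelConfig
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)


def _pairs_to_arrays(pairs: list[tuple[EcgSegment, EcgSegment]],
                     target_lead: str, input_lead: str):
    x3 = np.stack([src.samples for src, _ in pairs])
    xin = np.stack([src.lead(input_lead)[:, None] for src, _ in pairs])
    y = np.stack([tgt.lead(target_lead)[:, None] for _, tgt in pairs])
    return x3, xin, y


def _forward_batched(model: LeadModel, x3: np.ndarray, xin: np.ndarray,
                     rng: np.random.Generator, batch: int) -> np.ndarray:
    outs = []
    for lo in range(0, x3.shape[0], batch):
        pred = model(Tensor(x3[lo:lo + batch]), Tensor(xin[lo:lo + batch]),
                     rng, train=False)
        outs.append(pred.data)
    return np.concatenate(outs, axis=0)


def train_lead_model(train: list[tuple[EcgSegment, EcgSegment]],
                     val: list[tuple[EcgSegment, EcgSegment]],
                     target_lead: str, mapping: LeadMapping,
                     cfg: ModelConfig) -> TrainedLeadModel:
    """Fit one per-lead network by minimizing MSE with Adam.

    Validation loss is tracked per epoch and the parameters at its minimum
    are restored into the returned model ("best epoch" selection).  The run
    is fully reproducible from (data, cfg, cfg.seed).
    """
    if not train:
        raise ValueError("empty training set")
    if not val:
        raise ValueError("empty validation set")
    target_lead = canonical_lead(target_lead)
    input_lead = mapping.input_for(target_lead)
    L = train[0][0].n_samples
    for src, tgt in train + val:
        if src.n_samples != L or tgt.n_samples != L:
            raise ValueError("all segments must share the same length")
        if src.fs != train[0][0].fs:
            raise ValueError("all segments must share the same sampling rate")

    x3_tr, xin_tr, y_tr = _pairs_to_arrays(train, target_lead, input_lead)
    x3_va, xin_va, y_va = _pairs_to_arrays(val, target_lead, input_lead)

    model = build_model(cfg)
    opt = _nn.Adam(model.parameters(), lr=cfg.lr, clip_norm=cfg.grad_clip)
    shuffle_rng = np.random.default_rng([cfg.seed, 101])
    train_rng = np.random.default_rng([cfg.seed, 202])

    n = x3_tr.shape[0]
    batch = min(cfg.batch_size, n)
    train_losses, val_losses = [], []
    best_state, best_epoch, best_val = None, 0, math.inf

    with default_dtype(cfg.dtype):
        for epoch in range(1, cfg.epochs + 1):
            order = shuffle_rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, batch):
                idx = order[lo:lo + batch]
                model.zero_grad()
                pred = model(Tensor(x3_tr[idx]), Tensor(xin_tr[idx]),
                             train_rng, train=True)
                err = pred - Tensor(y_tr[idx])
                loss = (err * err).mean()
                lval = float(loss.data)
                if not math.isfinite(lval):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(lead {target_lead}); last finite losses: {train_losses[-3:]}")
                loss.backward()
                opt.step()
                epoch_loss += lval * len(idx)
            train_losses.append(epoch_loss / n)

            eval_rng = np.random.default_rng([cfg.seed, 303])
            pred_va = _forward_batched(model, x3_va, xin_va, eval_rng, batch)
            vloss = float(np.mean((pred_va - y_va) ** 2))
            val_losses.append(vloss)
            if vloss < best_val:
                best_val, best_epoch = vloss, epoch
                best_state = model.state_dict()
            logger.debug("lead %s epoch %d train %.6f val %.6f",
                         target_lead, epoch, train_losses[-1], vloss)

    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainedLeadModel(target_lead=target_lead, input_lead=input_lead,
                            model=model, best_epoch=best_epoch,
                            min_val_loss=best_val, config=cfg,
                            train_losses=train_losses, val_losses=val_losses)


def predict_lead(trained: TrainedLeadModel, segments: list[EcgSegment],
                 batch_size: int | None = None) -> np.ndarray:
    """Reconstruct one lead for a list of 3-lead segments -> (N, L)."""
    cfg = trained.config
    x3 = np.stack([s.samples for s in segments])
    xin = np.stack([s.lead(trained.input_lead)[:, None] for s in segments])
    rng = np.random.default_rng([cfg.seed, 303])
    with default_dtype(cfg.dtype):
        out = _forward_batched(trained.model, x3, xin, rng,
                               batch_size or min(cfg.batch_size, len(segments)))
    return out[:, :, 0].astype(np.float64)


def reconstruct_12lead(models: dict[str, TrainedLeadModel],
                       x: EcgSegment) -> EcgSegment:
    """Run all 12 per-lead networks on one 3-lead segment."""
    missing = [t for t in STANDARD_12_LEADS if t not in models]
    if missing:
        raise ValueError(f"missing trained models for leads: {missing}")
    cols = [predict_lead(models[t], [x])[0] for t in STANDARD_12_LEADS]
    return EcgSegment(np.column_stack(cols), fs=x.fs,
                      lead_names=STANDARD_12_LEADS,
                      subject_id=x.subject_id, t0=x.t0)


# -- classical baselines ----------------------------------------------------


@dataclass
class TransformMatrix:
    """Affine map from 3 input leads (+ intercept) to the 12 standard leads."""

    coefficients: np.ndarray  # (12, 4): three weights + intercept per lead
    input_leads: tuple[str, ...]
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != (12, 4):
            raise ValueError("coefficients must be a 12 x 4 matrix")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("coefficients must be finite")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.coefficients,
                          columns=[*self.input_leads, "intercept"])
        df.insert(0, "lead", STANDARD_12_LEADS)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fit_meta: dict | None = None) -> "TransformMatrix":
        df = pd.read_csv(path)
        leads = [canonical_lead(x) for x in df.pop("lead")]
        if tuple(leads) != STANDARD_12_LEADS:
            df = df.set_index(pd.Index(leads)).loc[list(STANDARD_12_LEADS)]
        input_leads = tuple(canonical_lead(c) for c in df.columns[:-1])
        return cls(df.to_numpy(), input_leads=input_leads,
                   fit_meta=fit_meta or {"method": "external"})


def fit_lsr(train: list[tuple[EcgSegment, EcgSegment]]) -> TransformMatrix:
    """Ordinary least squares of each target lead on the 3 inputs + intercept.

    Samples are pooled over all training segments.  A rank-deficient design
    is flagged in ``fit_meta`` and the minimum-norm solution returned.
    """
    if not train:
        raise ValueError("empty training set")
    xs = np.concatenate([src.samples for src, _ in train], axis=0)
    ys = np.concatenate([tgt.select(STANDARD_12_LEADS).samples
                         for _, tgt in train], axis=0)
    if xs.shape[0] < 4:
        raise ValueError("need at least 4 pooled samples")
    design = np.column_stack([xs, np.ones(xs.shape[0])])
    coef, _, rank, _ = np.linalg.lstsq(design, ys, rcond=None)
    meta = {"method": "lsr", "n_samples": int(xs.shape[0]),
            "rank_deficient": bool(rank < 4)}
    if rank < 4:
        logger.warning("LSR design is rank deficient (rank %d); "
                       "minimum-norm solution returned", rank)
    return TransformMatrix(coef.T, input_leads=train[0][0].lead_names,
                           fit_meta=meta)


def apply_matrix(tm: TransformMatrix, x: EcgSegment) -> EcgSegment:
    """Apply the affine transform per sample -> 12-lead segment."""
    if x.n_leads != 3:
        raise ValueError("transform input must have 3 leads")
    out = x.samples @ tm.coefficients[:, :3].T + tm.coefficients[:, 3]
    return EcgSegment(out, fs=x.fs, lead_names=STANDARD_12_LEADS,
                      subject_id=x.subject_id, t0=x.t0)


# -- dataset splitting ------------------------------------------------------


def split_dataset(records, ratios=(3, 1, 1), seed: int = 0, label_of=None):
    """Split records into train/val/test at the *subject* level.

    ``records`` is any sequence of objects with a ``subject_id`` attribute;
    ``label_of`` optionally maps a record to a diagnostic-class label, in
    which case the allocation is stratified per class (largest-remainder
    rounding).  Subjects never straddle partitions.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    if (ratios <= 0).any():
        raise ValueError("ratios must be positive")
    props = ratios / ratios.sum()
    k = len(props)

    by_subject: dict[str, list] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    subjects = sorted(by_subject)
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects to form {k} partitions")

    def subject_label(sid):
        if label_of is None:
            return ""
        labels = {label_of(r) for r in by_subject[sid]}
        if len(labels) != 1:
            raise ValueError(f"subject {sid} carries multiple class labels")
        return labels.pop()

    classes: dict[str, list[str]] = {}
    for sid in subjects:
        classes.setdefault(subject_label(sid), []).append(sid)

    rng = np.random.default_rng(seed)
    parts: list[list] = [[] for _ in range(k)]
    for label in sorted(classes):
        sids = classes[label]
        rng.shuffle(sids)
        n = len(sids)
        exact = props * n
        counts = np.floor(exact).astype(int)
        remainder = exact - counts
        for j in np.argsort(-remainder, kind="stable")[:n - counts.sum()]:
            counts[j] += 1
        start = 0
        for j, c in enumerate(counts):
            for sid in sids[start:start + c]:
                parts[j].extend(by_subject[sid])
            start += c
    return tuple(parts)
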