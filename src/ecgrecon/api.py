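"""High-level modelling interface: model objects fitted to data, returning
results objects that carry estimates, training diagnostics and summaries.

Two model families:

- :class:`LSRBaseline` — the classical affine least-squares transform from
  the 3 input leads to the 12 standard leads (pooled training samples).
- :class:`M2EformerECG` — the attention-based per-lead networks (one
  network per target lead; multi-period 2-D encoder + ProbSparse decoder,
  with the ``t_transformer`` and ``transformer`` ablations selectable
  through the config).

Both ``fit()`` methods return results objects with ``predict``,
``evaluate`` and ``summary``; plotting helpers import matplotlib lazily.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .leads import LeadMapping, select_input_leads
from .metrics import EvalReport, evaluate, mae, pearson_r
from .models import (ModelConfig, TrainedLeadModel, TransformMatrix,
                     apply_matrix, fit_lsr, predict_lead, reconstruct_12lead,
                     train_lead_model)
from .segment import STANDARD_12_LEADS, EcgSegment, canonical_lead

__all__ = ["LSRBaseline", "LSRResults", "M2EformerECG", "M2EformerResults"]

Pairs = list[tuple[EcgSegment, EcgSegment]]


class LSRBaseline:
    """Affine least-squares reconstruction model.

    Parameters
    ----------
    train : list of (3-lead input, 12-lead target) segment pairs.
    """

    def __init__(self, train: Pairs):
        if not train:
            raise ValueError("LSRBaseline needs training pairs")
        self.train_pairs = train

    def fit(self) -> "LSRResults":
        return LSRResults(fit_lsr(self.train_pairs), self.train_pairs)


class LSRResults:
    """Fitted affine transform and its evaluation helpers."""

    def __init__(self, transform: TransformMatrix, train_pairs: Pairs):
        self.transform = transform
        self.n_train_segments = len(train_pairs)

    @property
    def params(self) -> pd.DataFrame:
        return pd.DataFrame(self.transform.coefficients,
                            index=STANDARD_12_LEADS,
                            columns=[*self.transform.input_leads, "intercept"])

    def predict(self, x: EcgSegment) -> EcgSegment:
        return apply_matrix(self.transform, x)

    def evaluate(self, pairs: Pairs, tag: str = "test") -> EvalReport:
        preds = [self.predict(src) for src, _ in pairs]
        truths = [tgt.select(STANDARD_12_LEADS) for _, tgt in pairs]
        return evaluate(preds, truths,
                        provenance={"model": "lsr", "dataset": tag})

    def summary(self) -> str:
        lines = ["Least-squares affine lead transform",
                 f"  fitted on {self.n_train_segments} segments "
                 f"({self.transform.fit_meta.get('n_samples', '?')} pooled samples)",
                 "", self.params.round(4).to_string()]
        return "\n".join(lines)


class M2EformerECG:
    """Per-lead attention reconstruction model.

    Parameters
    ----------
    train, val : lists of (3-lead input, 12-lead target) segment pairs;
        validation drives best-epoch selection.
    config : ModelConfig, optional
        Architecture/training settings (ablation tag selects the variant).
    mapping : LeadMapping, optional
        Decoder input-lead assignment; computed from the training set by
        maximum correlation magnitude when omitted.
    """

    def __init__(self, train: Pairs, val: Pairs,
                 config: ModelConfig | None = None,
                 mapping: LeadMapping | None = None):
        self.train_pairs = train
        self.val_pairs = val
        self.config = config or ModelConfig()
        self.mapping = mapping or select_input_leads(train)

    def fit(self, leads=STANDARD_12_LEADS, progress: bool = False
            ) -> "M2EformerResults":
        """Train one network per requested target lead."""
        fitted: dict[str, TrainedLeadModel] = {}
        for lead in leads:
            lead = canonical_lead(lead)
            if progress:
                print(f"training lead {lead} ...", flush=True)
            fitted[lead] = train_lead_model(self.train_pairs, self.val_pairs,
                                            lead, self.mapping, self.config)
        return M2EformerResults(fitted, self.config, self.mapping)


class M2EformerResults:
    """Fitted per-lead networks plus training diagnostics."""

    def __init__(self, lead_models: dict[str, TrainedLeadModel],
                 config: ModelConfig, mapping: LeadMapping):
        self.lead_models = lead_models
        self.config = config
        self.mapping = mapping

    @property
    def leads(self) -> tuple[str, ...]:
        return tuple(self.lead_models)

    def predict(self, x: EcgSegment, leads=None) -> dict[str, np.ndarray]:
        """Reconstruct the requested leads for one 3-lead segment."""
        leads = leads or self.leads
        return {l: predict_lead(self.lead_models[canonical_lead(l)], [x])[0]
                for l in leads}

    def reconstruct(self, x: EcgSegment) -> EcgSegment:
        """Full 12-lead reconstruction (requires all 12 fitted models)."""
        return reconstruct_12lead(self.lead_models, x)

    def evaluate(self, pairs: Pairs, tag: str = "test"):
        """Score the fitted leads on held-out pairs.

        Returns a full :class:`EvalReport` when all 12 leads are fitted,
        otherwise a per-lead DataFrame of mean Pr / mean MAE.
        """
        if set(self.leads) >= set(STANDARD_12_LEADS):
            preds = [self.reconstruct(src) for src, _ in pairs]
            truths = [tgt.select(STANDARD_12_LEADS) for _, tgt in pairs]
            return evaluate(preds, truths, provenance={
                "model": self.config.ablation, "dataset": tag})
        rows = {}
        for lead in self.leads:
            tm = self.lead_models[lead]
            preds = predict_lead(tm, [src for src, _ in pairs])
            prs, maes = [], []
            for k, (_, tgt) in enumerate(pairs):
                truth = tgt.lead(lead)
                maes.append(mae(preds[k], truth))
                if preds[k].std() > 0 and truth.std() > 0:
                    prs.append(pearson_r(preds[k], truth))
            rows[lead] = {"mean_pr": float(np.mean(prs)),
                          "mean_mae": float(np.mean(maes)),
                          "n_segments": len(pairs)}
        return pd.DataFrame.from_dict(rows, orient="index")

    def training_table(self) -> pd.DataFrame:
        """Best epoch and minimum validation loss per lead."""
        rows = {l: {"input_lead": tm.input_lead,
                    "best_epoch": tm.best_epoch,
                    "min_val_loss": tm.min_val_loss}
                for l, tm in self.lead_models.items()}
        return pd.DataFrame.from_dict(rows, orient="index")

    def summary(self) -> str:
        cfg = self.config
        lines = [f"Per-lead reconstruction networks ({cfg.ablation})",
                 f"  d_model={cfg.d_model} m={cfg.m} C={cfg.C} "
                 f"layers={cfg.encoder_layers}+{cfg.decoder_layers} "
                 f"epochs={cfg.epochs} lr={cfg.lr:g} seed={cfg.seed}",
                 "", self.training_table().to_string()]
        return "\n".join(lines)

    # -- plotting (lazy matplotlib) ------------------------------------

    def plot_training(self, ax=None):
        """Validation-loss curves per lead."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for lead, tm in self.lead_models.items():
            ax.plot(np.arange(1, len(tm.val_losses) + 1), tm.val_losses,
                    label=lead)
        ax.set_xlabel("epoch")
        ax.set_ylabel("validation MSE (mV$^2$)")
        ax.legend(ncol=3, fontsize="small")
        return ax

    def plot_reconstruction(self, x: EcgSegment, truth: EcgSegment | None = None,
                            leads=None, axes=None):
        """Overlay reconstructed (and optionally recorded) traces."""
        import matplotlib.pyplot as plt
        leads = list(leads or self.leads)
        if axes is None:
            _, axes = plt.subplots(len(leads), 1, sharex=True,
                                   figsize=(8, 1.2 * len(leads)))
            axes = np.atleast_1d(axes)
        t = np.arange(x.n_samples) / x.fs
        preds = self.predict(x, leads)
        for ax, lead in zip(axes, leads):
            ax.plot(t, preds[lead], "r", lw=0.8, label="reconstructed")
            if truth is not None:
                ax.plot(t, truth.lead(lead), "k", lw=0.8, label="recorded")
            ax.set_ylabel(lead)
        axes[0].legend(fontsize="small")
        axes[-1].set_xlabel("time (s)")
        return axes
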