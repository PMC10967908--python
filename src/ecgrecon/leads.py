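"""Lead algebra: EASI derivation and correlation-driven input-lead selection.

The EASI system records four electrode potentials (E, A, S, I) and forms
three bipolar leads from them.  For reconstruction, each of the 12 standard
leads is paired with the one input lead (Frank VX/VY/VZ or EASI VES/VAS/VAI)
whose mean training-set Pearson correlation has the largest magnitude; the
signed correlation is kept as evidence.  Magnitude, not signed value, is the
criterion because several standard leads (aVR, V1-V4) view the cardiac
vector from the opposite side and correlate strongly *negatively* with
their best input lead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .segment import EASI_LEADS, STANDARD_12_LEADS, EcgSegment, canonical_lead

logger = logging.getLogger(__name__)

__all__ = ["LeadMapping", "easi_from_electrodes", "select_input_leads",
           "default_lead_mapping"]


@dataclass(frozen=True)
class LeadMapping:
    """Assignment of one input lead to each of the 12 standard leads.

    ``pairs`` maps target lead -> input lead; ``evidence`` maps
    (target, input) -> signed mean Pearson r over training segments.
    """

    pairs: dict[str, str]
    evidence: dict[tuple[str, str], float]

    def __post_init__(self):
        missing = [t for t in STANDARD_12_LEADS if t not in self.pairs]
        if missing:
            raise ValueError(f"mapping lacks target leads: {missing}")
        for r in self.evidence.values():
            if not -1.0 - 1e-9 <= r <= 1.0 + 1e-9:
                raise ValueError("correlation evidence outside [-1, 1]")

    def input_for(self, target: str) -> str:
        return self.pairs[canonical_lead(target)]


def easi_from_electrodes(e, a, s, i, fs: float, subject_id: str = "",
                         t0: float = 0.0) -> EcgSegment:
    """Form the three EASI leads from the four electrode potentials (mV).

    VES = E - S, VAS = A - S, VAI = A - I, elementwise.
    """
    arrays = [np.asarray(x, dtype=np.float64) for x in (e, a, s, i)]
    n = arrays[0].shape
    if any(x.shape != n for x in arrays):
        raise ValueError("electrode series must all have the same length")
    if any(x.ndim != 1 for x in arrays):
        raise ValueError("electrode series must be 1-D")
    if any(not np.isfinite(x).all() for x in arrays):
        raise ValueError("electrode potentials must be finite")
    e_, a_, s_, i_ = arrays
    samples = np.column_stack([e_ - s_, a_ - s_, a_ - i_])
    return EcgSegment(samples, fs=fs, lead_names=EASI_LEADS,
                      subject_id=subject_id, t0=t0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    return float((xc * yc).sum() / denom)


def select_input_leads(train: list[tuple[EcgSegment, EcgSegment]],
                       pooled: bool = False) -> LeadMapping:
    """Choose the decoder input lead per target lead from training pairs.

    Parameters
    ----------
    train : list of (input_segment, target_segment)
        Time-aligned 3-lead inputs and 12-lead targets.
    pooled : bool
        If True, compute one correlation over all samples pooled across
        segments; default is the mean of per-segment correlations.

    The input lead maximizing \\|mean r\\| wins; ties break by input lead
    order (first listed wins) for determinism.  Segments where either lead
    has zero variance are skipped with a warning.
    """
    if not train:
        raise ValueError("select_input_leads needs at least one training pair")
    src0, tgt0 = train[0]
    input_names = src0.lead_names
    target_names = [n for n in STANDARD_12_LEADS if n in tgt0.lead_names]
    if len(target_names) != 12:
        raise ValueError("target segments must carry all 12 standard leads")
    for src, tgt in train:
        if src.n_samples != tgt.n_samples or src.fs != tgt.fs:
            raise ValueError("input/target segments must be time-aligned")

    pairs: dict[str, str] = {}
    evidence: dict[tuple[str, str], float] = {}
    for target in target_names:
        mean_r: dict[str, float] = {}
        for inp in input_names:
            rs = []
            if pooled:
                xs, ys = [], []
                for src, tgt in train:
                    x, y = src.lead(inp), tgt.lead(target)
                    if x.std() == 0 or y.std() == 0:
                        logger.warning("zero-variance lead in segment; skipped "
                                       "(%s vs %s)", inp, target)
                        continue
                    xs.append(x)
                    ys.append(y)
                if xs:
                    rs = [_pearson(np.concatenate(xs), np.concatenate(ys))]
            else:
                for src, tgt in train:
                    x, y = src.lead(inp), tgt.lead(target)
                    if x.std() == 0 or y.std() == 0:
                        logger.warning("zero-variance lead in segment; skipped "
                                       "(%s vs %s)", inp, target)
                        continue
                    rs.append(_pearson(x, y))
            if not rs:
                continue
            mean_r[inp] = float(np.mean(rs))
        if not mean_r:
            raise ValueError(f"no usable training segment for target {target}")
        best = max(mean_r, key=lambda k: (abs(mean_r[k]), -input_names.index(k)))
        pairs[target] = best
        for inp, r in mean_r.items():
            evidence[(target, inp)] = r
    return LeadMapping(pairs=pairs, evidence=evidence)


def default_lead_mapping() -> LeadMapping:
    """The packaged Frank-XYZ default assignment (versioned config file)."""
    text = resources.files("ecgrecon").joinpath(
        "data/default_lead_mapping.yaml").read_text()
    cfg = yaml.safe_load(text)
    pairs = {canonical_lead(k): canonical_lead(v) for k, v in cfg["pairs"].items()}
    return LeadMapping(pairs=pairs, evidence={})
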