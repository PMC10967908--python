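"""Reconstruction quality metrics and report tables.

Two per-segment, per-lead metrics: the Pearson product-moment correlation
(Pr) between reconstructed and recorded lead, and the mean absolute error
(MAE, mV).  Reports aggregate per lead (mean, median, quartiles over
segments) and the "Total" column is the unweighted mean of the 12 per-lead
means.  Segments where either trace has zero variance have no defined
correlation; they are excluded from Pr (counted in the report) but kept for
MAE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import STANDARD_12_LEADS, EcgSegment

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "pearson_r", "mae", "evaluate", "best_segment",
           "paired_difference_test"]


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D series")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float((xc * yc).sum() / denom)


def mae(x, y) -> float:
    """Mean absolute difference (mV for ECG traces)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    return float(np.abs(x - y).mean())


@dataclass
class EvalReport:
    """Per-lead and total Pr/MAE summary over a set of test segments."""

    per_lead: pd.DataFrame          # index = lead, columns = summary stats
    total_pr: float
    total_mae: float
    n_segments: int
    pr_values: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    mae_values: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Report table: leads I..V6 as rows plus a Total row."""
        df = self.per_lead.copy()
        total = pd.DataFrame({"mean_pr": [self.total_pr],
                              "mean_mae": [self.total_mae]}, index=["Total"])
        return pd.concat([df, total])

    def to_csv(self, path) -> None:
        self.table().to_csv(path, index_label="lead",
                            float_format="%.6f")

    def to_markdown(self, path=None) -> str:
        df = self.table()
        cols = list(df.columns)
        lines = ["| lead | " + " | ".join(cols) + " |",
                 "|" + "---|" * (len(cols) + 1)]
        for lead, row in df.iterrows():
            cells = " | ".join("" if pd.isna(v) else f"{v:.4f}" for v in row)
            lines.append(f"| {lead} | {cells} |")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate(pred: list[EcgSegment], truth: list[EcgSegment],
             provenance: dict | None = None) -> EvalReport:
    """Score reconstructed against recorded 12-lead segments."""
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lists must align")
    if not pred:
        raise ValueError("no segments to evaluate")
    rows = {}
    pr_values: dict[str, np.ndarray] = {}
    mae_values: dict[str, np.ndarray] = {}
    for lead in STANDARD_12_LEADS:
        prs, maes, dropped = [], [], 0
        for p, t in zip(pred, truth):
            xp, xt = p.lead(lead), t.lead(lead)
            maes.append(mae(xp, xt))
            if xp.std() == 0 or xt.std() == 0:
                dropped += 1
                logger.warning("zero-variance %s segment excluded from Pr", lead)
                continue
            prs.append(pearson_r(xp, xt))
        if not prs:
            raise ValueError(f"no segment with defined correlation for {lead}")
        prs_arr = np.asarray(prs)
        maes_arr = np.asarray(maes)
        pr_values[lead] = prs_arr
        mae_values[lead] = maes_arr
        rows[lead] = {
            "mean_pr": prs_arr.mean(),
            "median_pr": np.median(prs_arr),
            "q1_pr": np.percentile(prs_arr, 25),
            "q3_pr": np.percentile(prs_arr, 75),
            "mean_mae": maes_arr.mean(),
            "median_mae": np.median(maes_arr),
            "q1_mae": np.percentile(maes_arr, 25),
            "q3_mae": np.percentile(maes_arr, 75),
            "n_segments": len(maes),
            "n_excluded_pr": dropped,
        }
    per_lead = pd.DataFrame.from_dict(rows, orient="index").loc[list(STANDARD_12_LEADS)]
    return EvalReport(per_lead=per_lead,
                      total_pr=float(per_lead["mean_pr"].mean()),
                      total_mae=float(per_lead["mean_mae"].mean()),
                      n_segments=len(pred),
                      pr_values=pr_values, mae_values=mae_values,
                      provenance=provenance or {})


def best_segment(record_pred: EcgSegment, record_truth: EcgSegment,
                 window_s: float = 10.0, stride_s: float = 1.0
                 ) -> tuple[float, float]:
    """Find the window with the highest 12-lead-mean correlation.

    Slides a ``window_s`` window at ``stride_s`` steps over the aligned
    records and returns (t0_seconds, mean_pr) of the best window; ties
    break toward the earliest window.
    """
    if record_pred.n_samples != record_truth.n_samples:
        raise ValueError("records must be aligned")
    fs = record_pred.fs
    win = int(round(window_s * fs))
    if record_pred.n_samples < win:
        raise ValueError("record shorter than the search window")
    stride = max(1, int(round(stride_s * fs)))
    best_t0, best_pr = 0.0, -np.inf
    leads = [l for l in STANDARD_12_LEADS if l in record_pred.lead_names]
    for start in range(0, record_pred.n_samples - win + 1, stride):
        prs = []
        for lead in leads:
            xp = record_pred.lead(lead)[start:start + win]
            xt = record_truth.lead(lead)[start:start + win]
            if xp.std() == 0 or xt.std() == 0:
                continue
            prs.append(pearson_r(xp, xt))
        if not prs:
            continue
        mean_pr = float(np.mean(prs))
        if mean_pr > best_pr:
            best_pr, best_t0 = mean_pr, start / fs
    return best_t0, best_pr


def paired_difference_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Plain paired t-test on per-segment metric values: (statistic, p)."""
    from scipy import stats
    res = stats.ttest_rel(np.asarray(a), np.asarray(b))
    return float(res.statistic), float(res.pvalue)
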