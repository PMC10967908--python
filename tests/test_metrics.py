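"""Pr/MAE metrics, report aggregation, best-segment search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgrecon as er
from ecgrecon.metrics import best_segment, evaluate, mae, pearson_r
from ecgrecon.segment import STANDARD_12_LEADS

series = st.lists(st.floats(min_value=-10, max_value=10, allow_nan=False),
                  min_size=4, max_size=40)


def hand_pearson(x, y):
    """Independent direct evaluation of the product-moment formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den


def test_pearson_basic_cases(rng):
    x = rng.standard_normal(50)
    assert pearson_r(x, x) == pytest.approx(1.0)
    assert pearson_r(x, -2 * x + 7) == pytest.approx(-1.0)
    assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)


def test_pearson_matches_hand_oracle(rng):
    for _ in range(20):
        x = rng.standard_normal(17)
        y = rng.standard_normal(17)
        assert pearson_r(x, y) == pytest.approx(hand_pearson(list(x), list(y)),
                                                abs=1e-12)


def test_pearson_zero_variance_errors():
    with pytest.raises(ValueError):
        pearson_r(np.ones(5), np.arange(5.0))


@settings(deadline=None, max_examples=100)
@given(series, st.floats(min_value=0.1, max_value=5),
       st.floats(min_value=-3, max_value=3))
def test_pearson_affine_invariance_and_sign(xs, a, b):
    x = np.asarray(xs)
    y = np.sin(np.arange(len(x)))  # fixed non-constant partner
    if x.std() == 0 or y.std() == 0:
        return
    r = pearson_r(x, y)
    assert pearson_r(a * x + b, y) == pytest.approx(r, abs=1e-8)
    assert pearson_r(-x, y) == pytest.approx(-r, abs=1e-8)


def test_mae_basic_cases(rng):
    x = rng.standard_normal(30)
    assert mae(x, x) == 0.0
    assert mae(x, x + 0.3) == pytest.approx(0.3)
    y = rng.standard_normal(30)
    assert mae(x, y) == pytest.approx(sum(abs(a - b) for a, b in zip(x, y)) / 30)


@settings(deadline=None, max_examples=60)
@given(series, series, series)
def test_mae_metric_axioms(xs, ys, zs):
    n = min(len(xs), len(ys), len(zs))
    x, y, z = np.asarray(xs[:n]), np.asarray(ys[:n]), np.asarray(zs[:n])
    assert mae(x, y) == pytest.approx(mae(y, x))
    assert mae(x, y) >= 0
    assert mae(x, z) <= mae(x, y) + mae(y, z) + 1e-12


def _segments(samples_list):
    return [er.EcgSegment(s, fs=250, lead_names=STANDARD_12_LEADS)
            for s in samples_list]


def test_evaluate_perfect_and_negated(rng):
    truth = _segments([rng.standard_normal((100, 12)) for _ in range(3)])
    report = evaluate(truth, truth)
    assert np.allclose(report.per_lead["mean_pr"], 1.0)
    assert np.allclose(report.per_lead["mean_mae"], 0.0)
    assert report.total_pr == pytest.approx(1.0)
    assert report.total_mae == pytest.approx(0.0)

    flipped = [t.with_samples(np.column_stack([-t.samples[:, 0],
                                               t.samples[:, 1:]]))
               for t in truth]
    rep2 = evaluate(flipped, truth)
    assert rep2.per_lead.loc["I", "mean_pr"] == pytest.approx(-1.0)
    assert np.allclose(rep2.per_lead["mean_pr"].iloc[1:], 1.0)


def test_evaluate_matches_hand_aggregation(rng):
    preds = _segments([rng.standard_normal((60, 12)) for _ in range(3)])
    truths = _segments([rng.standard_normal((60, 12)) for _ in range(3)])
    report = evaluate(preds, truths)
    # spreadsheet-style independent aggregation for two spot-checked leads
    for lead_idx, lead in [(0, "I"), (7, "V2")]:
        prs = [hand_pearson(list(p.samples[:, lead_idx]),
                            list(t.samples[:, lead_idx]))
               for p, t in zip(preds, truths)]
        maes = [np.abs(p.samples[:, lead_idx] - t.samples[:, lead_idx]).mean()
                for p, t in zip(preds, truths)]
        assert report.per_lead.loc[lead, "mean_pr"] == pytest.approx(np.mean(prs))
        assert report.per_lead.loc[lead, "median_mae"] == pytest.approx(np.median(maes))
    assert report.total_pr == pytest.approx(report.per_lead["mean_pr"].mean(),
                                            abs=1e-12)


def test_evaluate_total_equals_recomputation_from_values(rng):
    preds = _segments([rng.standard_normal((50, 12)) for _ in range(4)])
    truths = _segments([rng.standard_normal((50, 12)) for _ in range(4)])
    report = evaluate(preds, truths)
    recomputed = np.mean([report.pr_values[l].mean() for l in STANDARD_12_LEADS])
    assert report.total_pr == pytest.approx(recomputed, abs=1e-12)


def test_report_table_and_writers(tmp_path, rng):
    truth = _segments([rng.standard_normal((50, 12))])
    report = evaluate(truth, truth)
    table = report.table()
    assert list(table.index) == list(STANDARD_12_LEADS) + ["Total"]
    report.to_csv(tmp_path / "r.csv")
    md = report.to_markdown(tmp_path / "r.md")
    assert (tmp_path / "r.csv").exists()
    assert "| Total |" in md


def test_best_segment_finds_matching_window(rng):
    fs = 100
    n = 30 * fs
    truth_arr = rng.standard_normal((n, 12))
    pred_arr = rng.standard_normal((n, 12))
    pred_arr[10 * fs:20 * fs] = truth_arr[10 * fs:20 * fs]  # exact on [10, 20)
    truth = er.EcgSegment(truth_arr, fs=fs, lead_names=STANDARD_12_LEADS)
    pred = er.EcgSegment(pred_arr, fs=fs, lead_names=STANDARD_12_LEADS)
    t0, pr = best_segment(pred, truth)
    assert t0 == pytest.approx(10.0)
    assert pr == pytest.approx(1.0)


def test_best_segment_tie_breaks_to_first_window():
    fs = 50
    x = np.tile(np.sin(np.arange(20 * fs) / 7.0)[:, None], (1, 12))
    seg = er.EcgSegment(x, fs=fs, lead_names=STANDARD_12_LEADS)
    t0, pr = best_segment(seg, seg)
    assert t0 == 0.0
    assert pr == pytest.approx(1.0)


def test_best_segment_matches_exhaustive_oracle(rng):
    fs = 40
    n = 18 * fs
    truth = er.EcgSegment(rng.standard_normal((n, 12)), fs=fs,
                          lead_names=STANDARD_12_LEADS)
    noise = rng.standard_normal((n, 12))
    pred = truth.with_samples(truth.samples + noise * np.linspace(2, 0, n)[:, None])
    t0, pr = best_segment(pred, truth, window_s=10, stride_s=1)
    # exhaustive all-offsets oracle at the same stride
    best = (-np.inf, None)
    for start in range(0, n - 10 * fs + 1, fs):
        prs = [pearson_r(pred.samples[start:start + 10 * fs, c],
                         truth.samples[start:start + 10 * fs, c])
               for c in range(12)]
        m = np.mean(prs)
        if m > best[0]:
            best = (m, start / fs)
    assert pr == pytest.approx(best[0])
    assert t0 == best[1]
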