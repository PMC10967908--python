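"""Conditioning chain contracts: notch, detrend, smoothing, windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgrecon as er
from ecgrecon.preprocess import (PreprocessConfig, notch_filter,
                                 remove_baseline_poly, smooth_local_regression,
                                 window_segments)
from ecgrecon.segment import FRANK_LEADS

FS = 1000.0
CFG = PreprocessConfig()


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


def test_notch_zero_input():
    assert np.all(notch_filter(np.zeros(8000), FS, CFG) == 0)


def test_notch_attenuates_50hz_and_passes_5hz():
    t = np.arange(8000) / FS
    mid = slice(1000, 7000)  # central 6 s
    hum = np.sin(2 * np.pi * 50 * t)
    out = notch_filter(hum, FS, CFG)
    assert _rms(out[mid]) <= 0.1 * _rms(hum[mid])  # >= 20 dB
    low = np.sin(2 * np.pi * 5 * t)
    out5 = notch_filter(low, FS, CFG)
    assert abs(_rms(out5[mid]) - _rms(low[mid])) <= 0.05 * _rms(low[mid])


def test_notch_rejects_bad_frequency():
    with pytest.raises(ValueError):
        notch_filter(np.zeros(100), 80.0, CFG)  # 50 Hz >= Nyquist 40 Hz


def test_detrend_annihilates_cubic_drift():
    t = np.linspace(0, 8, 8000)
    out = remove_baseline_poly(0.2 * t ** 3, CFG)
    assert np.abs(out).max() <= 1e-8


def test_detrend_constant_and_mean():
    out = remove_baseline_poly(np.full(2000, 3.7), CFG)
    assert np.abs(out).max() <= 1e-9
    rng = np.random.default_rng(0)
    x = rng.standard_normal(2000)
    resid = remove_baseline_poly(x, CFG)
    assert abs(resid.mean()) <= 1e-9 * np.abs(x).max()


def test_detrend_preserves_10hz_sine():
    """Residual error on drift+sine equals the sine's projection onto the
    polynomial basis (computed by an independent least-squares oracle)."""
    t = np.linspace(0, 8, 8000)
    sine = np.sin(2 * np.pi * 10 * t)
    drift = 0.5 * t ** 3 - t ** 2
    out = remove_baseline_poly(drift + sine, CFG)
    rel = np.linalg.norm(out - sine) / np.linalg.norm(sine)
    # oracle: project the sine onto the degree-20 basis directly
    u = np.linspace(-1, 1, t.size)
    basis = np.polynomial.chebyshev.chebvander(u, CFG.poly_order)
    coef, *_ = np.linalg.lstsq(basis, sine, rcond=None)
    leak = np.linalg.norm(basis @ coef) / np.linalg.norm(sine)
    assert rel == pytest.approx(leak, abs=1e-6)
    assert rel <= 0.10  # small leakage: the sine survives detrending


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(min_value=-2, max_value=2), min_size=1, max_size=21))
def test_detrend_annihilates_any_low_degree_polynomial(coeffs):
    t = np.linspace(-1, 1, 600)
    x = np.polynomial.polynomial.polyval(t, coeffs)
    out = remove_baseline_poly(x, CFG)
    assert np.abs(out).max() <= 1e-7 * max(1.0, np.abs(x).max())


def test_smoothing_preserves_constant_and_line():
    assert np.allclose(smooth_local_regression(np.full(50, 2.2), CFG), 2.2)
    t = np.arange(200, dtype=float)
    line = 0.3 * t - 4.0
    assert np.abs(smooth_local_regression(line, CFG) - line).max() < 1e-10


def test_smoothing_reduces_white_noise_rmse():
    t = np.arange(2000) / 250.0
    clean = np.sin(2 * np.pi * 1.3 * t)
    wins = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        noisy = clean + 0.05 * rng.standard_normal(clean.size)
        sm = smooth_local_regression(noisy, CFG)
        if _rms(sm - clean) < _rms(noisy - clean):
            wins += 1
    assert wins == 100


def test_window_segment_counts():
    cfg = PreprocessConfig()
    rec = er.EcgSegment(np.random.default_rng(0).standard_normal((5000, 3)),
                        fs=250, lead_names=FRANK_LEADS)
    wins = window_segments(rec, cfg)  # 20 s at 8 s windows
    assert len(wins) == 2
    assert [w.t0 for w in wins] == [0.0, 8.0]
    assert all(w.n_samples == 2000 for w in wins)

    rec8 = er.EcgSegment(rec.samples[:2000], fs=250, lead_names=FRANK_LEADS)
    assert len(window_segments(rec8, cfg)) == 1

    with pytest.warns(UserWarning):
        assert window_segments(
            er.EcgSegment(rec.samples[:100], fs=250, lead_names=FRANK_LEADS),
            cfg) == []


def test_window_overlap_matches_index_oracle():
    cfg = PreprocessConfig(window_overlap=0.5)
    n = 60 * 250
    rec = er.EcgSegment(np.zeros((n, 3)) + np.arange(n)[:, None], fs=250,
                        lead_names=FRANK_LEADS)
    wins = window_segments(rec, cfg)
    # independent sliding-index oracle
    win, stride, count, start = 2000, 1000, 0, 0
    starts = []
    while start + win <= n:
        starts.append(start)
        count += 1
        start += stride
    assert len(wins) == count
    assert [int(w.t0 * 250) for w in wins] == starts


def test_preprocess_recovers_clean_ecg():
    cfg = er.SyntheticConfig(seed=4, powerline_mv=0.0, baseline_mv=0.0,
                             white_sigma_mv=0.0)
    clean = er.generate_source(cfg)
    t = np.arange(clean.n_samples) / cfg.fs
    contaminated = (clean.samples
                    + 0.2 * np.sin(2 * np.pi * 50 * t)[:, None]
                    + 0.8 * np.sin(2 * np.pi * 0.25 * t)[:, None])
    rec = clean.with_samples(contaminated)
    wins = er.preprocess_record(rec, PreprocessConfig(notch_hz=50.0))
    clean_wins = er.preprocess_record(clean, PreprocessConfig(notch_hz=50.0))
    assert wins
    for win, cw in zip(wins, clean_wins):
        for c in range(3):
            r = er.pearson_r(win.samples[:, c], cw.samples[:, c])
            assert r >= 0.95


def test_preprocess_nearly_idempotent():
    cfg = er.SyntheticConfig(seed=5)
    rec = er.add_noise(er.generate_source(cfg), cfg)
    once = er.preprocess_record(rec)
    for win in once:
        twice = er.preprocess_record(win)
        assert len(twice) == 1
        r0, r1 = _rms(win.samples), _rms(twice[0].samples)
        assert abs(r1 - r0) < 0.05 * r0


def test_preprocess_leadwise_permutation_identity():
    cfg = er.SyntheticConfig(seed=6)
    rec = er.add_noise(er.generate_source(cfg), cfg)
    base = er.preprocess_record(rec)
    permuted_rec = rec.select(("VZ", "VX", "VY"))
    perm = er.preprocess_record(permuted_rec)
    for w_base, w_perm in zip(base, perm):
        assert np.array_equal(w_base.samples,
                              w_perm.select(("VX", "VY", "VZ")).samples)


def test_config_yaml_roundtrip(tmp_path):
    cfg = PreprocessConfig(notch_hz=60.0, poly_order=12, window_overlap=0.25)
    path = tmp_path / "pre.yaml"
    cfg.to_yaml(path)
    assert PreprocessConfig.from_yaml(path) == cfg
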