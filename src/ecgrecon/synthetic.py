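"""Seedable synthetic ECG with linked 3-lead source and 12-lead projection.

The generator produces the statistical structure the reconstruction method
relies on, with closed-form ground truth:

- each heartbeat is a sum of Gaussian-shaped waves (P, Q, R, S, T), every
  wave carrying a fixed direction in a 3-D dipole space; the three source
  channels (the Frank VX/VY/VZ analogue) are the projections of that loop,
- the 12 standard leads are a linear lead-field image of the source
  (a fixed Dower-style 12 x 3 matrix, optionally mildly saturated through
  a tanh term; default exactly linear),
- an optional ectopic rhythm — a second train of scaled, widened QRS
  complexes at its own inter-beat period — is superimposed on the sinus
  train, giving the composite its multicycle spectrum,
- additive contaminants: 50 Hz powerline, low-frequency baseline wander,
  and white noise.

Subject-level variation (wave morphology and lead-field jitter drawn once
per subject) makes subject-disjoint splits meaningful.  Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .segment import FRANK_LEADS, STANDARD_12_LEADS, EcgSegment

__all__ = ["WaveParam", "SyntheticConfig", "SubjectRecord", "SyntheticDataset",
           "DEFAULT_LEAD_FIELD", "generate_source", "project_12lead",
           "add_noise", "insert_ectopy", "make_dataset"]


@dataclass
class WaveParam:
    """One Gaussian wave of the beat: amplitude (mV), center offset and
    width as fractions of the beat period, and a 3-D direction."""

    amp: float
    center: float
    width: float
    direction: tuple[float, float, float]

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("wave width must be positive")


def _default_waves() -> dict[str, WaveParam]:
    # widths are fractions of the beat period; at 60 bpm they give a
    # ~100 ms QRS, ~150 ms P wave and ~400 ms T wave; the prominent T keeps
    # the beat's spectral energy concentrated at the rhythm fundamental
    return {
        "P": WaveParam(0.18, 0.18, 0.050, (0.4, 0.8, 0.3)),
        "Q": WaveParam(-0.12, 0.36, 0.013, (0.6, 0.5, -0.4)),
        "R": WaveParam(1.10, 0.40, 0.025, (0.7, 0.6, -0.3)),
        "S": WaveParam(-0.25, 0.44, 0.014, (-0.3, 0.5, 0.8)),
        "T": WaveParam(0.45, 0.65, 0.100, (0.5, 0.7, 0.2)),
    }


#: Dower-style fixed lead field: rows = 12 standard leads, columns = X, Y, Z.
DEFAULT_LEAD_FIELD = np.array([
    [0.632, -0.235, 0.059],   # I
    [0.235, 1.066, -0.132],   # II
    [-0.397, 1.301, -0.191],  # III
    [-0.434, -0.415, 0.037],  # aVR
    [0.515, -0.768, 0.125],   # aVL
    [-0.081, 1.184, -0.162],  # aVF
    [-0.515, 0.157, -0.917],  # V1
    [0.044, 0.164, -1.387],   # V2
    [0.882, 0.098, -1.277],   # V3
    [1.213, 0.127, -0.601],   # V4
    [1.125, 0.127, -0.086],   # V5
    [0.831, 0.076, 0.230],    # V6
])


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are desk-scale (250 Hz, 8 s windows)."""

    fs: float = 250.0
    duration_s: float = 24.0
    heart_rate_bpm: float = 60.0
    hr_jitter_frac: float = 0.03
    waves: dict[str, WaveParam] = field(default_factory=_default_waves)
    lead_field: np.ndarray = field(default_factory=lambda: DEFAULT_LEAD_FIELD.copy())
    nonlinearity_amp: float = 0.0
    # ectopic rhythm: its own rate (0 = off), amplitude/width of the broad
    # PVC-like deflection relative to the sinus R wave, phase offset as a
    # fraction of the sinus period, and timing jitter of the ectopic train
    ectopic_rate_per_min: float = 0.0
    ectopic_morph_scale: float = 0.6
    ectopic_width_scale: float = 6.0
    ectopic_coupling_frac: float = 0.45
    ectopic_jitter_frac: float = 0.06
    # subject-level variation (drawn once per subject by make_dataset)
    subject_morph_jitter: float = 0.15
    subject_leadfield_jitter: float = 0.10
    # contaminants
    powerline_mv: float = 0.05
    baseline_mv: float = 0.10
    baseline_hz: float = 0.30
    white_sigma_mv: float = 0.01
    seed: int = 0

    def __post_init__(self):
        self.lead_field = np.asarray(self.lead_field, dtype=np.float64)
        if self.lead_field.shape != (12, 3):
            raise ValueError("lead_field must be 12 x 3")
        if self.powerline_mv > 0 and self.fs <= 100.0:
            raise ValueError("fs must exceed 100 Hz when powerline noise is on")
        if self.ectopic_rate_per_min < 0:
            raise ValueError("ectopic rate must be >= 0")
        if self.heart_rate_bpm <= 0 or self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("rates and durations must be positive")


def _wave_train(t: np.ndarray, onsets: np.ndarray, period: float,
                waves: dict[str, WaveParam]) -> np.ndarray:
    """Sum of directed Gaussian waves over beats -> (len(t), 3)."""
    out = np.zeros((t.size, 3))
    for wp in waves.values():
        direction = np.asarray(wp.direction, dtype=np.float64)
        direction = direction / np.linalg.norm(direction)
        sigma = wp.width * period
        for onset in onsets:
            center = onset + wp.center * period
            g = np.exp(-0.5 * ((t - center) / sigma) ** 2)
            out += wp.amp * np.outer(g, direction)
    return out


def generate_source(cfg: SyntheticConfig,
                    rng: np.random.Generator | None = None) -> EcgSegment:
    """Sinus-rhythm 3-lead source (VX, VY, VZ analogue), deterministic per seed."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    period = 60.0 / cfg.heart_rate_bpm
    onsets = []
    pos = 0.0
    while pos < cfg.duration_s:
        onsets.append(pos)
        jitter = cfg.hr_jitter_frac * rng.standard_normal() if cfg.hr_jitter_frac else 0.0
        pos += period * max(0.2, 1.0 + jitter)
    samples = _wave_train(t, np.asarray(onsets), period, cfg.waves)
    return EcgSegment(samples, fs=cfg.fs, lead_names=FRANK_LEADS)


def insert_ectopy(src: EcgSegment, cfg: SyntheticConfig,
                  rng: np.random.Generator | None = None) -> EcgSegment:
    """Superimpose an ectopic QRS train at its own inter-beat period.

    Ectopic beats are scaled, widened QRS complexes (Q/R/S waves only) with
    a slightly rotated dipole direction; rate 0 returns the input unchanged.
    """
    if cfg.ectopic_rate_per_min <= 0:
        return src
    rng = rng if rng is not None else np.random.default_rng([cfg.seed, 7])
    period_e = 60.0 / cfg.ectopic_rate_per_min
    sinus_period = 60.0 / cfg.heart_rate_bpm
    offset = cfg.ectopic_coupling_frac * sinus_period
    onsets = np.arange(offset, src.duration_s, period_e)
    if cfg.ectopic_jitter_frac:
        onsets = onsets + (cfg.ectopic_jitter_frac * period_e
                           * rng.standard_normal(onsets.size))
    r = cfg.waves["R"]
    d = np.asarray(r.direction) + 0.15 * rng.standard_normal(3)
    pvc = {"R": WaveParam(r.amp * cfg.ectopic_morph_scale, r.center,
                          r.width * cfg.ectopic_width_scale, tuple(d))}
    t = np.arange(src.n_samples) / src.fs
    ect = _wave_train(t, onsets, sinus_period, pvc)
    return src.with_samples(src.samples + ect)


def project_12lead(src: EcgSegment, cfg: SyntheticConfig) -> EcgSegment:
    """Project the 3-lead source through the lead field -> 12 leads.

    With ``nonlinearity_amp`` = 0 the map is exactly linear; otherwise a
    mild tanh saturation term of that amplitude is added.
    """
    if src.n_leads != 3:
        raise ValueError("source must have 3 leads")
    linear = src.samples @ cfg.lead_field.T
    out = linear
    if cfg.nonlinearity_amp:
        out = linear + cfg.nonlinearity_amp * np.tanh(linear)
    return EcgSegment(out, fs=src.fs, lead_names=STANDARD_12_LEADS,
                      subject_id=src.subject_id, t0=src.t0)


def add_noise(seg: EcgSegment, cfg: SyntheticConfig,
              rng: np.random.Generator | None = None) -> EcgSegment:
    """Add powerline, baseline-wander and white noise per the config."""
    if cfg.powerline_mv == 0 and cfg.baseline_mv == 0 and cfg.white_sigma_mv == 0:
        return seg
    rng = rng if rng is not None else np.random.default_rng([cfg.seed, 13])
    t = np.arange(seg.n_samples) / seg.fs
    out = seg.samples.copy()
    if cfg.powerline_mv:
        phase = rng.uniform(0, 2 * math.pi)
        out += cfg.powerline_mv * np.sin(2 * math.pi * 50.0 * t + phase)[:, None]
    if cfg.baseline_mv:
        for c in range(seg.n_leads):
            phase = rng.uniform(0, 2 * math.pi)
            out[:, c] += cfg.baseline_mv * np.sin(
                2 * math.pi * cfg.baseline_hz * t + phase)
    if cfg.white_sigma_mv:
        out += cfg.white_sigma_mv * rng.standard_normal(out.shape)
    return seg.with_samples(out)


@dataclass
class SubjectRecord:
    """One synthetic subject: noisy recordings plus clean ground truth."""

    subject_id: str
    source: EcgSegment        # 3-lead, with noise
    twelve: EcgSegment        # 12-lead, with noise
    clean_source: EcgSegment  # 3-lead, noiseless
    clean_twelve: EcgSegment  # 12-lead, noiseless
    lead_field: np.ndarray
    label: str = ""


@dataclass
class SyntheticDataset:
    """A collection of subject records with retained ground truth."""

    records: list[SubjectRecord]
    config: SyntheticConfig

    def pairs(self, records: list[SubjectRecord] | None = None,
              window_s: float = 8.0, clean: bool = False,
              preprocess=None) -> list[tuple[EcgSegment, EcgSegment]]:
        """(3-lead input, 12-lead target) windows across the given records.

        ``preprocess`` optionally takes a
        :class:`~ecgrecon.preprocess.PreprocessConfig`; the conditioning
        chain (notch, detrend, smoothing) is then applied to source and
        target records before windowing, as in the full pipeline.
        """
        out = []
        for rec in records if records is not None else self.records:
            src = rec.clean_source if clean else rec.source
            tgt = rec.clean_twelve if clean else rec.twelve
            if preprocess is not None:
                from .preprocess import preprocess_record
                from dataclasses import replace as _rep
                cfg = _rep(preprocess, window_s=window_s)
                out.extend(zip(preprocess_record(src, cfg),
                               preprocess_record(tgt, cfg)))
                continue
            win = int(round(window_s * src.fs))
            for start in range(0, src.n_samples - win + 1, win):
                t0 = start / src.fs
                out.append((
                    replace(src, samples=src.samples[start:start + win], t0=t0),
                    replace(tgt, samples=tgt.samples[start:start + win], t0=t0),
                ))
        return out


def _jitter_waves(waves: dict[str, WaveParam], rng: np.random.Generator,
                  frac: float = 0.15) -> dict[str, WaveParam]:
    out = {}
    for name, wp in waves.items():
        out[name] = WaveParam(
            amp=wp.amp * (1 + frac * rng.uniform(-1, 1)),
            center=wp.center,
            width=wp.width * (1 + frac * rng.uniform(-1, 1)),
            direction=tuple(np.asarray(wp.direction)
                            * (1 + 0.5 * frac * rng.uniform(-1, 1, 3))),
        )
    return out


def make_dataset(cfg: SyntheticConfig, n_subjects: int,
                 segments_per_subject: int | None = None,
                 window_s: float = 8.0) -> SyntheticDataset:
    """Generate a subject-varied dataset with retained ground truth.

    Wave morphology and the lead field are jittered once per subject
    (15% on amplitudes/widths, 10% on lead-field entries), so train and
    held-out subjects genuinely differ.  ``segments_per_subject`` sets each
    record's duration to that many ``window_s`` windows; if None, the
    config duration is used.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    records = []
    for s in range(n_subjects):
        rng = np.random.default_rng([cfg.seed, 1000 + s])
        sub_cfg = replace(
            cfg,
            waves=_jitter_waves(cfg.waves, rng, cfg.subject_morph_jitter),
            lead_field=cfg.lead_field * (
                1 + cfg.subject_leadfield_jitter * rng.uniform(-1, 1, (12, 3))),
            heart_rate_bpm=cfg.heart_rate_bpm * (1 + 0.1 * rng.uniform(-1, 1)),
        )
        if segments_per_subject is not None:
            sub_cfg = replace(sub_cfg, duration_s=segments_per_subject * window_s)
        sid = f"S{s:03d}"
        clean_src = generate_source(sub_cfg, rng)
        clean_src = insert_ectopy(clean_src, sub_cfg, rng)
        clean_src = replace(clean_src, subject_id=sid)
        clean_12 = project_12lead(clean_src, sub_cfg)
        noisy_src = add_noise(clean_src, sub_cfg, rng)
        noisy_12 = add_noise(clean_12, sub_cfg, rng)
        records.append(SubjectRecord(
            subject_id=sid, source=noisy_src, twelve=noisy_12,
            clean_source=clean_src, clean_twelve=clean_12,
            lead_field=sub_cfg.lead_field, label=""))
    return SyntheticDataset(records=records, config=cfg)
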