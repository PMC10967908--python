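"""Core container for fixed-rate multi-lead ECG windows.

All amplitudes inside the package are millivolts; unit conversion happens
only at the I/O boundary.  Lead names are case-insensitive on input and are
canonicalized to the standard vocabulary below.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: the clinical reference montage, in reporting order
STANDARD_12_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
                     "V1", "V2", "V3", "V4", "V5", "V6")
#: Frank orthogonal vectorcardiographic leads
FRANK_LEADS = ("VX", "VY", "VZ")
#: EASI bipolar leads from the E-A-S-I electrode set
EASI_LEADS = ("VES", "VAS", "VAI")

_CANONICAL = {name.upper(): name
              for name in STANDARD_12_LEADS + FRANK_LEADS + EASI_LEADS}
# common aliases seen in WFDB headers (PTB uses lowercase vx/vy/vz)
_CANONICAL.update({"X": "VX", "Y": "VY", "Z": "VZ"})


def canonical_lead(name: str) -> str:
    """Map a lead label to its canonical spelling (case-insensitive)."""
    key = str(name).strip().upper()
    if key in _CANONICAL:
        return _CANONICAL[key]
    raise ValueError(f"unknown lead name: {name!r}")


@dataclass
class EcgSegment:
    """A window of multi-lead ECG sampled at a fixed rate.

    Parameters
    ----------
    samples : ndarray, shape (L, n_leads)
        Amplitudes in mV, one column per lead.
    fs : float
        Sampling rate in Hz.
    lead_names : tuple of str
        Canonical lead labels, one per column.
    subject_id : str
        Opaque subject identifier (drives subject-level data splits).
    t0 : float
        Window start offset within its source record, seconds.
    """

    samples: np.ndarray
    fs: float
    lead_names: tuple[str, ...]
    subject_id: str = ""
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (L, n_leads) array")
        if self.samples.shape[0] < 2:
            raise ValueError("a segment needs at least 2 samples")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        names = tuple(canonical_lead(n) for n in self.lead_names)
        if len(names) != self.samples.shape[1]:
            raise ValueError("lead_names length must match the column count")
        if len(set(names)) != len(names):
            raise ValueError("lead_names must be unique")
        self.lead_names = names

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_leads(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead as a 1-D array (view)."""
        name = canonical_lead(name)
        try:
            col = self.lead_names.index(name)
        except ValueError:
            raise KeyError(f"segment has no lead {name!r} "
                           f"(has {', '.join(self.lead_names)})") from None
        return self.samples[:, col]

    def select(self, names) -> "EcgSegment":
        """Sub-segment with the requested leads in the requested order."""
        names = tuple(canonical_lead(n) for n in names)
        cols = []
        for n in names:
            if n not in self.lead_names:
                raise KeyError(f"segment has no lead {n!r}")
            cols.append(self.lead_names.index(n))
        return replace(self, samples=self.samples[:, cols], lead_names=names)

    def with_samples(self, samples: np.ndarray) -> "EcgSegment":
        return replace(self, samples=samples)
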