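"""Record and artifact I/O.

Supports two record formats:

- WFDB-compatible records (a text ``.hea`` header plus a 16-bit
  little-endian interleaved ``.dat`` signal file, format 16).  The reader
  honors per-signal gain/baseline and converts to mV; the writer defaults
  to a 0.5 µV LSB (gain 2000 ADC units/mV).  This is a minimal reader and
  writer for the header fields the package needs, not a full
  implementation of the format.
- CSV matrices: one column per lead, header row of lead names, values in
  mV.  CSV carries no sampling rate, so reading CSV requires ``fs``.

Model checkpoints are ``.npz`` bundles of named parameter arrays plus a
JSON sidecar with the config; run manifests are JSON (config, seed,
package version, input hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import LeadModel, ModelConfig, TrainedLeadModel, build_model
from .segment import EcgSegment, canonical_lead

__all__ = ["read_record", "write_record", "save_lead_model", "load_lead_model",
           "write_manifest", "file_sha256"]

_UNIT_TO_MV = {"mv": 1.0, "uv": 1e-3, "µv": 1e-3, "v": 1e3, "mV": 1.0}


def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_tokens = lines[0].split()
    name = rec_tokens[0].split("/")[0]
    nsig = int(rec_tokens[1])
    fs = float(rec_tokens[2].split("/")[0]) if len(rec_tokens) > 2 else 250.0
    nsamp = int(rec_tokens[3]) if len(rec_tokens) > 3 else None
    signals = []
    for ln in lines[1:1 + nsig]:
        tokens = ln.split()
        fname, fmt = tokens[0], tokens[1]
        gain_tok = tokens[2] if len(tokens) > 2 else "200/mV"
        if "/" in gain_tok:
            gain_part, units = gain_tok.split("/", 1)
        else:
            gain_part, units = gain_tok, "mV"
        if "(" in gain_part:
            gain_s, base_s = gain_part.split("(")
            baseline = int(base_s.rstrip(")"))
        else:
            gain_s, baseline = gain_part, 0
        gain = float(gain_s) if gain_s else 200.0
        desc = " ".join(tokens[8:]) if len(tokens) > 8 else f"ch{len(signals)}"
        signals.append(dict(file=fname, fmt=fmt, gain=gain, baseline=baseline,
                            units=units.strip().lower(), desc=desc))
    return name, nsig, fs, nsamp, signals


def read_record(path, wanted_leads=None, fs: float | None = None) -> EcgSegment:
    """Read a WFDB or CSV record into an :class:`EcgSegment` (mV).

    ``path`` is a ``.hea`` file, a WFDB record base name, or a ``.csv``
    file.  ``wanted_leads`` selects leads by canonical name (all leads in
    file order when None).  ``fs`` is required for CSV input.
    """
    path = Path(path)
    if path.suffix == ".csv":
        if fs is None:
            raise ValueError("CSV records carry no sampling rate; pass fs")
        df = pd.read_csv(path)
        names = [canonical_lead(c) for c in df.columns]
        seg = EcgSegment(df.to_numpy(dtype=np.float64), fs=fs,
                         lead_names=names, subject_id=path.stem)
        return seg.select(wanted_leads) if wanted_leads is not None else seg

    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    name, nsig, fs_h, nsamp, signals = _parse_header(hea)
    fmts = {s["fmt"] for s in signals}
    if fmts != {"16"}:
        raise ValueError(f"only format 16 signals supported, found {fmts}")
    for s in signals:
        if s["units"] not in _UNIT_TO_MV:
            raise ValueError(f"signal {s['desc']!r} has non-voltage units "
                             f"{s['units']!r}")
    dat = hea.parent / signals[0]["file"]
    raw = np.fromfile(dat, dtype="<i2")
    if nsamp is None:
        nsamp = raw.size // nsig
    raw = raw[:nsamp * nsig].reshape(nsamp, nsig).astype(np.float64)
    cols = []
    names = []
    for j, s in enumerate(signals):
        mv = (raw[:, j] - s["baseline"]) / s["gain"] * _UNIT_TO_MV[s["units"]] * 1.0
        cols.append(mv)
        names.append(canonical_lead(s["desc"]))
    seg = EcgSegment(np.column_stack(cols), fs=fs_h, lead_names=names,
                     subject_id=name)
    return seg.select(wanted_leads) if wanted_leads is not None else seg


def write_record(seg: EcgSegment, path, fmt: str = "wfdb",
                 lsb_uv: float = 0.5) -> list[Path]:
    """Write a segment as a WFDB record (format 16) or a CSV matrix.

    ``lsb_uv`` sets the WFDB quantization step (default 0.5 µV, i.e. gain
    2000 ADC units per mV); amplitudes exceeding the 16-bit range at that
    gain raise an error suggesting a coarser LSB.
    """
    path = Path(path)
    if fmt == "csv":
        if path.suffix != ".csv":
            path = path.with_suffix(".csv")
        pd.DataFrame(seg.samples, columns=list(seg.lead_names)).to_csv(
            path, index=False)
        return [path]
    if fmt != "wfdb":
        raise ValueError("fmt must be 'wfdb' or 'csv'")
    base = path.with_suffix("") if path.suffix in (".hea", ".dat") else path
    gain = 1000.0 / lsb_uv  # ADC units per mV
    scaled = np.round(seg.samples * gain)
    if np.abs(scaled).max() > 32767:
        raise ValueError(
            f"amplitude {np.abs(seg.samples).max():.2f} mV exceeds the "
            f"16-bit range at LSB {lsb_uv} µV; increase lsb_uv")
    ints = scaled.astype("<i2")
    dat_name = base.name + ".dat"
    lines = [f"{base.name} {seg.n_leads} {seg.fs:g} {seg.n_samples}"]
    for j, lead in enumerate(seg.lead_names):
        first = int(ints[0, j])
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} 0 0 {lead}")
    hea = base.with_suffix(".hea")
    hea.write_text("\n".join(lines) + "\n")
    dat = base.with_suffix(".dat")
    ints.reshape(-1).tofile(dat)
    return [hea, dat]


# -- checkpoints ------------------------------------------------------------


def save_lead_model(trained: TrainedLeadModel, out_dir) -> Path:
    """Write one per-lead checkpoint: params (.npz) + meta (.json) + curve (.csv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = trained.target_lead
    np.savez(out_dir / f"model_{tag}.npz", **trained.model.state_dict())
    meta = {
        "target_lead": trained.target_lead,
        "input_lead": trained.input_lead,
        "best_epoch": trained.best_epoch,
        "min_val_loss": trained.min_val_loss,
        "config": dataclasses.asdict(trained.config),
    }
    (out_dir / f"model_{tag}.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame({"epoch": np.arange(1, len(trained.train_losses) + 1),
                  "train_loss": trained.train_losses,
                  "val_loss": trained.val_losses}).to_csv(
        out_dir / f"curve_{tag}.csv", index=False)
    return out_dir / f"model_{tag}.npz"


def load_lead_model(out_dir, target_lead: str) -> TrainedLeadModel:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"model_{target_lead}.json").read_text())
    cfg_dict = meta["config"]
    cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
    cfg = ModelConfig(**cfg_dict)
    model = build_model(cfg)
    with np.load(out_dir / f"model_{target_lead}.npz") as npz:
        model.load_state_dict(dict(npz.items()))
    curve = pd.read_csv(out_dir / f"curve_{target_lead}.csv")
    return TrainedLeadModel(
        target_lead=meta["target_lead"], input_lead=meta["input_lead"],
        model=model, best_epoch=meta["best_epoch"],
        min_val_loss=meta["min_val_loss"], config=cfg,
        train_losses=list(curve["train_loss"]),
        val_losses=list(curve["val_loss"]))


# -- manifests --------------------------------------------------------------


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict, seed: int | None,
                   inputs: list = ()) -> Path:
    """Write the JSON run manifest (config, seed, version, input hashes)."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {str(p): file_sha256(p) for p in inputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
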