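"""Reading and writing recordings, annotations, and tabular results.

Two on-disk recording formats are supported:

* **Plain-array format** (native): ``<base>.yaml`` header (id, fs, labels,
  metadata), ``<base>.npy`` float32 signal in microvolts, and
  ``<base>.events.csv`` sidecar with columns ``time_s,moaas``.
* **EDF**: read through :mod:`mne`; a minimal EDF writer (16-bit, 1-second
  data records) is provided so the generator can export EDF and the read
  path can be exercised round-trip.
"""

from __future__ import annotations

import hashlib
import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import AnnotationError, SedEEGError
from .recording import CohortMeta, MOAASEvent, Recording

EVENTS_HEADER = ["time_s", "moaas"]


# ---------------------------------------------------------------------------
# annotations sidecar
# ---------------------------------------------------------------------------

def read_events_csv(path) -> list[MOAASEvent]:
    """Read a ``time_s,moaas`` sidecar table, validating row by row."""
    path = Path(path)
    events = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if [h.strip() for h in header] != EVENTS_HEADER:
            raise AnnotationError(
                f"{path}: expected header 'time_s,moaas', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                t = float(parts[0])
                score = int(parts[1])
                events.append(MOAASEvent(time_s=t, score=score))
            except (ValueError, IndexError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return events


def write_events_csv(events, path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(EVENTS_HEADER) + "\n")
        for ev in events:
            fh.write(f"{ev.time_s:.6g},{ev.score}\n")


# ---------------------------------------------------------------------------
# plain-array format
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, base) -> dict:
    """Write a recording in the plain-array format; returns the file map."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    sig_path = base.with_suffix(".npy")
    ev_path = base.parent / (base.name + ".events.csv")
    hdr_path = base.with_suffix(".yaml")
    np.save(sig_path, recording.signal.astype(np.float32))
    write_events_csv(recording.events, ev_path)
    header = {
        "id": recording.id,
        "fs": float(recording.fs),
        "channel_labels": list(recording.channel_labels),
        "meta": recording.meta.as_dict() if recording.meta else None,
        "signal_file": sig_path.name,
        "events_file": ev_path.name,
    }
    with open(hdr_path, "w") as fh:
        yaml.safe_dump(header, fh, sort_keys=True)
    return {"header": hdr_path, "signal": sig_path, "events": ev_path}


def _read_plain(hdr_path: Path, annotation_path=None) -> Recording:
    with open(hdr_path) as fh:
        header = yaml.safe_load(fh)
    sig = np.load(hdr_path.parent / header["signal_file"]).astype(float)
    ev_path = annotation_path or hdr_path.parent / header["events_file"]
    events = read_events_csv(ev_path) if Path(ev_path).exists() else []
    meta = CohortMeta(**header["meta"]) if header.get("meta") else None
    return Recording(
        id=header["id"],
        signal=sig,
        fs=float(header["fs"]),
        channel_labels=list(header["channel_labels"]),
        events=events,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf(path: Path, annotation_path=None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # volts -> microvolts
    events = []
    if annotation_path is not None:
        events = read_events_csv(annotation_path)
    else:
        for ann in raw.annotations:
            desc = str(ann["description"]).strip()
            if desc.upper().startswith("MOAAS"):
                events.append(
                    MOAASEvent(time_s=float(ann["onset"]), score=int(desc.split()[-1]))
                )
    return Recording(
        id=path.stem,
        signal=signal,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
    )


def write_edf(recording: Recording, path) -> Path:
    """Write a minimal plain-EDF file (int16 samples, 1-s data records).

    The sampling rate must be a whole number of samples per second.
    Annotations are not embedded; use the events sidecar.
    """
    path = Path(path)
    fs = recording.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise SedEEGError("EDF writer requires an integer sampling rate")
    ns = recording.n_channels
    sig = recording.signal
    n_records = int(np.ceil(recording.n_samples / spr))
    padded = np.zeros((ns, n_records * spr))
    padded[:, : recording.n_samples] = sig

    phys_min = np.floor(padded.min(axis=1))
    phys_max = np.ceil(padded.max(axis=1))
    phys_max = np.where(phys_max <= phys_min, phys_min + 1, phys_max)
    dig_min, dig_max = -32768, 32767

    def pad(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),  # patient
            pad(f"Startdate X X X X {recording.id}", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(256 * (ns + 1), 8),
            pad("", 44),
            pad(n_records, 8),
            pad("1", 8),  # record duration, seconds
            pad(ns, 4),
        ]
    )
    fields = [
        [pad(lbl, 16) for lbl in recording.channel_labels],
        [pad("AgAgCl electrode", 80)] * ns,
        [pad("uV", 8)] * ns,
        [pad(f"{phys_min[i]:.0f}", 8) for i in range(ns)],
        [pad(f"{phys_max[i]:.0f}", 8) for i in range(ns)],
        [pad(dig_min, 8)] * ns,
        [pad(dig_max, 8)] * ns,
        [pad("", 80)] * ns,
        [pad(spr, 8)] * ns,
        [pad("", 32)] * ns,
    ]
    header += b"".join(b"".join(col) for col in fields)

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - gain * dig_min
    digital = np.round((padded - offset[:, None]) / gain[:, None])
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(struct.pack(f"<{ns * spr}h", *chunk.ravel()))
    return path


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_recording(path, annotation_path=None) -> Recording:
    """Read a recording (EDF or plain-array format) into the data model.

    Channel labels are normalized to canonical 10-20 names; the four frontal
    electrodes (Fp1, F7, Fp2, F8) must be present. Events are sorted by time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path, annotation_path)
    elif path.suffix.lower() in (".yaml", ".yml"):
        rec = _read_plain(path, annotation_path)
    else:
        raise SedEEGError(f"unrecognized recording format: {path.suffix!r}")
    rec.require_channels()
    return rec


# ---------------------------------------------------------------------------
# results writer
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_results(result, out_dir, config=None, seed=None) -> dict:
    """Write an :class:`~sedeeg.evaluate.EvaluationResult` as CSV + manifest.

    Emits deterministic CSVs (per-fold predictions, AUC summary, per-fold
    feature importances, subgroup matrix) plus a JSON manifest carrying the
    config hash, seed and package version. Writing the same result twice
    produces byte-identical files.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    files = {}

    pred_path = out_dir / "predictions.csv"
    result.predictions.to_csv(pred_path, index=False, float_format=_FLOAT_FMT)
    files["predictions"] = pred_path

    summary = pd.DataFrame(
        [
            {
                "auc": result.auc,
                "ci_lo": result.auc_ci[0],
                "ci_hi": result.auc_ci[1],
                "sensitivity": result.sensitivity,
                "specificity": result.specificity,
                "f1": result.f1,
            }
        ]
    )
    summary_path = out_dir / "auc_summary.csv"
    summary.to_csv(summary_path, index=False, float_format=_FLOAT_FMT)
    files["auc_summary"] = summary_path

    imp_path = out_dir / "importances.csv"
    if result.importances is not None and len(result.importances):
        imp = pd.DataFrame(result.importances, columns=result.feature_names)
        imp.insert(0, "fold", range(len(imp)))
    else:
        imp = pd.DataFrame(columns=["fold", *(result.feature_names or [])])
    imp.to_csv(imp_path, index=False, float_format=_FLOAT_FMT)
    files["importances"] = imp_path

    sub_path = out_dir / "subgroups.csv"
    rows = [
        {
            "train_group": a,
            "test_group": b,
            "auc": cell[0],
            "ci_lo": cell[1],
            "ci_hi": cell[2],
        }
        for (a, b), cell in sorted((result.subgroup_matrix or {}).items())
    ]
    pd.DataFrame(rows, columns=["train_group", "test_group", "auc", "ci_lo", "ci_hi"]).to_csv(
        sub_path, index=False, float_format=_FLOAT_FMT
    )
    files["subgroups"] = sub_path

    cfg_json = json.dumps(config, sort_keys=True, default=str) if config is not None else ""
    manifest = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "n_predictions": int(len(result.predictions)),
        "files": {k: v.name for k, v in files.items()},
    }
    man_path = out_dir / "manifest.json"
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["manifest"] = man_path
    return files
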