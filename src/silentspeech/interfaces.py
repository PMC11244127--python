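"""File I/O, dataset manifests, configuration and logging.

The canonical on-disk recording format is a CSV (``time`` column plus one
column per channel) with a JSON sidecar carrying the sampling rate,
channel roles, annotations, and the config hash / seed that produced the
file.  EDF/EDF+ files are read through :mod:`mne` when available.  A
dataset manifest is a JSON file listing per-sample recording paths,
labels, subjects and rates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import Annotation, Recording

__all__ = [
    "SCHEMA_VERSION",
    "DatasetManifest",
    "read_recording",
    "write_recording",
    "write_dataset",
    "read_dataset",
    "load_config",
    "config_hash",
    "setup_logging",
    "DEFAULT_CONFIG",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

# All study constants in one place; any can be overridden from a YAML file.
DEFAULT_CONFIG: dict = {
    "sampling_rate": 4000.0,       # Hz (the hardware also supports 4096)
    "window_ms": 500.0,            # moving window: 2000 samples at 4 kHz
    "bands": {
        "alpha": [8.0, 12.0],
        "beta": [13.0, 30.0],
        "gamma": [30.0, 100.0],
        "alpha_beta": [8.0, 30.0],
        "emg_split_hz": 25.0,
    },
    "epochs": {"pre_s": 2.0, "spike_s": 3.0},
    "anova_alpha": 0.05,
    "train": {
        "learning_rate": 1.0e-4,
        "batch_size": 16,
        "patience": 250,
        "max_epochs": 5000,
    },
    "fewshot": {"k": 3, "n_ref_trials": 4},
    "cv": {"fraction": 0.10, "iterations": 10, "repetitions": 3},
}


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s")


def config_hash(config: dict) -> str:
    """Short content hash of a config mapping (for artifact provenance)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> dict:
    """DEFAULT_CONFIG, deep-updated with the YAML file at ``path`` if given."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}

        def merge(base: dict, upd: dict) -> None:
            for k, v in upd.items():
                if isinstance(v, dict) and isinstance(base.get(k), dict):
                    merge(base[k], v)
                else:
                    base[k] = v

        merge(cfg, user)
    return cfg


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path: str | Path,
                    fmt: str = "csv", seed: int | None = None,
                    config: dict | None = None) -> Path:
    """Write a recording as CSV + JSON sidecar; returns the CSV path.

    The sidecar records sampling rate, channel roles, annotations, schema
    version, and — when given — the seed and config hash that produced the
    data, so every artifact carries its provenance.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported write format {fmt!r}; recordings are "
                         "written as CSV + JSON sidecar (EDF is read-only)")
    if recording.n_samples == 0:
        raise ValueError("refusing to write a zero-length recording")
    path = Path(path).with_suffix(".csv")
    names = [f"{role}{i}" for i, role in enumerate(recording.channel_roles)]
    df = pd.DataFrame(
        {"time": np.arange(recording.n_samples) / recording.sampling_rate})
    for name, ch in zip(names, recording.channels):
        df[name] = ch
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "sampling_rate": recording.sampling_rate,
        "channel_roles": list(recording.channel_roles),
        "channel_names": names,
        "annotations": [asdict(a) for a in recording.annotations],
        "meta": {k: v for k, v in recording.meta.items()
                 if isinstance(v, (str, int, float, bool))},
    }
    if seed is not None:
        sidecar["seed"] = int(seed)
    if config is not None:
        sidecar["config_hash"] = config_hash(config)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read a recording from CSV (+ JSON sidecar) or EDF.

    The format is inferred from the file extension unless given.  CSV files
    require their sidecar; a missing sidecar or a channel-count mismatch
    between sidecar and data is an error naming the offending field.
    """
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return _read_edf(path)
    if fmt != "csv":
        raise ValueError(f"unknown recording format {fmt!r}")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"CSV recording {path} is missing its JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("sampling_rate", "channel_roles", "channel_names"):
        if key not in sidecar:
            raise ValueError(f"sidecar {sidecar_path} missing field {key!r}")
    df = pd.read_csv(path)
    names = sidecar["channel_names"]
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(f"CSV {path} missing channel columns {missing} "
                         "declared in sidecar field 'channel_names'")
    channels = np.vstack([df[n].to_numpy(dtype=np.float64) for n in names])
    annotations = [Annotation(**a) for a in sidecar.get("annotations", [])]
    return Recording(channels=channels,
                     channel_roles=list(sidecar["channel_roles"]),
                     sampling_rate=float(sidecar["sampling_rate"]),
                     annotations=annotations,
                     meta=dict(sidecar.get("meta", {})))


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    channels = raw.get_data() * 1e6  # volts -> microvolts
    roles = ["EMG" if "emg" in name.lower() else "EEG"
             for name in raw.ch_names]
    annotations = [Annotation(onset=float(o), duration=float(d), label=str(l))
                   for o, d, l in zip(raw.annotations.onset,
                                      raw.annotations.duration,
                                      raw.annotations.description)]
    return Recording(channels=channels, channel_roles=roles,
                     sampling_rate=float(raw.info["sfreq"]),
                     annotations=annotations, meta={"source": str(path)})


# ---------------------------------------------------------------------------
# dataset manifests
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Index of a labeled recording collection on disk."""

    entries: list = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION
    classes: tuple[str, ...] = ()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {"schema_version": self.schema_version,
             "classes": list(self.classes),
             "entries": self.entries}, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        data = json.loads(Path(path).read_text())
        manifest = cls(entries=data["entries"],
                       schema_version=data.get("schema_version", 0),
                       classes=tuple(data.get("classes", ())))
        base = Path(path).parent
        for e in manifest.entries:
            rec_path = base / e["path"]
            if not rec_path.exists():
                raise FileNotFoundError(f"manifest entry missing: {rec_path}")
            if manifest.classes and e["label"] not in manifest.classes:
                raise ValueError(f"label {e['label']!r} not in configured "
                                 f"classes {manifest.classes}")
        return manifest


def write_dataset(recordings: list[Recording], out_dir: str | Path,
                  seed: int | None = None) -> Path:
    """Write labeled recordings plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    classes = sorted({r.meta.get("label", "") for r in recordings} - {""})
    for i, rec in enumerate(recordings):
        name = rec.meta.get("sample_id") or f"sample{i:03d}"
        csv_path = write_recording(rec, out_dir / name, seed=seed)
        entries.append({"path": csv_path.name, "format": "csv",
                        "label": rec.meta.get("label", ""),
                        "subject": rec.meta.get("subject", ""),
                        "sampling_rate": rec.sampling_rate})
    manifest = DatasetManifest(entries=entries, classes=tuple(classes))
    return manifest.save(out_dir / "manifest.json")


def read_dataset(manifest_path: str | Path) -> list[Recording]:
    manifest = DatasetManifest.load(manifest_path)
    base = Path(manifest_path).parent
    out = []
    for e in manifest.entries:
        rec = read_recording(base / e["path"], fmt=e.get("format", "csv"))
        rec.meta.setdefault("label", e.get("label", ""))
        rec.meta.setdefault("subject", e.get("subject", ""))
        rec.meta.setdefault("sample_id", Path(e["path"]).stem)
        out.append(rec)
    return out
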