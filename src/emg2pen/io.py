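"""Trial container I/O.

A dataset is a directory of per-trial CSV files plus a JSON manifest.
Each trial contributes:

* ``<trial_id>.csv`` — columns ``t, x, y, emg1..emgC`` at the envelope
  rate ``fs_env`` (the emg columns hold the cached envelope when one has
  been precomputed, zeros otherwise; the manifest records which);
* ``<trial_id>_raw.csv`` — columns ``t, emg1..emgC`` at the raw rate
  ``fs_raw``.

The manifest lists every file with a SHA-256 checksum, the generating
configuration (for synthetic data) and the seed, so any dataset can be
verified and reproduced. An equivalent single-file HDF5 container with the
same schema is available through :func:`write_trials_hdf5` /
:func:`read_trials_hdf5`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, InvalidInputError

__all__ = [
    "TrialRecord",
    "DatasetManifest",
    "read_trials",
    "write_trials",
    "read_trials_hdf5",
    "write_trials_hdf5",
]

CONTAINER_VERSION = "1"
_FLOAT_FMT = "%.17g"  # lossless text round-trip for float64


@dataclass(frozen=True)
class TrialRecord:
    """One handwriting trial.

    ``emg`` is (n_channels, n_raw) raw EMG at ``fs_raw``; ``pen`` is
    (2, n_env) tablet coordinates at ``fs_env``; ``envelope`` optionally
    caches the preprocessed (n_channels, n_env) envelope.
    """

    trial_id: str
    subject_id: str
    symbol: int
    emg: np.ndarray
    pen: np.ndarray
    fs_raw: float
    fs_env: float
    envelope: np.ndarray | None = None

    def __post_init__(self) -> None:
        emg = np.asarray(self.emg, dtype=float)
        pen = np.asarray(self.pen, dtype=float)
        if pen.ndim != 2 or pen.shape[0] != 2:
            raise InvalidInputError(
                f"trial {self.trial_id}: pen must be (2, n); got {pen.shape}"
            )
        if emg.ndim != 2:
            raise InvalidInputError(
                f"trial {self.trial_id}: emg must be (channels, n); got {emg.shape}"
            )
        object.__setattr__(self, "emg", emg)
        object.__setattr__(self, "pen", pen)
        if self.envelope is not None:
            env = np.asarray(self.envelope, dtype=float)
            if env.shape[1] != pen.shape[1]:
                raise InvalidInputError(
                    f"trial {self.trial_id}: envelope length {env.shape[1]} "
                    f"!= pen length {pen.shape[1]}"
                )
            object.__setattr__(self, "envelope", env)

    @property
    def n_channels(self) -> int:
        return self.emg.shape[0] if self.emg.shape[1] else (
            self.envelope.shape[0] if self.envelope is not None else self.emg.shape[0]
        )


@dataclass
class DatasetManifest:
    version: str
    trials: list[dict]
    config: dict | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_trials(
    records,
    path,
    config: dict | None = None,
    seed: int | None = None,
) -> DatasetManifest:
    """Write trial records and a checksummed manifest to directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        n_env = rec.pen.shape[1]
        n_ch = rec.envelope.shape[0] if rec.envelope is not None else rec.emg.shape[0]
        emg_cols = [f"emg{i + 1}" for i in range(n_ch)]
        env_vals = rec.envelope if rec.envelope is not None else np.zeros((n_ch, n_env))
        env_df = pd.DataFrame(
            {"t": np.arange(n_env) / rec.fs_env, "x": rec.pen[0], "y": rec.pen[1]}
            | {c: env_vals[i] for i, c in enumerate(emg_cols)}
        )
        env_file = f"{rec.trial_id}.csv"
        env_df.to_csv(path / env_file, index=False, float_format=_FLOAT_FMT)

        raw_df = pd.DataFrame(
            {"t": np.arange(rec.emg.shape[1]) / rec.fs_raw}
            | {c: rec.emg[i] for i, c in enumerate(emg_cols[: rec.emg.shape[0]])}
        )
        raw_file = f"{rec.trial_id}_raw.csv"
        raw_df.to_csv(path / raw_file, index=False, float_format=_FLOAT_FMT)

        entries.append(
            {
                "trial_id": rec.trial_id,
                "subject_id": rec.subject_id,
                "symbol": int(rec.symbol),
                "fs_raw": rec.fs_raw,
                "fs_env": rec.fs_env,
                "n_channels": n_ch,
                "has_envelope": rec.envelope is not None,
                "files": {
                    env_file: _sha256(path / env_file),
                    raw_file: _sha256(path / raw_file),
                },
            }
        )
    manifest = DatasetManifest(
        version=CONTAINER_VERSION, trials=entries, config=config, seed=seed
    )
    (path / "manifest.json").write_text(
        json.dumps(
            {
                "version": manifest.version,
                "config": manifest.config,
                "seed": manifest.seed,
                "trials": manifest.trials,
            },
            indent=1,
        )
    )
    return manifest


def _read_csv_checked(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed file
        raise FormatError(f"{path.name}: cannot parse CSV ({exc})") from exc
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    return df


def read_trials(path, verify: bool = True) -> list[TrialRecord]:
    """Read a trial container directory back into :class:`TrialRecord` objects.

    With ``verify`` (default) every file's SHA-256 is checked against the
    manifest; a mismatch raises :class:`IntegrityError`.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    records = []
    for entry in manifest["trials"]:
        for fname, checksum in entry["files"].items():
            fpath = path / fname
            if not fpath.exists():
                raise IntegrityError(f"{fname}: listed in manifest but missing")
            if verify and _sha256(fpath) != checksum:
                raise IntegrityError(f"{fname}: checksum mismatch")
        n_ch = int(entry["n_channels"])
        emg_cols = [f"emg{i + 1}" for i in range(n_ch)]
        env_file, raw_file = list(entry["files"])
        env_df = _read_csv_checked(path / env_file, ["t", "x", "y", *emg_cols])
        raw_df = _read_csv_checked(path / raw_file, ["t", *emg_cols])
        envelope = (
            env_df[emg_cols].to_numpy().T if entry.get("has_envelope") else None
        )
        records.append(
            TrialRecord(
                trial_id=entry["trial_id"],
                subject_id=entry["subject_id"],
                symbol=int(entry["symbol"]),
                emg=raw_df[emg_cols].to_numpy().T,
                pen=env_df[["x", "y"]].to_numpy().T,
                fs_raw=float(entry["fs_raw"]),
                fs_env=float(entry["fs_env"]),
                envelope=envelope,
            )
        )
    return records


def write_trials_hdf5(records, path, config: dict | None = None,
                      seed: int | None = None) -> None:
    """Single-file HDF5 container with the same schema as the CSV directory."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["version"] = CONTAINER_VERSION
        if config is not None:
            f.attrs["config"] = json.dumps(config)
        if seed is not None:
            f.attrs["seed"] = seed
        for rec in records:
            g = f.create_group(rec.trial_id)
            g.attrs.update(
                subject_id=rec.subject_id,
                symbol=int(rec.symbol),
                fs_raw=rec.fs_raw,
                fs_env=rec.fs_env,
            )
            g.create_dataset("emg", data=rec.emg)
            g.create_dataset("pen", data=rec.pen)
            if rec.envelope is not None:
                g.create_dataset("envelope", data=rec.envelope)


def read_trials_hdf5(path) -> list[TrialRecord]:
    import h5py

    records = []
    with h5py.File(path, "r") as f:
        for trial_id in sorted(f):
            g = f[trial_id]
            records.append(
                TrialRecord(
                    trial_id=trial_id,
                    subject_id=str(g.attrs["subject_id"]),
                    symbol=int(g.attrs["symbol"]),
                    emg=g["emg"][()],
                    pen=g["pen"][()],
                    fs_raw=float(g.attrs["fs_raw"]),
                    fs_env=float(g.attrs["fs_env"]),
                    envelope=g["envelope"][()] if "envelope" in g else None,
                )
            )
    return records
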