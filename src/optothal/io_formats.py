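"""On-disk data products and their readers/writers.

Three data products move through the pipeline:

* behavior logs — one CSV row per trial (onset and response latency in ms
  from nose-poke entry, plus the stimulation condition),
* spike trains — one CSV of spike times per unit plus a trial table of
  stimulation epochs (seconds),
* LFP epochs — a trials x samples matrix in an HDF5 container with a JSON
  sidecar carrying the sampling metadata.

The dialect is fixed (UTF-8, comma separator, "." decimal point, no
sniffing) so that write -> read round-trips are bit-stable: exact for
integers and text, bit-equal for floats. Readers validate invariants and
reject bad input rather than coercing it.

Times are stored in the units natural to each product: milliseconds for
behavior, seconds for spikes. LFP values are depth potentials in microvolts;
negative deflections are depth-negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "StimulusCondition",
    "TrialRecord",
    "BehavioralSession",
    "EpochSpec",
    "SpikeTrain",
    "LFPEpochs",
    "read_behavior_log",
    "write_behavior_log",
    "read_spike_train",
    "write_spike_train",
    "read_lfp_epochs",
    "write_lfp_epochs",
    "write_results_table",
]

ONSET_MIN_MS = 250.0
ONSET_MAX_MS = 1750.0

_BEHAVIOR_COLUMNS = [
    "trial_index",
    "onset_ms",
    "response_ms",
    "modality",
    "frequency_hz",
    "amplitude_mw",
    "duty_cycle",
    "stim_duration_ms",
]


class FormatError(Exception):
    """The file does not have the expected structure."""


class ValidationError(Exception):
    """The file parsed but violates a data invariant."""


@dataclass(frozen=True)
class StimulusCondition:
    """Stimulation protocol of a behavioral session.

    ``modality`` is "visual" or "optogenetic"; optogenetic trials carry a
    pulse frequency (Hz), light amplitude (mW), duty cycle (fraction of
    each cycle the light is on), and total stimulation duration (ms).
    """

    modality: str
    frequency_hz: float = 0.0
    amplitude_mw: float = 0.0
    duty_cycle: float = 0.5
    stim_duration_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.modality not in ("visual", "optogenetic"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if not (0.0 < self.duty_cycle <= 1.0):
            raise ValidationError(f"duty_cycle {self.duty_cycle} outside (0, 1]")
        if self.modality == "optogenetic" and self.frequency_hz <= 0:
            raise ValidationError("optogenetic trials require frequency_hz > 0")


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial.

    ``onset_ms`` is stimulus onset, ``response_ms`` nose-poke withdrawal,
    both relative to nose-poke entry; ``response_ms`` is None when the
    animal remained in the poke until trial timeout.
    """

    trial_index: int
    onset_ms: float
    response_ms: float | None = None

    def __post_init__(self) -> None:
        if self.onset_ms <= 0:
            raise ValidationError(f"onset_ms must be > 0, got {self.onset_ms}")
        if not (ONSET_MIN_MS <= self.onset_ms <= ONSET_MAX_MS):
            raise ValidationError(
                f"onset_ms {self.onset_ms} outside [{ONSET_MIN_MS}, {ONSET_MAX_MS}]"
            )
        if self.response_ms is not None and self.response_ms <= 0:
            raise ValidationError(f"response_ms must be > 0, got {self.response_ms}")


@dataclass(frozen=True)
class BehavioralSession:
    animal_id: str
    session_id: str
    trials: tuple[TrialRecord, ...]
    condition: StimulusCondition

    def __post_init__(self) -> None:
        idx = [t.trial_index for t in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("trial_index must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class EpochSpec:
    """Stimulation epoch of one trial, in session seconds."""

    trial_start_s: float
    stim_onset_s: float
    stim_offset_s: float
    frequency_hz: float

    def __post_init__(self) -> None:
        if not (self.trial_start_s <= self.stim_onset_s < self.stim_offset_s):
            raise ValidationError(
                "epoch ordering violated: need trial_start <= stim_onset < stim_offset"
            )


@dataclass(frozen=True)
class SpikeTrain:
    """Spike timestamps of one unit plus the trial epochs they belong to."""

    unit_id: str
    spike_times_s: np.ndarray
    trials: tuple[EpochSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        object.__setattr__(self, "spike_times_s", t)
        if t.ndim != 1:
            raise ValidationError("spike_times_s must be 1-D")
        if t.size and t[0] < 0:
            raise ValidationError("spike times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("spike times must be strictly sorted")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)


@dataclass(frozen=True)
class LFPEpochs:
    """Trial-aligned LFP: matrix of depth potentials in microvolts.

    ``data[i, j]`` is trial i at time ``t0_ms + 1000 * j / fs_hz``
    milliseconds relative to stimulation onset.
    """

    data: np.ndarray
    fs_hz: float
    t0_ms: float
    site_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 2:
            raise ValidationError("LFP data must be a trials x samples matrix")
        if self.fs_hz < 600:
            raise ValidationError(
                f"fs_hz {self.fs_hz} < 600: cannot represent 300 Hz content"
            )

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + 1000.0 * np.arange(self.n_samples) / self.fs_hz


# ----------------------------------------------------------------- behavior


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_behavior_log(
    path, animal_id: str = "", session_id: str = ""
) -> BehavioralSession:
    """Parse a behavior-log CSV into a validated :class:`BehavioralSession`.

    The file must carry the header columns ``trial_index``, ``onset_ms``,
    ``response_ms`` (empty cell = no withdrawal) and the condition columns
    ``modality, frequency_hz, amplitude_mw, duty_cycle, stim_duration_ms``.
    Row order is preserved; invariant violations raise, never coerce.
    """
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    _require_columns(df, _BEHAVIOR_COLUMNS, path)
    trials = []
    for row in df.itertuples(index=False):
        resp = None if pd.isna(row.response_ms) else float(row.response_ms)
        trials.append(
            TrialRecord(
                trial_index=int(row.trial_index),
                onset_ms=float(row.onset_ms),
                response_ms=resp,
            )
        )
    first = df.iloc[0]
    condition = StimulusCondition(
        modality=str(first["modality"]),
        frequency_hz=float(first["frequency_hz"]),
        amplitude_mw=float(first["amplitude_mw"]),
        duty_cycle=float(first["duty_cycle"]),
        stim_duration_ms=float(first["stim_duration_ms"]),
    )
    return BehavioralSession(
        animal_id=animal_id, session_id=session_id,
        trials=tuple(trials), condition=condition,
    )


def write_behavior_log(session: BehavioralSession, path) -> Path:
    path = Path(path)
    c = session.condition
    rows = [
        {
            "trial_index": t.trial_index,
            "onset_ms": t.onset_ms,
            "response_ms": "" if t.response_ms is None else repr(t.response_ms),
            "modality": c.modality,
            "frequency_hz": c.frequency_hz,
            "amplitude_mw": c.amplitude_mw,
            "duty_cycle": c.duty_cycle,
            "stim_duration_ms": c.stim_duration_ms,
        }
        for t in session.trials
    ]
    _write_rows(rows, _BEHAVIOR_COLUMNS, path)
    return path


# ------------------------------------------------------------------- spikes


def read_spike_train(unit_path, trials_path=None, unit_id: str = "") -> SpikeTrain:
    """Read one unit's ``spike_time_s`` CSV plus an optional trial table.

    The trial table has columns ``trial_start_s, stim_onset_s,
    stim_offset_s, frequency_hz``, one row per trial.
    """
    unit_path = Path(unit_path)
    df = pd.read_csv(unit_path, encoding="utf-8")
    _require_columns(df, ["spike_time_s"], unit_path)
    times = df["spike_time_s"].to_numpy(dtype=float)
    epochs: tuple[EpochSpec, ...] = ()
    if trials_path is not None:
        trials_path = Path(trials_path)
        tdf = pd.read_csv(trials_path, encoding="utf-8")
        _require_columns(
            tdf,
            ["trial_start_s", "stim_onset_s", "stim_offset_s", "frequency_hz"],
            trials_path,
        )
        epochs = tuple(
            EpochSpec(float(r.trial_start_s), float(r.stim_onset_s),
                      float(r.stim_offset_s), float(r.frequency_hz))
            for r in tdf.itertuples(index=False)
        )
    return SpikeTrain(
        unit_id=unit_id or unit_path.stem, spike_times_s=times, trials=epochs
    )


def write_spike_train(train: SpikeTrain, unit_path, trials_path=None) -> Path:
    unit_path = Path(unit_path)
    rows = [{"spike_time_s": float(t)} for t in train.spike_times_s]
    _write_rows(rows, ["spike_time_s"], unit_path)
    if trials_path is not None:
        trows = [
            {
                "trial_start_s": e.trial_start_s,
                "stim_onset_s": e.stim_onset_s,
                "stim_offset_s": e.stim_offset_s,
                "frequency_hz": e.frequency_hz,
            }
            for e in train.trials
        ]
        _write_rows(
            trows,
            ["trial_start_s", "stim_onset_s", "stim_offset_s", "frequency_hz"],
            Path(trials_path),
        )
    return unit_path


# --------------------------------------------------------------------- LFP


def read_lfp_epochs(matrix_path, sidecar_path) -> LFPEpochs:
    """Read the trials x samples matrix (HDF5 dataset ``lfp_uv``) and its
    JSON sidecar ``{fs_hz, t0_ms, site_id, n_trials, n_samples}``.

    A shape mismatch between the sidecar and the matrix raises FormatError.
    Values are preserved to full float64 precision.
    """
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
    for key in ("fs_hz", "t0_ms"):
        if key not in meta:
            raise FormatError(f"{sidecar_path}: sidecar missing key {key!r}")
    with h5py.File(matrix_path, "r") as f:
        if "lfp_uv" not in f:
            raise FormatError(f"{matrix_path}: missing dataset 'lfp_uv'")
        data = f["lfp_uv"][...]
    if "n_trials" in meta or "n_samples" in meta:
        declared = (meta.get("n_trials", data.shape[0]),
                    meta.get("n_samples", data.shape[1]))
        if tuple(data.shape) != tuple(declared):
            raise FormatError(
                f"{matrix_path}: shape {data.shape} != sidecar-declared {declared}"
            )
    return LFPEpochs(
        data=data,
        fs_hz=float(meta["fs_hz"]),
        t0_ms=float(meta["t0_ms"]),
        site_id=str(meta.get("site_id", "")),
    )


def write_lfp_epochs(epochs: LFPEpochs, matrix_path, sidecar_path) -> Path:
    matrix_path = Path(matrix_path)
    with h5py.File(matrix_path, "w") as f:
        f.create_dataset("lfp_uv", data=np.asarray(epochs.data, dtype=np.float64))
    meta = {
        "fs_hz": epochs.fs_hz,
        "t0_ms": epochs.t0_ms,
        "site_id": epochs.site_id,
        "n_trials": epochs.n_trials,
        "n_samples": epochs.n_samples,
    }
    Path(sidecar_path).write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return matrix_path


# ------------------------------------------------------------------ tables


def _format_cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))  # shortest round-trip repr: bit-stable
    return str(v)


def _write_rows(rows, columns, path: Path) -> None:
    lines = [",".join(columns)]
    for row in rows:
        lines.append(",".join(_format_cell(row[c]) for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_results_table(records: list[dict], path, columns=None) -> Path:
    """Write keyed metric rows as deterministic, full-precision CSV.

    Column order is the key order of the first record (or ``columns`` when
    given); all records must share exactly the same keys. An empty record
    list yields a header-only file. Identical inputs produce byte-identical
    files.
    """
    path = Path(path)
    if not records:
        path.write_text(",".join(columns or []) + "\n", encoding="utf-8")
        return path
    columns = list(columns) if columns is not None else list(records[0].keys())
    keyset = set(columns)
    for i, r in enumerate(records):
        if set(r.keys()) != keyset:
            raise ValidationError(f"record {i} keys differ from the first record")
    _write_rows(records, columns, path)
    return path
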