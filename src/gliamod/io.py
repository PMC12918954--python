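"""Recording and table I/O.

Units are fixed package-wide: voltage in mV, current in pA, time in ms,
capacitance in pF.  Derived units follow from these: resistance in GΩ
(mV/pA), conductance in nS (pA/mV), charge in pC (pA·ms / 1000... see
:mod:`gliamod.features`), current density in pA/pF.

On-disk format for recordings is a long-form CSV (columns ``trial``,
``sweep``, ``sample_index``, ``command``, ``recorded``) plus a JSON sidecar
carrying the sampling interval, clamp mode, capacitance, sweep labels and
free-form metadata.  The format is plain text so externally acquired data
can be converted in without binary vendor parsers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Sweep",
    "Recording",
    "read_recording",
    "write_recording",
    "read_table",
    "write_table",
    "RecordingFormatError",
    "SchemaError",
]


class RecordingFormatError(ValueError):
    """Raised for malformed or inconsistent recording files."""


class SchemaError(ValueError):
    """Raised when a table does not match its declared schema."""


@dataclass
class Sweep:
    """A single time-aligned command/recorded pair.

    In current clamp (mode ``"CC"``) the command is injected current (pA)
    and the recorded signal is membrane voltage (mV); in voltage clamp
    (mode ``"VC"``) the command is voltage (mV) and the recorded signal is
    membrane current (pA).
    """

    dt: float
    command: np.ndarray
    recorded: np.ndarray
    mode: str
    label: str = ""

    def __post_init__(self) -> None:
        self.command = np.asarray(self.command, dtype=float)
        self.recorded = np.asarray(self.recorded, dtype=float)
        if self.dt <= 0:
            raise RecordingFormatError(f"dt must be positive, got {self.dt}")
        if self.mode not in ("CC", "VC"):
            raise RecordingFormatError(f"mode must be 'CC' or 'VC', got {self.mode!r}")
        if self.command.shape != self.recorded.shape or self.command.ndim != 1:
            raise RecordingFormatError("command and recorded must be equal-length 1-D arrays")
        if len(self.command) < 2:
            raise RecordingFormatError(
                f"sweep must have at least 2 samples, got {len(self.command)}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.command)

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(self.n_samples) * self.dt

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sweep):
            return NotImplemented
        return (
            self.dt == other.dt
            and self.mode == other.mode
            and self.label == other.label
            and np.array_equal(self.command, other.command)
            and np.array_equal(self.recorded, other.recorded)
        )


@dataclass
class Recording:
    """An ordered set of sweeps grouped by trial.

    ``trials`` is a list of trials; each trial is a list of :class:`Sweep`
    (one per stimulus in the protocol, e.g. one per test potential in a
    step family).  All sweeps share the sampling interval and clamp mode,
    and every trial presents the same sweep labels in the same order.
    """

    trials: list[list[Sweep]]
    capacitance: float
    rmp_measured: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise RecordingFormatError(f"capacitance must be positive, got {self.capacitance}")
        if len(self.trials) < 1 or any(len(t) < 1 for t in self.trials):
            raise RecordingFormatError("recording must contain at least one non-empty trial")
        ref = self.trials[0]
        labels = [s.label for s in ref]
        for trial in self.trials:
            if [s.label for s in trial] != labels:
                raise RecordingFormatError("all trials must share the same sweep labels")
            for s in trial:
                if s.dt != ref[0].dt or s.mode != ref[0].mode:
                    raise RecordingFormatError("all sweeps must share dt and mode")

    @property
    def dt(self) -> float:
        return self.trials[0][0].dt

    @property
    def mode(self) -> str:
        return self.trials[0][0].mode

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_sweeps(self) -> int:
        """Number of sweeps per trial."""
        return len(self.trials[0])

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.trials[0]]

    def trial_mean(self) -> list[Sweep]:
        """Average recorded signals pointwise across trials, per sweep slot."""
        out = []
        for j, ref in enumerate(self.trials[0]):
            rec = np.mean([t[j].recorded for t in self.trials], axis=0)
            out.append(Sweep(ref.dt, ref.command.copy(), rec, ref.mode, ref.label))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.capacitance == other.capacitance
            and self.rmp_measured == other.rmp_measured
            and self.metadata == other.metadata
            and len(self.trials) == len(other.trials)
            and all(
                len(a) == len(b) and all(x == y for x, y in zip(a, b))
                for a, b in zip(self.trials, other.trials)
            )
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as long-form CSV plus JSON sidecar.

    The round trip through :func:`read_recording` is lossless: floats are
    serialised with ``repr`` precision (17 significant digits).
    """
    path = Path(path)
    rows = []
    for i, trial in enumerate(rec.trials):
        for j, sweep in enumerate(trial):
            n = sweep.n_samples
            rows.append(
                pd.DataFrame(
                    {
                        "trial": np.full(n, i, dtype=int),
                        "sweep": np.full(n, j, dtype=int),
                        "sample_index": np.arange(n),
                        "command": sweep.command,
                        "recorded": sweep.recorded,
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "dt": rec.dt,
        "mode": rec.mode,
        "capacitance": rec.capacitance,
        "rmp_measured": rec.rmp_measured,
        "labels": rec.labels,
        "metadata": rec.metadata,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise RecordingFormatError(f"missing sidecar file {sidecar_path}")
    with open(sidecar_path) as fh:
        try:
            sidecar = json.load(fh)
        except json.JSONDecodeError as exc:
            raise RecordingFormatError(f"malformed sidecar JSON: {exc}") from exc
    for key in ("dt", "mode", "capacitance", "labels"):
        if key not in sidecar:
            raise RecordingFormatError(f"sidecar missing required key {key!r}")
    dt = sidecar["dt"]
    if not isinstance(dt, (int, float)) or dt <= 0:
        raise RecordingFormatError(f"sidecar dt must be a positive number, got {dt!r}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise RecordingFormatError(f"malformed CSV: {exc}") from exc
    required = {"trial", "sweep", "sample_index", "command", "recorded"}
    if not required.issubset(df.columns):
        raise RecordingFormatError(f"CSV missing columns {sorted(required - set(df.columns))}")
    labels = sidecar["labels"]
    trials: list[list[Sweep]] = []
    expected_len: int | None = None
    for i in sorted(df["trial"].unique()):
        tdf = df[df["trial"] == i]
        sweeps = []
        sweep_ids = sorted(tdf["sweep"].unique())
        if len(sweep_ids) != len(labels):
            raise RecordingFormatError(
                f"trial {i} has {len(sweep_ids)} sweeps, sidecar lists {len(labels)} labels"
            )
        for j in sweep_ids:
            sdf = tdf[tdf["sweep"] == j].sort_values("sample_index")
            if expected_len is None:
                expected_len = len(sdf)
            elif len(sdf) != expected_len:
                raise RecordingFormatError(
                    f"inconsistent sweep lengths: expected {expected_len}, "
                    f"trial {i} sweep {j} has {len(sdf)}"
                )
            sweeps.append(
                Sweep(
                    dt=float(dt),
                    command=sdf["command"].to_numpy(),
                    recorded=sdf["recorded"].to_numpy(),
                    mode=sidecar["mode"],
                    label=labels[int(j)],
                )
            )
        trials.append(sweeps)
    return Recording(
        trials=trials,
        capacitance=sidecar["capacitance"],
        rmp_measured=sidecar.get("rmp_measured"),
        metadata=sidecar.get("metadata", {}),
    )


def read_table(path: str | Path, schema: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a TSV table, checking required columns and their types.

    ``schema`` maps required column names to ``float``, ``int`` or ``str``.
    Unknown columns are preserved untouched.  An empty data section yields
    an empty frame with the header's columns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        for col, typ in schema.items():
            if typ in (float, int):
                try:
                    df[col] = df[col].astype(float if typ is float else int)
                except (ValueError, TypeError) as exc:
                    raise SchemaError(f"column {col!r} is not numeric: {exc}") from exc
            else:
                df[col] = df[col].astype(str) if len(df) else df[col]
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV with stable column order (as given)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
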