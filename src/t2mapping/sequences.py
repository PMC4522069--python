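"""Echo-time schedules and the noiseless monoexponential decay model.

Three sequence designs are supported, each defined purely by how it samples
the transverse-relaxation decay curve:

* ``MESE``  — multi-echo spin echo, 9 echoes, TE1 = 12 ms, dTE = 5.8 ms
  (the reference sequence);
* ``GraSE`` — gradient spin echo, 9 echoes, TE1 = 15 ms, dTE = 7.7 ms;
* ``T2prep`` — T2-prepared balanced SSFP with preparation times
  0, 25, 50, 75 ms (the t = 0 point is an ordinary sample of the curve).

All times are milliseconds, stored as floats; no other unit appears
anywhere in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SEQUENCE_DEFAULTS",
    "EchoSchedule",
    "DecayParams",
    "build_schedule",
    "decay_signal",
]

#: Per-sequence defaults: (TE1 ms, echo spacing ms, number of echoes).
#: T2prep is defined by an explicit preparation-time list instead.
SEQUENCE_DEFAULTS: dict[str, tuple[float, float, int]] = {
    "MESE": (12.0, 5.8, 9),
    "GraSE": (15.0, 7.7, 9),
}

T2PREP_TIMES: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0)

_KNOWN_SEQUENCES = ("MESE", "GraSE", "T2prep")


class UnknownSequenceError(ValueError):
    """Raised for a sequence name outside {MESE, GraSE, T2prep}."""


@dataclass(frozen=True)
class EchoSchedule:
    """Ordered echo / preparation times (ms) of one T2-weighting series.

    Parameters
    ----------
    sequence_name
        One of ``"MESE"``, ``"GraSE"``, ``"T2prep"``.
    times
        Strictly increasing, non-negative echo times in milliseconds.
    """

    sequence_name: str
    times: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.sequence_name not in _KNOWN_SEQUENCES:
            raise UnknownSequenceError(
                f"unknown sequence {self.sequence_name!r}; "
                f"expected one of {_KNOWN_SEQUENCES}"
            )
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        arr = np.asarray(times, dtype=float)
        if arr.size < 2:
            raise ValueError("a schedule needs at least 2 echo times")
        if np.any(arr < 0):
            raise ValueError("echo times must be >= 0")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("echo times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    # --- JSON sidecar round trip -------------------------------------
    def to_json_dict(self) -> dict:
        return {"sequence": self.sequence_name, "times_ms": list(self.times)}

    @classmethod
    def from_json_dict(cls, d: dict) -> "EchoSchedule":
        try:
            name = d["sequence"]
            times = d["times_ms"]
        except KeyError as exc:
            raise ValueError(f"sidecar missing required key {exc}") from exc
        return cls(sequence_name=name, times=tuple(times))

    def write_sidecar(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    @classmethod
    def read_sidecar(cls, path: str | Path) -> "EchoSchedule":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"sidecar not found: {path}")
        return cls.from_json_dict(json.loads(path.read_text()))


@dataclass(frozen=True)
class DecayParams:
    """Parameters of one pixel's monoexponential decay S(t) = S0*exp(-t/T2).

    ``t1`` is carried for the synthetic-data generator's T1 shine-through
    hook only; the pure decay model never reads it.
    """

    s0: float
    t2: float
    t1: float = 1000.0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError(f"S0 must be > 0, got {self.s0}")
        if self.t2 <= 0:
            raise ValueError(f"T2 must be > 0, got {self.t2}")
        if self.t1 <= 0:
            raise ValueError(f"T1 must be > 0, got {self.t1}")


def build_schedule(
    sequence_name: str,
    te1: float | None = None,
    delta_te: float | None = None,
    n_echoes: int | None = None,
) -> EchoSchedule:
    """Build the echo-time schedule of a named sequence.

    For MESE and GraSE the times form the arithmetic progression
    ``te1 + k*delta_te``, ``k = 0..n_echoes-1``; defaults are the
    sequences' protocol values.  For T2prep the preparation-time list
    {0, 25, 50, 75} ms is returned and ``te1``/``delta_te``/``n_echoes``
    are ignored.
    """
    if sequence_name == "T2prep":
        return EchoSchedule("T2prep", T2PREP_TIMES)
    if sequence_name not in SEQUENCE_DEFAULTS:
        raise UnknownSequenceError(
            f"unknown sequence {sequence_name!r}; expected one of {_KNOWN_SEQUENCES}"
        )
    d_te1, d_dte, d_n = SEQUENCE_DEFAULTS[sequence_name]
    te1 = d_te1 if te1 is None else float(te1)
    delta_te = d_dte if delta_te is None else float(delta_te)
    n_echoes = d_n if n_echoes is None else int(n_echoes)
    if n_echoes < 2:
        raise ValueError("n_echoes must be >= 2")
    if te1 < 0:
        raise ValueError("te1 must be >= 0")
    if delta_te <= 0:
        raise ValueError("delta_te must be > 0")
    times = te1 + delta_te * np.arange(n_echoes, dtype=float)
    return EchoSchedule(sequence_name, tuple(times))


def decay_signal(
    params: DecayParams, schedule: EchoSchedule | Sequence[float]
) -> np.ndarray:
    """Noiseless magnitude S0*exp(-t/T2) at each scheduled time.

    Returns a float vector aligned with ``schedule.times``; strictly
    positive and non-increasing in t.
    """
    times = (
        schedule.times_array
        if isinstance(schedule, EchoSchedule)
        else np.asarray(schedule, dtype=float)
    )
    return params.s0 * np.exp(-times / params.t2)
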