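"""Data model and on-disk formats for photometry sessions, cohorts and behavior logs.

A recording session carries two aligned fluorescence streams: the 465 nm
calcium-dependent channel (GCaMP) and the 405 nm isosbestic control, plus the
stimulus-onset timestamps and the design labels (sex, treatment, timepoint,
stimulus kind) needed to place the session in the cohort grid.

Two interchange dialects are supported:

* ``csv`` — a plain delimited file with columns ``time_s,f465,f405`` and a JSON
  sidecar (same path, ``.json`` extension) holding the design labels, sampling
  metadata and stimulus events.  Portable and diffable; the canonical format.
* ``container`` — a single HDF5 file per session, for scale.

Times are in seconds relative to an arbitrary session clock; ``event_times``
refer to stimulus *onset*.  All downstream peri-event windows are half-open
``[onset - pre, onset + post)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "TREATMENTS",
    "TIMEPOINTS",
    "STIMULUS_KINDS",
    "HEMISPHERES",
    "BEHAVIORS",
    "ValidationError",
    "SessionFormatError",
    "RawSession",
    "BehaviorLog",
    "CohortManifest",
    "read_session",
    "write_session",
    "read_behavior_log",
    "write_behavior_log",
    "read_manifest",
]

SEXES = frozenset({"female", "male"})
TREATMENTS = frozenset({"vehicle", "psilocin"})
TIMEPOINTS = (
    "baseline",
    "injection",
    "day2",
    "day6",
    "day28",
    "auditory_initial",
    "auditory_final",
)
STIMULUS_KINDS = frozenset({"air_puff", "auditory_only"})
HEMISPHERES = frozenset({"left", "right", "unspecified"})
BEHAVIORS = frozenset({"walking", "rearing", "darting", "immobile"})


class ValidationError(ValueError):
    """A structurally well-formed input violates a domain invariant."""


class SessionFormatError(ValueError):
    """A file does not match the declared dialect (missing field/column...)."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class RawSession:
    """One two-channel recording with stimulus timestamps and design labels.

    ``hemisphere`` is carried as metadata only; it never enters computation
    (the original hemisphere choice from baseline signal quality is not
    reproducible from the data model).
    """

    subject_id: str
    sex: str
    treatment: str
    timepoint: str
    stimulus_kind: str
    sampling_rate: float
    t0: float
    signal_465: np.ndarray
    signal_405: np.ndarray
    event_times: np.ndarray
    hemisphere: str = "unspecified"
    # Air-puff sessions carry exactly two puffs (5 min ISI) by design; set
    # False to admit sessions with a different event count.
    enforce_event_count: bool = field(default=True, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.signal_465 = _as_float_array(self.signal_465, "signal_465")
        self.signal_405 = _as_float_array(self.signal_405, "signal_405")
        self.event_times = _as_float_array(self.event_times, "event_times")
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.signal_465.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample timestamps ``t0 + i / fs``."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.stimulus_kind not in STIMULUS_KINDS:
            raise ValidationError(f"unknown stimulus_kind {self.stimulus_kind!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"unknown hemisphere {self.hemisphere!r}")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.signal_465.size != self.signal_405.size:
            raise ValidationError(
                "channel length mismatch: "
                f"signal_465 has {self.signal_465.size} samples, "
                f"signal_405 has {self.signal_405.size}"
            )
        if self.signal_465.size < 2:
            raise ValidationError("signals must contain at least 2 samples")
        t_end = self.t0 + self.n_samples / self.sampling_rate
        for t in self.event_times:
            if not (self.t0 <= t < t_end):
                raise ValidationError(
                    f"event at {t} s outside recording [{self.t0}, {t_end}) s"
                )
        if np.any(np.diff(self.event_times) <= 0):
            raise ValidationError("event_times must be strictly increasing")
        if (
            self.enforce_event_count
            and self.stimulus_kind == "air_puff"
            and self.event_times.size != 2
        ):
            raise ValidationError(
                f"air_puff session carries {self.event_times.size} events, "
                "expected exactly 2 (pass enforce_event_count=False to override)"
            )

    def __eq__(self, other) -> bool:  # array-valued fields need elementwise compare
        if not isinstance(other, RawSession):
            return NotImplemented
        for f in fields(self):
            if not f.compare:
                continue
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, np.ndarray):
                if not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return True


@dataclass
class BehaviorLog:
    """Timestamped state events for one subject at one timepoint.

    Events are ``(behavior, start_s, stop_s)`` bouts scored upstream from
    video (BORIS-style export); behaviors are walking, rearing, darting and
    immobile.
    """

    subject_id: str
    timepoint: str
    events: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        by_behavior: dict[str, list[tuple[float, float]]] = {}
        for behavior, start, stop in self.events:
            if behavior not in BEHAVIORS:
                raise ValidationError(f"unknown behavior label {behavior!r}")
            if stop < start:
                raise ValidationError(
                    f"{behavior} bout has stop {stop} s < start {start} s"
                )
            by_behavior.setdefault(behavior, []).append((float(start), float(stop)))
        for behavior, bouts in by_behavior.items():
            bouts.sort()
            for (s0, e0), (s1, _e1) in zip(bouts, bouts[1:]):
                if s1 < e0:
                    raise ValidationError(
                        f"overlapping {behavior} bouts at {s0}-{e0} and {s1}- s"
                    )

    def bouts(self, behavior: str) -> list[tuple[float, float]]:
        return [(s, e) for b, s, e in self.events if b == behavior]


MANIFEST_COLUMNS = (
    "subject_id",
    "sex",
    "treatment",
    "timepoint",
    "stimulus_kind",
    "session_path",
    "behavior_path",
)


@dataclass
class CohortManifest:
    """The sex x treatment x timepoint grid of sessions on disk."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise SessionFormatError(f"manifest missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        t = self.table
        dup = t.duplicated(subset=["subject_id", "timepoint"])
        if dup.any():
            rows = t.loc[dup, ["subject_id", "timepoint"]].to_records(index=False)
            raise ValidationError(f"duplicate subject within timepoint: {list(rows)}")
        grouped = t.groupby("subject_id")[["sex", "treatment"]].nunique()
        bad = grouped[(grouped > 1).any(axis=1)]
        if len(bad):
            raise ValidationError(
                f"inconsistent sex/treatment across timepoints for {list(bad.index)}"
            )

    def subjects(self) -> list[str]:
        return sorted(self.table["subject_id"].unique())

    def select(self, **labels) -> pd.DataFrame:
        out = self.table
        for key, val in labels.items():
            out = out[out[key] == val]
        return out


# ---------------------------------------------------------------------------
# Session readers / writers
# ---------------------------------------------------------------------------

_META_KEYS = (
    "subject_id",
    "sex",
    "treatment",
    "timepoint",
    "stimulus_kind",
    "hemisphere",
    "sampling_rate",
    "t0",
)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_session(path, format: str = "csv", enforce_event_count: bool = True) -> RawSession:
    """Read and validate one session in the given dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_session_csv(path, enforce_event_count)
    if format == "container":
        return _read_session_container(path, enforce_event_count)
    raise ValueError(f"unknown session format {format!r}")


def write_session(session: RawSession, path, format: str = "csv") -> None:
    """Write a session so that :func:`read_session` round-trips every field."""
    path = Path(path)
    if format == "csv":
        _write_session_csv(session, path)
    elif format == "container":
        _write_session_container(session, path)
    else:
        raise ValueError(f"unknown session format {format!r}")


def _read_session_csv(path: Path, enforce_event_count: bool) -> RawSession:
    df = pd.read_csv(path)
    for col in ("time_s", "f465", "f405"):
        if col not in df.columns:
            raise SessionFormatError(f"session CSV {path} missing column {col!r}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SessionFormatError(f"missing events/metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _META_KEYS + ("events",):
        if key not in meta:
            raise SessionFormatError(f"sidecar {sidecar} missing field {key!r}")
    events = [ev["time_s"] for ev in meta["events"]]
    return RawSession(
        subject_id=meta["subject_id"],
        sex=meta["sex"],
        treatment=meta["treatment"],
        timepoint=meta["timepoint"],
        stimulus_kind=meta["stimulus_kind"],
        hemisphere=meta["hemisphere"],
        sampling_rate=float(meta["sampling_rate"]),
        t0=float(meta["t0"]),
        signal_465=df["f465"].to_numpy(),
        signal_405=df["f405"].to_numpy(),
        event_times=np.asarray(events, dtype=float),
        enforce_event_count=enforce_event_count,
    )


def _write_session_csv(session: RawSession, path: Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": session.times(),
            "f465": session.signal_465,
            "f405": session.signal_405,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {key: getattr(session, key) for key in _META_KEYS}
    meta["events"] = [
        {"time_s": float(t), "kind": session.stimulus_kind}
        for t in session.event_times
    ]
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_session_container(path: Path, enforce_event_count: bool) -> RawSession:
    with h5py.File(path, "r") as h5:
        for name in ("signal_465", "signal_405", "event_times"):
            if name not in h5:
                raise SessionFormatError(f"container {path} missing dataset {name!r}")
        missing = [k for k in _META_KEYS if k not in h5.attrs]
        if missing:
            raise SessionFormatError(f"container {path} missing attrs {missing}")
        kwargs = {k: h5.attrs[k] for k in _META_KEYS}
        kwargs["sampling_rate"] = float(kwargs["sampling_rate"])
        kwargs["t0"] = float(kwargs["t0"])
        return RawSession(
            signal_465=h5["signal_465"][:],
            signal_405=h5["signal_405"][:],
            event_times=h5["event_times"][:],
            enforce_event_count=enforce_event_count,
            **kwargs,
        )


def _write_session_container(session: RawSession, path: Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("signal_465", data=session.signal_465)
        h5.create_dataset("signal_405", data=session.signal_405)
        h5.create_dataset("event_times", data=session.event_times)
        for key in _META_KEYS:
            value = getattr(session, key)
            h5.attrs[key] = value if isinstance(value, (int, float)) else str(value)


# ---------------------------------------------------------------------------
# Behavior logs and manifests
# ---------------------------------------------------------------------------


def read_behavior_log(path, timepoint: str = "baseline") -> BehaviorLog:
    """Read a BORIS-style tabular export ``subject_id,behavior,start_s,stop_s``.

    The file holds one subject; a ``timepoint`` column overrides the argument.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("subject_id", "behavior", "start_s", "stop_s"):
        if col not in df.columns:
            raise SessionFormatError(f"behavior log {path} missing column {col!r}")
    subjects = df["subject_id"].unique()
    if len(subjects) != 1:
        raise SessionFormatError(
            f"behavior log {path} must hold one subject, found {list(subjects)}"
        )
    if "timepoint" in df.columns:
        tps = df["timepoint"].unique()
        if len(tps) != 1:
            raise SessionFormatError(f"behavior log {path} mixes timepoints {list(tps)}")
        timepoint = tps[0]
    events = [
        (row.behavior, float(row.start_s), float(row.stop_s))
        for row in df.itertuples()
    ]
    return BehaviorLog(subject_id=str(subjects[0]), timepoint=timepoint, events=events)


def write_behavior_log(log: BehaviorLog, path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": log.subject_id,
                "timepoint": log.timepoint,
                "behavior": b,
                "start_s": s,
                "stop_s": e,
            }
            for b, s, e in log.events
        ],
        columns=["subject_id", "timepoint", "behavior", "start_s", "stop_s"],
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_manifest(path) -> CohortManifest:
    df = pd.read_csv(Path(path))
    return CohortManifest(df)


def load_cohort(manifest: CohortManifest, root: Path | None = None, format: str = "csv",
                **select) -> list[RawSession]:
    """Read every session the manifest rows (optionally filtered) point at."""
    rows = manifest.select(**select) if select else manifest.table
    sessions = []
    for row in rows.itertuples():
        p = Path(row.session_path)
        if root is not None and not p.is_absolute():
            p = Path(root) / p
        sessions.append(read_session(p, format=format))
    return sessions
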