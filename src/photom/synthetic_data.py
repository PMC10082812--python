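"""Synthetic two-channel photometry sessions and cohorts with known ground truth.

The generator emulates the structure of an air-puff reactivity study so every
pipeline stage is testable without recorded data:

* a double-exponential photobleaching baseline *shared* across channels
  (channel-specific scale), steepest early in the session;
* motion artifacts: sparse transients added to both channels with
  channel-specific gains — exactly the shared component the isosbestic
  regression is able to remove;
* a true fractional calcium signal ``dff_true`` built from bi-exponential
  transients: stimulus-evoked responses (unit-peak waveform, so programmed
  amplitudes are in dF/F units) plus spontaneous events;
* additive white noise per channel;
* cohort-level effect programming: per-(sex, treatment, timepoint) evoked
  amplitude multipliers, per-subject random effects, and active/passive
  threat-responder proportions driving the behavior logs.

Channels are assembled as::

    f405 = F0_405 + s405 * B(t) + g405 * motion(t) + noise
    f465 = F0_465 * (1 + dff_true(t)) + s465 * B(t) + g465 * motion(t) + noise

Everything is deterministic given the seed; cohort files written twice with
the same parameters and seed are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .session_io import (
    BehaviorLog,
    CohortManifest,
    RawSession,
    write_behavior_log,
    write_session,
)

__all__ = [
    "SignalParams",
    "EffectSpec",
    "GroundTruth",
    "CohortData",
    "DEFAULT_GROUP_SIZES",
    "AIR_PUFF_TIMEPOINTS",
    "air_puff_events",
    "auditory_events",
    "biexp_kernel",
    "simulate_session",
    "simulate_cohort",
]

#: study group sizes: (sex, treatment) -> n subjects
DEFAULT_GROUP_SIZES = {
    ("female", "vehicle"): 9,
    ("female", "psilocin"): 7,
    ("male", "vehicle"): 10,
    ("male", "psilocin"): 11,
}

AIR_PUFF_TIMEPOINTS = ("baseline", "injection", "day2", "day6", "day28")


def air_puff_events(habituation_s: float = 600.0, isi_s: float = 300.0,
                    first_offset_s: float = 30.0, tail_s: float = 30.0):
    """Default air-puff session: 10 min habituation, two puffs, 5 min ISI.

    Returns ``(event_times, duration_s)``.
    """
    first = habituation_s + first_offset_s
    events = [first, first + isi_s]
    return events, events[-1] + tail_s


def auditory_events(habituation_s: float = 600.0, isi_s: float = 180.0,
                    first_offset_s: float = 30.0, tail_s: float = 30.0):
    """Auditory-only session: same template with a 3 min ISI."""
    return air_puff_events(habituation_s, isi_s, first_offset_s, tail_s)


@dataclass(frozen=True)
class SignalParams:
    """Signal model parameters; defaults emulate a GCaMP7f air-puff session."""

    fs: float = 200.0                      # raw sampling rate, Hz
    duration_s: float = 960.0
    # shared bleaching shape A1*exp(-t/tau1) + A2*exp(-t/tau2), channel scales;
    # time constants chosen so most bleaching happens during habituation
    bleach: tuple[float, float, float, float] = (20.0, 60.0, 8.0, 300.0)
    bleach_scale_465: float = 1.0
    bleach_scale_405: float = 0.8
    baseline_465: float = 100.0            # F0, a.u.
    baseline_405: float = 80.0
    # motion artifacts: Poisson rate, amplitude sd (a.u.), channel gains,
    # and waveform time constants (slow, fiber-bending-like)
    motion_rate: float = 0.02
    motion_amplitude: float = 5.0
    motion_gain_465: float = 1.0
    motion_gain_405: float = 0.8
    motion_rise_s: float = 0.1
    motion_decay_s: float = 2.0
    # bi-exponential calcium transient kernel (unit peak)
    transient_rise_s: float = 0.05
    transient_decay_s: float = 0.5
    # stimulus-evoked response: peak dF/F, onset latency, latency jitter,
    # sustained duration (the underlying drive lasts this long)
    evoked_amplitude: float = 0.05
    evoked_latency_s: float = 0.1
    evoked_jitter_s: float = 0.02
    evoked_duration_s: float = 8.0
    # spontaneous transients
    spontaneous_rate: float = 0.05         # events / s
    spontaneous_amplitude: float = 0.015   # mean dF/F (exponential)
    noise_sd: float = 0.3                  # a.u., per channel
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        for name in ("motion_rate", "motion_amplitude", "transient_rise_s",
                     "transient_decay_s", "evoked_jitter_s", "evoked_duration_s",
                     "spontaneous_rate", "spontaneous_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class EffectSpec:
    """Cohort-level effect programming.

    ``amplitude_multiplier`` scales the evoked dF/F amplitude per
    (sex, treatment, timepoint); unlisted cells default to 1.  The default
    encodes the study's directional findings: an acute evoked increase in
    psilocin-treated females and a persistent decrease in psilocin-treated
    males at the 2/6/28-day follow-ups.  ``subject_sd`` is the s.d. of a
    log-normal per-subject amplitude multiplier (a stable subject trait).
    ``active_probability`` gives the chance a subject is an active (darting)
    threat responder, per (sex, treatment).
    """

    amplitude_multiplier: dict = field(default_factory=lambda: {
        ("female", "psilocin", "injection"): 2.0,
        ("female", "psilocin", "day2"): 1.3,
        ("male", "psilocin", "day2"): 0.4,
        ("male", "psilocin", "day6"): 0.4,
        ("male", "psilocin", "day28"): 0.4,
    })
    subject_sd: float = 0.15
    active_probability: dict = field(default_factory=lambda: {
        ("female", "vehicle"): 0.8,
        ("female", "psilocin"): 0.8,
        ("male", "vehicle"): 0.5,
        ("male", "psilocin"): 0.5,
    })

    def multiplier(self, sex: str, treatment: str, timepoint: str) -> float:
        return float(self.amplitude_multiplier.get((sex, treatment, timepoint), 1.0))

    def p_active(self, sex: str, treatment: str) -> float:
        return float(self.active_probability.get((sex, treatment), 0.5))


@dataclass
class GroundTruth:
    """What the generator actually injected, at the raw sampling rate."""

    dff_true: np.ndarray
    motion: np.ndarray
    evoked_amplitudes: np.ndarray  # per stimulus event (peak dF/F)
    evoked_onsets: np.ndarray      # absolute seconds (latency + jitter applied)


@dataclass
class CohortData:
    """An in-memory simulated cohort plus its ground-truth table."""

    sessions: list[RawSession]
    ground_truths: list[GroundTruth]
    behavior_logs: list[BehaviorLog]
    responder: dict[str, bool]  # subject_id -> active responder
    truth_table: pd.DataFrame   # one row per session with programmed amplitudes


def biexp_kernel(rise_s: float, decay_s: float, fs: float,
                 length_s: float | None = None) -> np.ndarray:
    """Unit-peak bi-exponential transient ``exp(-t/decay) - exp(-t/rise)``."""
    if decay_s <= 0:
        raise ValueError("decay must be positive")
    length_s = length_s if length_s is not None else 8.0 * decay_s
    t = np.arange(max(2, round(length_s * fs))) / fs
    if rise_s <= 0:
        k = np.exp(-t / decay_s)
    else:
        k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (rise >= decay?)")
    return k / peak


def _evoked_waveform(params: SignalParams) -> np.ndarray:
    """Unit-peak evoked response: transient kernel x sustained decaying drive.

    The underlying drive declines exponentially (time constant = duration)
    and stops at ``evoked_duration_s``; convolving with the transient kernel
    gives a fast rise, a distinct early peak, and a sustained tail — the
    shape of an aversive-stimulus response that outlasts the stimulus itself.
    """
    k = biexp_kernel(params.transient_rise_s, params.transient_decay_s, params.fs)
    n_drive = max(1, round(params.evoked_duration_s * params.fs))
    t = np.arange(n_drive) / params.fs
    drive = np.exp(-t / params.evoked_duration_s) if params.evoked_duration_s > 0 \
        else np.ones(1)
    w = fftconvolve(k, drive)
    return w / w.max()


def _impulse_train(n: int, fs: float, times: np.ndarray, amps: np.ndarray) -> np.ndarray:
    train = np.zeros(n)
    idx = np.round(np.asarray(times) * fs).astype(int)
    keep = (idx >= 0) & (idx < n)
    np.add.at(train, idx[keep], np.asarray(amps)[keep])
    return train


def simulate_session(
    params: SignalParams,
    events,
    *,
    subject_id: str = "sim",
    sex: str = "female",
    treatment: str = "vehicle",
    timepoint: str = "baseline",
    stimulus_kind: str = "air_puff",
    rng: np.random.Generator | None = None,
) -> tuple[RawSession, GroundTruth]:
    """Generate one session; deterministic given ``params.seed`` (or ``rng``)."""
    events = np.asarray(events, dtype=float)
    if np.any(events < 0) or np.any(events >= params.duration_s):
        raise ValueError("stimulus events must lie inside the session duration")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    fs = params.fs
    n = round(params.duration_s * fs)
    t = np.arange(n) / fs

    a1, tau1, a2, tau2 = params.bleach
    bleach = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)

    # motion artifacts: sparse signed transients, shared waveform
    n_motion = rng.poisson(params.motion_rate * params.duration_s)
    motion_times = rng.uniform(0, params.duration_s, size=n_motion)
    motion_amps = rng.normal(0.0, params.motion_amplitude, size=n_motion)
    motion_kernel = biexp_kernel(params.motion_rise_s, params.motion_decay_s, fs)
    motion = fftconvolve(
        _impulse_train(n, fs, motion_times, motion_amps), motion_kernel
    )[:n]

    # true fractional calcium signal
    evoked_wave = _evoked_waveform(params)
    jitter = rng.normal(0.0, params.evoked_jitter_s, size=events.size)
    onsets = events + params.evoked_latency_s + jitter
    amps = np.full(events.size, params.evoked_amplitude)
    dff_true = fftconvolve(_impulse_train(n, fs, onsets, amps), evoked_wave)[:n]

    n_spont = rng.poisson(params.spontaneous_rate * params.duration_s)
    spont_times = rng.uniform(0, params.duration_s, size=n_spont)
    spont_amps = rng.exponential(params.spontaneous_amplitude, size=n_spont) \
        if params.spontaneous_amplitude > 0 else np.zeros(n_spont)
    spont_kernel = biexp_kernel(params.transient_rise_s, params.transient_decay_s, fs)
    dff_true = dff_true + fftconvolve(
        _impulse_train(n, fs, spont_times, spont_amps), spont_kernel
    )[:n]

    noise465 = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd else 0.0
    noise405 = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd else 0.0

    f465 = (params.baseline_465 * (1.0 + dff_true)
            + params.bleach_scale_465 * bleach
            + params.motion_gain_465 * motion + noise465)
    f405 = (params.baseline_405
            + params.bleach_scale_405 * bleach
            + params.motion_gain_405 * motion + noise405)

    session = RawSession(
        subject_id=subject_id,
        sex=sex,
        treatment=treatment,
        timepoint=timepoint,
        stimulus_kind=stimulus_kind,
        sampling_rate=fs,
        t0=0.0,
        signal_465=f465,
        signal_405=f405,
        event_times=events,
        enforce_event_count=False,
    )
    truth = GroundTruth(
        dff_true=dff_true,
        motion=motion,
        evoked_amplitudes=amps,
        evoked_onsets=onsets,
    )
    return session, truth


def _behavior_log(subject_id: str, timepoint: str, active: bool, puff_times,
                  window_s: float, rng: np.random.Generator) -> BehaviorLog:
    """Active responders dart within 2 s of each puff; passive ones stay immobile."""
    events: list[tuple[str, float, float]] = []
    for puff in puff_times:
        if active:
            onset = puff + rng.uniform(0.0, 2.0)
            events.append(("darting", onset, onset + rng.uniform(0.5, 2.0)))
        else:
            events.append(("immobile", puff, puff + window_s))
    # background locomotion between puffs
    walk_start = rng.uniform(0.0, 5.0)
    events.append(("walking", walk_start, walk_start + rng.uniform(5.0, 20.0)))
    return BehaviorLog(subject_id=subject_id, timepoint=timepoint, events=events)


def simulate_cohort(
    effects: EffectSpec | None = None,
    base: SignalParams | None = None,
    *,
    seed: int = 0,
    group_sizes: dict | None = None,
    timepoints=AIR_PUFF_TIMEPOINTS,
    events=None,
    behavior_window_s: float = 10.0,
    out_dir=None,
) -> CohortData:
    """One session per subject x timepoint with programmed group effects.

    Per-subject log-normal amplitude multipliers persist across timepoints;
    responder type (active/passive) is drawn once per subject.  When
    ``out_dir`` is given the cohort is also written to disk (manifest,
    session CSVs with JSON sidecars, behavior logs, ground_truth.csv).
    """
    effects = effects or EffectSpec()
    base = base or SignalParams()
    group_sizes = group_sizes or DEFAULT_GROUP_SIZES
    if events is None:
        ev, duration = air_puff_events()
        if abs(duration - base.duration_s) > 1e-9:
            base = replace(base, duration_s=duration)
        events = ev
    events = list(np.asarray(events, dtype=float))

    root = np.random.SeedSequence(seed)
    sessions: list[RawSession] = []
    truths: list[GroundTruth] = []
    logs: list[BehaviorLog] = []
    responder: dict[str, bool] = {}
    rows = []

    group_index = {g: j for j, g in enumerate(sorted(group_sizes))}
    for (sex, treatment), n_subj in group_sizes.items():
        for i in range(n_subj):
            subject_id = f"{sex[0]}{treatment[0]}{i:02d}"
            ss = np.random.SeedSequence(
                entropy=root.entropy,
                spawn_key=(group_index[(sex, treatment)], i),
            )
            subj_rng = np.random.default_rng(ss)
            subj_mult = float(np.exp(subj_rng.normal(0.0, effects.subject_sd))) \
                if effects.subject_sd > 0 else 1.0
            active = bool(subj_rng.uniform() < effects.p_active(sex, treatment))
            responder[subject_id] = active
            for timepoint in timepoints:
                mult = effects.multiplier(sex, treatment, timepoint)
                amp = base.evoked_amplitude * mult * subj_mult
                params = replace(base, evoked_amplitude=amp, seed=None)
                session, truth = simulate_session(
                    params, events,
                    subject_id=subject_id, sex=sex, treatment=treatment,
                    timepoint=timepoint, stimulus_kind="air_puff",
                    rng=subj_rng,
                )
                log = _behavior_log(subject_id, timepoint, active, events,
                                    behavior_window_s, subj_rng)
                sessions.append(session)
                truths.append(truth)
                logs.append(log)
                rows.append({
                    "subject_id": subject_id, "sex": sex, "treatment": treatment,
                    "timepoint": timepoint, "programmed_amplitude": amp,
                    "group_multiplier": mult, "subject_multiplier": subj_mult,
                    "active_responder": active,
                })
    truth_table = pd.DataFrame(rows)
    cohort = CohortData(sessions=sessions, ground_truths=truths,
                        behavior_logs=logs, responder=responder,
                        truth_table=truth_table)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir), seed)
    return cohort


def _write_cohort(cohort: CohortData, out_dir: Path, seed: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for session, log in zip(cohort.sessions, cohort.behavior_logs):
        stem = f"{session.subject_id}_{session.timepoint}"
        session_path = out_dir / f"{stem}.csv"
        behavior_path = out_dir / f"{stem}_behavior.csv"
        write_session(session, session_path, format="csv")
        write_behavior_log(log, behavior_path)
        manifest_rows.append({
            "subject_id": session.subject_id,
            "sex": session.sex,
            "treatment": session.treatment,
            "timepoint": session.timepoint,
            "stimulus_kind": session.stimulus_kind,
            "session_path": session_path.name,
            "behavior_path": behavior_path.name,
        })
    manifest = pd.DataFrame(manifest_rows)
    CohortManifest(manifest)  # validate before writing
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    cohort.truth_table.to_csv(out_dir / "ground_truth.csv", index=False,
                              float_format="%.17g")
    (out_dir / "simulation.json").write_text(json.dumps({"seed": seed}, indent=1))
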