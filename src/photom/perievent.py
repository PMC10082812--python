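"""Stimulus-locked windowing, trial averaging, 500 ms binning and summaries.

dF/F is collected in a half-open window, 5 s before to 10 s after each
stimulus onset.  The per-trial segments of a session are averaged pointwise
into one subject mean trace, which is then reduced to 500 ms bins: 10 pre
bins (indices -10..-1) and 20 post bins (0..19), with the onset sample
opening post bin 0.  Baseline normalization subtracts the mean of the 10 pre
bins from every bin, so traces are comparable across sessions with different
basal activity.  Group statistics downstream consume only the 20 post bins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import DffTrace
from .session_io import ValidationError

__all__ = [
    "PeriEventWindow",
    "SubjectMeanTrace",
    "BinnedTrace",
    "SubjectSummary",
    "extract_windows",
    "average_trials",
    "bin_trace",
    "baseline_normalize",
    "summarize_subject",
    "perievent_pipeline",
]


def _is_multiple(a: float, b: float, tol: float = 1e-9) -> bool:
    r = a / b
    return abs(r - round(r)) < tol


@dataclass(frozen=True)
class PeriEventWindow:
    """Analysis window around stimulus onset: 5 s pre, 10 s post, 500 ms bins."""

    pre_s: float = 5.0
    post_s: float = 10.0
    bin_s: float = 0.5

    def __post_init__(self) -> None:
        if min(self.pre_s, self.post_s, self.bin_s) <= 0:
            raise ValueError("pre_s, post_s and bin_s must be positive")
        if not (_is_multiple(self.pre_s, self.bin_s) and _is_multiple(self.post_s, self.bin_s)):
            raise ValueError("pre_s and post_s must be integer multiples of bin_s")

    @property
    def n_pre_bins(self) -> int:
        return round(self.pre_s / self.bin_s)

    @property
    def n_post_bins(self) -> int:
        return round(self.post_s / self.bin_s)

    @property
    def n_bins(self) -> int:
        return self.n_pre_bins + self.n_post_bins


DEFAULT_WINDOW = PeriEventWindow()


@dataclass
class SubjectMeanTrace:
    """Pointwise mean of the per-trial dF/F segments of one subject/session."""

    subject_id: str
    timepoint: str
    fs: float
    trace: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")


@dataclass
class BinnedTrace:
    """Bin means over the peri-event window; 30 bins for the default window.

    ``bins[i]`` for ``i < n_pre`` are the pre-stimulus bins (-n_pre..-1 on
    the conventional axis); ``bins[n_pre + b]`` is post bin ``b``.
    """

    subject_id: str
    timepoint: str
    bins: np.ndarray
    n_pre: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if not 0 < self.n_pre < self.bins.size:
            raise ValidationError("n_pre must split the bins into pre and post")
        if self.normalized:
            pre_mean = self.bins[: self.n_pre].mean()
            # 1e-12 absolute at dF/F scale; relative for larger magnitudes
            tol = 1e-12 * max(1.0, float(np.max(np.abs(self.bins), initial=0.0)))
            if abs(pre_mean) > tol:
                raise ValidationError(
                    f"normalized trace has pre-bin mean {pre_mean:.3g} != 0"
                )

    @property
    def pre(self) -> np.ndarray:
        return self.bins[: self.n_pre]

    @property
    def post(self) -> np.ndarray:
        return self.bins[self.n_pre :]

    def bin_index(self) -> np.ndarray:
        """Conventional axis: -n_pre..-1 then 0..n_post-1."""
        return np.arange(self.bins.size) - self.n_pre


@dataclass(frozen=True)
class SubjectSummary:
    """Peak point (max post bin) and post-stimulus mean of a normalized trace."""

    peak_point: float
    post_mean: float


def extract_windows(
    dff: DffTrace,
    window: PeriEventWindow = DEFAULT_WINDOW,
    on_edge: str = "error",
) -> list[np.ndarray]:
    """One sample-aligned vector per stimulus event.

    Each vector covers ``[onset - pre_s, onset + post_s)`` with the onset at
    index ``round(pre_s * fs)``.  Events without enough history or future
    raise (or are skipped with a warning when ``on_edge="skip"``).
    """
    if on_edge not in {"error", "skip"}:
        raise ValueError("on_edge must be 'error' or 'skip'")
    fs = dff.sampling_rate
    n_pre = round(window.pre_s * fs)
    n_post = round(window.post_s * fs)
    out = []
    for t in dff.event_times:
        onset = round((t - dff.t0) * fs)
        lo, hi = onset - n_pre, onset + n_post
        if lo < 0 or hi > dff.dff.size:
            msg = (
                f"event at {t} s too close to a recording edge for a "
                f"[-{window.pre_s}, +{window.post_s}) s window"
            )
            if on_edge == "error":
                raise ValidationError(msg)
            import warnings

            warnings.warn(msg)
            continue
        out.append(dff.dff[lo:hi].copy())
    return out


def average_trials(trials: list[np.ndarray], subject_id: str = "", timepoint: str = "baseline",
                   fs: float = 1.0) -> SubjectMeanTrace:
    """Pointwise mean across trials (permutation-invariant)."""
    if not trials:
        raise ValidationError("no trials to average")
    lengths = {len(t) for t in trials}
    if len(lengths) != 1:
        raise ValidationError(f"ragged trial lengths {sorted(lengths)}")
    mean = np.mean(np.stack([np.asarray(t, float) for t in trials]), axis=0)
    return SubjectMeanTrace(
        subject_id=subject_id, timepoint=timepoint, fs=fs,
        trace=mean, n_trials=len(trials),
    )


def bin_trace(trace: SubjectMeanTrace, window: PeriEventWindow = DEFAULT_WINDOW) -> BinnedTrace:
    """Reduce a mean trace to bin means.

    Bin ``b`` covers ``[b * bin_s, (b+1) * bin_s)`` relative to the window
    start.  Boundaries are placed at the nearest sample, so when ``bin_s*fs``
    is not an integer the leftover samples go to the nearest bin edge.
    """
    fs = trace.fs
    if window.bin_s * fs < 1:
        raise ValidationError("fewer than one sample per bin")
    n_bins = window.n_bins
    expected = round((window.pre_s + window.post_s) * fs)
    if trace.trace.size != expected:
        raise ValidationError(
            f"trace length {trace.trace.size} inconsistent with window "
            f"({expected} samples at {fs} Hz)"
        )
    edges = np.round(np.arange(n_bins + 1) * window.bin_s * fs).astype(int)
    edges[-1] = trace.trace.size
    bins = np.array([
        trace.trace[edges[b]: edges[b + 1]].mean() for b in range(n_bins)
    ])
    return BinnedTrace(
        subject_id=trace.subject_id,
        timepoint=trace.timepoint,
        bins=bins,
        n_pre=window.n_pre_bins,
        normalized=False,
    )


def baseline_normalize(binned: BinnedTrace) -> BinnedTrace:
    """Subtract the pre-stimulus bin mean from every bin (exactly once)."""
    if binned.normalized:
        raise ValidationError("trace already baseline-normalized")
    out = binned.bins - binned.bins[: binned.n_pre].mean()
    # second centering pass removes the cancellation residual of huge offsets
    out = out - out[: binned.n_pre].mean()
    return replace(binned, bins=out, normalized=True)


def summarize_subject(binned: BinnedTrace) -> SubjectSummary:
    """Peak point and 20-bin post mean of a normalized binned trace."""
    if not binned.normalized:
        raise ValidationError("summaries are defined on normalized traces")
    post = binned.post
    return SubjectSummary(peak_point=float(post.max()), post_mean=float(post.mean()))


def perievent_pipeline(dff: DffTrace, window: PeriEventWindow = DEFAULT_WINDOW,
                       on_edge: str = "error") -> BinnedTrace:
    """extract -> average -> bin -> normalize, a pure function of its inputs."""
    trials = extract_windows(dff, window, on_edge=on_edge)
    mean = average_trials(trials, dff.subject_id, dff.timepoint, dff.sampling_rate)
    return baseline_normalize(bin_trace(mean, window))


def binned_traces_by_group(sessions, preprocess_params=None,
                           window: PeriEventWindow = DEFAULT_WINDOW):
    """Run raw sessions through preprocess + peri-event binning, grouped.

    Returns ``{(sex, treatment): {timepoint: [BinnedTrace, ...]}}`` — the
    shape the cohort statistics consume.
    """
    from .preprocess import preprocess_session

    groups: dict = {}
    for s in sessions:
        binned = perievent_pipeline(preprocess_session(s, preprocess_params), window)
        groups.setdefault((s.sex, s.treatment), {}).setdefault(s.timepoint, []).append(binned)
    return groups
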