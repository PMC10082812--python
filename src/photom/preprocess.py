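"""Raw two-channel fluorescence to isosbestic-corrected dF/F.

The correction exploits the 405 nm isosbestic excitation, at which GCaMP
fluorescence is calcium-independent: photobleaching, fiber bending and motion
contaminate both channels, so an affine least-squares fit of the (smoothed)
405 nm channel onto the 465 nm channel predicts the calcium-independent part
of the GCaMP signal.  The fractional residual

    dF/F = (F465 - F405_fitted) / F405_fitted

is the calcium readout.  The chain is deterministic:

    artifact removal (per channel)  ->  block-mean downsampling
    ->  moving-average smoothing of the 405 channel  ->  OLS fit
    ->  dF/F

Event timestamps are absolute seconds and pass through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .session_io import RawSession, ValidationError

__all__ = [
    "PreprocessParams",
    "DffTrace",
    "remove_artifacts",
    "downsample",
    "smooth",
    "fit_isosbestic",
    "compute_dff",
    "preprocess_session",
]

#: flagged-sample fraction above which preprocessing warns / refuses
QC_WARN_FRACTION = 0.10
QC_ERROR_FRACTION = 0.50

#: fitted-denominator floor, as a fraction of the median fitted value
DENOMINATOR_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable knobs of the preprocessing chain.

    ``downsample_factor=None`` picks the factor that brings the sampling rate
    closest to ``target_fs`` (~100 Hz, conventional for fast GCaMP kinetics).
    Smoothing is applied to *both* channels by default: filtering the two
    channels identically before the regression is what lets common-mode
    artifacts cancel exactly; smoothing only the isosbestic regressor leaves
    an unmatched fast artifact component in the 465 channel.  Set
    ``smooth_465=False`` to smooth the 405 channel alone.
    """

    downsample_factor: int | None = None
    target_fs: float = 100.0
    smooth_window_s: float = 0.25
    smooth_465: bool = True
    artifact_mad_k: float = 8.0
    detrend: str = "none"  # {"none", "linear", "exp2"}; regression handles bleach
    dff_denominator: str = "fitted_405"  # or "fitted_baseline"

    def __post_init__(self) -> None:
        if self.downsample_factor is not None and self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.smooth_window_s < 0:
            raise ValueError("smooth_window_s must be >= 0")
        if self.artifact_mad_k <= 0:
            raise ValueError("artifact_mad_k must be > 0")
        if self.detrend not in {"none", "linear", "exp2"}:
            raise ValueError(f"unknown detrend {self.detrend!r}")
        if self.dff_denominator not in {"fitted_405", "fitted_baseline"}:
            raise ValueError(f"unknown dff_denominator {self.dff_denominator!r}")

    def factor_for(self, fs: float) -> int:
        if self.downsample_factor is not None:
            return self.downsample_factor
        return max(1, round(fs / self.target_fs))


@dataclass
class DffTrace:
    """Isosbestic-corrected dF/F time series with sampling metadata."""

    subject_id: str
    timepoint: str
    sampling_rate: float
    t0: float
    dff: np.ndarray
    event_times: np.ndarray
    fit: tuple[float, float]  # (slope, intercept) of the isosbestic regression
    qc: float  # fraction of raw samples flagged as artifact (either channel)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=float)
        if not np.all(np.isfinite(self.dff)):
            raise ValidationError("dff contains non-finite samples")
        if not 0.0 <= self.qc <= 1.0:
            raise ValidationError("qc fraction must lie in [0, 1]")

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.dff.size) / self.sampling_rate


def remove_artifacts(signal, k: float) -> tuple[np.ndarray, np.ndarray]:
    """Replace gross outliers by linear interpolation from valid neighbours.

    A sample is flagged when ``|x - median| > k * MAD`` (raw median absolute
    deviation, no normality scaling).  When ``MAD == 0`` zero deviation is
    typical: constant signals pass untouched, while any sample that deviates
    at all is infinitely many MADs out and is flagged.
    Flagged runs are linearly interpolated between the nearest unflagged
    samples; flagged endpoints clamp to the nearest valid value.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValidationError("artifact removal needs at least 3 samples")
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    mask = dev > k * mad if mad > 0 else dev > 0
    if mask.all():
        raise ValidationError("all samples flagged as artifact; signal uninterpretable")
    if not mask.any():
        return x.copy(), mask
    out = x.copy()
    idx = np.arange(x.size)
    out[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    return out, mask


def downsample(signal, fs: float, factor: int) -> tuple[np.ndarray, float]:
    """Block-mean decimation by ``factor``; a trailing partial block is dropped."""
    if factor < 1:
        raise ValueError("downsample factor must be >= 1")
    x = np.asarray(signal, dtype=float)
    if factor == 1:
        return x.copy(), fs
    n = (x.size // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1), fs / factor


def smooth(signal, fs: float, window_s: float) -> np.ndarray:
    """Centered moving average; edges use shrinking windows.

    The window is rounded to the nearest odd sample count so it centers
    exactly; a window of one sample (or ``window_s == 0``) is the identity.
    """
    x = np.asarray(signal, dtype=float)
    w = int(round(window_s * fs))
    if window_s > 0 and w < 1:
        raise ValueError("smoothing window shorter than one sample")
    if w % 2 == 0:
        w += 1 if w > 0 else 0
    if w > x.size:  # window longer than the signal: largest odd usable width
        w = x.size if x.size % 2 else x.size - 1
    if w <= 1:
        return x.copy()
    kernel = np.ones(w)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones(x.size), kernel, mode="same")
    return sums / counts


def fit_isosbestic(f465, f405) -> tuple[float, float, np.ndarray]:
    """OLS fit predicting the 465 channel from the 405 channel.

    Returns ``(slope, intercept, fitted_405)`` with
    ``fitted_405 = slope * f405 + intercept``, the affine map minimising the
    residual sum of squares.
    """
    y = np.asarray(f465, dtype=float)
    x = np.asarray(f405, dtype=float)
    if x.size != y.size:
        raise ValidationError("channel length mismatch in isosbestic fit")
    if x.size < 2:
        raise ValidationError("isosbestic fit needs at least 2 samples")
    if np.ptp(x) == 0:
        raise ValidationError("isosbestic channel is constant; regression degenerate")
    xm, ym = x.mean(), y.mean()
    xc = x - xm
    slope = float(np.dot(xc, y - ym) / np.dot(xc, xc))
    intercept = float(ym - slope * xm)
    return slope, intercept, slope * x + intercept


def compute_dff(f465, fitted_405) -> np.ndarray:
    """Elementwise fractional residual ``(F465 - fit) / fit``.

    Fitted values are floored at ``1e-6 x median(fitted)``; a sample at or
    below the floor makes the ratio meaningless and raises, reporting the
    first offending index.
    """
    y = np.asarray(f465, dtype=float)
    f = np.asarray(fitted_405, dtype=float)
    floor = DENOMINATOR_FLOOR_FRACTION * np.median(f)
    bad = f <= floor
    if bad.any():
        i = int(np.argmax(bad))
        raise ValidationError(
            f"fitted denominator non-positive after floor guard at sample {i} "
            f"(value {f[i]:.3g})"
        )
    return (y - f) / f


def _detrend(x: np.ndarray, fs: float, mode: str) -> np.ndarray:
    if mode == "none":
        return x
    t = np.arange(x.size) / fs
    if mode == "linear":
        coef = np.polyfit(t, x, 1)
        return x - np.polyval(coef, t) + x.mean()
    # exp2: double-exponential baseline fit, subtracted back to the signal mean.
    from scipy.optimize import curve_fit

    def model(t, a1, k1, a2, k2, c):
        return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t) + c

    span = t[-1] if t[-1] > 0 else 1.0
    p0 = (np.ptp(x) / 2, 2.0 / span, np.ptp(x) / 2, 0.2 / span, float(np.min(x)))
    try:
        popt, _ = curve_fit(model, t, x, p0=p0, maxfev=5000)
        return x - model(t, *popt) + x.mean()
    except RuntimeError:
        warnings.warn("exp2 detrend failed to converge; leaving signal untrended")
        return x


def preprocess_session(raw: RawSession, params: PreprocessParams | None = None) -> DffTrace:
    """Run the full deterministic chain on one session.

    QC is the fraction of raw samples flagged on either channel; above 10 %
    a warning is emitted, above 50 % the session is refused (comparable to
    the study practice of excluding subjects for lack of signal).
    """
    params = params or PreprocessParams()
    f465, mask465 = remove_artifacts(raw.signal_465, params.artifact_mad_k)
    f405, mask405 = remove_artifacts(raw.signal_405, params.artifact_mad_k)
    qc = float(np.mean(mask465 | mask405))
    if qc > QC_ERROR_FRACTION:
        raise ValidationError(
            f"{qc:.0%} of samples flagged as artifact; session unusable"
        )
    if qc > QC_WARN_FRACTION:
        warnings.warn(f"{qc:.0%} of samples flagged as artifact")

    factor = params.factor_for(raw.sampling_rate)
    f465, fs = downsample(f465, raw.sampling_rate, factor)
    f405, _ = downsample(f405, raw.sampling_rate, factor)

    if params.detrend != "none":
        f465 = _detrend(f465, fs, params.detrend)
        f405 = _detrend(f405, fs, params.detrend)

    f405s = smooth(f405, fs, params.smooth_window_s)
    if params.smooth_465:
        f465 = smooth(f465, fs, params.smooth_window_s)

    slope, intercept, fitted = fit_isosbestic(f465, f405s)
    if params.dff_denominator == "fitted_baseline":
        # flat baseline alternative: the fitted curve's session mean
        fitted_denom = np.full_like(fitted, fitted.mean())
        dff = (f465 - fitted) / fitted_denom
    else:
        dff = compute_dff(f465, fitted)

    return DffTrace(
        subject_id=raw.subject_id,
        timepoint=raw.timepoint,
        sampling_rate=fs,
        t0=raw.t0,
        dff=dff,
        event_times=raw.event_times.copy(),
        fit=(slope, intercept),
        qc=qc,
    )
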