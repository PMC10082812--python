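"""Subject-resampling bootstrap confidence bands for binned group traces.

The within-group inferential device: for a group of n subject traces, draw n
subjects with replacement, average per bin, repeat (1000 iterations by
default), and take per-bin percentile bounds of the resampled means (99 % CI
by default).  A post-stimulus bin is declared a significant increase when
the *lower* band exceeds zero (strict, one-sided-positive); pre-stimulus
bins are never tested.

The default resampling unit is the whole subject trace — one index draw per
subject per iteration — which preserves within-subject correlation across
bins.  Per-bin independent resampling is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .perievent import BinnedTrace
from .session_io import ValidationError

__all__ = ["BootstrapParams", "BootstrapResult", "bootstrap_ci", "significance_mask"]


@dataclass(frozen=True)
class BootstrapParams:
    n_iter: int = 1000
    ci_level: float = 99.0
    seed: int | None = None
    resample_unit: str = "subject_trace"  # or "per_bin"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 < self.ci_level < 100:
            raise ValueError("ci_level must lie in (0, 100)")
        if self.resample_unit not in {"subject_trace", "per_bin"}:
            raise ValueError(f"unknown resample_unit {self.resample_unit!r}")


@dataclass
class BootstrapResult:
    """Per-bin band of resampled group means plus the significance mask."""

    labels: dict
    mean_curve: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    sig_mask: np.ndarray  # post bins only
    n_pre: int
    n_subjects: int
    params: BootstrapParams

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValidationError("lower band exceeds upper band")


def _group_matrix(group) -> tuple[np.ndarray, int, dict]:
    """Stack a list of normalized BinnedTrace (or a 2D array) into (n, bins)."""
    if isinstance(group, np.ndarray):
        mat = np.asarray(group, dtype=float)
        if mat.ndim != 2:
            raise ValidationError("trace matrix must be 2-D (subjects x bins)")
        return mat, -1, {}
    traces: list[BinnedTrace] = list(group)
    if not traces:
        raise ValidationError("empty group")
    lengths = {t.bins.size for t in traces}
    if len(lengths) != 1:
        raise ValidationError(f"ragged binned traces {sorted(lengths)}")
    n_pre = {t.n_pre for t in traces}
    if len(n_pre) != 1:
        raise ValidationError("traces disagree on pre/post split")
    labels = {"timepoint": {t.timepoint for t in traces}}
    return np.stack([t.bins for t in traces]), n_pre.pop(), labels


def bootstrap_ci(group, params: BootstrapParams | None = None, *,
                 n_pre: int | None = None) -> BootstrapResult:
    """Percentile band of resampled group-mean traces.

    ``group`` is a list of normalized :class:`BinnedTrace` (or directly a
    ``(n_subjects, n_bins)`` array, in which case ``n_pre`` must be given).
    Deterministic given ``params.seed``.
    """
    params = params or BootstrapParams()
    mat, inferred_pre, labels = _group_matrix(group)
    if inferred_pre < 0:
        if n_pre is None:
            raise ValueError("n_pre is required when passing a bare matrix")
        inferred_pre = n_pre
    n, n_bins = mat.shape
    if n < 2:
        raise ValidationError("bootstrap needs at least 2 subjects")
    rng = np.random.default_rng(params.seed)
    if params.resample_unit == "subject_trace":
        idx = rng.integers(0, n, size=(params.n_iter, n))
        boot_means = mat[idx].mean(axis=1)  # (n_iter, n_bins)
    else:
        idx = rng.integers(0, n, size=(params.n_iter, n, n_bins))
        boot_means = np.take_along_axis(
            np.broadcast_to(mat, (params.n_iter, n, n_bins)), idx, axis=1
        ).mean(axis=1)
    alpha = (100.0 - params.ci_level) / 2.0
    lower = np.percentile(boot_means, alpha, axis=0, method="linear")
    upper = np.percentile(boot_means, 100.0 - alpha, axis=0, method="linear")
    result = BootstrapResult(
        labels=labels,
        mean_curve=mat.mean(axis=0),
        lower=lower,
        upper=upper,
        sig_mask=lower[inferred_pre:] > 0,
        n_pre=inferred_pre,
        n_subjects=n,
        params=params,
    )
    return result


def significance_mask(result: BootstrapResult) -> np.ndarray:
    """Post-stimulus bins whose lower CI bound strictly exceeds zero."""
    return result.lower[result.n_pre :] > 0
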