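"""Threat-response classification and locomotion/rearing aggregation.

Animals respond to the air-puff with one of two coping strategies: an
*active* response — darting, immediate fleeing from the stimulus — or a
*passive* response — immobility following the puff.  Classification is
rule-based on the scored behavior log:

* active  — a darting bout *starts* inside the post-puff window
  (darting takes precedence when both behaviors occur);
* passive — immobility covers at least ``immobile_fraction`` of the window;
* unclassified otherwise (including an empty log).

The post-puff window length is a sensitivity parameter; the default of 10 s
matches the photometry analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .session_io import BEHAVIORS, BehaviorLog, ValidationError

__all__ = [
    "ThreatResponse",
    "classify_response",
    "response_table",
    "duration_in_interval",
]

DEFAULT_WINDOW_S = 10.0
DEFAULT_IMMOBILE_FRACTION = 0.5


@dataclass(frozen=True)
class ThreatResponse:
    subject_id: str
    timepoint: str
    response: str  # {"active", "passive", "unclassified"}
    latency_s: float | None = None  # puff onset to darting onset (active only)

    def __post_init__(self) -> None:
        if self.response not in {"active", "passive", "unclassified"}:
            raise ValidationError(f"unknown response {self.response!r}")
        if self.latency_s is not None and self.latency_s < 0:
            raise ValidationError("latency must be >= 0")


def classify_response(
    log: BehaviorLog,
    puff_time: float,
    window_s: float = DEFAULT_WINDOW_S,
    immobile_fraction: float = DEFAULT_IMMOBILE_FRACTION,
) -> ThreatResponse:
    """Apply the darting-precedence rule over ``[puff_time, puff_time + window_s)``."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t_hi = puff_time + window_s
    dart_onsets = sorted(
        s for s, _e in log.bouts("darting") if puff_time <= s < t_hi
    )
    if dart_onsets:
        return ThreatResponse(
            subject_id=log.subject_id,
            timepoint=log.timepoint,
            response="active",
            latency_s=dart_onsets[0] - puff_time,
        )
    covered = duration_in_interval(log, "immobile", (puff_time, t_hi))
    if covered >= immobile_fraction * window_s:
        return ThreatResponse(
            subject_id=log.subject_id, timepoint=log.timepoint, response="passive"
        )
    return ThreatResponse(
        subject_id=log.subject_id, timepoint=log.timepoint, response="unclassified"
    )


def response_table(
    responses_a: list[ThreatResponse], responses_b: list[ThreatResponse]
) -> np.ndarray:
    """2x2 contingency counts: rows = groups, columns = (active, passive).

    Unclassified subjects are excluded with a warning.  Feeds
    :func:`photom.cohort_stats.fisher_exact_2x2`.
    """
    if not responses_a or not responses_b:
        raise ValidationError("both groups must be non-empty")
    table = np.zeros((2, 2), dtype=int)
    n_dropped = 0
    for row, responses in enumerate((responses_a, responses_b)):
        for r in responses:
            if r.response == "active":
                table[row, 0] += 1
            elif r.response == "passive":
                table[row, 1] += 1
            else:
                n_dropped += 1
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} unclassified subject(s) from the table")
    return table


def duration_in_interval(log: BehaviorLog, behavior: str, interval) -> float:
    """Total overlap (seconds) of one behavior's bouts with a time interval."""
    if behavior not in BEHAVIORS:
        raise ValidationError(f"unknown behavior label {behavior!r}")
    lo, hi = float(interval[0]), float(interval[1])
    if hi < lo:
        raise ValidationError("interval end precedes start")
    total = 0.0
    for s, e in log.bouts(behavior):
        total += max(0.0, min(e, hi) - max(s, lo))
    return total
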