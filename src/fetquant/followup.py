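"""Longitudinal (baseline -> follow-up) consistency of clinical metrics.

Treatment response is read from the change in BTV, T_MEAN/B and T_MAX/B
between a baseline and a follow-up examination. This module computes those
changes for any pairing of attenuation-correction methods at the two ends
(ref->ref, ref->test, test->ref, test->test) and flags test changes that
deviate from the reference change by more than 5 percentage points (ratio
metrics) or 10 percentage points (BTV), the same scale of clinical
relevance as the single-timepoint acceptance criteria.

The percent-change denominator is always the first (baseline-role) value of
the pairing. Percentages are reported rounded to the nearest integer
(half away from zero) only at presentation; internal values stay exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "FollowupChange",
    "DeviationThresholds",
    "DeviationRecord",
    "StudyPair",
    "change_metrics",
    "compare_changes",
    "cross_modality_change",
    "round_pct",
]


def round_pct(x: float) -> int:
    """Nearest-integer percent, rounding halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class FollowupChange:
    subject_id: str
    metric_name: str
    ac_baseline: str
    ac_followup: str
    value_baseline: float
    value_followup: float
    abs_change: float
    pct_change: float
    direction: str  # "increase" | "decrease" | "stable"

    @property
    def pct_change_rounded(self) -> int:
        return round_pct(self.pct_change)


def change_metrics(
    value_baseline: float,
    value_followup: float,
    *,
    subject_id: str = "",
    metric_name: str = "",
    ac_baseline: str = "",
    ac_followup: str = "",
    stability_band_pct: float = 2.0,
) -> FollowupChange:
    """Absolute and percent change of one metric between two examinations.

    ``direction`` is "stable" when |pct_change| < stability_band_pct
    (default 2%), otherwise "increase"/"decrease" by sign.
    """
    if value_baseline <= 0:
        raise ValueError(f"baseline value must be positive, got {value_baseline}")
    abs_change = value_followup - value_baseline
    pct_change = 100.0 * abs_change / value_baseline
    if abs(pct_change) < stability_band_pct:
        direction = "stable"
    else:
        direction = "increase" if pct_change > 0 else "decrease"
    return FollowupChange(
        subject_id=subject_id,
        metric_name=metric_name,
        ac_baseline=ac_baseline,
        ac_followup=ac_followup,
        value_baseline=float(value_baseline),
        value_followup=float(value_followup),
        abs_change=float(abs_change),
        pct_change=float(pct_change),
        direction=direction,
    )


@dataclass(frozen=True)
class DeviationThresholds:
    ratio_points: float = 5.0
    btv_points: float = 10.0


@dataclass(frozen=True)
class DeviationRecord:
    subject_id: str
    metric_name: str
    pairing_test: str
    pairing_ref: str
    deviation_points: float
    flagged: bool
    discordant_direction: bool


def compare_changes(
    change_test: FollowupChange,
    change_ref: FollowupChange,
    thresholds: DeviationThresholds = DeviationThresholds(),
) -> DeviationRecord:
    """Deviation of a test follow-up change from the reference change.

    Flagged when the deviation exceeds (strictly) 10 percentage points for
    BTV or 5 points for the ratio metrics. ``discordant_direction`` marks
    the clinically worst case: one method reads progression where the other
    reads response.
    """
    if change_test.metric_name != change_ref.metric_name:
        raise ValueError(
            f"metric mismatch: {change_test.metric_name!r} vs "
            f"{change_ref.metric_name!r}"
        )
    if change_test.subject_id != change_ref.subject_id:
        raise ValueError("compare_changes requires changes from the same subject")
    metric = change_test.metric_name
    bound = thresholds.btv_points if metric == "btv_ml" else thresholds.ratio_points
    deviation = change_test.pct_change - change_ref.pct_change
    discordant = {change_test.direction, change_ref.direction} == {
        "increase",
        "decrease",
    }
    return DeviationRecord(
        subject_id=change_test.subject_id,
        metric_name=metric,
        pairing_test=f"{change_test.ac_baseline}->{change_test.ac_followup}",
        pairing_ref=f"{change_ref.ac_baseline}->{change_ref.ac_followup}",
        deviation_points=float(deviation),
        flagged=abs(deviation) > bound,
        discordant_direction=discordant,
    )


@dataclass(frozen=True)
class StudyPair:
    """One subject's metric values at both timepoints under every method."""

    subject_id: str
    metric_name: str
    baseline: Mapping[str, float]  # method label -> value
    followup: Mapping[str, float]


def cross_modality_change(
    study_pairs: Sequence[StudyPair],
    baseline_method: str,
    followup_method: str,
    stability_band_pct: float = 2.0,
) -> list[FollowupChange]:
    """Follow-up changes using a stated method at each end.

    ``baseline_method == followup_method`` gives the within-modality change;
    mixed labels emulate switching the attenuation-correction method during
    clinical follow-up.
    """
    changes = []
    for pair in study_pairs:
        if baseline_method not in pair.baseline:
            raise KeyError(
                f"subject {pair.subject_id!r}: no baseline value for method "
                f"{baseline_method!r}"
            )
        if followup_method not in pair.followup:
            raise KeyError(
                f"subject {pair.subject_id!r}: no follow-up value for method "
                f"{followup_method!r}"
            )
        changes.append(
            change_metrics(
                pair.baseline[baseline_method],
                pair.followup[followup_method],
                subject_id=pair.subject_id,
                metric_name=pair.metric_name,
                ac_baseline=baseline_method,
                ac_followup=followup_method,
                stability_band_pct=stability_band_pct,
            )
        )
    return changes
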