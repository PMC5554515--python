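"""Method-agreement statistics on log-transformed clinical metrics.

The between-method distribution of T_MEAN/B, T_MAX/B and BTV is close to
log-normal, so agreement is summarised Bland-Altman style on per-study log
ratios d_i = ln(test_i / ref_i) and exponentiated back to percentages:

    mean %            = 100 * (exp(d_bar) - 1)
    95% CI of mean    = 100 * (exp(d_bar +/- 1.96 * SD_d / sqrt(n)) - 1)
    limits of agreem. = 100 * (exp(d_bar +/- 1.96 * SD_d) - 1)

When subjects contribute repeated examinations, SD_d comes from a one-way
variance-components decomposition (between-subject + within-subject), the
standard repeated-measures correction of the Bland-Altman framework; with
one study per subject it reduces exactly to the ordinary sample SD.

The module also houses the clinical acceptance rules used to judge whether
a test attenuation-correction method may replace the reference on a given
study, and the T_MAX/B diagnostic categorisation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedComparison",
    "BlandAltmanResult",
    "AcceptanceThresholds",
    "AcceptanceVerdict",
    "CategoryShiftTable",
    "bland_altman",
    "sd_with_repeated_measures",
    "acceptance_check",
    "classify_category",
    "category_shift_table",
    "CATEGORIES",
]

RATIO_METRICS = ("t_mean_over_b", "t_max_over_b")
CATEGORIES = ("reactive", "equivocal", "active")


@dataclass(frozen=True)
class PairedComparison:
    """One study's value of one metric under a test method, paired with the
    reference value. Difference fields are derived, never stored, so the
    consistency invariant rel_diff_pct == 100*(exp(log_ratio)-1) holds by
    construction."""

    subject_id: str
    study_id: str
    metric_name: str
    value_test: float
    value_ref: float

    @property
    def abs_diff(self) -> float:
        return self.value_test - self.value_ref

    @property
    def rel_diff_pct(self) -> float:
        if self.value_ref == 0:
            raise ValueError(
                f"relative difference undefined for study {self.study_id!r}: "
                f"reference value is zero"
            )
        return 100.0 * (self.value_test - self.value_ref) / self.value_ref

    @property
    def log_ratio(self) -> float:
        if self.value_test <= 0 or self.value_ref <= 0:
            raise ValueError(
                f"log ratio undefined for study {self.study_id!r} "
                f"({self.metric_name}): values must be positive, got "
                f"test={self.value_test}, ref={self.value_ref}"
            )
        return math.log(self.value_test / self.value_ref)


@dataclass
class BlandAltmanResult:
    """Log-scale agreement summary, exponentiated to percentages."""

    n: int
    n_subjects: int
    d_bar: float
    sd_d: float
    mean_pct: float
    ci_mean_pct: tuple[float, float]
    loa_pct: tuple[float, float]
    ci_loa_pct: tuple[tuple[float, float], tuple[float, float]]
    p_value: float
    metric_name: str = ""
    method: str = ""


def _exp_pct(x: float) -> float:
    return 100.0 * (math.exp(x) - 1.0)


def sd_with_repeated_measures(
    d_values: Sequence[float], subject_ids: Sequence[str]
) -> float:
    """SD of log differences corrected for repeated studies per subject.

    One-way variance-components estimate: with k subjects contributing
    m_i studies each (N total),

        MS_W  = within-subject mean square      (df N - k)
        MS_B  = between-subject mean square     (df k - 1)
        m0    = (N - sum(m_i^2)/N) / (k - 1)
        sigma_b^2 = max(0, (MS_B - MS_W) / m0)
        SD_d  = sqrt(sigma_b^2 + MS_W)

    With all m_i == 1 this is exactly the ordinary sample SD.
    """
    d = np.asarray(d_values, dtype=float)
    subjects = list(subject_ids)
    if d.size != len(subjects):
        raise ValueError("d_values and subject_ids have different lengths")
    if d.size < 2:
        raise ValueError("need at least two studies to estimate an SD")

    counts = Counter(subjects)
    k = len(counts)
    n_total = d.size
    if k == 1:
        raise ValueError(
            "between-subject variance is inestimable from a single subject "
            "with replicates"
        )
    if n_total == k:  # one study per subject: ordinary sample SD
        return float(np.std(d, ddof=1))

    grand = d.mean()
    by_subject: dict[str, list[float]] = {}
    for value, subj in zip(d, subjects):
        by_subject.setdefault(subj, []).append(value)

    ss_within = 0.0
    ss_between = 0.0
    for subj, values in by_subject.items():
        arr = np.asarray(values)
        ss_within += float(((arr - arr.mean()) ** 2).sum())
        ss_between += arr.size * float((arr.mean() - grand) ** 2)
    ms_within = ss_within / (n_total - k)
    ms_between = ss_between / (k - 1)
    m0 = (n_total - sum(m * m for m in counts.values()) / n_total) / (k - 1)
    sigma_b2 = max(0.0, (ms_between - ms_within) / m0)
    return float(math.sqrt(sigma_b2 + ms_within))


def bland_altman(
    comparisons: Sequence[PairedComparison],
    subject_ids: Sequence[str] | None = None,
    z: float = 1.96,
    eq3: str = "anova",
    metric_name: str = "",
    method: str = "",
) -> BlandAltmanResult:
    """Bland-Altman agreement of a test method against the reference.

    Parameters
    ----------
    comparisons
        Paired values of a single metric, one entry per study.
    subject_ids
        Override of the per-study subject labels (defaults to the ids
        carried by the comparisons); used for the repeated-measures SD.
    eq3
        How the 95% CI of the limits of agreement is computed.
        ``"anova"`` (default): limit +/- z*sqrt(3)*SD_d/sqrt(n), the
        standard large-sample variance of an agreement limit.
        ``"literal"``: exp(d_bar +/- 3*SD_d/sqrt(2n)), a narrower reading
        kept selectable for sensitivity analysis.

    Notes
    -----
    ``n`` counts studies; the number of distinct subjects is reported
    alongside as ``n_subjects``.
    """
    if len(comparisons) < 3:
        raise ValueError("Bland-Altman analysis requires at least 3 studies")
    if eq3 not in ("anova", "literal"):
        raise ValueError(f"unknown eq3 variant {eq3!r}")
    if subject_ids is None:
        subject_ids = [c.subject_id for c in comparisons]
    if len(subject_ids) != len(comparisons):
        raise ValueError("subject_ids length does not match comparisons")

    d = np.array([c.log_ratio for c in comparisons])  # raises naming the study
    n = d.size
    d_bar = float(d.mean())
    sd_d = sd_with_repeated_measures(d, subject_ids)
    se = sd_d / math.sqrt(n)

    lo_limit = d_bar - z * sd_d
    hi_limit = d_bar + z * sd_d
    if eq3 == "anova":
        half = z * math.sqrt(3.0) * sd_d / math.sqrt(n)
        ci_loa = (
            (_exp_pct(lo_limit - half), _exp_pct(lo_limit + half)),
            (_exp_pct(hi_limit - half), _exp_pct(hi_limit + half)),
        )
    else:
        lo = _exp_pct(d_bar - 3.0 * sd_d / math.sqrt(2.0 * n))
        hi = _exp_pct(d_bar + 3.0 * sd_d / math.sqrt(2.0 * n))
        ci_loa = ((lo, lo), (hi, hi))

    if sd_d > 0:
        p_value = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        p_value = 1.0 if d_bar == 0 else 0.0

    return BlandAltmanResult(
        n=n,
        n_subjects=len(set(subject_ids)),
        d_bar=d_bar,
        sd_d=sd_d,
        mean_pct=_exp_pct(d_bar),
        ci_mean_pct=(_exp_pct(d_bar - z * se), _exp_pct(d_bar + z * se)),
        loa_pct=(_exp_pct(lo_limit), _exp_pct(hi_limit)),
        ci_loa_pct=ci_loa,
        p_value=p_value,
        metric_name=metric_name,
        method=method,
    )


@dataclass(frozen=True)
class AcceptanceThresholds:
    """Clinical bounds below which a test method is interchangeable with
    the reference on a study. A metric passes when EITHER its absolute or
    its relative difference is strictly inside the bound; the mix reflects
    that a larger absolute change is acceptable in large or highly active
    tumors."""

    t_mean_abs: float = 0.05
    t_max_abs: float = 0.1
    ratio_rel_pct: float = 5.0
    btv_abs_ml: float = 2.0
    btv_rel_pct: float = 10.0
    peak_mm: float = 10.0

    def __post_init__(self) -> None:
        for name in ("t_mean_abs", "t_max_abs", "ratio_rel_pct", "btv_abs_ml",
                     "btv_rel_pct", "peak_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class AcceptanceVerdict:
    study_id: str
    t_mean_pass: bool
    t_max_pass: bool
    btv_pass: bool

    @property
    def overall_pass(self) -> bool:
        return self.t_mean_pass and self.t_max_pass and self.btv_pass


def _passes(comp: PairedComparison, abs_bound: float, rel_bound_pct: float) -> bool:
    return abs(comp.abs_diff) < abs_bound or abs(comp.rel_diff_pct) < rel_bound_pct


def acceptance_check(
    c_tmean: PairedComparison,
    c_tmax: PairedComparison,
    c_btv: PairedComparison,
    thresholds: AcceptanceThresholds = AcceptanceThresholds(),
) -> AcceptanceVerdict:
    """Classify one study against the clinical acceptance criteria:
    T_MEAN/B within ±0.05 or 5%, T_MAX/B within ±0.1 or 5%, BTV within
    ±2 mL or 10% (strict inequalities, either bound suffices)."""
    expected = {
        "t_mean_over_b": c_tmean,
        "t_max_over_b": c_tmax,
        "btv_ml": c_btv,
    }
    for name, comp in expected.items():
        if comp.metric_name != name:
            raise ValueError(
                f"expected a {name} comparison, got {comp.metric_name!r}"
            )
    if not (c_tmean.study_id == c_tmax.study_id == c_btv.study_id):
        raise ValueError("acceptance_check requires comparisons from one study")
    return AcceptanceVerdict(
        study_id=c_tmean.study_id,
        t_mean_pass=_passes(c_tmean, thresholds.t_mean_abs, thresholds.ratio_rel_pct),
        t_max_pass=_passes(c_tmax, thresholds.t_max_abs, thresholds.ratio_rel_pct),
        btv_pass=_passes(c_btv, thresholds.btv_abs_ml, thresholds.btv_rel_pct),
    )


def classify_category(
    t_max_over_b: float,
    reactive_below: float = 2.0,
    active_above: float = 2.4,
) -> str:
    """Diagnostic category from T_MAX/B: below 2.0 is considered reactive
    tissue, above 2.4 active tumor; the closed interval [2.0, 2.4] is
    equivocal (boundary values deliberately assigned to the equivocal
    zone)."""
    if t_max_over_b <= 0:
        raise ValueError("T_MAX/B must be positive")
    if t_max_over_b < reactive_below:
        return "reactive"
    if t_max_over_b > active_above:
        return "active"
    return "equivocal"


@dataclass
class CategoryShiftTable:
    """3x3 contingency of reference-category rows vs test-category columns."""

    counts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            0, index=list(CATEGORIES), columns=list(CATEGORIES), dtype=int
        )
    )

    @property
    def n_off_diagonal(self) -> int:
        total = int(self.counts.to_numpy().sum())
        diag = int(np.trace(self.counts.to_numpy()))
        return total - diag


def category_shift_table(
    pairs: Iterable[tuple[str, str]],
) -> CategoryShiftTable:
    """Tally (reference category, test category) pairs."""
    table = CategoryShiftTable()
    for ref_cat, test_cat in pairs:
        if ref_cat not in CATEGORIES or test_cat not in CATEGORIES:
            raise ValueError(f"unknown category in pair ({ref_cat!r}, {test_cat!r})")
        table.counts.loc[ref_cat, test_cat] += 1
    return table
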