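"""End-to-end orchestration: phantom cohort -> delineation -> statistics.

`run_pipeline` composes everything in this package: it generates (or loads)
a cohort, delineates each study under every attenuation-correction method,
pairs each method against the reference, classifies acceptance and
diagnostic categories, computes cohort-level Bland-Altman tables per metric
and method, and runs the longitudinal follow-up consistency analysis.
Per-study failures are logged and quarantined, never fatal to the cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .agreement import (
    AcceptanceThresholds,
    PairedComparison,
    acceptance_check,
    bland_altman,
    category_shift_table,
    classify_category,
)
from .config import AnalysisConfig
from .followup import (
    DeviationThresholds,
    StudyPair,
    compare_changes,
    cross_modality_change,
)
from .imaging import (
    DelineationConfig,
    TumorDelineation,
    background_mean,
    delineate_btv,
    jaccard,
    peak_shift,
    shape_deviation,
    tumor_metrics,
)
from .phantom import StudyRecord, generate_cohort

logger = logging.getLogger(__name__)

BA_METRICS = ("t_mean_over_b", "t_max_over_b", "btv_ml", "t_mean")


@dataclass
class PipelineResult:
    study_metrics: pd.DataFrame
    comparisons: pd.DataFrame
    acceptance: pd.DataFrame
    ba_table: pd.DataFrame
    category_shifts: dict[str, "pd.DataFrame"]
    followup_changes: pd.DataFrame
    followup_deviations: pd.DataFrame
    summary: dict
    quarantined: list[dict] = field(default_factory=list)


def delineate_study(
    record: StudyRecord, config: AnalysisConfig | None = None
) -> dict[str, tuple[float, TumorDelineation]]:
    """Delineate one study under every method: label -> (B, delineation).

    The same background ROI is used for all methods; B is measured per
    method on that ROI, so the threshold adapts to each method's bias.
    The ground-truth tumor region serves as the component prior (the
    clinician-seed analogue).
    """
    config = config or AnalysisConfig()
    dcfg = DelineationConfig(
        threshold_ratio=config.threshold_ratio,
        min_component_ml=config.min_component_ml,
    )
    scene = record.scene
    out = {}
    for label, img in scene.biased_images.items():
        b = background_mean(img, scene.background_roi_mask)
        delin = delineate_btv(
            img,
            b,
            exclusion_mask=scene.exclusion_mask,
            tumor_prior_mask=scene.tumor_truth_mask,
            config=dcfg,
        )
        out[label] = (b, delin)
    return out


def _study_rows(record, delineations, config):
    rows = []
    for label, (b, delin) in delineations.items():
        row = {
            "subject_id": record.subject_id,
            "study_id": record.study_id,
            "timepoint": record.timepoint,
            "method": label,
            "background_b": b,
            "btv_ml": delin.btv_ml,
            "t_mean": delin.t_mean,
            "t_max": delin.t_max,
            "threshold_used": delin.threshold_used,
        }
        if not delin.is_empty:
            tm, tx = tumor_metrics(delin)
            row["t_mean_over_b"] = tm
            row["t_max_over_b"] = tx
            row["category"] = classify_category(tx)
        else:
            row["t_mean_over_b"] = np.nan
            row["t_max_over_b"] = np.nan
            row["category"] = "empty"
        rows.append(row)
    return rows


def _comparison_rows(record, delineations, config, thresholds):
    ref_label = config.reference_label
    b_ref, delin_ref = delineations[ref_label]
    comp_rows, accept_rows = [], []
    ref_metrics = {
        "btv_ml": delin_ref.btv_ml,
        "t_mean": delin_ref.t_mean,
        "t_max": delin_ref.t_max,
    }
    if delin_ref.is_empty:
        raise ValueError(f"reference delineation empty for study {record.study_id}")
    tm_ref, tx_ref = tumor_metrics(delin_ref)
    ref_metrics["t_mean_over_b"] = tm_ref
    ref_metrics["t_max_over_b"] = tx_ref

    for label, (b, delin) in delineations.items():
        if label == ref_label:
            continue
        if delin.is_empty:
            raise ValueError(
                f"empty delineation for method {label} on study {record.study_id}"
            )
        tm, tx = tumor_metrics(delin)
        test_metrics = {
            "btv_ml": delin.btv_ml,
            "t_mean": delin.t_mean,
            "t_max": delin.t_max,
            "t_mean_over_b": tm,
            "t_max_over_b": tx,
        }
        comps = {}
        for metric, value in test_metrics.items():
            comp = PairedComparison(
                subject_id=record.subject_id,
                study_id=record.study_id,
                metric_name=metric,
                value_test=value,
                value_ref=ref_metrics[metric],
            )
            comps[metric] = comp
            comp_rows.append(
                {
                    "subject_id": record.subject_id,
                    "study_id": record.study_id,
                    "timepoint": record.timepoint,
                    "method": label,
                    "metric": metric,
                    "value_test": comp.value_test,
                    "value_ref": comp.value_ref,
                    "abs_diff": comp.abs_diff,
                    "rel_diff_pct": comp.rel_diff_pct,
                    "log_ratio": comp.log_ratio,
                }
            )
        verdict = acceptance_check(
            comps["t_mean_over_b"], comps["t_max_over_b"], comps["btv_ml"], thresholds
        )
        dist, exceeds = peak_shift(delin_ref, delin, criterion_mm=thresholds.peak_mm)
        jac = jaccard(delin_ref.mask, delin.mask)
        report = shape_deviation(
            delin_ref.mask,
            delin.mask,
            spacing=record.scene.truth_activity.spacing,
            smoothing_fwhm_mm=config.smoothing_fwhm_mm,
            binarization_level=config.binarization_level,
        )
        accept_rows.append(
            {
                "subject_id": record.subject_id,
                "study_id": record.study_id,
                "timepoint": record.timepoint,
                "method": label,
                "t_mean_pass": verdict.t_mean_pass,
                "t_max_pass": verdict.t_max_pass,
                "btv_pass": verdict.btv_pass,
                "overall_pass": verdict.overall_pass,
                "peak_shift_mm": dist,
                "peak_exceeds": exceeds,
                "jaccard": jac,
                "n_warps_over_1ml": report.n_warps_over_1ml,
                "category_ref": classify_category(tx_ref),
                "category_test": classify_category(tx),
            }
        )
    return comp_rows, accept_rows


def _followup_analysis(study_metrics: pd.DataFrame, config: AnalysisConfig):
    ref = config.reference_label
    dev_thresholds = DeviationThresholds(
        ratio_points=config.followup_ratio_points,
        btv_points=config.followup_btv_points,
    )
    methods = sorted(set(study_metrics["method"]) - {ref})
    metrics = ("btv_ml", "t_mean_over_b", "t_max_over_b")

    # subjects with both timepoints
    by_subject = study_metrics.groupby("subject_id")["timepoint"].agg(set)
    paired_subjects = [
        s for s, tps in by_subject.items() if {"baseline", "followup"} <= tps
    ]

    change_rows, dev_rows = [], []
    for subject in paired_subjects:
        sub = study_metrics[study_metrics["subject_id"] == subject]
        for metric in metrics:
            values = {
                tp: dict(zip(grp["method"], grp[metric]))
                for tp, grp in sub.groupby("timepoint")
            }
            pair = StudyPair(
                subject_id=subject,
                metric_name=metric,
                baseline=values["baseline"],
                followup=values["followup"],
            )
            (ref_change,) = cross_modality_change(
                [pair], ref, ref, config.stability_band_pct
            )
            pairings = [(ref, ref)]
            pairings += [
                (a, b)
                for m in methods
                for a, b in ((m, m), (ref, m), (m, ref))
            ]
            for a, b in pairings:
                (change,) = cross_modality_change(
                    [pair], a, b, config.stability_band_pct
                )
                change_rows.append(
                    {
                        "subject_id": subject,
                        "metric": metric,
                        "ac_baseline": a,
                        "ac_followup": b,
                        "value_baseline": change.value_baseline,
                        "value_followup": change.value_followup,
                        "abs_change": change.abs_change,
                        "pct_change": change.pct_change,
                        "pct_change_rounded": change.pct_change_rounded,
                        "direction": change.direction,
                    }
                )
                if (a, b) != (ref, ref):
                    dev = compare_changes(change, ref_change, dev_thresholds)
                    dev_rows.append(
                        {
                            "subject_id": subject,
                            "metric": metric,
                            "pairing": dev.pairing_test,
                            "deviation_points": dev.deviation_points,
                            "flagged": dev.flagged,
                            "discordant_direction": dev.discordant_direction,
                        }
                    )
    return pd.DataFrame(change_rows), pd.DataFrame(dev_rows)


def run_pipeline(
    config: AnalysisConfig,
    records: Sequence[StudyRecord] | None = None,
) -> PipelineResult:
    """Run the full analysis; deterministic given the config seed.

    A pre-generated cohort can be supplied via ``records`` (the config's
    cohort block is then ignored); otherwise one is generated.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if records is None:
        cohort = config.cohort
        logger.info(
            "generating cohort: n=%d, followup fraction=%.2f, grid=%s, seed=%d",
            cohort.n_subjects, cohort.followup_fraction, cohort.grid_shape, config.seed,
        )
        records = generate_cohort(
            cohort.n_subjects,
            {k: v.to_profile() for k, v in cohort.method_profiles.items()},
            followup_fraction=cohort.followup_fraction,
            seed=config.seed,
            reference_label=config.reference_label,
            grid_shape=tuple(cohort.grid_shape),
            spacing=tuple(cohort.spacing_mm),
            noise_sd=cohort.noise_sd,
        )

    thresholds = AcceptanceThresholds(**config.acceptance.model_dump())
    study_rows, comp_rows, accept_rows, quarantined = [], [], [], []
    for record in records:
        try:
            delineations = delineate_study(record, config)
            study_rows.extend(_study_rows(record, delineations, config))
            c_rows, a_rows = _comparison_rows(record, delineations, config, thresholds)
            comp_rows.extend(c_rows)
            accept_rows.extend(a_rows)
        except Exception as exc:  # quarantine, do not abort the cohort
            logger.warning("study %s quarantined: %s", record.study_id, exc)
            quarantined.append({"study_id": record.study_id, "error": str(exc)})

    study_metrics = pd.DataFrame(study_rows)
    comparisons = pd.DataFrame(comp_rows)
    acceptance = pd.DataFrame(accept_rows)

    ba_rows = []
    if not comparisons.empty:
        for (method, metric), grp in comparisons.groupby(["method", "metric"]):
            if metric not in BA_METRICS:
                continue
            comps = [
                PairedComparison(
                    subject_id=r.subject_id,
                    study_id=r.study_id,
                    metric_name=metric,
                    value_test=r.value_test,
                    value_ref=r.value_ref,
                )
                for r in grp.itertuples()
            ]
            if len(comps) < 3:
                continue
            res = bland_altman(comps, metric_name=metric, method=method)
            ba_rows.append(
                {
                    "method": method,
                    "metric": metric,
                    "n": res.n,
                    "n_subjects": res.n_subjects,
                    "mean_pct": res.mean_pct,
                    "ci_mean_lo_pct": res.ci_mean_pct[0],
                    "ci_mean_hi_pct": res.ci_mean_pct[1],
                    "loa_lo_pct": res.loa_pct[0],
                    "loa_hi_pct": res.loa_pct[1],
                    "p_value": res.p_value,
                }
            )
    ba_table = pd.DataFrame(ba_rows)

    category_shifts = {}
    if not acceptance.empty:
        for method, grp in acceptance.groupby("method"):
            table = category_shift_table(
                list(zip(grp["category_ref"], grp["category_test"]))
            )
            category_shifts[method] = table.counts

    followup_changes, followup_deviations = _followup_analysis(study_metrics, config) \
        if not study_metrics.empty else (pd.DataFrame(), pd.DataFrame())

    summary = _summarise(
        study_metrics, acceptance, ba_table, category_shifts,
        followup_deviations, quarantined, config,
    )

    result = PipelineResult(
        study_metrics=study_metrics,
        comparisons=comparisons,
        acceptance=acceptance,
        ba_table=ba_table,
        category_shifts=category_shifts,
        followup_changes=followup_changes,
        followup_deviations=followup_deviations,
        summary=summary,
        quarantined=quarantined,
    )
    if config.output_dir:
        _write_outputs(result, records, config)
    return result


def _summarise(study_metrics, acceptance, ba_table, category_shifts,
               followup_deviations, quarantined, config):
    summary: dict = {
        "n_studies": int(study_metrics["study_id"].nunique()) if not study_metrics.empty else 0,
        "n_subjects": int(study_metrics["subject_id"].nunique()) if not study_metrics.empty else 0,
        "reference": config.reference_label,
        "n_quarantined": len(quarantined),
        "methods": {},
    }
    if acceptance.empty:
        return summary
    for method, grp in acceptance.groupby("method"):
        n = len(grp)
        entry = {
            "n_studies": n,
            "n_failing_acceptance": int((~grp["overall_pass"]).sum()),
            "jaccard_mean": float(grp["jaccard"].mean()),
            "jaccard_sd": float(grp["jaccard"].std(ddof=1)) if n > 1 else 0.0,
            "fraction_with_warp_over_1ml": float((grp["n_warps_over_1ml"] > 0).mean()),
            "fraction_peak_over_criterion": float(grp["peak_exceeds"].mean()),
            "n_category_changes": int(
                category_shift_table(
                    list(zip(grp["category_ref"], grp["category_test"]))
                ).n_off_diagonal
            ),
        }
        if not followup_deviations.empty:
            within = followup_deviations[
                followup_deviations["pairing"] == f"{method}->{method}"
            ]
            if not within.empty:
                entry["followup_within_flagged"] = int(within["flagged"].sum())
        summary["methods"][method] = entry
    if not ba_table.empty:
        summary["bland_altman"] = ba_table.to_dict(orient="records")
    return summary


def _write_outputs(result: PipelineResult, records, config: AnalysisConfig) -> None:
    out = Path(config.output_dir)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    result.study_metrics.to_csv(tables / "study_metrics.csv", index=False)
    result.comparisons.to_csv(tables / "comparisons.csv", index=False)
    result.acceptance.to_csv(tables / "acceptance.csv", index=False)
    result.ba_table.to_csv(tables / "agreement_table.csv", index=False)
    if not result.followup_changes.empty:
        result.followup_changes.to_csv(tables / "followup_changes.csv", index=False)
        result.followup_deviations.to_csv(tables / "followup_deviations.csv", index=False)
    for method, counts in result.category_shifts.items():
        counts.to_csv(tables / f"category_shift_{method}.csv")
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2))


def simulate_to_disk(config: AnalysisConfig, out_dir: str | Path):
    """Generate the configured cohort and write it as NIfTI studies."""
    cohort = config.cohort
    records = generate_cohort(
        cohort.n_subjects,
        {k: v.to_profile() for k, v in cohort.method_profiles.items()},
        followup_fraction=cohort.followup_fraction,
        seed=config.seed,
        reference_label=config.reference_label,
        grid_shape=tuple(cohort.grid_shape),
        spacing=tuple(cohort.spacing_mm),
        noise_sd=cohort.noise_sd,
    )
    manifest = fio.write_cohort(records, out_dir)
    return records, manifest
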