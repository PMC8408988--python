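"""Cohort assembly and end-to-end discovery / validation analyses.

This module ties the stages together: failure-free-interval (FFI)
derivation from treatment records, ACT sensitive/resistant labelling,
the four-group response x HR-status subtypes, the combined
(HRD-or-immune-positive) responder classifier, and two orchestrated runs:

* :func:`run_discovery` — genome-level analysis of a full multi-omic
  bundle: scar scoring and HR-status calls, signature exposures, TMB,
  BRCA1 promoter methylation, immune scoring, survival comparisons
  (Kaplan-Meier/log-rank, adjusted Cox, likelihood-ratio test) and the
  time-fixed ROC comparison of combined status against HRD status alone.
* :func:`run_validation` — transcriptome-level analysis of an expression
  cohort against a frozen signature: HRDPS scoring, immune scoring, the
  four combined groups, survival and pCR-rate comparisons.

Reports are plain nested dicts (JSON-serialisable, stable key order).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from . import immune as immune_mod
from . import scars as scars_mod
from . import signatures as sig_mod
from . import stats as stats_mod
from .expression import HrdSignature, call_hrdps_positive, prognostic_score

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44

SENSITIVE, RESISTANT, UNASSIGNABLE = "sensitive", "resistant", "unassignable"

COMBINED_POSITIVE, COMBINED_NEGATIVE = "positive", "negative"
FOUR_BOTH_POS, FOUR_HRD_ONLY, FOUR_IS_ONLY, FOUR_BOTH_NEG = (
    "both+", "HRD-only+", "IS-only+", "both-",
)


@dataclass(frozen=True)
class TreatmentRecord:
    """Dated treatment course of one patient."""

    sample_id: str
    therapy_end: date
    progression: date | None = None
    death: date | None = None
    last_followup: date | None = None
    best_response: str = "unknown"  # CR, PR, SD, PD, unknown


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the discovery analysis."""

    hrd_threshold: int = 42
    sbs3_threshold: float = 0.3
    meth_cutoff: float = 0.9
    is_quantile: float = 0.75
    horizon: float = 60.0  # months; the "5-year" time point


def months_between(start: date, end: date) -> float:
    return (end - start).days / DAYS_PER_MONTH


def derive_ffi(record: TreatmentRecord) -> tuple[float, int]:
    """Failure-free interval: months from therapy end to the earliest of
    progression/recurrence or death (event), else to last follow-up
    (censored).  Negative intervals are rejected."""
    failures = [d for d in (record.progression, record.death) if d is not None]
    if failures:
        first = min(failures)
        t = months_between(record.therapy_end, first)
        if t < 0:
            raise ValueError(
                f"sample {record.sample_id}: failure date {first} precedes therapy end"
            )
        return t, 1
    if record.last_followup is None:
        raise ValueError(f"sample {record.sample_id}: no failure date and no follow-up date")
    t = months_between(record.therapy_end, record.last_followup)
    if t < 0:
        raise ValueError(
            f"sample {record.sample_id}: follow-up {record.last_followup} precedes therapy end"
        )
    return t, 0


def label_act_response(clinical: pd.DataFrame) -> pd.Series:
    """Sensitive/resistant ACT labels.

    A recorded best response takes precedence: complete response (CR) is
    sensitive; progressive or stable disease (PD/SD) is resistant.
    Otherwise the FFI-median rule applies: strictly above the cohort
    median is sensitive, at or below is resistant.  Samples with neither
    a usable response nor an FFI are unassignable.
    """
    ffi = clinical["ffi_months"] if "ffi_months" in clinical else pd.Series(dtype=float)
    median = float(ffi.dropna().median()) if ffi.notna().any() else np.nan
    labels = {}
    for sample, row in clinical.iterrows():
        response = str(row.get("response", "unknown"))
        if response == "CR":
            labels[sample] = SENSITIVE
        elif response in ("PD", "SD"):
            labels[sample] = RESISTANT
        elif pd.notna(row.get("ffi_months")) and not np.isnan(median):
            labels[sample] = SENSITIVE if row["ffi_months"] > median else RESISTANT
        else:
            labels[sample] = UNASSIGNABLE
    return pd.Series(labels, name="act_response")


def subtype_label(act_response: str, hr_deficient: bool) -> str:
    """Four-group subtype label, e.g. "ACT-S&HR-D"."""
    if act_response == UNASSIGNABLE:
        return UNASSIGNABLE
    act = "ACT-S" if act_response == SENSITIVE else "ACT-R"
    hr = "HR-D" if hr_deficient else "HR-P"
    return f"{act}&{hr}"


def combined_status(labels: pd.DataFrame, mode: str = "genome") -> pd.DataFrame:
    """Combined responder classifier: positive iff HRD (genome mode) or
    HRDPS-positive (transcriptome mode) OR immune-score positive.

    ``labels`` needs boolean columns ``is_positive`` plus ``hr_deficient``
    (genome) or ``hrdps_positive`` (transcriptome).  Returns binary and
    four-group classifications; samples with a missing component are
    unassignable.
    """
    if mode == "genome":
        first_col = "hr_deficient"
    elif mode == "transcriptome":
        first_col = "hrdps_positive"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for col in (first_col, "is_positive"):
        if col not in labels.columns:
            raise KeyError(f"combined status ({mode} mode) requires column {col!r}")
    out = {}
    for sample, row in labels.iterrows():
        a, b = row[first_col], row["is_positive"]
        if pd.isna(a) or pd.isna(b):
            out[sample] = {"combined_binary": UNASSIGNABLE, "combined_four": UNASSIGNABLE}
            continue
        a, b = bool(a), bool(b)
        binary = COMBINED_POSITIVE if (a or b) else COMBINED_NEGATIVE
        if a and b:
            four = FOUR_BOTH_POS
        elif a:
            four = FOUR_HRD_ONLY
        elif b:
            four = FOUR_IS_ONLY
        else:
            four = FOUR_BOTH_NEG
        out[sample] = {"combined_binary": binary, "combined_four": four}
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("sample")


# ---------------------------------------------------------------------------
# Orchestrated runs
# ---------------------------------------------------------------------------

def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-24s %.2fs", name, t1 - t0)
    return t1


def run_discovery(bundle, config: PipelineConfig = PipelineConfig()) -> dict:
    """Genome-level discovery analysis of a multi-omic cohort bundle.

    Returns a JSON-serialisable report; deterministic for a fixed bundle.
    Stage failures propagate with the stage name attached.
    """
    report: dict = {}
    t0 = time.perf_counter()
    try:
        stage = "scar_scoring"
        scores = scars_mod.score_cohort(
            bundle.segments, bundle.genome, bundle.mutations, threshold=config.hrd_threshold
        )
        t0 = _stage(stage, t0)

        stage = "mutational_signatures"
        spectra = sig_mod.build_spectra(bundle.mutations)
        exposures = sig_mod.fit_cohort_exposures(spectra)
        sbs3_dominant = exposures["SBS3"] >= config.sbs3_threshold
        tmb = bundle.mutations.groupby("sample").apply(
            scars_mod.compute_tmb, include_groups=False
        )
        t0 = _stage(stage, t0)

        stage = "brca1_methylation"
        meth_calls = {
            s: scars_mod.call_brca1_methylation(
                bundle.methylation[s], sample_id=s, cutoff=config.meth_cutoff
            )
            for s in bundle.samples
        }
        t0 = _stage(stage, t0)

        stage = "immune_scoring"
        activities = immune_mod.single_sample_activity(bundle.expression_log, bundle.gene_sets)
        is_scores = immune_mod.immune_score_pathway(activities)
        is_positive = immune_mod.call_is_positive(is_scores, quantile=config.is_quantile)
        t0 = _stage(stage, t0)

        stage = "labelling"
        clinical = bundle.clinical
        act = label_act_response(clinical)
        labels = pd.DataFrame(
            {
                "hr_deficient": scores["hr_status"] == scars_mod.HR_DEFICIENT,
                "is_positive": is_positive,
                "act_response": act,
            }
        ).loc[bundle.samples]
        labels["subtype"] = [
            subtype_label(labels.loc[s, "act_response"], bool(labels.loc[s, "hr_deficient"]))
            for s in labels.index
        ]
        combined = combined_status(labels, mode="genome")
        labels = labels.join(combined)
        t0 = _stage(stage, t0)

        stage = "survival_analysis"
        hr_groups = np.where(labels["hr_deficient"], "HR-deficient", "HR-proficient")
        km_ffi = stats_mod.km_logrank(
            clinical["ffi_months"], clinical["ffi_event"], hr_groups
        )
        km_os = stats_mod.km_logrank(clinical["os_months"], clinical["os_event"], hr_groups)
        surv_df = pd.DataFrame(
            {
                "time": clinical["ffi_months"],
                "event": clinical["ffi_event"],
                "hrd": labels["hr_deficient"].astype(int),
                "combined": (labels["combined_binary"] == COMBINED_POSITIVE).astype(int),
                "age": clinical["age"],
                "stage_iii": (clinical["stage"] == "III").astype(int),
            }
        )
        cox_hrd = stats_mod.cox_fit(surv_df, "time", "event", ["hrd", "age", "stage_iii"])
        cox_clinical = stats_mod.cox_fit(surv_df, "time", "event", ["age", "stage_iii"])
        cox_full = stats_mod.cox_fit(
            surv_df, "time", "event", ["age", "stage_iii", "combined"]
        )
        lr_stat, lr_p = stats_mod.lr_test(cox_clinical, cox_full)

        # positivity is protective, so the risk score for "failure by the
        # horizon" is the negated status indicator
        auc_combined = stats_mod.roc_at_time(
            1 - surv_df["combined"], surv_df["time"], surv_df["event"], config.horizon
        )
        auc_hrd = stats_mod.roc_at_time(
            1 - surv_df["hrd"], surv_df["time"], surv_df["event"], config.horizon
        )
        t0 = _stage(stage, t0)
    except Exception as exc:
        raise RuntimeError(f"discovery pipeline failed at stage {stage!r}: {exc}") from exc

    four_counts = labels["combined_four"].value_counts().to_dict()
    subtype_counts = labels["subtype"].value_counts().to_dict()
    report = {
        "n_samples": int(len(bundle.samples)),
        "hr_status": {
            "n_deficient": int(labels["hr_deficient"].sum()),
            "prevalence": float(labels["hr_deficient"].mean()),
            "threshold": config.hrd_threshold,
        },
        "sbs3": {"n_dominant": int(sbs3_dominant.sum())},
        "tmb": {"median": float(tmb.median())},
        "brca1_methylation": {
            "n_silenced": int(sum(bool(c.silenced) for c in meth_calls.values() if not c.missing))
        },
        "immune": {"n_positive": int(is_positive.sum())},
        "subtypes": {k: int(v) for k, v in sorted(subtype_counts.items())},
        "combined_four": {k: int(v) for k, v in sorted(four_counts.items())},
        "survival": {
            "km_ffi_logrank_p": km_ffi.p_value,
            "km_os_logrank_p": km_os.p_value,
            "ffi_hr_hrd": cox_hrd.hazard_ratio("hrd"),
            "ffi_hr_hrd_ci": list(cox_hrd.ci("hrd")),
            "ffi_hr_hrd_p": cox_hrd.p_value("hrd"),
            "lr_test_stat": lr_stat,
            "lr_test_p": lr_p,
            "auc_combined": auc_combined,
            "auc_hrd_alone": auc_hrd,
            "horizon_months": config.horizon,
        },
    }
    report["per_sample"] = {
        s: {
            "hrd_score": int(scores.loc[s, "hrd_score"]),
            "hr_deficient": bool(labels.loc[s, "hr_deficient"]),
            "is_positive": bool(labels.loc[s, "is_positive"]),
            "act_response": labels.loc[s, "act_response"],
            "subtype": labels.loc[s, "subtype"],
            "combined_binary": labels.loc[s, "combined_binary"],
        }
        for s in bundle.samples
    }
    return report


def run_validation(
    expression_log: pd.DataFrame,
    signature: HrdSignature,
    gene_sets,
    clinical: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Transcriptome-level validation of a frozen signature on an
    expression cohort: HRDPS and immune scoring, combined four-group
    survival comparison, and the pCR-rate table by combined status."""
    try:
        stage = "hrdps_scoring"
        ps = prognostic_score(expression_log, signature)
        hrdps_positive = call_hrdps_positive(ps["hrdps"])

        stage = "immune_scoring"
        activities = immune_mod.single_sample_activity(expression_log, gene_sets)
        is_scores = immune_mod.immune_score_pathway(activities)
        is_positive = immune_mod.call_is_positive(is_scores, quantile=config.is_quantile)

        stage = "combined_status"
        labels = pd.DataFrame(
            {"hrdps_positive": hrdps_positive, "is_positive": is_positive}
        )
        combined = combined_status(labels, mode="transcriptome")
        labels = labels.join(combined)

        stage = "survival_analysis"
        usable = clinical.index.intersection(labels.index)
        groups = labels.loc[usable, "combined_four"].to_numpy()
        km = stats_mod.km_logrank(
            clinical.loc[usable, "os_months"], clinical.loc[usable, "os_event"], groups
        )
        survival_at_horizon = km.survival_at(config.horizon)

        stage = "pcr_table"
        pcr = (clinical.loc[usable, "response"] == "CR").astype(int)
        binary = labels.loc[usable, "combined_binary"]
        table = np.array(
            [
                [int(pcr[binary == COMBINED_POSITIVE].sum()),
                 int((1 - pcr[binary == COMBINED_POSITIVE]).sum())],
                [int(pcr[binary == COMBINED_NEGATIVE].sum()),
                 int((1 - pcr[binary == COMBINED_NEGATIVE]).sum())],
            ]
        )
        fisher = stats_mod.fisher_exact(table)
    except Exception as exc:
        raise RuntimeError(f"validation pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "n_samples": int(len(labels)),
        "hrdps": {"n_positive": int(hrdps_positive.sum())},
        "immune": {"n_positive": int(is_positive.sum())},
        "combined_four": {
            k: int(v) for k, v in sorted(labels["combined_four"].value_counts().items())
        },
        "survival": {
            "logrank_p": km.p_value,
            "survival_at_horizon": {k: float(v) for k, v in sorted(survival_at_horizon.items())},
        },
        "pcr": {
            "table": table.tolist(),
            "rate_positive": float(table[0, 0] / table[0].sum()) if table[0].sum() else None,
            "rate_negative": float(table[1, 0] / table[1].sum()) if table[1].sum() else None,
            "fisher_p_two_sided": fisher.p_two_sided,
        },
    }


def report_to_json(report: dict) -> str:
    """Serialise a report with a stable key order for diffability."""
    return json.dumps(report, indent=2, sort_keys=True, default=float)
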