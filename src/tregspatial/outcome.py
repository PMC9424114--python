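"""Survival endpoints and outcome models.

Endpoints follow the standard adjuvant-trial definitions: 5-year
relapse-free survival (RFS) is time from surgery to recurrence or death
from any cause, administratively censored at 60 months, evaluated in
stage I-III patients with an R0 resection (negative margin > 1 mm) who had
no pre-operative radiotherapy and no synchronous primary tumor; overall
survival (time to death from any cause) is the endpoint for the separate
stage IV analysis.

Kaplan-Meier estimation, the log-rank test, and Cox proportional-hazards
fitting (Efron ties, stratified by cohort) are delegated to lifelines.
The bootstrap variable-retention wrapper (resample patients, run
p-value-based backward elimination, keep variables retained in >= 30% of
replicates) is implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io import ClinicalRecord, clinical_to_frame

log = logging.getLogger("tregspatial")

HORIZON_MONTHS = 60.0
EXCLUSION_ORDER = ("stageIV", "not_R0", "preop_radiotherapy", "synchronous",
                   "missing_data")


@dataclass
class EndpointRecord:
    patient_id: str
    endpoint: str  # RFS5 / OS5
    time_months: float
    event: bool
    inclusion: bool
    exclusion_reason: str  # one of EXCLUSION_ORDER or "none"
    cohort: str = "1"


def compute_endpoint(record: ClinicalRecord, endpoint: str) -> tuple[float, bool]:
    """(time, event) for one patient.

    RFS5: time to the first of relapse or death, censored at follow-up or
    60 months; OS5: death only.  Event times must be positive.
    """
    if endpoint not in ("RFS5", "OS5"):
        raise ValueError(f"unknown endpoint '{endpoint}'")
    event_times = []
    if endpoint == "RFS5":
        if record.relapse_months is not None:
            event_times.append(record.relapse_months)
    if record.death_months is not None:
        event_times.append(record.death_months)
    for t in event_times + [record.followup_months]:
        if t is not None and t <= 0:
            raise ValueError(
                f"patient {record.patient_id}: non-positive time {t}"
            )
    censor_time = min(record.followup_months, HORIZON_MONTHS)
    if event_times:
        t_event = min(event_times)
        if t_event <= HORIZON_MONTHS:
            return float(t_event), True
    return float(censor_time), False


def apply_cohort_filters(
    records: Sequence[ClinicalRecord], endpoint: str = "RFS5"
) -> list[EndpointRecord]:
    """Endpoint records with inclusion flags.

    RFS5 includes stage I-III, R0, no pre-operative radiotherapy, no
    synchronous primary; OS5 is the separate stage IV analysis (non-stage-IV
    patients fail the stage criterion).  The first matching exclusion
    reason, in the documented order, is recorded.
    """
    out = []
    for r in records:
        reason = "none"
        if endpoint == "RFS5":
            if r.tnm_stage == "IV":
                reason = "stageIV"
            elif r.r_status != "R0":
                reason = "not_R0"
            elif r.preop_radio:
                reason = "preop_radiotherapy"
            elif r.synchronous_primary:
                reason = "synchronous"
        elif endpoint == "OS5":
            if r.tnm_stage != "IV":
                reason = "stageIV"
            elif r.preop_radio:
                reason = "preop_radiotherapy"
            elif r.synchronous_primary:
                reason = "synchronous"
        else:
            raise ValueError(f"unknown endpoint '{endpoint}'")
        if reason == "none" and (r.followup_months is None or np.isnan(r.followup_months)):
            reason = "missing_data"
        time, event = compute_endpoint(r, endpoint) if reason == "none" else (0.0, False)
        out.append(
            EndpointRecord(
                patient_id=r.patient_id,
                endpoint=endpoint,
                time_months=time if reason == "none" else float("nan"),
                event=event,
                inclusion=reason == "none",
                exclusion_reason=reason,
                cohort=r.cohort,
            )
        )
    return out


def endpoints_to_frame(endpoints: Sequence[EndpointRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "endpoint": e.endpoint,
                "time_months": e.time_months,
                "event": int(e.event),
                "inclusion": int(e.inclusion),
                "exclusion_reason": e.exclusion_reason,
                "cohort": e.cohort,
            }
            for e in endpoints
        ]
    )


# ---------------------------------------------------------------------------
# estimators


def km_estimate(times, events) -> tuple[pd.DataFrame, float]:
    """Product-limit survival curve with Greenwood confidence band.

    Returns (curve frame with timeline / survival / lower / upper columns,
    survival at 60 months).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.size == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    ci = kmf.confidence_interval_survival_function_
    curve = pd.DataFrame(
        {
            "timeline": kmf.survival_function_.index.to_numpy(float),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(float),
            "lower": ci.iloc[:, 0].to_numpy(float),
            "upper": ci.iloc[:, 1].to_numpy(float),
        }
    )
    s60 = float(kmf.predict(HORIZON_MONTHS))
    return curve, s60


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square across >= 2 groups; returns (statistic, p)."""
    groups = pd.Series(groups).astype(str)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    res = multivariate_logrank_test(np.asarray(times, float), groups,
                                    np.asarray(events, int))
    return float(res.test_statistic), float(res.p_value)


DEFAULT_COVARIATES = (
    "ieCD8_high", "mean_cd25_high", "proximity_significant",
    "pT3", "pT4", "pN1", "pN2", "msi", "age",
)


def survival_frame(
    endpoints: Sequence[EndpointRecord],
    features: pd.DataFrame,
    recode_pt12: bool = True,
) -> pd.DataFrame:
    """Model frame for Cox fitting: time, event, cohort and dummy-coded
    covariates, included patients only.

    ``features`` is the per-patient feature table (from the image pipeline
    or the synthetic generator); pT1 and pT2 are combined into the
    reference level by default.
    """
    ep = endpoints_to_frame(endpoints)
    ep = ep[ep["inclusion"] == 1]
    df = ep.merge(features, on="patient_id", how="inner", suffixes=("", "_feat"))
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "time": df["time_months"],
            "event": df["event"],
            "cohort": df["cohort"],
        }
    )
    for col in ("ieCD8_high", "mean_cd25_high", "proximity_significant"):
        if col in df.columns:
            out[col] = df[col].astype(float)
    if "pT" in df.columns:
        pt = df["pT"].astype(str)
        if not recode_pt12:
            out["pT2"] = (pt == "2").astype(float)
        out["pT3"] = (pt == "3").astype(float)
        out["pT4"] = (pt == "4").astype(float)
    if "pN" in df.columns:
        out["pN1"] = (df["pN"].astype(str) == "1").astype(float)
        out["pN2"] = (df["pN"].astype(str) == "2").astype(float)
    if "msi" in df.columns:
        out["msi"] = (df["msi"] == "MSI").astype(float)
    if "age" in df.columns:
        out["age"] = df["age"].astype(float)
    return out.reset_index(drop=True)


def cox_fit(
    frame: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    strata: str | None = "cohort",
) -> tuple[pd.DataFrame, dict]:
    """Cox proportional-hazards fit (Efron ties), complete cases only.

    Returns (coefficient table with HR / 95% CI / p per covariate,
    diagnostics dict with concordance, AIC and the proportional-hazards
    test p-values).
    """
    covariates = [c for c in covariates if c in frame.columns]
    cols = ["time", "event"] + covariates + ([strata] if strata else [])
    data = frame[cols].dropna()
    n_dropped = len(frame) - len(data)
    if n_dropped:
        log.info("cox_fit: %d incomplete cases dropped", n_dropped)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="time", event_col="event",
                strata=strata if strata else None)
    except Exception as exc:
        raise RuntimeError(
            f"Cox model did not converge on n={len(data)}, "
            f"events={int(data['event'].sum())}: {exc}"
        ) from exc
    summ = cph.summary
    table = pd.DataFrame(
        {
            "covariate": summ.index,
            "HR": np.exp(summ["coef"]).to_numpy(),
            "ci_lower": np.exp(summ["coef lower 95%"]).to_numpy(),
            "ci_upper": np.exp(summ["coef upper 95%"]).to_numpy(),
            "p": summ["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    try:
        from lifelines.statistics import proportional_hazard_test

        ph = proportional_hazard_test(cph, data, time_transform="rank")
        ph_p = dict(zip(ph.summary.index.get_level_values(0), ph.summary["p"]))
    except Exception:  # diagnostic only
        ph_p = {}
    diagnostics = {
        "concordance": float(cph.concordance_index_),
        "AIC": float(cph.AIC_partial_),
        "n": int(len(data)),
        "events": int(data["event"].sum()),
        "ph_test_p": ph_p,
    }
    return table, diagnostics


# ---------------------------------------------------------------------------
# bootstrap variable selection


def _backward_eliminate(data, covariates, strata, stay_p) -> list[str]:
    current = list(covariates)
    while current:
        cph = CoxPHFitter()
        try:
            cph.fit(
                data[["time", "event"] + current + ([strata] if strata else [])],
                duration_col="time", event_col="event",
                strata=strata if strata else None,
            )
        except Exception:
            # degenerate resample (e.g. constant covariate): drop the first
            # offender and continue
            variances = data[current].var()
            worst = variances.idxmin()
            current.remove(worst)
            continue
        pvals = cph.summary["p"]
        worst = pvals.idxmax()
        if pvals[worst] <= stay_p:
            break
        current.remove(worst)
    return current


def bootstrap_selection(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    B: int = 1000,
    retain_threshold: float = 0.30,
    stay_p: float = 0.157,
    strata: str | None = "cohort",
    seed: int = 0,
) -> tuple[list[str], pd.Series]:
    """Bootstrap + backward-selection variable retention.

    Each of ``B`` replicates resamples patients with replacement, runs
    p-value-based backward elimination (stay criterion p <= ``stay_p``,
    the 1-df AIC-equivalent by default), and records the surviving
    variables.  Variables retained in >= ``retain_threshold`` of replicates
    form the retained set.
    """
    if B < 50:
        raise ValueError("B < 50 bootstrap replicates is too few for retention "
                         "frequencies")
    covariates = [c for c in covariates if c in frame.columns]
    data = frame[["time", "event"] + covariates + ([strata] if strata else [])].dropna()
    rng = np.random.default_rng(seed)
    hits = {c: 0 for c in covariates}
    n = len(data)
    for _ in range(B):
        idx = rng.integers(0, n, n)
        boot = data.iloc[idx].reset_index(drop=True)
        for c in _backward_eliminate(boot, covariates, strata, stay_p):
            hits[c] += 1
    freq = pd.Series({c: hits[c] / B for c in covariates}, name="retention")
    retained = [c for c in covariates if freq[c] >= retain_threshold]
    return retained, freq
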