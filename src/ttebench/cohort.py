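"""Active-comparator new-user cohort construction.

Identifies first-time initiators of the exposure or comparator drug after a
drug-free washout, applies continuous-enrollment and eligibility criteria
including cardiovascular risk tiers, and emits the indexed cohort together
with a step-by-step attrition table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import claims
from .errors import ConfigError, DataIntegrityError, EmptyArmError

log = logging.getLogger(__name__)

RISK_TIERS = ("low", "moderate", "high")


@dataclass(frozen=True)
class EligibilitySpec:
    """Eligibility criteria for one pairwise comparison.

    Washout is assessed against exposure, comparator AND same-class codes,
    so "new user" means new to the whole class comparison.  ``risk_tier_required``
    restricts the cohort to the named cardiovascular risk tiers; the full
    set {low, moderate, high} is the expanded (routine-care) population.
    """

    exposure_codes: frozenset[str] = frozenset({claims.EXPOSURE_CODE})
    comparator_codes: frozenset[str] = frozenset({claims.COMPARATOR_CODE})
    same_class_codes: frozenset[str] = frozenset(claims.SAME_CLASS_CODES)
    washout_days: int = 365
    min_enrollment_days: int = 365
    risk_tier_required: frozenset[str] = frozenset(RISK_TIERS)
    # tier rules: code sets assessed over the washout-length lookback
    established_cvd_codes: frozenset[str] = frozenset({claims.covariate_code("cvd_history")})
    subclinical_cvd_codes: frozenset[str] = frozenset({claims.covariate_code("microalbuminuria")})
    high_risk_min_age: int = 50
    moderate_risk_min_age: int = 60
    exclusion_codes: frozenset[str] = frozenset()
    exclusion_lookback_days: int = 365
    required_history_codes: frozenset[str] = frozenset()
    required_history_lookback_days: int = 365

    def validate(self) -> None:
        if self.exposure_codes & self.comparator_codes:
            raise ConfigError("exposure_codes and comparator_codes must be disjoint")
        if self.washout_days <= 0:
            raise ConfigError("washout_days must be > 0")
        if self.min_enrollment_days <= 0:
            raise ConfigError("min_enrollment_days must be > 0")
        if not self.risk_tier_required <= set(RISK_TIERS):
            raise ConfigError(f"risk_tier_required must be a subset of {RISK_TIERS}")
        if not self.risk_tier_required:
            raise ConfigError("risk_tier_required must be non-empty")


def identify_new_users(bundle: claims.ClaimsBundle,
                       spec: EligibilitySpec) -> pd.DataFrame:
    """Candidate index events: one row (patient_id, arm, index_day) per patient.

    The candidate is the first fill of an exposure or comparator code.  It
    qualifies only if no fill of any code in the combined class (exposure,
    comparator, same-class) occurred in the washout window
    ``[index_day - washout_days, index_day)``.  Patients whose first fills
    of both classes fall on the same day cannot be assigned an arm and are
    excluded.
    """
    disp = bundle.dispensings
    if disp.empty:
        log.warning("dispensings table is empty; no new users identified")
        return pd.DataFrame(columns=["patient_id", "arm", "index_day"])

    study = disp[disp["drug_code"].isin(spec.exposure_codes | spec.comparator_codes)]
    if study.empty:
        log.warning("no fills of study drugs present; no new users identified")
        return pd.DataFrame(columns=["patient_id", "arm", "index_day"])

    first_day = study.groupby("patient_id")["fill_day"].min().rename("index_day")
    first_fills = study.merge(first_day, on="patient_id")
    first_fills = first_fills[first_fills["fill_day"] == first_fills["index_day"]]

    is_expo = first_fills["drug_code"].isin(spec.exposure_codes)
    arms = first_fills.assign(is_expo=is_expo).groupby("patient_id")["is_expo"].agg(["any", "all"])
    dual = arms["any"] & ~arms["all"]  # both classes filled on the index day
    cand = pd.DataFrame({
        "patient_id": arms.index,
        "arm": np.where(arms["all"], "exposure", "comparator"),
        "index_day": first_day.loc[arms.index].to_numpy(),
    })
    cand = cand[~dual.to_numpy()]

    # washout: any class fill strictly before the index day within the window
    class_codes = spec.exposure_codes | spec.comparator_codes | spec.same_class_codes
    prior = disp[disp["drug_code"].isin(class_codes)].merge(
        cand[["patient_id", "index_day"]], on="patient_id")
    bad = prior[(prior["fill_day"] < prior["index_day"])
                & (prior["fill_day"] >= prior["index_day"] - spec.washout_days)]
    cand = cand[~cand["patient_id"].isin(bad["patient_id"].unique())]
    return cand.reset_index(drop=True)


def check_enrollment(spans: Sequence[tuple[int, int]], index_day: int,
                     min_enrollment_days: int) -> bool:
    """True iff a single half-open span covers ``[index_day - min_days, index_day]``.

    Spans must be sorted and non-overlapping.
    """
    prev_end = None
    for start, end in spans:
        if start >= end:
            raise DataIntegrityError(f"invalid enrollment span [{start}, {end})")
        if prev_end is not None and start < prev_end:
            raise DataIntegrityError("enrollment spans unsorted or overlapping")
        prev_end = end
        if start <= index_day - min_enrollment_days and end > index_day:
            return True
    return False


def assign_risk_tier(age: float, history_codes: Iterable[str],
                     spec: EligibilitySpec) -> str:
    """Cardiovascular risk tier from age and lookback diagnosis history.

    High: age >= 50 with established cardiovascular disease; moderate:
    age >= 60 with a subclinical risk marker; otherwise low.  Code sets
    are configuration, not hard-coded vocabularies.
    """
    history = set(history_codes)
    if age >= spec.high_risk_min_age and history & spec.established_cvd_codes:
        return "high"
    if age >= spec.moderate_risk_min_age and history & spec.subclinical_cvd_codes:
        return "moderate"
    return "low"


def build_cohort(bundle: claims.ClaimsBundle, spec: EligibilitySpec,
                 database_id: str = "db0") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply all eligibility steps in order; return (cohort, attrition).

    Order: new-user identification (washout, same-day duals) -> continuous
    enrollment -> exclusions / required history (only when configured) ->
    risk-tier filter.  The attrition table records the remaining count
    after each step and is non-increasing by construction.
    """
    spec.validate()
    attrition: list[tuple[str, int]] = []

    study_codes = spec.exposure_codes | spec.comparator_codes
    users = bundle.dispensings[bundle.dispensings["drug_code"].isin(study_codes)]
    attrition.append(("patients with a study-drug fill", users["patient_id"].nunique()))

    cand = identify_new_users(bundle, spec)
    attrition.append(("new users (washout, same-day duals excluded)", len(cand)))

    # continuous enrollment covering [index - min_enrollment_days, index]
    enr = bundle.enrollment.sort_values(["patient_id", "span_start_day"])
    spans_by_pid = {pid: list(zip(g["span_start_day"], g["span_end_day"]))
                    for pid, g in enr.groupby("patient_id")}
    keep = [check_enrollment(spans_by_pid.get(row.patient_id, ()), row.index_day,
                             spec.min_enrollment_days)
            for row in cand.itertuples()]
    cand = cand[np.asarray(keep, dtype=bool)] if len(cand) else cand
    attrition.append(("continuous enrollment", len(cand)))

    dx = bundle.diagnoses.merge(cand[["patient_id", "index_day"]], on="patient_id")
    dx_pre = dx[dx["day"] < dx["index_day"]]

    if spec.exclusion_codes or spec.required_history_codes:
        if spec.exclusion_codes:
            w = spec.exclusion_lookback_days
            bad = dx_pre[(dx_pre["code"].isin(spec.exclusion_codes))
                         & (dx_pre["day"] >= dx_pre["index_day"] - w)]
            cand = cand[~cand["patient_id"].isin(bad["patient_id"].unique())]
        if spec.required_history_codes:
            w = spec.required_history_lookback_days
            good = dx_pre[(dx_pre["code"].isin(spec.required_history_codes))
                          & (dx_pre["day"] >= dx_pre["index_day"] - w)]
            cand = cand[cand["patient_id"].isin(good["patient_id"].unique())]
        attrition.append(("exclusions / required history", len(cand)))

    # risk tier: needs a computable age
    cand = cand.merge(bundle.patients[["patient_id", "birth_year"]],
                      on="patient_id", how="left")
    missing = cand["birth_year"].isna()
    if missing.any():
        log.info("%d patients flagged ineligible: missing birth_year", missing.sum())
    cand = cand[~missing].copy()
    cand["age"] = (claims.EPOCH_YEAR + cand["index_day"] // 365) - cand["birth_year"]

    tier_codes = spec.established_cvd_codes | spec.subclinical_cvd_codes
    lookback = dx_pre[dx_pre["code"].isin(tier_codes)
                      & (dx_pre["day"] >= dx_pre["index_day"] - spec.washout_days)]
    history = lookback.groupby("patient_id")["code"].agg(set).to_dict()
    cand["risk_tier"] = [
        assign_risk_tier(row.age, history.get(row.patient_id, ()), spec)
        for row in cand.itertuples()
    ]
    cand = cand[cand["risk_tier"].isin(spec.risk_tier_required)]
    attrition.append(("risk tier", len(cand)))

    cohort = cand[["patient_id", "arm", "index_day", "risk_tier", "age"]].copy()
    cohort["database_id"] = database_id
    cohort = cohort.reset_index(drop=True)

    counts = cohort["arm"].value_counts()
    if counts.get("exposure", 0) == 0 or counts.get("comparator", 0) == 0:
        raise EmptyArmError(
            f"cohort has an empty arm after eligibility filters (counts: {counts.to_dict()})")

    attrition_df = pd.DataFrame(attrition, columns=["criterion", "n_remaining"])
    return cohort, attrition_df
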