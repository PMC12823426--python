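"""As-treated / as-started follow-up and endpoint ascertainment.

Follow-up starts the day after the index dispensing (index-day events are
baseline history) and ends at the earliest of: an endpoint event,
treatment discontinuation (last supply end plus a grace period; as-treated
only), a switch to the comparator drug, a fill of another same-class
agent, disenrollment, or the administrative end of the window (52 weeks =
364 days by default).  On an exact tie the endpoint outranks every
censoring reason.  Same-day composite components resolve by a fixed
severity order (death > myocardial infarction > stroke > others).

For composites that do not include death, a death inside follow-up is
recorded as a competing event (``competing_death``) so that downstream
absolute risks can use the Aalen–Johansen estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import claims
from .cohort import EligibilitySpec
from .errors import ConfigError

#: fixed severity order for same-day composite components
COMPONENT_SEVERITY = ("death", "myocardial_infarction", "stroke")

CENSOR_HIERARCHY = ("discontinuation", "switch", "same_class_start",
                    "disenrollment", "study_end")


@dataclass(frozen=True)
class EndpointDef:
    """A named (composite) endpoint.

    ``components`` maps component names to their diagnosis code sets; the
    special component ``"death"`` reads the deaths table.  ``primary`` and
    ``negative_control`` drive reporting; estimator choice downstream is
    Kaplan–Meier when death is a component and Aalen–Johansen otherwise.
    """

    name: str
    components: Mapping[str, frozenset[str]]
    primary: bool = False
    negative_control: bool = False

    @property
    def includes_death(self) -> bool:
        return "death" in self.components

    def ordered_components(self) -> list[str]:
        sev = {c: i for i, c in enumerate(COMPONENT_SEVERITY)}
        return sorted(self.components, key=lambda c: (sev.get(c, len(sev)), c))


@dataclass(frozen=True)
class FollowUpSpec:
    """Follow-up window, grace period, causal contrast and endpoints."""

    endpoints: tuple[EndpointDef, ...]
    max_days: int = 364           # "52 weeks"
    grace_days: int = 45
    contrast: str = "as_treated"  # or "as_started"
    censor_on: tuple[str, ...] = CENSOR_HIERARCHY

    def validate(self) -> None:
        if self.max_days <= 0:
            raise ConfigError("max_days must be > 0")
        if self.grace_days < 0:
            raise ConfigError("grace_days must be >= 0")
        if self.contrast not in ("as_treated", "as_started"):
            raise ConfigError("contrast must be 'as_treated' or 'as_started'")
        if not self.endpoints:
            raise ConfigError("at least one endpoint must be defined")
        for ep in self.endpoints:
            if not ep.components:
                raise ConfigError(f"endpoint {ep.name!r} has no components")

    def endpoint(self, name: str) -> EndpointDef:
        for ep in self.endpoints:
            if ep.name == name:
                return ep
        raise ConfigError(f"endpoint {name!r} is not defined in the follow-up spec")


def endpoints_from_scenario(config: claims.ScenarioConfig) -> tuple[EndpointDef, ...]:
    """Default endpoint set for a synthetic scenario.

    Builds the all-cause composite (death + nonfatal components), the
    nonfatal-only composite, each nonfatal component alone, plus one
    endpoint per negative-control outcome.
    """
    nonfatal = [o for o in config.outcomes
                if not o.fatal and not o.negative_control]
    ncs = [o for o in config.outcomes if o.negative_control]
    comp = {o.name: frozenset({claims.outcome_code(o.name)}) for o in nonfatal}
    eps = [
        EndpointDef("mace", {**comp, "death": frozenset()}, primary=True),
        EndpointDef("mace_nonfatal", dict(comp)),
    ]
    eps += [EndpointDef(o.name, {o.name: frozenset({claims.outcome_code(o.name)})})
            for o in nonfatal]
    eps += [EndpointDef(o.name, {o.name: frozenset({claims.outcome_code(o.name)})},
                        negative_control=True) for o in ncs]
    return tuple(eps)


def exposure_episode(fill_days: Sequence[int], days_supply: Sequence[int] | int,
                     index_day: int, grace_days: int) -> int:
    """Discontinuation day of the continuous-exposure episode.

    Fills chain while the next fill occurs no later than the running
    supply end plus the grace period; the episode ends at the final
    chained supply end plus the grace period.  A single fill is a valid
    episode.
    """
    days = sorted(fill_days)
    if not days or days[0] != index_day:
        raise ConfigError("exposure episode must start with a fill on the index day")
    if isinstance(days_supply, int):
        supplies = [days_supply] * len(days)
    else:
        supplies = [s for _, s in sorted(zip(fill_days, days_supply))]
    supply_end = days[0] + supplies[0]
    for day, sup in zip(days[1:], supplies[1:]):
        if day <= supply_end + grace_days:
            supply_end = max(supply_end, day + sup)
        else:
            break
    return supply_end + grace_days


def determine_exit(event_days: Mapping[str, int | None], censor_days: Mapping[str, int | None],
                   index_day: int, spec: FollowUpSpec,
                   endpoint: EndpointDef) -> tuple[int, str, str | None, str | None]:
    """Resolve one patient's exit for one endpoint.

    ``event_days`` maps component names (plus ``"death"`` when observed) to
    their first post-index day; ``censor_days`` maps censoring reasons to
    days.  Returns ``(time, status, event_component, censor_reason)`` with
    time in days since index (>= 1).
    """
    active = list(spec.censor_on)
    if spec.contrast == "as_started":
        active = [r for r in active
                  if r not in ("discontinuation", "switch", "same_class_start")]

    censor_day, censor_reason = None, None
    for reason in active:  # hierarchy order breaks exact censor-day ties
        day = censor_days.get(reason)
        if day is not None and (censor_day is None or day < censor_day):
            censor_day, censor_reason = day, reason
    if censor_day is None:
        raise ConfigError("no applicable censoring rule produced an exit day")

    # earliest component event, severity order breaking same-day ties
    ev_day, ev_comp = None, None
    for comp in endpoint.ordered_components():
        day = event_days.get(comp)
        if day is not None and day > index_day and (ev_day is None or day < ev_day):
            ev_day, ev_comp = day, comp

    death_day = event_days.get("death")

    if ev_day is not None and ev_day <= censor_day:
        # nonfatal composite: a strictly earlier death is a competing event
        if (not endpoint.includes_death and death_day is not None
                and death_day < ev_day):
            return death_day - index_day, "competing_death", None, None
        return ev_day - index_day, "event", ev_comp, None

    if (not endpoint.includes_death and death_day is not None
            and index_day < death_day <= censor_day):
        return death_day - index_day, "competing_death", None, None

    return censor_day - index_day, "censored", None, censor_reason


def _episode_ends(pids: np.ndarray, fill_days: np.ndarray, supplies: np.ndarray,
                  grace_days: int) -> dict[int, int]:
    """Vectorized-friendly episode chaining over (pid-sorted) fill arrays.

    Mirrors :func:`exposure_episode` row by row; equality with the scalar
    reference is asserted property-style in the test suite.
    """
    out: dict[int, int] = {}
    current_pid = None
    supply_end = 0
    broken = False
    for pid, day, sup in zip(pids.tolist(), fill_days.tolist(), supplies.tolist()):
        if pid != current_pid:
            if current_pid is not None:
                out[current_pid] = supply_end + grace_days
            current_pid, supply_end, broken = pid, day + sup, False
        elif not broken:
            if day <= supply_end + grace_days:
                supply_end = max(supply_end, day + sup)
            else:
                broken = True
    if current_pid is not None:
        out[current_pid] = supply_end + grace_days
    return out


def build_followup(bundle: claims.ClaimsBundle, cohort: pd.DataFrame,
                   spec: FollowUpSpec,
                   eligibility: EligibilitySpec | None = None) -> dict[str, pd.DataFrame]:
    """Per-endpoint follow-up records for every cohort member.

    Returns ``{endpoint_name: DataFrame(patient_id, arm, time, status,
    event_component, censor_reason)}``; every member yields exactly one
    record per endpoint and no time exceeds ``spec.max_days``.
    """
    spec.validate()
    eligibility = eligibility or EligibilitySpec()

    pids = cohort["patient_id"].to_numpy()
    index_day = dict(zip(pids, cohort["index_day"].to_numpy()))
    arm = dict(zip(pids, cohort["arm"].to_numpy()))
    members = set(pids.tolist())

    disp = bundle.dispensings.merge(
        cohort[["patient_id", "arm", "index_day"]], on="patient_id")
    is_expo_code = disp["drug_code"].isin(eligibility.exposure_codes)
    is_comp_code = disp["drug_code"].isin(eligibility.comparator_codes)
    expo_arm = disp["arm"] == "exposure"

    # per-patient censoring days -------------------------------------
    own = disp[((expo_arm & is_expo_code) | (~expo_arm & is_comp_code))
               & (disp["fill_day"] >= disp["index_day"])]
    own = own.sort_values(["patient_id", "fill_day"], kind="mergesort")
    disc_day = _episode_ends(own["patient_id"].to_numpy(),
                             own["fill_day"].to_numpy(),
                             own["days_supply"].to_numpy(), spec.grace_days)

    other = disp[((expo_arm & is_comp_code) | (~expo_arm & is_expo_code))
                 & (disp["fill_day"] > disp["index_day"])]
    switch_day = other.groupby("patient_id")["fill_day"].min().to_dict()

    sc = disp[disp["drug_code"].isin(eligibility.same_class_codes)
              & (disp["fill_day"] > disp["index_day"])]
    same_class_day = sc.groupby("patient_id")["fill_day"].min().to_dict()

    enr = bundle.enrollment.merge(cohort[["patient_id", "index_day"]], on="patient_id")
    covering = enr[(enr["span_start_day"] <= enr["index_day"])
                   & (enr["span_end_day"] > enr["index_day"])]
    disenroll_day = covering.groupby("patient_id")["span_end_day"].min().to_dict()

    # per-patient first event day per component ----------------------
    all_codes: dict[str, str] = {}
    for ep in spec.endpoints:
        for comp, codes in ep.components.items():
            for code in codes:
                all_codes[code] = comp
    dx = bundle.diagnoses[bundle.diagnoses["patient_id"].isin(members)
                          & bundle.diagnoses["code"].isin(all_codes)]
    comp_day: dict[int, dict[str, int]] = {p: {} for p in members}
    if len(dx):
        dxv = dx.assign(component=dx["code"].map(all_codes))
        firsts = dxv.groupby(["patient_id", "component"])["day"].min()
        for (pid, comp), day in firsts.items():
            if day > index_day[pid]:
                comp_day[pid][comp] = int(day)
    for row in bundle.deaths.itertuples():
        if row.patient_id in members and row.death_day > index_day[row.patient_id]:
            comp_day[row.patient_id]["death"] = int(row.death_day)

    results: dict[str, list] = {ep.name: [] for ep in spec.endpoints}
    for pid in pids:
        idx = index_day[pid]
        censors = {
            "discontinuation": disc_day.get(pid),
            "switch": switch_day.get(pid),
            "same_class_start": same_class_day.get(pid),
            "disenrollment": disenroll_day.get(pid, idx + 1),
            "study_end": idx + spec.max_days,
        }
        # administrative cap applies in both contrasts
        censors = {k: (min(v, idx + spec.max_days) if v is not None else None)
                   for k, v in censors.items()}
        events = comp_day[pid]
        for ep in spec.endpoints:
            t, status, comp, reason = determine_exit(events, censors, idx, spec, ep)
            results[ep.name].append((pid, arm[pid], t, status, comp, reason))

    return {name: pd.DataFrame(rows, columns=["patient_id", "arm", "time",
                                              "status", "event_component",
                                              "censor_reason"])
            for name, rows in results.items()}


def censoring_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Count and proportion of each censoring reason among censored records."""
    censored = records[records["status"] == "censored"]
    if censored.empty:
        return pd.DataFrame(columns=["censor_reason", "count", "proportion"])
    counts = censored["censor_reason"].value_counts()
    return pd.DataFrame({
        "censor_reason": counts.index,
        "count": counts.to_numpy(),
        "proportion": counts.to_numpy() / counts.sum(),
    }).reset_index(drop=True)
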