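"""End-to-end study orchestration.

One declarative :class:`StudyConfig` drives the whole emulation:
generate (or load) claims -> build the new-user cohort -> assess baseline
covariates and pre-matching balance -> estimate propensity scores and
match 1:1 within caliper, separately per database -> construct as-treated
follow-up -> estimate per-database hazard ratios -> pool by fixed-effects
inverse variance -> compute absolute risks and bootstrap risk differences
on the combined matched data -> score agreement against any configured
reference-trial estimates.

Runs are fully reproducible from (config, seeds); each stochastic stage
derives its stream from the config's seeds only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import balance as balance_mod
from . import claims as claims_mod
from . import cohort as cohort_mod
from . import followup as followup_mod
from . import matching as matching_mod
from . import survival as survival_mod
from .benchmark import AgreementReport, agreement_metrics, pool_fixed_effects, se_from_ci
from .errors import ConfigError, TTEBenchError
from .estimates import EffectEstimate

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkRef:
    """A published reference-trial estimate to benchmark one endpoint against."""

    endpoint: str
    hr: float
    ci_low: float
    ci_high: float
    primary: bool = False
    label: str = ""


@dataclass
class StudyConfig:
    """Declarative specification of one study run."""

    scenario: claims_mod.ScenarioConfig | None
    eligibility: cohort_mod.EligibilitySpec
    covariates: tuple[balance_mod.CovariateDef, ...]
    followup: followup_mod.FollowUpSpec
    claims_dirs: tuple[str, ...] = ()
    caliper: float = matching_mod.DEFAULT_CALIPER
    match_seed: int = 0
    bootstrap_replicates: int = 1000
    bootstrap_seed: int = 0
    horizon: int = 364
    benchmarks: tuple[BenchmarkRef, ...] = ()
    compute_risk_difference: bool = True
    compute_crude: bool = True


@dataclass
class Finding:
    field: str
    severity: str  # "error" | "warning"
    message: str


def validate_config(config: StudyConfig) -> list[Finding]:
    """Machine-readable validation findings; empty means the config is runnable."""
    findings: list[Finding] = []

    def err(field_name, msg):
        findings.append(Finding(field_name, "error", msg))

    if config.scenario is None and not config.claims_dirs:
        err("scenario", "either a scenario or claims_dirs must be supplied")
    if config.scenario is not None and config.claims_dirs:
        findings.append(Finding("claims_dirs", "warning",
                                "both scenario and claims_dirs given; scenario wins"))
    if config.scenario is not None:
        try:
            config.scenario.validate()
        except ConfigError as exc:
            err("scenario", str(exc))
    try:
        config.eligibility.validate()
    except ConfigError as exc:
        err("eligibility", str(exc))
    try:
        config.followup.validate()
    except ConfigError as exc:
        err("followup", str(exc))
    if config.caliper <= 0:
        err("matching.caliper", "caliper must be > 0")
    if config.bootstrap_replicates < 2:
        err("bootstrap.replicates", "bootstrap replicates must be >= 2")
    if config.horizon <= 0 or config.horizon > config.followup.max_days:
        err("horizon", "horizon must lie in (0, followup.max_days]")
    endpoint_names = {ep.name for ep in config.followup.endpoints}
    for ref in config.benchmarks:
        if ref.endpoint not in endpoint_names:
            err("benchmarks", f"benchmark endpoint {ref.endpoint!r} absent from endpoints")
        if not (0 < ref.ci_low <= ref.hr <= ref.ci_high):
            err("benchmarks", f"benchmark for {ref.endpoint!r}: invalid HR/CI ordering")
    return findings


@dataclass
class EndpointResult:
    """Everything computed for one endpoint."""

    name: str
    per_database: list[EffectEstimate]
    pooled: EffectEstimate
    crude_pooled: EffectEstimate | None
    risk_difference: survival_mod.RiskDifference | None
    negative_control: bool
    negative_control_flagged: bool | None  # CI excludes 1 -> residual confounding


@dataclass
class StudyReport:
    """Consolidated output of :func:`run_study`."""

    attrition: dict[str, pd.DataFrame]
    balance_pre: pd.DataFrame
    balance_post: pd.DataFrame
    max_smd_pre: float
    max_smd_post: float
    n_matched_pairs: dict[str, int]
    endpoints: dict[str, EndpointResult]
    censoring: pd.DataFrame
    agreement: dict[str, AgreementReport]
    provenance: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for db, tab in self.attrition.items():
            tab.to_csv(out / f"attrition_{db}.csv", index=False)
        self.balance_pre.to_csv(out / "balance_pre.csv", index=False)
        self.balance_post.to_csv(out / "balance_post.csv", index=False)
        self.censoring.to_csv(out / "censoring.csv", index=False)
        rows = []
        for name, res in self.endpoints.items():
            for est in res.per_database + [res.pooled]:
                rows.append({"endpoint": name, "source": est.source, "hr": est.hr,
                             "ci_low": est.ci_low, "ci_high": est.ci_high,
                             "log_hr": est.log_hr, "se_log_hr": est.se_log_hr,
                             "flag": est.flag})
        pd.DataFrame(rows).to_csv(out / "estimates.csv", index=False)
        summary = {
            "max_smd_pre": self.max_smd_pre,
            "max_smd_post": self.max_smd_post,
            "n_matched_pairs": self.n_matched_pairs,
            "endpoints": {
                name: {
                    "pooled_hr": res.pooled.hr,
                    "pooled_ci": [res.pooled.ci_low, res.pooled.ci_high],
                    "crude_hr": res.crude_pooled.hr if res.crude_pooled else None,
                    "rd": dataclasses.asdict(res.risk_difference)
                        if res.risk_difference else None,
                    "negative_control_flagged": res.negative_control_flagged,
                }
                for name, res in self.endpoints.items()
            },
            "agreement": {
                name: {"z": rep.z,
                       "statistical": rep.statistical_agreement,
                       "directional": rep.directional_agreement,
                       "estimate": rep.estimate_agreement,
                       "standardized_difference": rep.standardized_difference_agreement}
                for name, rep in self.agreement.items()
            },
            "provenance": self.provenance,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2, default=float))


def default_study_config(scenario: str | claims_mod.ScenarioConfig = "benchmark_like",
                         *, seed: int | None = None,
                         n_patients: int | None = None,
                         n_databases: int | None = None,
                         bootstrap_replicates: int = 1000,
                         benchmarks: tuple[BenchmarkRef, ...] = (),
                         compute_risk_difference: bool = True) -> StudyConfig:
    """A runnable config derived from a synthetic scenario.

    Eligibility, covariate definitions and endpoints are derived from the
    scenario's own covariate and outcome specifications, so the analysis
    measures exactly what the generator simulates.
    """
    if isinstance(scenario, str):
        scenario = claims_mod.scenario(scenario, seed=seed, n_patients=n_patients,
                                       n_databases=n_databases)
    elif seed is not None or n_patients is not None or n_databases is not None:
        overrides = {k: v for k, v in dict(seed=seed, n_patients=n_patients,
                                           n_databases=n_databases).items()
                     if v is not None}
        scenario = dataclasses.replace(scenario, **overrides)
    base_seed = scenario.seed % (2**31)
    return StudyConfig(
        scenario=scenario,
        eligibility=cohort_mod.EligibilitySpec(),
        covariates=balance_mod.covariate_defs_from_scenario(scenario),
        followup=followup_mod.FollowUpSpec(
            endpoints=followup_mod.endpoints_from_scenario(scenario)),
        match_seed=base_seed + 1,
        bootstrap_seed=base_seed + 2,
        bootstrap_replicates=bootstrap_replicates,
        benchmarks=benchmarks,
        compute_risk_difference=compute_risk_difference,
    )


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, TTEBenchError):
                raise TTEBenchError(f"stage {name!r} failed: {exc}") from exc
            if isinstance(exc, TTEBenchError) and not str(exc).startswith("stage"):
                raise TTEBenchError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


def _safe_cox(records: pd.DataFrame, source: str) -> EffectEstimate:
    """Cox fit that degrades to a flagged estimate when no events occur."""
    import math as _math
    try:
        return survival_mod.cox_hr(records, source=source)
    except TTEBenchError:
        return EffectEstimate(hr=_math.nan, ci_low=_math.nan, ci_high=_math.nan,
                              log_hr=_math.nan, se_log_hr=_math.inf,
                              source=source, flag="no_events")


def _safe_pool(estimates: list[EffectEstimate]) -> EffectEstimate:
    """Pool the estimable inputs; fully degenerate input stays flagged."""
    import math as _math
    finite = [e for e in estimates
              if _math.isfinite(e.se_log_hr) and e.se_log_hr > 0
              and _math.isfinite(e.log_hr)]
    if not finite:
        return EffectEstimate(hr=_math.nan, ci_low=_math.nan, ci_high=_math.nan,
                              log_hr=_math.nan, se_log_hr=_math.inf,
                              source="pooled", flag="no_events")
    pooled = pool_fixed_effects(finite)
    if len(finite) < len(estimates):
        pooled.flag = "partial"
    return pooled


def run_study(config: StudyConfig) -> StudyReport:
    """Execute all stages per database, pool, and benchmark where configured."""
    findings = [f for f in validate_config(config) if f.severity == "error"]
    if findings:
        raise ConfigError("; ".join(f"{f.field}: {f.message}" for f in findings))

    if config.scenario is not None:
        with _stage("generate"):
            bundles = claims_mod.generate_population(config.scenario)
    else:
        with _stage("load"):
            bundles = [claims_mod.ClaimsBundle.read(d) for d in config.claims_dirs]
    db_ids = [f"db{i}" for i in range(len(bundles))]

    attrition: dict[str, pd.DataFrame] = {}
    matrices_pre, matrices_post = [], []
    matched_follow: dict[str, list[pd.DataFrame]] = {ep.name: []
                                                     for ep in config.followup.endpoints}
    crude_ests: dict[str, list[EffectEstimate]] = {ep.name: []
                                                   for ep in config.followup.endpoints}
    matched_ests: dict[str, list[EffectEstimate]] = {ep.name: []
                                                     for ep in config.followup.endpoints}
    n_matched: dict[str, int] = {}

    for i, (db, bundle) in enumerate(zip(db_ids, bundles)):
        with _stage("cohort"):
            cohort, attr = cohort_mod.build_cohort(bundle, config.eligibility, db)
        attrition[db] = attr
        log.info("%s: cohort n=%d (%s)", db, len(cohort),
                 cohort["arm"].value_counts().to_dict())

        with _stage("covariates"):
            matrix = balance_mod.assess_covariates(bundle, cohort, config.covariates)
        matrices_pre.append(matrix)

        with _stage("propensity"):
            model = matching_mod.estimate_propensity(matrix)
        expo = matrix["arm"].to_numpy() == "exposure"
        with _stage("matching"):
            match = matching_mod.match_caliper(
                model.scores[expo], model.scores[~expo],
                caliper=config.caliper, seed=config.match_seed + i,
                exposure_ids=matrix.loc[expo, "patient_id"].to_numpy(),
                comparator_ids=matrix.loc[~expo, "patient_id"].to_numpy())
        n_matched[db] = match.n_pairs
        log.info("%s: %d matched pairs (caliper %.3g)", db, match.n_pairs, config.caliper)

        matched_ids = set(match.matched_ids().tolist())
        matched_cohort = cohort[cohort["patient_id"].isin(matched_ids)]
        matrices_post.append(matrix[matrix["patient_id"].isin(matched_ids)])

        with _stage("followup"):
            fu_matched = followup_mod.build_followup(bundle, matched_cohort,
                                                     config.followup,
                                                     config.eligibility)
            fu_crude = (followup_mod.build_followup(bundle, cohort, config.followup,
                                                    config.eligibility)
                        if config.compute_crude else None)

        with _stage("estimation"):
            for ep in config.followup.endpoints:
                rec = fu_matched[ep.name]
                matched_follow[ep.name].append(rec)
                matched_ests[ep.name].append(_safe_cox(rec, db))
                if fu_crude is not None:
                    crude_ests[ep.name].append(
                        _safe_cox(fu_crude[ep.name], f"{db}-crude"))

    with _stage("balance"):
        pre = pd.concat(matrices_pre, ignore_index=True)
        post = pd.concat(matrices_post, ignore_index=True)
        balance_pre = balance_mod.balance_table(pre)
        balance_post = balance_mod.balance_table(post)

    endpoints: dict[str, EndpointResult] = {}
    with _stage("pooling"):
        for ep in config.followup.endpoints:
            pooled = _safe_pool(matched_ests[ep.name])
            crude_pooled = (_safe_pool(crude_ests[ep.name])
                            if crude_ests[ep.name] else None)
            combined = pd.concat(matched_follow[ep.name], ignore_index=True)
            rd = None
            if config.compute_risk_difference:
                rd = survival_mod.risk_difference(
                    combined, config.horizon,
                    n_bootstrap=config.bootstrap_replicates,
                    seed=config.bootstrap_seed)
            nc_flag = pooled.excludes_null if ep.negative_control else None
            endpoints[ep.name] = EndpointResult(
                name=ep.name, per_database=matched_ests[ep.name], pooled=pooled,
                crude_pooled=crude_pooled, risk_difference=rd,
                negative_control=ep.negative_control,
                negative_control_flagged=nc_flag)

    primary = next((ep for ep in config.followup.endpoints if ep.primary),
                   config.followup.endpoints[0])
    censoring = followup_mod.censoring_summary(
        pd.concat(matched_follow[primary.name], ignore_index=True))

    agreement: dict[str, AgreementReport] = {}
    with _stage("benchmark"):
        for ref in config.benchmarks:
            trial = se_from_ci(ref.hr, ref.ci_low, ref.ci_high, source="trial")
            agreement[ref.endpoint] = agreement_metrics(
                endpoints[ref.endpoint].pooled, trial,
                assess_statistical=ref.primary)

    cfg_text = repr(config)
    provenance = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "scenario_seed": config.scenario.seed if config.scenario else None,
        "match_seed": config.match_seed,
        "bootstrap_seed": config.bootstrap_seed,
        "n_databases": len(bundles),
    }

    return StudyReport(
        attrition=attrition, balance_pre=balance_pre, balance_post=balance_post,
        max_smd_pre=balance_pre.attrs["max_smd"],
        max_smd_post=balance_post.attrs["max_smd"],
        n_matched_pairs=n_matched, endpoints=endpoints, censoring=censoring,
        agreement=agreement, provenance=provenance)


# ---------------------------------------------------------------------------
# Declarative YAML configs (thin surface used by the CLI)
# ---------------------------------------------------------------------------

def load_study_config(path: str | Path) -> StudyConfig:
    """Build a StudyConfig from a YAML document.

    Supported keys: ``scenario`` (preset name), ``seed``, ``n_patients``,
    ``n_databases``, ``caliper``, ``horizon``, ``bootstrap: {replicates,
    seed}``, ``benchmarks:`` list of {endpoint, hr, ci_low, ci_high,
    primary, label}, ``compute_risk_difference``.
    """
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("study config must be a YAML mapping")
    refs = tuple(BenchmarkRef(endpoint=b["endpoint"], hr=b["hr"],
                              ci_low=b["ci_low"], ci_high=b["ci_high"],
                              primary=bool(b.get("primary", False)),
                              label=b.get("label", ""))
                 for b in doc.get("benchmarks", []))
    cfg = default_study_config(
        doc.get("scenario", "benchmark_like"),
        seed=doc.get("seed"),
        n_patients=doc.get("n_patients"),
        n_databases=doc.get("n_databases"),
        bootstrap_replicates=doc.get("bootstrap", {}).get("replicates", 1000),
        benchmarks=refs,
        compute_risk_difference=doc.get("compute_risk_difference", True),
    )
    if "caliper" in doc:
        cfg.caliper = float(doc["caliper"])
    if "horizon" in doc:
        cfg.horizon = int(doc["horizon"])
    if "seed" in doc.get("bootstrap", {}):
        cfg.bootstrap_seed = int(doc["bootstrap"]["seed"])
    return cfg
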