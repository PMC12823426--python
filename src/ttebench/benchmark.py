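"""Fixed-effects pooling and trial-agreement benchmarking.

Database-specific log hazard ratios are pooled by fixed-effects
inverse-variance meta-analysis.  Agreement between a real-world-evidence
(RWE) emulation estimate and its reference randomized-trial (RCT)
estimate is scored with the four binary RCT-DUPLICATE metrics:

* statistical agreement — both estimates significant on the same side of
  the null, or both non-significant (primary endpoints only);
* directional agreement — both log hazard ratios on the same side of 0;
* estimate agreement — the RWE point estimate inside the trial's 95% CI;
* standardized-difference agreement — |Z| < 1.96 with

      Z = (theta_RCT - theta_RWE) / sqrt(var_RCT + var_RWE)

  computed on the log-HR scale, SEs recovered from CI widths.

The package ships the published benchmark table (emulation and reference
trial HR/CI pairs for two cardiovascular outcome trials) as input data
for worked examples and regression checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .estimates import EffectEstimate

#: printed two-sided threshold for standardized-difference agreement
Z_THRESHOLD = 1.96


def se_from_ci(hr: float, ci_low: float, ci_high: float, *,
               source: str = "") -> EffectEstimate:
    """Rebuild an :class:`EffectEstimate` from a published HR and 95% CI."""
    return EffectEstimate.from_ci(hr, ci_low, ci_high, source=source)


def z_statistic(rwe: EffectEstimate, trial: EffectEstimate) -> float:
    """Standardized difference (trial minus RWE) on the log-HR scale."""
    var = trial.se_log_hr**2 + rwe.se_log_hr**2
    if var == 0.0:
        raise ConfigError("z_statistic: combined variance is zero")
    return (trial.log_hr - rwe.log_hr) / math.sqrt(var)


@dataclass
class AgreementReport:
    """The four binary verdicts (None = not assessed) plus the Z statistic."""

    z: float
    statistical_agreement: bool | None
    directional_agreement: bool
    estimate_agreement: bool
    standardized_difference_agreement: bool
    threshold: float
    rwe: EffectEstimate
    trial: EffectEstimate


def _same_side_significant(a: EffectEstimate, b: EffectEstimate) -> bool:
    if a.excludes_null and b.excludes_null:
        return (a.ci_high < 1.0) == (b.ci_high < 1.0)
    return (not a.excludes_null) and (not b.excludes_null)


def agreement_metrics(rwe: EffectEstimate, trial: EffectEstimate,
                      assess_statistical: bool = True,
                      threshold: float = Z_THRESHOLD) -> AgreementReport:
    """Score one emulation/trial estimate pair on the four agreement metrics.

    Statistical agreement is assessed only when ``assess_statistical`` is
    true (primary endpoints); secondary endpoints are not powered for it
    and report None.
    """
    z = z_statistic(rwe, trial)
    return AgreementReport(
        z=z,
        statistical_agreement=(_same_side_significant(rwe, trial)
                               if assess_statistical else None),
        directional_agreement=(rwe.log_hr < 0) == (trial.log_hr < 0),
        estimate_agreement=trial.ci_low <= rwe.hr <= trial.ci_high,
        standardized_difference_agreement=abs(z) < threshold,
        threshold=threshold,
        rwe=rwe,
        trial=trial,
    )


def pool_fixed_effects(estimates: Sequence[EffectEstimate]) -> EffectEstimate:
    """Fixed-effects inverse-variance pooling of log hazard ratios.

    Weights are 1/se_i^2; the pooled SE is 1/sqrt(sum of weights).  The
    pooled variance can never exceed the smallest input variance.
    """
    if not estimates:
        raise ConfigError("pool_fixed_effects: empty estimate list")
    for est in estimates:
        if not (est.se_log_hr > 0) or not math.isfinite(est.se_log_hr):
            raise ConfigError("pool_fixed_effects: every estimate needs a finite se > 0")
    w = np.array([1.0 / est.se_log_hr**2 for est in estimates])
    theta = np.array([est.log_hr for est in estimates])
    pooled_log = float((w * theta).sum() / w.sum())
    pooled_se = float(1.0 / math.sqrt(w.sum()))
    n_events: dict[str, int] = {}
    for est in estimates:
        for arm, k in est.n_events.items():
            n_events[arm] = n_events.get(arm, 0) + k
    return EffectEstimate.from_log(pooled_log, pooled_se, n_events=n_events,
                                   source="pooled")


def _verdict(v: bool | None) -> str:
    return "N/A" if v is None else ("Yes" if v else "No")


def benchmark_table(pairs: Iterable[tuple[str, EffectEstimate, EffectEstimate, bool]]
                    ) -> pd.DataFrame:
    """Agreement grid: one row per (label, rwe, trial, primary) tuple.

    Verdicts render as Yes/No/N/A; statistical agreement is emitted only
    for rows flagged primary.
    """
    rows = []
    for label, rwe, trial, primary in pairs:
        rep = agreement_metrics(rwe, trial, assess_statistical=primary)
        rows.append({
            "endpoint": label,
            "rwe": f"{rwe.hr:.2f} ({rwe.ci_low:.2f} to {rwe.ci_high:.2f})",
            "trial": f"{trial.hr:.2f} ({trial.ci_low:.2f} to {trial.ci_high:.2f})",
            "SA": _verdict(rep.statistical_agreement),
            "DA": _verdict(rep.directional_agreement),
            "EA": _verdict(rep.estimate_agreement),
            "SD": _verdict(rep.standardized_difference_agreement),
            "z": rep.z,
        })
    return pd.DataFrame(rows, columns=["endpoint", "rwe", "trial",
                                       "SA", "DA", "EA", "SD", "z"])


def load_published_benchmarks() -> pd.DataFrame:
    """The packaged table of published emulation/trial HR-CI pairs."""
    with resources.files("ttebench.data").joinpath("published_benchmarks.csv").open() as fh:
        return pd.read_csv(fh)


def published_pairs() -> list[tuple[str, EffectEstimate, EffectEstimate, bool]]:
    """Published benchmark rows in the form :func:`benchmark_table` takes."""
    table = load_published_benchmarks()
    out = []
    for row in table.itertuples():
        label = f"{row.study}: {row.endpoint}"
        rwe = se_from_ci(row.hr_rwe, row.ci_low_rwe, row.ci_high_rwe, source="rwe")
        trial = se_from_ci(row.hr_trial, row.ci_low_trial, row.ci_high_trial,
                           source="trial")
        out.append((label, rwe, trial, bool(row.primary)))
    return out
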