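"""Baseline covariate assessment and standardized-mean-difference balance.

Covariates are assembled over a half-open pre-index window
``[index - window, index)``: an event on the index day itself is
post-baseline and never counts.  Balance between arms is quantified with
the absolute standardized mean difference (SMD), with the conventional
pooled-variance denominator:

    continuous:  |m1 - m0| / sqrt((s1^2 + s0^2) / 2)
    binary:      |p1 - p0| / sqrt((p1 (1-p1) + p0 (1-p0)) / 2)

Values below 0.10 are read as adequate balance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import claims
from .errors import ConfigError, DegenerateArmError

#: conventional adequacy threshold for the absolute SMD
SMD_THRESHOLD = 0.10


@dataclass(frozen=True)
class CovariateDef:
    """How to compute one baseline covariate from the claims tables.

    kind:
        ``"binary"`` — 1 iff any diagnosis code from ``codes`` appears in
        the window; ``"count"`` — number of such rows; ``"age"`` — index
        year minus birth year (codes unused).
    """

    name: str
    kind: str
    codes: frozenset[str] = frozenset()
    window_days: int = 365


def covariate_defs_from_scenario(config: claims.ScenarioConfig) -> tuple[CovariateDef, ...]:
    """Definitions matching the synthetic generator's baseline traces."""
    defs = []
    for cov in config.covariates:
        if cov.kind == "age":
            defs.append(CovariateDef(cov.name, "age"))
        else:
            defs.append(CovariateDef(cov.name, cov.kind,
                                     frozenset({claims.covariate_code(cov.name)})))
    return tuple(defs)


def assess_covariates(bundle: claims.ClaimsBundle, cohort: pd.DataFrame,
                      definitions: Sequence[CovariateDef]) -> pd.DataFrame:
    """Covariate matrix for the cohort: one row per member, no missing cells.

    Binary absence is coded 0.  Returns a DataFrame indexed like ``cohort``
    with one column per definition plus the key columns ``patient_id`` and
    ``arm`` carried through for downstream stages.
    """
    names = [d.name for d in definitions]
    if len(set(names)) != len(names):
        raise ConfigError("covariate definitions: names must be unique")

    out = cohort[["patient_id", "arm", "index_day"]].copy()
    needs_dx = [d for d in definitions if d.kind in ("binary", "count")]
    if needs_dx:
        if bundle.diagnoses is None or bundle.diagnoses.empty:
            dx = pd.DataFrame(columns=["patient_id", "code", "day", "index_day"])
        else:
            dx = bundle.diagnoses.merge(cohort[["patient_id", "index_day"]],
                                        on="patient_id")
    for d in definitions:
        if d.kind == "age":
            if "age" in cohort.columns:
                out[d.name] = cohort["age"].to_numpy(dtype=float)
            else:
                if "birth_year" not in bundle.patients.columns:
                    raise ConfigError(f"covariate {d.name!r} needs birth_year in patients")
                by = bundle.patients.set_index("patient_id")["birth_year"]
                out[d.name] = (claims.EPOCH_YEAR + out["index_day"] // 365
                               - by.reindex(out["patient_id"]).to_numpy())
        elif d.kind in ("binary", "count"):
            hit = dx[dx["code"].isin(d.codes)
                     & (dx["day"] >= dx["index_day"] - d.window_days)
                     & (dx["day"] < dx["index_day"])]
            counts = hit.groupby("patient_id").size()
            vals = counts.reindex(out["patient_id"]).fillna(0).to_numpy(dtype=float)
            out[d.name] = (vals > 0).astype(float) if d.kind == "binary" else vals
        else:
            raise ConfigError(f"covariate {d.name!r}: unknown kind {d.kind!r}")
    return out.drop(columns=["index_day"]).reset_index(drop=True)


def standardized_mean_difference(mean_t: float, mean_c: float,
                                 sd_t: float | None = None,
                                 sd_c: float | None = None,
                                 binary: bool = False) -> float:
    """Absolute SMD between a treated and a control summary.

    For binary covariates pass the proportions as the means; the Bernoulli
    variances are derived internally.  Both-variances-zero with equal means
    returns 0; with unequal means returns +inf with a warning.
    """
    if binary:
        for p in (mean_t, mean_c):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"binary SMD needs proportions in [0, 1], got {p}")
        var_t, var_c = mean_t * (1 - mean_t), mean_c * (1 - mean_c)
    else:
        if sd_t is None or sd_c is None:
            raise ConfigError("continuous SMD needs sd_t and sd_c")
        if sd_t < 0 or sd_c < 0:
            raise ConfigError("standard deviations must be >= 0")
        var_t, var_c = sd_t**2, sd_c**2
    denom = math.sqrt((var_t + var_c) / 2.0)
    diff = abs(mean_t - mean_c)
    if denom == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("SMD: zero variance in both arms with unequal means; "
                      "returning +inf", stacklevel=2)
        return math.inf
    return diff / denom


def _is_binary(col: np.ndarray) -> bool:
    return bool(np.isin(np.unique(col), (0.0, 1.0)).all())


def balance_table(matrix: pd.DataFrame,
                  covariates: Sequence[str] | None = None) -> pd.DataFrame:
    """One BalanceRow per covariate plus a ``max_smd`` attribute.

    ``matrix`` is the output of :func:`assess_covariates` (must contain an
    ``arm`` column).  Binary columns are detected by their {0, 1} support
    and summarised as proportions; all others as mean (sd).
    """
    if matrix.empty:
        raise DegenerateArmError("covariate matrix is empty")
    if covariates is None:
        covariates = [c for c in matrix.columns
                      if c not in ("patient_id", "arm", "database_id")]
    arms = {arm: matrix[matrix["arm"] == arm] for arm in ("exposure", "comparator")}
    for arm, sub in arms.items():
        if len(sub) < 2:
            raise DegenerateArmError(f"arm {arm!r} has fewer than 2 members")

    rows = []
    for name in covariates:
        xt = arms["exposure"][name].to_numpy(dtype=float)
        xc = arms["comparator"][name].to_numpy(dtype=float)
        binary = _is_binary(np.concatenate([xt, xc]))
        if binary:
            smd = standardized_mean_difference(xt.mean(), xc.mean(), binary=True)
            rows.append((name, "binary", xt.mean(), np.nan, xc.mean(), np.nan, smd))
        else:
            smd = standardized_mean_difference(xt.mean(), xc.mean(),
                                               xt.std(ddof=1), xc.std(ddof=1))
            rows.append((name, "continuous", xt.mean(), xt.std(ddof=1),
                         xc.mean(), xc.std(ddof=1), smd))
    table = pd.DataFrame(rows, columns=["covariate", "type", "mean_exposure",
                                        "sd_exposure", "mean_comparator",
                                        "sd_comparator", "smd"])
    table.attrs["max_smd"] = float(table["smd"].max())
    return table
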