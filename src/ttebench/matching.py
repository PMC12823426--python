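"""Propensity-score estimation and 1:1 nearest-neighbor caliper matching.

The propensity score is the modeled probability of receiving the exposure
rather than the comparator given baseline covariates, fit by
maximum-likelihood logistic regression.  Matching is greedy nearest
neighbor without replacement: exposure members are processed in a seeded
random order, and each takes the closest still-unmatched comparator whose
absolute score gap does not exceed the caliper (0.01 on the probability
scale by default, following the convention for claims-based emulations).
Ties in the gap are broken by the lowest comparator id, so the procedure
is fully deterministic given the seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, SeparationError

log = logging.getLogger(__name__)

DEFAULT_CALIPER = 0.01


@dataclass
class PropensityModel:
    """Fitted logistic propensity model.

    ``coefficients`` holds the intercept plus one log-odds coefficient per
    retained covariate; ``scores`` are the fitted probabilities in (0, 1)
    for every cohort member, equal to inverse-logit of the linear predictor.
    """

    coefficients: pd.Series
    scores: np.ndarray
    converged: bool
    dropped_constant: tuple[str, ...] = ()
    separation_warnings: tuple[str, ...] = ()


def estimate_propensity(matrix: pd.DataFrame,
                        arm: np.ndarray | pd.Series | None = None,
                        covariates: list[str] | None = None,
                        maxiter: int = 100, gtol: float = 1e-8) -> PropensityModel:
    """Maximum-likelihood logistic fit of arm on baseline covariates.

    ``matrix`` is a covariate matrix (as from ``balance.assess_covariates``);
    ``arm`` defaults to its ``arm`` column.  Constant columns are dropped
    with a log message.  Quasi-separation (fitted probabilities pinned to
    0/1 or runaway coefficients) produces a warning naming the covariates;
    perfect separation raises :class:`SeparationError`.
    """
    if arm is None:
        if "arm" not in matrix.columns:
            raise ConfigError("estimate_propensity: no arm labels supplied")
        arm = matrix["arm"]
    y = (np.asarray(arm) == "exposure").astype(float) \
        if np.asarray(arm).dtype.kind in "OUS" else np.asarray(arm, dtype=float)
    if covariates is None:
        covariates = [c for c in matrix.columns
                      if c not in ("patient_id", "arm", "database_id")]
    X = matrix[covariates].astype(float)

    dropped = tuple(c for c in covariates if X[c].nunique() <= 1)
    if dropped:
        log.info("dropping constant covariates from the propensity model: %s", dropped)
        X = X.drop(columns=list(dropped))

    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter, gtol=gtol, method="lbfgs")
        except Exception as exc:  # statsmodels raises PerfectSeparationError subclass
            raise SeparationError(
                f"propensity model failed to fit ({exc}); prune separating covariates"
            ) from exc

    scores = np.asarray(res.predict(Xc))
    # perfect separation: the fit classifies every observation with
    # probability ~1; the MLE is at infinity and only the iteration cap
    # stopped it
    if len(X.columns) and np.abs(scores - y).max() < 1e-3:
        raise SeparationError(
            "perfect separation: fitted probabilities match arm labels exactly; "
            "prune separating covariates")
    sep_warnings = []
    eps = 1e-8
    if np.any(scores <= eps) or np.any(scores >= 1 - eps):
        big = res.params.drop("const").abs()
        suspects = tuple(big[big > 15].index)
        sep_warnings.append(
            f"quasi-separation: fitted probabilities at machine 0/1; "
            f"suspect covariates {suspects or tuple(X.columns)}")
        log.warning(sep_warnings[-1])

    return PropensityModel(coefficients=res.params, scores=scores,
                           converged=bool(res.mle_retvals.get("converged", True)),
                           dropped_constant=dropped,
                           separation_warnings=tuple(sep_warnings))


@dataclass
class MatchedCohort:
    """Result of 1:1 caliper matching.

    ``pairs`` has one row per matched pair with both ids, both scores and
    the absolute score gap; every gap is <= ``caliper`` and each patient
    appears in at most one pair.
    """

    pairs: pd.DataFrame
    unmatched_exposure: np.ndarray
    unmatched_comparator: np.ndarray
    caliper: float
    seed: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> np.ndarray:
        return np.concatenate([self.pairs["exposure_id"].to_numpy(),
                               self.pairs["comparator_id"].to_numpy()])


def match_caliper(exposure_scores: np.ndarray, comparator_scores: np.ndarray,
                  caliper: float = DEFAULT_CALIPER, seed: int = 0,
                  exposure_ids: np.ndarray | None = None,
                  comparator_ids: np.ndarray | None = None) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Exposure members are visited in a seeded random permutation; each is
    paired with the unmatched comparator minimising the absolute score
    gap, provided the gap is within the caliper.  Equal gaps resolve to
    the lowest comparator id.  Runs in O((nE + nC) log nC) via a sorted
    doubly-linked list over the comparator scores.
    """
    if caliper <= 0:
        raise ConfigError("matching caliper must be > 0")
    es = np.asarray(exposure_scores, dtype=float)
    cs = np.asarray(comparator_scores, dtype=float)
    eids = np.arange(len(es)) if exposure_ids is None else np.asarray(exposure_ids)
    cids = np.arange(len(cs)) if comparator_ids is None else np.asarray(comparator_ids)
    if len(es) == 0 or len(cs) == 0:
        log.warning("match_caliper: an arm is empty; returning no pairs")
        empty = pd.DataFrame(columns=["pair_id", "exposure_id", "comparator_id",
                                      "score_exposure", "score_comparator", "gap"])
        return MatchedCohort(empty, eids, cids, caliper, seed)

    order = np.random.default_rng(seed).permutation(len(es))

    # comparators sorted by (score, id); doubly-linked alive list
    c_order = np.lexsort((cids, cs))
    s = cs[c_order]
    ids_sorted = cids[c_order]
    n = len(s)
    nxt = np.arange(1, n + 2)          # sentinel n = "past the end"
    prv = np.arange(-1, n + 1)         # sentinel -1 = "before the start"
    alive = np.ones(n, dtype=bool)

    def first_alive_right(j: int) -> int:
        while j < n and not alive[j]:
            j = nxt[j]
        return j

    def first_alive_left(j: int) -> int:
        while j >= 0 and not alive[j]:
            j = prv[j]
        return j

    pairs = []
    for k in order:
        target = es[k]
        j = int(np.searchsorted(s, target))
        right = first_alive_right(j)
        left = first_alive_left(j - 1)
        gap_r = s[right] - target if right < n else np.inf
        gap_l = target - s[left] if left >= 0 else np.inf
        if min(gap_l, gap_r) > caliper:
            continue
        if gap_r < gap_l:
            chosen = right
        elif gap_l < gap_r:
            chosen = left
        else:
            # equal gaps: lowest comparator id; within an equal-score run the
            # leftmost alive node carries the smallest id
            lo, p = left, prv[left]
            while p >= 0:
                if alive[p]:
                    if s[p] != s[left]:
                        break
                    lo = p
                p = prv[p]
            chosen = lo if ids_sorted[lo] < ids_sorted[right] else right
        gap = abs(s[chosen] - target)
        pairs.append((eids[k], ids_sorted[chosen], target, s[chosen], gap))
        alive[chosen] = False
        if prv[chosen] >= 0:
            nxt[prv[chosen]] = nxt[chosen]
        if nxt[chosen] <= n:
            prv[nxt[chosen]] = prv[chosen]

    pairs_df = pd.DataFrame(pairs, columns=["exposure_id", "comparator_id",
                                            "score_exposure", "score_comparator",
                                            "gap"])
    pairs_df.insert(0, "pair_id", np.arange(len(pairs_df)))
    matched_c = set(pairs_df["comparator_id"])
    matched_e = set(pairs_df["exposure_id"])
    return MatchedCohort(
        pairs=pairs_df,
        unmatched_exposure=np.asarray([i for i in eids if i not in matched_e]),
        unmatched_comparator=np.asarray([i for i in cids if i not in matched_c]),
        caliper=caliper, seed=seed,
    )
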