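"""Effect estimates on the hazard-ratio scale.

An :class:`EffectEstimate` carries both the ratio-scale summary printed in
reports (HR with a 95% CI) and the log-scale point/standard-error pair that
meta-analytic pooling and trial-agreement statistics operate on.  When an
estimate is reconstructed from a published HR and CI, the log-scale SE is
recovered from the CI width assuming a Wald interval:

    se = (ln(ci_high) - ln(ci_low)) / (2 * 1.959964)

The full-precision normal quantile 1.959964 is used for CI<->SE conversion;
the printed threshold 1.96 is reserved for the agreement cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigError

#: full-precision two-sided 95% normal quantile, used for CI <-> SE conversion
Z_95 = 1.959964


@dataclass
class EffectEstimate:
    """A hazard ratio with its 95% CI and log-scale representation.

    Attributes
    ----------
    hr, ci_low, ci_high
        Ratio-scale point estimate and Wald 95% confidence bounds.
    log_hr, se_log_hr
        Log-scale point estimate and standard error (the unit of pooling).
    n_events
        Event counts, by arm, when known.
    source
        Provenance tag: a database id, ``"pooled"``, or ``"trial"``.
    flag
        Optional quality flag, e.g. ``"monotone"`` for an infinite-MLE fit.
    """

    hr: float
    ci_low: float
    ci_high: float
    log_hr: float
    se_log_hr: float
    n_events: dict[str, int] = field(default_factory=dict)
    source: str = ""
    flag: str | None = None

    @classmethod
    def from_log(cls, log_hr: float, se_log_hr: float, *, n_events=None,
                 source: str = "", flag: str | None = None) -> "EffectEstimate":
        return cls(
            hr=math.exp(log_hr),
            ci_low=math.exp(log_hr - Z_95 * se_log_hr),
            ci_high=math.exp(log_hr + Z_95 * se_log_hr),
            log_hr=log_hr,
            se_log_hr=se_log_hr,
            n_events=dict(n_events or {}),
            source=source,
            flag=flag,
        )

    @classmethod
    def from_ci(cls, hr: float, ci_low: float, ci_high: float, *,
                source: str = "") -> "EffectEstimate":
        """Reconstruct log-scale point/SE from a published HR and 95% CI."""
        if not (0 < ci_low <= hr <= ci_high):
            raise ConfigError(
                f"effect estimate ordering violated: require 0 < ci_low <= hr <= ci_high, "
                f"got hr={hr}, ci_low={ci_low}, ci_high={ci_high}"
            )
        se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
        return cls(hr=hr, ci_low=ci_low, ci_high=ci_high,
                   log_hr=math.log(hr), se_log_hr=se, source=source)

    @property
    def excludes_null(self) -> bool:
        """True when the 95% CI excludes HR = 1."""
        return self.ci_low > 1.0 or self.ci_high < 1.0
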