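"""Fixed-effect meta-analysis of log hazard ratios across studies.

Inverse-variance pooling with Cochran's Q heterogeneity statistic
(chi-square, k-1 df), a two-sided Wald test for attenuation of a term's
effect between two nested models, and the Bonferroni multiplicity
threshold.  Pooling is fixed-effect only; no between-study variance is
estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .survival import HazardEstimate

__all__ = [
    "MetaInputError",
    "MetaResult",
    "fixed_effect_meta",
    "wald_attenuation_test",
    "bonferroni_threshold",
]


class MetaInputError(ValueError):
    pass


@dataclass
class MetaResult:
    """Pooled fixed-effect estimate with heterogeneity diagnostics."""

    term: str
    pooled_log_hr: float
    pooled_se: float
    k: int
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_p: Optional[float] = None
    inputs: list[HazardEstimate] = field(default_factory=list)

    @property
    def pooled_hr(self) -> float:
        return float(np.exp(self.pooled_log_hr))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.pooled_log_hr - 1.96 * self.pooled_se)),
            float(np.exp(self.pooled_log_hr + 1.96 * self.pooled_se)),
        )

    @property
    def z(self) -> float:
        return self.pooled_log_hr / self.pooled_se

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))

    def as_estimate(self, study_id: str = "META") -> HazardEstimate:
        """The pooled result in the per-study interchange shape."""
        first = self.inputs[0] if self.inputs else None
        return HazardEstimate(
            term=self.term,
            log_hr=self.pooled_log_hr,
            se=self.pooled_se,
            n_cases=sum(e.n_cases for e in self.inputs),
            n_controls=sum(e.n_controls for e in self.inputs),
            study_id=study_id,
            stratum=first.stratum if first else "",
            model_id=first.model_id if first else "",
            disease=first.disease if first else "",
        )


def fixed_effect_meta(estimates: list[HazardEstimate]) -> MetaResult:
    """Inverse-variance fixed-effect pooling with Cochran's Q.

    Weights are 1/se^2; the pooled estimate is the weighted mean of the
    per-study log hazard ratios and the pooled SE is (sum of weights)^-1/2.
    Q = sum w_i (beta_i - pooled)^2 on k-1 df with an upper-tail chi-square
    p-value.  A single study passes through unchanged with Q undefined.
    """
    if not estimates:
        raise MetaInputError("no estimates to pool")
    terms = {e.term for e in estimates}
    if len(terms) != 1:
        raise MetaInputError(f"mixed terms in meta-analysis input: {sorted(terms)}")
    diseases = {e.disease for e in estimates}
    if len(diseases) != 1:
        raise MetaInputError(f"mixed diseases in meta-analysis input: {sorted(diseases)}")
    if any(e.se is None or e.se <= 0 for e in estimates):
        raise MetaInputError("all estimates must carry a positive SE")

    term = estimates[0].term
    k = len(estimates)
    beta = np.array([e.log_hr for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if k == 1:
        return MetaResult(
            term=term, pooled_log_hr=float(beta[0]), pooled_se=float(se[0]),
            k=1, inputs=list(estimates),
        )
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (beta - pooled) ** 2))
    q_df = k - 1
    return MetaResult(
        term=term, pooled_log_hr=pooled, pooled_se=pooled_se, k=k,
        q_stat=q, q_df=q_df, q_p=float(stats.chi2.sf(q, q_df)),
        inputs=list(estimates),
    )


def wald_attenuation_test(
    est_a: HazardEstimate, est_b: HazardEstimate
) -> tuple[float, float]:
    """Two-sided Wald z-test for a coefficient difference between two models.

    Treats the two fits as independent (no same-sample covariance
    correction); returns (z, p).
    """
    if est_a.term != est_b.term:
        raise MetaInputError(
            f"attenuation test needs matching terms, got "
            f"{est_a.term!r} vs {est_b.term!r}"
        )
    if est_a.disease != est_b.disease:
        raise MetaInputError("attenuation test needs matching diseases")
    z = (est_a.log_hr - est_b.log_hr) / np.sqrt(est_a.se**2 + est_b.se**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise MetaInputError("alpha must lie in (0, 1)")
    if m < 1:
        raise MetaInputError("m must be a positive integer")
    return alpha / m
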