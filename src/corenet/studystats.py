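"""Closed-form study-design statistics.

Two-group power under the normal approximation, and Mendelian
genotype-ratio summaries (a 1-df chi-squared goodness of fit of an
observed category count against an expected proportion, default the 25%
homozygote fraction from a heterozygote intercross).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerDesign:
    """Two-group comparison design: effect size, group SDs and sizes, alpha."""

    delta: float
    sd1: float
    sd2: float
    n1: int
    n2: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("standard deviations must be positive")
        if self.delta < 0:
            raise ValueError("delta must be >= 0 (magnitude of the difference)")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class RatioObservation:
    """Observed count k in one category out of n, against expected p0."""

    k: int
    n: int
    p0: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")
        if self.n == 0:
            raise ValueError("n must be positive")
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0, 1)")


def power_two_group_z(design: PowerDesign) -> float:
    """Power of a two-sided two-sample z test (Welch-type standard error).

    power = Phi( delta / sqrt(sd1^2/n1 + sd2^2/n2) - z_{1-alpha/2} ).
    As delta -> 0 this tends to alpha/2 (the probability of rejecting in
    the favourable direction under the null); as delta -> infinity it
    tends to 1.
    """
    se = (design.sd1**2 / design.n1 + design.sd2**2 / design.n2) ** 0.5
    z_crit = stats.norm.ppf(1 - design.alpha / 2)
    return float(stats.norm.cdf(design.delta / se - z_crit))


def ratio_summary(obs: RatioObservation) -> dict[str, float]:
    """Percent observed plus a 1-df chi-squared test against p0.

    Returns ``percent`` (100*k/n, rounded to one decimal as printed in
    reports), ``chi2`` and the upper-tail ``p`` on 1 df.  chi2 is 0 iff
    k equals the expected count exactly.
    """
    expected = [obs.n * obs.p0, obs.n * (1 - obs.p0)]
    observed = [obs.k, obs.n - obs.k]
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return {
        "percent": round(100.0 * obs.k / obs.n, 1),
        "chi2": float(chi2),
        "p": p,
    }
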