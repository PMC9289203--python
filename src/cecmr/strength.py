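"""Instrument-strength diagnostics and power for binary-outcome MR.

Weak instruments (F ≲ 10) bias two-sample MR toward the null, so the
variance in the exposure explained by the instrument and the corresponding
F statistic are reported alongside every analysis.  Power for a binary
outcome uses the standard normal-approximation non-centrality formula for
an instrumental-variable logistic association, the method of the widely
used online MR power calculators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .summary import SummaryAssociation


@dataclass(frozen=True)
class StrengthSummary:
    """Variance explained per SNP and in total, with the instrument F."""

    per_snp_r2: tuple[tuple[str, float], ...]
    total_r2: float
    f_statistic: float
    n: int
    k: int


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the binary-outcome power approximation.

    ``r2`` is the exposure variance explained by the instrument,
    ``or_alt`` the alternative-hypothesis odds ratio per SD of exposure,
    ``alpha`` the two-sided significance level.
    """

    n_total: int
    case_fraction: float
    r2: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValidationError("n_total must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValidationError("case_fraction must lie in (0, 1)")
        if not 0 <= self.r2 < 1:
            raise ValidationError("r2 must lie in [0, 1)")
        if self.or_alt <= 0:
            raise ValidationError("or_alt must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")


def variance_explained(beta: float, eaf: float) -> float:
    """Exposure variance explained by one SNP: 2·β²·MAF·(1−MAF), with the
    minor-allele frequency MAF = min(eaf, 1−eaf) and β in SD units."""
    if not 0 < eaf < 1:
        raise ValidationError(f"eaf must lie in (0, 1), got {eaf}")
    maf = min(eaf, 1.0 - eaf)
    return 2.0 * beta * beta * maf * (1.0 - maf)


def f_statistic(r2: float, n: int, k: int) -> float:
    """Instrument F statistic (r²/k) / ((1−r²)/(n−k−1)); reduces to
    r²(n−2)/(1−r²) for a single SNP."""
    if not 0 <= r2 < 1:
        raise ValidationError(f"r2 must lie in [0, 1), got {r2}")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise ValidationError(f"need n > k+1, got n={n}, k={k}")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def instrument_strength(associations: Sequence[SummaryAssociation],
                        n: int) -> StrengthSummary:
    """Summarise an instrument from its exposure-GWAS rows (each must carry
    an EAF); ``n`` is the exposure-GWAS sample size."""
    per_snp = []
    for rec in associations:
        if rec.eaf is None:
            raise ValidationError(f"{rec.snp_id}: eaf required for r2")
        per_snp.append((rec.snp_id, variance_explained(rec.beta, rec.eaf)))
    total = float(sum(r2 for _, r2 in per_snp))
    k = len(per_snp)
    return StrengthSummary(
        per_snp_r2=tuple(per_snp),
        total_r2=total,
        f_statistic=f_statistic(total, n, k),
        n=n,
        k=k,
    )


def power_binary_outcome(spec: PowerSpec) -> float:
    """Power of the two-sided level-α MR test of a binary outcome.

    Φ( √(N·r²·p(1−p))·|ln OR| − z_{1−α/2} ) with p the case fraction.
    At OR = 1 this evaluates to α/2 exactly (the one tail of the null
    rejection region the formula tracks) — documented limit, not an error.
    """
    p = spec.case_fraction
    ncp = np.sqrt(spec.n_total * spec.r2 * p * (1.0 - p)) * abs(np.log(spec.or_alt))
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_crit))
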