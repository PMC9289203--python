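"""Cochran Q heterogeneity within an instrument set and between outcomes.

Within an instrument set, Q measures dispersion of the per-SNP Wald ratios
about the IVW estimate and is the standard check for invalid (pleiotropic)
instruments.  The same fixed-effect machinery compares causal estimates
across outcomes — e.g. whether the effect of cholesterol efflux capacity on
ischemic stroke is genuinely weaker than on coronary artery disease.  The
I² index expresses the excess of Q over its degrees of freedom as the
fraction of variance attributable to heterogeneity, truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .estimators import _arrays, _ivw_theta_se
from .summary import HarmonizedInstrument


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran Q with per-unit contributions wᵢ(θᵢ−θ̂)² summing to Q."""

    Q: float
    df: int
    pvalue: float
    i_squared: float
    contributions: tuple[tuple[str, float], ...]

    @property
    def i_squared_percent(self) -> int:
        """I² as the integer percentage used in reports."""
        return round(100.0 * self.i_squared)


def i_squared(Q: float, df: int) -> float:
    """I² = max(0, (Q − df)/Q); defined as 0 when Q = 0."""
    if Q < 0:
        raise ValidationError(f"Q must be non-negative, got {Q}")
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    if Q == 0:
        return 0.0
    return max(0.0, (Q - df) / Q)


def _q_result(labels: Sequence[str], thetas: np.ndarray, weights: np.ndarray
              ) -> HeterogeneityResult:
    pooled = float(np.sum(weights * thetas) / np.sum(weights))
    contrib = weights * (thetas - pooled) ** 2
    q = float(np.sum(contrib))
    df = len(thetas) - 1
    return HeterogeneityResult(
        Q=q,
        df=df,
        pvalue=float(stats.chi2.sf(q, df)),
        i_squared=i_squared(q, df),
        contributions=tuple(zip(labels, contrib.tolist())),
    )


def cochran_q(instruments: Sequence[HarmonizedInstrument]
              ) -> HeterogeneityResult:
    """Cochran Q of the per-SNP ratio estimates about the fixed-effect IVW
    estimate, with weights βXᵢ²/seYᵢ² and df = k − 1."""
    if len(instruments) < 2:
        raise ValueError("cochran_q requires at least two instruments")
    bx, by, sey = _arrays(instruments)
    thetas = by / bx
    weights = bx**2 / sey**2
    # the pooled mean with these weights IS the IVW estimate
    assert np.isclose(float(np.sum(weights * thetas) / np.sum(weights)),
                      _ivw_theta_se(bx, by, sey)[0])
    return _q_result([i.snp_id for i in instruments], thetas, weights)


def compare_estimates(estimates: Sequence[tuple[str, float, float]]
                      ) -> HeterogeneityResult:
    """Fixed-effect heterogeneity test between causal estimates.

    ``estimates`` holds ``(label, theta, se)`` triples — e.g. the per-outcome
    IVW estimates with their fixed-model SEs.  Q is computed about the
    inverse-variance-weighted mean with weights 1/se², df = m − 1.
    """
    if len(estimates) < 2:
        raise ValueError("compare_estimates requires at least two estimates")
    labels = [label for label, _, _ in estimates]
    thetas = np.array([theta for _, theta, _ in estimates], dtype=float)
    ses = np.array([se for _, _, se in estimates], dtype=float)
    if np.any(ses <= 0):
        bad = [labels[i] for i in np.nonzero(ses <= 0)[0]]
        raise ValidationError(f"non-positive SE for {bad}")
    return _q_result(labels, thetas, 1.0 / ses**2)
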