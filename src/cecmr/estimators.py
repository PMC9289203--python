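"""Two-sample Mendelian randomization estimators on harmonized instruments.

All estimators consume :class:`~cecmr.summary.HarmonizedInstrument` lists
(βX in SD units of the exposure, βY in log-odds) and return a causal
log-odds estimate per 1-SD higher exposure, with normal-based confidence
intervals and the exponentiated odds-ratio scale alongside.

Weights are first-order ("NOME") throughout: the exposure SE is carried on
each instrument but does not enter the weights, matching the convention of
the summary-data MR literature.  Available methods:

* :func:`wald_ratio` — single-instrument ratio with delta-method SE;
* :func:`ivw` — inverse-variance weighted combination (fixed or
  multiplicative random-effects variance);
* :func:`mr_egger` — weighted regression with a free intercept estimating
  average directional pleiotropy;
* :func:`simple_median` / :func:`weighted_median` — median of the per-SNP
  ratio distribution, robust to up to 50% invalid instruments, with
  parametric-bootstrap SEs;
* :func:`multivariable_ivw` — joint weighted regression on several
  exposures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .summary import HarmonizedInstrument

#: Two-sided 95% normal quantile used for every confidence interval.
Z_95 = 1.959964

#: Default number of parametric-bootstrap replicates for median estimators.
DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio θᵢ = βY/βX with first-order delta SE seY/|βX|."""

    snp_id: str
    theta: float
    se_theta: float

    @property
    def weight(self) -> float:
        """Inverse-variance weight 1/se_theta² = βX²/seY²."""
        return self.se_theta ** -2


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds scale with its OR transform."""

    method: str
    n_snps: int
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    variance_model: str = "fixed"
    exposure: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))

    @classmethod
    def from_theta_se(cls, method: str, n_snps: int, theta: float, se: float,
                      variance_model: str = "fixed", exposure: str = "",
                      ) -> "MREstimate":
        theta = float(theta)
        se = float(se)
        return cls(
            method=method,
            n_snps=n_snps,
            theta=theta,
            se=se,
            ci_low=theta - Z_95 * se,
            ci_high=theta + Z_95 * se,
            pvalue=float(2.0 * stats.norm.sf(abs(theta) / se)),
            variance_model=variance_model,
            exposure=exposure,
        )


@dataclass(frozen=True)
class EggerIntercept:
    """MR-Egger intercept: average directional pleiotropy in log-odds/allele."""

    value: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float


@dataclass(frozen=True)
class EggerEstimate:
    """MR-Egger fit: pleiotropy-corrected slope plus the intercept test."""

    slope: MREstimate
    intercept: EggerIntercept


def ratio_estimate(instrument: HarmonizedInstrument) -> RatioEstimate:
    """Per-SNP ratio βY/βX with first-order delta-method SE seY/|βX|."""
    if instrument.beta_exposure == 0:
        raise DegenerateInstrumentError(
            f"{instrument.snp_id}: beta_exposure is zero, ratio undefined"
        )
    return RatioEstimate(
        snp_id=instrument.snp_id,
        theta=instrument.beta_outcome / instrument.beta_exposure,
        se_theta=instrument.se_outcome / abs(instrument.beta_exposure),
    )


def wald_ratio(instrument: HarmonizedInstrument) -> MREstimate:
    """Single-instrument causal estimate: the SNP-outcome effect divided by
    the SNP-exposure effect, SE by the first-order delta method."""
    ratio = ratio_estimate(instrument)
    return MREstimate.from_theta_se("wald", 1, ratio.theta, ratio.se_theta)


def _arrays(instruments: Sequence[HarmonizedInstrument]
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([i.beta_exposure for i in instruments], dtype=float)
    by = np.array([i.beta_outcome for i in instruments], dtype=float)
    sey = np.array([i.se_outcome for i in instruments], dtype=float)
    if np.any(bx == 0):
        bad = [i.snp_id for i in instruments if i.beta_exposure == 0]
        raise DegenerateInstrumentError(f"zero exposure effect for {bad}")
    return bx, by, sey


def _ivw_theta_se(bx: np.ndarray, by: np.ndarray, sey: np.ndarray
                  ) -> tuple[float, float]:
    w = bx**2 / sey**2
    theta = float(np.sum(bx * by / sey**2) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return theta, se


def ivw(instruments: Sequence[HarmonizedInstrument],
        variance_model: str = "fixed") -> MREstimate:
    """Inverse-variance weighted estimate.

    Equivalent to the through-origin regression of βY on βX weighted by
    1/seY²: θ̂ = Σ βXᵢβYᵢ/seYᵢ² / Σ βXᵢ²/seYᵢ².  The fixed variance model
    uses SE = (Σ βXᵢ²/seYᵢ²)^(−1/2); the multiplicative random-effects
    model inflates it by sqrt(Q/(k−1)) when the instrument Cochran Q
    exceeds its degrees of freedom.
    """
    if len(instruments) == 0:
        raise ValueError("ivw requires at least one instrument")
    if variance_model not in ("fixed", "multiplicative"):
        raise ValueError(f"unknown variance_model {variance_model!r}")
    bx, by, sey = _arrays(instruments)
    theta, se = _ivw_theta_se(bx, by, sey)
    k = len(instruments)
    if variance_model == "multiplicative" and k >= 2:
        w = bx**2 / sey**2
        q = float(np.sum(w * (by / bx - theta) ** 2))
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return MREstimate.from_theta_se("ivw", k, theta, se,
                                    variance_model=variance_model)


def _weighted_lstsq(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                    scale: str = "residual",
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """WLS fit returning (coef, cov, dof).

    ``scale="residual"`` multiplies the covariance by RSS_w/(n−p) with no
    lower truncation (MR-Egger convention); ``scale="fixed"`` leaves it at
    inv(X'WX) (fixed-effect convention, exact IVW reduction at one column).
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    xtx = Xw.T @ Xw
    rank = np.linalg.matrix_rank(xtx)
    if rank < X.shape[1]:
        raise CollinearityError(
            f"design matrix has rank {rank} < {X.shape[1]} columns"
        )
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ coef
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof if scale == "residual" else 1.0
    cov = sigma2 * np.linalg.inv(xtx)
    return coef, cov, dof


def mr_egger(instruments: Sequence[HarmonizedInstrument]) -> EggerEstimate:
    """MR-Egger regression: weighted least squares of βY on βX with a free
    intercept, weights 1/seY², every instrument oriented so βX ≥ 0.

    The slope is the pleiotropy-corrected causal estimate (valid under the
    InSIDE assumption); the intercept estimates average directional
    pleiotropy.  SEs carry the residual scaling sqrt(RSS_w/(k−2)) with no
    floor at 1; intervals are normal-based.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs >= 3 instruments, got {len(instruments)}"
        )
    bx, by, sey = _arrays(instruments)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    X = np.column_stack([np.ones_like(bx), bx])
    coef, cov, _ = _weighted_lstsq(X, by, 1.0 / sey**2)
    se = np.sqrt(np.diag(cov))
    slope = MREstimate.from_theta_se("egger_slope", len(instruments),
                                     coef[1], se[1])
    intercept = EggerIntercept(
        value=float(coef[0]),
        se=float(se[0]),
        ci_low=float(coef[0] - Z_95 * se[0]),
        ci_high=float(coef[0] + Z_95 * se[0]),
        pvalue=float(2.0 * stats.norm.sf(abs(coef[0]) / se[0])),
    )
    return EggerEstimate(slope=slope, intercept=intercept)


def weighted_median_point(thetas: np.ndarray, weights: np.ndarray,
                          snp_ids: Sequence[str] | None = None) -> float:
    """Median of the weighted empirical distribution of ratio estimates.

    Ratios are ordered (stable, ties broken by snp_id), cumulative
    standardized weights pⱼ = (Σ_{i≤j} wᵢ − wⱼ/2)/Σw computed, and the
    estimate is the linear interpolation of θ across p at p = 0.5, clamped
    to the extreme ratios when 0.5 falls outside [p₁, p_k].
    """
    thetas = np.asarray(thetas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if snp_ids is None:
        order = np.argsort(thetas, kind="stable")
    else:
        order = sorted(range(len(thetas)),
                       key=lambda i: (thetas[i], snp_ids[i]))
    th = thetas[order]
    w = weights[order]
    p = (np.cumsum(w) - w / 2.0) / np.sum(w)
    return float(np.interp(0.5, p, th))


def _median_estimate(instruments: Sequence[HarmonizedInstrument],
                     method: str, weighted: bool, n_boot: int,
                     seed: int | None) -> MREstimate:
    if len(instruments) < 3:
        raise InsufficientInstrumentsError(
            f"{method} needs >= 3 instruments, got {len(instruments)}"
        )
    bx, by, sey = _arrays(instruments)
    sex = np.array([i.se_exposure for i in instruments], dtype=float)
    ids = [i.snp_id for i in instruments]

    def point(bx_: np.ndarray, by_: np.ndarray) -> float:
        th = by_ / bx_
        w = bx_**2 / sey**2 if weighted else np.full(len(bx_), 1.0 / len(bx_))
        return weighted_median_point(th, w, ids)

    theta = point(bx, by)
    # Parametric bootstrap: resample both sides from their sampling
    # distributions and take the SD of the recomputed medians.
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sex)
        by_b = rng.normal(by, sey)
        bx_b[bx_b == 0] = np.finfo(float).tiny  # guard measure-zero event
        reps[b] = point(bx_b, by_b)
    se = float(np.std(reps, ddof=1))
    return MREstimate.from_theta_se(method, len(instruments), theta, se)


def simple_median(instruments: Sequence[HarmonizedInstrument],
                  n_boot: int = DEFAULT_N_BOOT,
                  seed: int | None = 0) -> MREstimate:
    """Median of the per-SNP ratio distribution with equal weights 1/k;
    SE by parametric bootstrap (``seed`` makes it reproducible)."""
    return _median_estimate(instruments, "simple_median", False, n_boot, seed)


def weighted_median(instruments: Sequence[HarmonizedInstrument],
                    n_boot: int = DEFAULT_N_BOOT,
                    seed: int | None = 0) -> MREstimate:
    """Median of the ratio distribution weighted by the inverse variance of
    each ratio (βX²/seY²); consistent when valid instruments carry more
    than half the total weight.  SE by parametric bootstrap."""
    return _median_estimate(instruments, "weighted_median", True, n_boot, seed)


def multivariable_ivw(
    beta_exposures: np.ndarray,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
    exposure_names: Sequence[str] | None = None,
) -> list[MREstimate]:
    """Multivariable IVW: WLS of βY on the k×E matrix of exposure effects
    without intercept, weights 1/seY²; one slope per exposure.

    With a single exposure column this reduces exactly to :func:`ivw`
    with the fixed variance model (the covariance is inv(X'WX), not
    residual-scaled).
    """
    X = np.atleast_2d(np.asarray(beta_exposures, dtype=float))
    if X.ndim != 2:
        raise ValueError("beta_exposures must be a k x E matrix")
    y = np.asarray(beta_outcome, dtype=float)
    sey = np.asarray(se_outcome, dtype=float)
    k, n_exp = X.shape
    if exposure_names is None:
        exposure_names = [f"exposure_{j}" for j in range(n_exp)]
    if k < n_exp + 1:
        raise InsufficientInstrumentsError(
            f"multivariable IVW needs >= E+1 = {n_exp + 1} instruments, got {k}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < n_exp:
        # name a minimal dependent set for the error message
        dependent = []
        for j in range(n_exp):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                dependent.append(exposure_names[j])
        raise CollinearityError(
            f"exposure matrix has rank {rank} < {n_exp}; "
            f"linearly dependent columns include {dependent}"
        )
    coef, cov, _ = _weighted_lstsq(X, y, 1.0 / sey**2, scale="fixed")
    se = np.sqrt(np.diag(cov))
    return [
        MREstimate.from_theta_se("mv_ivw", k, coef[j], se[j],
                                 exposure=str(exposure_names[j]))
        for j in range(n_exp)
    ]
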