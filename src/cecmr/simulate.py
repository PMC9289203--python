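"""Synthetic two-sample GWAS summary statistics with known causal effect.

Every estimator in the package can be validated without any download by
generating the summary statistics it consumes directly from their
asymptotic sampling distributions — no individual-level genotypes are
simulated.  For SNP j with minor-allele frequency fⱼ:

* true exposure effect bⱼ = |N(0, exposure_effect_sd²)|, exposure in SD
  units — the effect allele is reported as the exposure-increasing one, the
  convention of published instrument tables, which also makes *directional*
  pleiotropy well-defined (a direct effect of fixed sign on that allele);
* true outcome effect  θ·bⱼ + αⱼ, with αⱼ the direct (pleiotropic) effect —
  zero for valid instruments, drawn N(±pleiotropy_mean, pleiotropy_sd²) for
  the invalid fraction (signs mixed under *balanced* pleiotropy, one-sided
  under *directional*);
* observed effects add noise with the standard large-sample SEs
  seXⱼ = 1/√(2fⱼ(1−fⱼ)·n_exp) and seYⱼ = 1/√(2fⱼ(1−fⱼ)·N·p(1−p)) for a
  binary outcome with case fraction p.

The default configuration mirrors the study design the bundled data come
from: an exposure GWAS of 5,293 individuals, an outcome GWAS of
60,801 cases / 123,504 controls, per-SNP exposure effects of the magnitude
seen at the bundled loci (SD 0.2), and a protective causal effect of
ln(0.85) per SD of exposure.  Linkage disequilibrium and sample overlap are
deliberately absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError
from .summary import HarmonizedInstrument, SummaryAssociation, harmonize_tables

_DEFAULT_THETA = math.log(0.85)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic two-sample dataset."""

    m_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_effect_sd: float = 0.2
    theta: float = _DEFAULT_THETA
    pleiotropy_mode: str = "none"          # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0
    n_exposure: int = 5293
    n_outcome_cases: int = 60801
    n_outcome_controls: int = 123504
    scramble_alleles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not 0 < low < high <= 0.5:
            raise ValidationError(
                f"maf_range must satisfy 0 < low < high <= 0.5, got {self.maf_range}"
            )
        if not 0 <= self.prop_invalid <= 1:
            raise ValidationError("prop_invalid must lie in [0, 1]")
        if min(self.n_exposure, self.n_outcome_cases,
               self.n_outcome_controls) <= 0:
            raise ValidationError("all sample sizes must be positive")
        if self.m_snps < 1:
            raise ValidationError("m_snps must be >= 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValidationError(
                f"unknown pleiotropy_mode {self.pleiotropy_mode!r}"
            )


@dataclass(frozen=True)
class SimulatedStudy:
    """A generated dataset plus the truth that produced it."""

    config: SimulationConfig
    theta: float
    pleiotropy: np.ndarray          # per-SNP direct effects alpha_j
    true_beta_exposure: np.ndarray
    true_beta_outcome: np.ndarray
    exposure_table: list[SummaryAssociation] = field(repr=False)
    outcome_table: list[SummaryAssociation] = field(repr=False)

    def harmonized(self) -> list[HarmonizedInstrument]:
        """Harmonize the two generated tables (exercises the same code path
        real data take, including any scrambled allele orientations)."""
        return harmonize_tables(self.exposure_table, self.outcome_table)


def simulate_two_sample_summary(config: SimulationConfig) -> SimulatedStudy:
    """Draw one synthetic two-sample summary dataset; deterministic under a
    fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    m = config.m_snps
    maf = rng.uniform(*config.maf_range, size=m)
    # coded to the exposure-increasing allele, as instrument tables are
    b_exp = np.abs(rng.normal(0.0, config.exposure_effect_sd, size=m))

    alpha = np.zeros(m)
    if config.pleiotropy_mode != "none" and config.prop_invalid > 0:
        n_invalid = int(round(config.prop_invalid * m))
        invalid = rng.choice(m, size=n_invalid, replace=False)
        if config.pleiotropy_mode == "balanced":
            signs = rng.choice([-1.0, 1.0], size=n_invalid)
        else:
            signs = np.ones(n_invalid)
        alpha[invalid] = rng.normal(signs * config.pleiotropy_mean,
                                    config.pleiotropy_sd)

    b_out = config.theta * b_exp + alpha

    n_total = config.n_outcome_cases + config.n_outcome_controls
    case_frac = config.n_outcome_cases / n_total
    var_g = 2.0 * maf * (1.0 - maf)
    se_exp = 1.0 / np.sqrt(var_g * config.n_exposure)
    se_out = 1.0 / np.sqrt(var_g * n_total * case_frac * (1.0 - case_frac))

    obs_exp = rng.normal(b_exp, se_exp)
    obs_out = rng.normal(b_out, se_out)

    flip = (rng.random(m) < 0.5) if config.scramble_alleles else np.zeros(m, bool)

    exposure_table, outcome_table = [], []
    for j in range(m):
        snp = f"snp{j:04d}"
        exposure_table.append(SummaryAssociation(
            snp_id=snp, effect_allele="A", other_allele="G",
            eaf=float(maf[j]), beta=float(obs_exp[j]), se=float(se_exp[j]),
            trait="exposure",
        ))
        ea, oa, sgn = ("G", "A", -1.0) if flip[j] else ("A", "G", 1.0)
        outcome_table.append(SummaryAssociation(
            snp_id=snp, effect_allele=ea, other_allele=oa,
            eaf=float(1 - maf[j]) if flip[j] else float(maf[j]),
            beta=float(sgn * obs_out[j]), se=float(se_out[j]),
            trait="outcome",
        ))

    return SimulatedStudy(
        config=config,
        theta=config.theta,
        pleiotropy=alpha,
        true_beta_exposure=b_exp,
        true_beta_outcome=b_out,
        exposure_table=exposure_table,
        outcome_table=outcome_table,
    )


def replicate(config: SimulationConfig, n_replicates: int,
              ) -> list[SimulatedStudy]:
    """Independent replicate datasets, seeds derived as seed + replicate
    index so each replicate is reproducible in isolation."""
    return [
        simulate_two_sample_summary(replace(config, seed=config.seed + r))
        for r in range(n_replicates)
    ]
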