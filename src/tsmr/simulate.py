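"""Synthetic paired GWAS summary statistics with known ground truth.

The generator embodies the structural model under which two-sample MR is
valid: variant j has a true effect gamma_j on the exposure, and its true
effect on the outcome is

    beta_out_true_j = theta * gamma_j + alpha_j,

where theta is the causal effect (log-OR scale) and alpha_j is a direct
(horizontally pleiotropic) effect — zero for valid instruments, drawn
around zero for balanced pleiotropy, and around a positive mean for
directional pleiotropy.  alpha is drawn independently of gamma, so the
InSIDE condition holds by construction.

Observed summary statistics add sampling noise: with allele frequency
p_j and a unit-variance trait the analytic standard error of a
per-allele estimate from n samples is (2 p_j (1 - p_j) n)^(-1/2); the
observed betas are drawn normally around the truth with those SEs, and
p-values come from the two-sided normal.  Everything is deterministic
given the seed.

``n_exp`` and ``n_out`` are *effective* precision parameters, not
nominal head-counts.  A case-control GWAS of nc cases and nco controls
has effective size 4 nc nco / (nc + nco), and published trait scalings
rarely equal unit variance, so the defaults here are the effective
sizes implied by the printed standard errors of the packaged study
datasets: n_exp = 145,000 reproduces exposure SEs of ~0.004 and, with
true effects gamma ~ N(0.04, 0.012^2), instrument F-statistics of
roughly 40-110; n_out = 12,000 reproduces outcome SEs of ~0.012-0.022.
In this regime the outcome noise dominates each Wald ratio's sampling
error (se_out >> |theta| se_exp), as in the packaged data, which is the
regime the first-order ratio SEs assume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .gwas_io import SummaryStatRecord, SummaryStatSet

__all__ = ["SimConfig", "SimTruth", "SimDataset", "simulate", "scenario_battery"]

_NON_PALINDROMIC_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic two-sample MR dataset."""

    n_snps: int = 4
    theta: float = -0.6
    gamma_mean: float = 0.04
    gamma_sd: float = 0.012
    gamma_values: tuple[float, ...] | None = None
    eaf_bounds: tuple[float, float] = (0.05, 0.95)
    n_exp: int = 145_000
    n_out: int = 12_000
    pleiotropy_mode: str = "none"  # none | balanced | directional
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    outlier_index: int | None = None
    outlier_shift: float = 0.0  # in units of the outcome SE
    palindromic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        if self.n_exp < 100 or self.n_out < 100:
            raise ValueError("GWAS sample sizes must be >= 100")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.alpha_sd < 0:
            raise ValueError("alpha_sd must be >= 0")
        lo, hi = self.eaf_bounds
        if not (0 < lo < hi < 1):
            raise ValueError("eaf_bounds must satisfy 0 < lo < hi < 1")
        if not (0 <= self.palindromic_fraction <= 1):
            raise ValueError("palindromic_fraction must be in [0, 1]")
        if self.gamma_values is not None and len(self.gamma_values) != self.n_snps:
            raise ValueError("gamma_values length must equal n_snps")
        if self.outlier_index is not None and not (0 <= self.outlier_index < self.n_snps):
            raise ValueError("outlier_index out of range")


@dataclass(frozen=True)
class SimTruth:
    theta: float
    gamma: np.ndarray
    alpha: np.ndarray


@dataclass
class SimDataset:
    exposure: SummaryStatSet
    outcome: SummaryStatSet
    truth: SimTruth
    config: SimConfig


def simulate(config: SimConfig, seed: int | None = None) -> SimDataset:
    """Draw one synthetic dataset; ``seed`` overrides ``config.seed``."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    j = config.n_snps

    eaf = rng.uniform(*config.eaf_bounds, size=j)
    if config.gamma_values is not None:
        gamma = np.asarray(config.gamma_values, dtype=float)
    else:
        gamma = rng.normal(config.gamma_mean, config.gamma_sd, size=j)
    if config.pleiotropy_mode == "none":
        alpha = np.zeros(j)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.alpha_sd, size=j)
    else:
        alpha = rng.normal(config.alpha_mean, config.alpha_sd, size=j)

    se_exp = (2.0 * eaf * (1.0 - eaf) * config.n_exp) ** -0.5
    se_out = (2.0 * eaf * (1.0 - eaf) * config.n_out) ** -0.5
    beta_exp = rng.normal(gamma, se_exp)
    beta_out_true = config.theta * gamma + alpha
    beta_out = rng.normal(beta_out_true, se_out)
    if config.outlier_index is not None:
        beta_out[config.outlier_index] += config.outlier_shift * se_out[config.outlier_index]

    n_pal = int(round(config.palindromic_fraction * j))
    pal_flags = np.array([True] * n_pal + [False] * (j - n_pal))
    rng.shuffle(pal_flags)
    alleles = [
        _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        if pal
        else _NON_PALINDROMIC_PAIRS[rng.integers(len(_NON_PALINDROMIC_PAIRS))]
        for pal in pal_flags
    ]

    def _records(betas, ses, n):
        pvals = np.clip(2.0 * stats.norm.sf(np.abs(betas / ses)), 1e-300, 1.0)
        return [
            SummaryStatRecord(
                snp_id=f"rs{1000 + i}",
                effect_allele=alleles[i][0],
                other_allele=alleles[i][1],
                beta=float(betas[i]),
                se=float(ses[i]),
                pval=float(pvals[i]),
                n=n,
                eaf=float(eaf[i]),
            )
            for i in range(j)
        ]

    exposure = SummaryStatSet.from_records(
        "sim_exposure", _records(beta_exp, se_exp, config.n_exp)
    )
    outcome = SummaryStatSet.from_records(
        "sim_outcome", _records(beta_out, se_out, config.n_out)
    )
    return SimDataset(
        exposure=exposure,
        outcome=outcome,
        truth=SimTruth(config.theta, gamma, alpha),
        config=config,
    )


def scenario_battery() -> dict[str, SimConfig]:
    """Named generative scenarios exercising every pipeline diagnostic.

    * ``null`` — no causal effect, valid instruments.
    * ``causal-no-pleiotropy`` — protective effect, valid instruments;
      the reference scenario for CI-coverage checks.
    * ``balanced-pleiotropy`` — direct effects centred on zero.
    * ``directional-pleiotropy`` — one-sided direct effects that the
      Egger intercept should detect.
    * ``single-outlier`` — one variant's outcome effect shifted by
      10 outcome-SEs, the target of the RSS outlier test.
    """
    base = SimConfig(n_snps=10, theta=-0.6)
    return {
        "null": replace(base, theta=0.0, seed=101),
        "causal-no-pleiotropy": replace(base, seed=102),
        "balanced-pleiotropy": replace(
            base, n_snps=20, pleiotropy_mode="balanced", alpha_sd=0.01, seed=103
        ),
        "directional-pleiotropy": replace(
            base,
            n_snps=30,
            pleiotropy_mode="directional",
            alpha_mean=0.02,
            alpha_sd=0.01,
            seed=104,
        ),
        "single-outlier": replace(
            base, n_snps=20, outlier_index=0, outlier_shift=10.0, seed=105
        ),
    }
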