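"""Causal-effect estimators for two-sample Mendelian randomization.

Each harmonized variant j contributes a Wald ratio
theta_j = beta_out_j / beta_exp_j.  The estimators here combine those
ratios under different identifying assumptions:

* IVW — inverse-variance-weighted mean of the ratios, equivalent to a
  zero-intercept weighted regression of outcome on exposure betas.
  Consistent when every instrument is valid.  The default
  multiplicative-random-effects model inflates the fixed-effect SE by
  max(1, sqrt(Q / (J - 1))) so heterogeneity widens, never narrows,
  the interval.
* Weighted median — the 50% point of the inverse-variance-weighted
  empirical ratio distribution; consistent when instruments carrying at
  least half of the weight are valid.  Its SE comes from a parametric
  bootstrap that redraws both betas from their sampling distributions.
* MR-Egger — weighted regression with a free intercept; the slope is
  the causal estimate under the InSIDE assumption and the intercept
  absorbs (and tests for) directional pleiotropy.  Instruments are
  first oriented so all exposure betas are non-negative.

Binary-outcome effects are on the log odds-ratio scale;
:func:`to_odds_ratio` maps (beta, SE) to OR with a 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedVariant, orient_to_positive_exposure

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "EggerFit",
    "EstimationError",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "weighted_median_point",
    "egger",
    "to_odds_ratio",
    "DEFAULT_BOOT_SEED",
]

DEFAULT_BOOT_SEED = 20220
_Z95 = 1.96  # conventional 95% CI multiplier


class EstimationError(ValueError):
    """Estimator preconditions violated."""


@dataclass(frozen=True)
class RatioEstimate:
    """Single-variant Wald ratio with its inverse-variance weight."""

    snp_id: str
    theta: float
    se_theta: float

    @property
    def weight(self) -> float:
        return self.se_theta**-2


@dataclass(frozen=True)
class MREstimate:
    """A combined causal-effect estimate on the log-OR scale."""

    method: str
    nsnp: int
    beta: float
    se: float
    pval: float
    or_: float
    or_lci95: float
    or_uci95: float
    meta: dict = field(default_factory=dict, compare=False)

    @classmethod
    def build(cls, method: str, nsnp: int, beta: float, se: float, pval: float, **meta):
        or_, lo, hi = to_odds_ratio(beta, se)
        return cls(method, nsnp, beta, se, min(max(pval, 1e-300), 1.0), or_, lo, hi, meta)


@dataclass(frozen=True)
class EggerFit:
    """MR-Egger slope (causal estimate) and intercept (pleiotropy) terms."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float
    df: int
    residual_scale: float


def _as_list(variants) -> list[HarmonizedVariant]:
    return list(variants)


def wald_ratio(v: HarmonizedVariant, se_method: str = "first_order") -> RatioEstimate:
    """Per-variant causal estimate theta = beta_out / beta_exp.

    ``first_order`` SE = se_out / |beta_exp|; ``second_order`` adds the
    exposure-noise term sqrt(se_out^2/beta_exp^2 +
    beta_out^2 se_exp^2 / beta_exp^4).
    """
    if v.beta_exp == 0:
        raise EstimationError(f"{v.snp_id}: Wald ratio undefined for beta_exp = 0")
    theta = v.beta_out / v.beta_exp
    if se_method == "first_order":
        se = v.se_out / abs(v.beta_exp)
    elif se_method == "second_order":
        se = np.sqrt(
            v.se_out**2 / v.beta_exp**2 + v.beta_out**2 * v.se_exp**2 / v.beta_exp**4
        )
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return RatioEstimate(v.snp_id, theta, se)


def _ratio_arrays(variants, se_method):
    ratios = [wald_ratio(v, se_method) for v in variants]
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    return theta, w


def ivw(
    variants,
    model: str = "multiplicative_random_effects",
    se_method: str = "first_order",
) -> MREstimate:
    """Inverse-variance-weighted causal estimate.

    beta = sum(w_j theta_j) / sum(w_j) with w_j = se(theta_j)^-2.  Under
    ``multiplicative_random_effects`` the fixed-effect SE is scaled by
    max(1, sqrt(Q/(J-1))) where Q is Cochran's Q about the fixed-effect
    estimate; p-values use the standard normal.
    """
    if model not in ("fixed", "multiplicative_random_effects"):
        raise ValueError(f"unknown IVW model {model!r}")
    variants = _as_list(variants)
    if len(variants) < 2:
        raise EstimationError("IVW requires at least 2 variants")
    theta, w = _ratio_arrays(variants, se_method)
    sw = w.sum()
    if sw <= 0:
        raise EstimationError("all IVW weights are zero")
    beta = float(np.sum(w * theta) / sw)
    se_fixed = float(sw**-0.5)
    q = float(np.sum(w * (theta - beta) ** 2))
    se = se_fixed
    if model == "multiplicative_random_effects":
        se = se_fixed * max(1.0, np.sqrt(q / (len(variants) - 1)))
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate.build(
        "IVW", len(variants), beta, se, pval,
        model=model, se_method=se_method, q=q, se_fixed=se_fixed,
    )


def weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by the standardized-cumulative-weight construction.

    Ratios are sorted ascending; with normalized weights p_j the
    standardized cumulative weight is s_j = sum_{k<=j} p_k - p_j/2, and
    the estimate interpolates theta against s at s = 0.5.  Outside
    [s_1, s_J] the extreme ratio is returned (no extrapolation).
    """
    order = np.argsort(theta, kind="stable")
    t = np.asarray(theta, dtype=float)[order]
    p = np.asarray(weights, dtype=float)[order]
    p = p / p.sum()
    s = np.cumsum(p) - p / 2.0
    if s[0] >= 0.5:
        return float(t[0])
    if s[-1] <= 0.5:
        return float(t[-1])
    return float(np.interp(0.5, s, t))


def weighted_median(
    variants,
    n_boot: int = 1000,
    seed: int | None = DEFAULT_BOOT_SEED,
    se_method: str = "first_order",
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Each bootstrap iteration redraws every (beta_exp, beta_out) from
    normal distributions centred at the observed values with their
    standard errors and recomputes the weighted median; the SE is the
    standard deviation over iterations.
    """
    variants = _as_list(variants)
    if len(variants) < 3:
        raise EstimationError("weighted median requires at least 3 variants")
    if n_boot < 100:
        raise EstimationError("n_boot must be at least 100")
    theta, w = _ratio_arrays(variants, se_method)
    beta = weighted_median_point(theta, w)
    order = np.argsort(theta, kind="stable")
    p = w[order] / w.sum()
    s = np.cumsum(p) - p / 2.0
    clamped = bool(s[0] >= 0.5 or s[-1] <= 0.5)
    if clamped:
        warnings.warn(
            "weighted median clamped at an extreme ratio "
            "(cumulative weight never crosses 0.5)",
            stacklevel=2,
        )

    bx = np.array([v.beta_exp for v in variants])
    by = np.array([v.beta_out for v in variants])
    sx = np.array([v.se_exp for v in variants])
    sy = np.array([v.se_out for v in variants])
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, len(variants)))
    by_star = rng.normal(by, sy, size=(n_boot, len(variants)))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_star = by_star / bx_star
        if se_method == "first_order":
            se_star = sy / np.abs(bx_star)
        else:
            se_star = np.sqrt(sy**2 / bx_star**2 + by_star**2 * sx**2 / bx_star**4)
        w_star = se_star**-2.0
    boot = np.empty(n_boot)
    for b in range(n_boot):
        ok = np.isfinite(theta_star[b]) & np.isfinite(w_star[b]) & (w_star[b] > 0)
        boot[b] = weighted_median_point(theta_star[b][ok], w_star[b][ok])
    se = float(boot.std(ddof=1))
    pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
    return MREstimate.build(
        "WeightedMedian", len(variants), beta, se, pval,
        n_boot=n_boot, seed=seed, se_method=se_method, clamped=clamped,
    )


def egger(variants, se_method: str = "first_order") -> EggerFit:
    """MR-Egger weighted regression with a free intercept.

    After orienting all exposure betas non-negative, beta_out is
    regressed on beta_exp with weights se_out^-2.  Coefficient SEs are
    inflated by max(1, sqrt(RSS_w / (J - 2))) and p-values use the
    t-distribution with J - 2 degrees of freedom.  (``se_method`` is
    recorded for the slope estimate's metadata; the regression weights
    are first-order outcome weights.)
    """
    variants = orient_to_positive_exposure(_as_list(variants))
    j = len(variants)
    if j < 3:
        raise EstimationError("MR-Egger requires at least 3 variants")
    bx = np.array([v.beta_exp for v in variants])
    by = np.array([v.beta_out for v in variants])
    w = np.array([v.se_out**-2 for v in variants])
    if np.allclose(bx, bx[0]):
        raise EstimationError("MR-Egger undefined: no variance in exposure betas")
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    rss_w = float(np.sum(w * resid**2))
    df = j - 2
    scale = rss_w / df
    cov_unscaled = np.linalg.inv(xtwx)
    inflation = max(1.0, scale)
    ses = np.sqrt(np.diag(cov_unscaled) * inflation)
    tvals = coef / ses
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    slope = MREstimate.build(
        "Egger_slope", j, float(coef[1]), float(ses[1]), float(pvals[1]),
        se_method=se_method, rss_w=rss_w,
    )
    return EggerFit(
        slope=slope,
        intercept=float(coef[0]),
        intercept_se=float(ses[0]),
        intercept_pval=float(min(pvals[0], 1.0)),
        df=df,
        residual_scale=float(np.sqrt(scale)),
    )


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Map a log-OR and its SE to (OR, 95% CI lower, 95% CI upper)."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - _Z95 * se)),
        float(np.exp(beta + _Z95 * se)),
    )
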