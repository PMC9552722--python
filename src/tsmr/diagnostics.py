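"""Heterogeneity, pleiotropy, outlier and sensitivity diagnostics.

The validity checks that accompany a two-sample MR estimate:

* Cochran's Q — heterogeneity of the per-variant ratios about either
  the fixed-effect IVW estimate (df = J - 1) or the MR-Egger fit
  (df = J - 2), referred to the upper chi-square tail.
* MR-Egger intercept test — a non-zero intercept indicates directional
  horizontal pleiotropy (p > 0.05 read as "no significant pleiotropy").
* A residual-sum-of-squares pleiotropy test in the MR-PRESSO style —
  the observed leave-one-out weighted RSS is compared with its
  parametric-simulation distribution (global test); when globally
  significant, per-variant residuals identify outliers
  (Bonferroni-adjusted), and a distortion test asks whether removing
  them changes the IVW estimate more than removing random variants.
* Leave-one-out and single-variant tables for forest-style sensitivity
  displays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EggerFit,
    EstimationError,
    MREstimate,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
)

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "cochran_q",
    "egger_intercept_test",
    "EggerInterceptTest",
    "mr_presso",
    "leave_one_out",
    "single_snp_table",
    "PLEIOTROPY_ALPHA",
]

PLEIOTROPY_ALPHA = 0.05
_Z95 = 1.96


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # "IVW" or "MR_Egger"
    q: float
    q_df: int
    q_pval: float


@dataclass(frozen=True)
class EggerInterceptTest:
    intercept: float
    se: float
    pval: float
    verdict: str


@dataclass(frozen=True)
class PressoResult:
    rss_obs: float
    global_pval: float
    n_sim: int
    seed: int | None
    outlier_pvals: dict | None = None  # snp_id -> Bonferroni-adjusted p
    outliers: list = field(default_factory=list)
    distortion_pval: float | None = None
    corrected_estimate: MREstimate | None = None


def cochran_q(variants, about: str = "ivw_fixed", se_method: str = "first_order") -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic.

    ``ivw_fixed``: Q = sum w_j (theta_j - theta_fixed)^2 with df = J - 1;
    ``egger``: weighted residual sum of squares about the Egger
    regression with df = J - 2.
    """
    variants = list(variants)
    j = len(variants)
    if about == "ivw_fixed":
        if j < 2:
            raise EstimationError("IVW Q requires at least 2 variants")
        est = ivw(variants, model="fixed", se_method=se_method)
        q, df = est.meta["q"], j - 1
        method = "IVW"
    elif about == "egger":
        if j < 3:
            raise EstimationError("Egger Q requires at least 3 variants")
        fit = egger(variants, se_method=se_method)
        q, df = fit.slope.meta["rss_w"], j - 2
        method = "MR_Egger"
    else:
        raise ValueError(f"unknown Q reference {about!r}")
    return HeterogeneityResult(method, float(q), df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(fit: EggerFit, alpha: float = PLEIOTROPY_ALPHA) -> EggerInterceptTest:
    """Directional-pleiotropy verdict from the MR-Egger intercept."""
    verdict = (
        "no significant pleiotropy"
        if fit.intercept_pval > alpha
        else "significant directional pleiotropy"
    )
    return EggerInterceptTest(fit.intercept, fit.intercept_se, fit.intercept_pval, verdict)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, inv_sy2: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorised over rows.

    With first-order ratio weights the IVW estimate equals
    sum(bx by / sy^2) / sum(bx^2 / sy^2); dropping one variant subtracts
    its terms from both sums.
    """
    num = bx * by * inv_sy2
    den = bx * bx * inv_sy2
    num_tot = num.sum(axis=-1, keepdims=True)
    den_tot = den.sum(axis=-1, keepdims=True)
    return (num_tot - num) / (den_tot - den)


def _presso_residuals(bx, by, sy) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant weighted squared LOO residuals and their row sums."""
    inv_sy2 = sy**-2.0
    slopes = _loo_slopes(bx, by, inv_sy2)
    resid2 = (by - slopes * bx) ** 2 * inv_sy2
    return resid2, resid2.sum(axis=-1)


def mr_presso(
    variants,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = PLEIOTROPY_ALPHA,
) -> PressoResult:
    """Residual-sum-of-squares pleiotropy test with outlier detection.

    The observed statistic is RSS = sum_j (beta_out_j -
    theta_(-j) beta_exp_j)^2 / se_out_j^2, where theta_(-j) is the IVW
    estimate excluding variant j.  ``n_sim`` parametric replicates redraw
    beta_exp_j ~ N(beta_exp_j, se_exp_j) and beta_out_j ~
    N(theta_(-j) beta_exp_j, se_out_j); the global p-value is
    (1 + #{RSS* >= RSS_obs}) / (n_sim + 1).  If globally significant at
    ``outlier_alpha``, each variant's observed residual is referred to
    its simulated residual distribution (Bonferroni-adjusted over J);
    when outliers are found, an outlier-robust IVW estimate is reported
    along with a distortion p-value comparing the estimate shift against
    removal of random same-sized variant subsets.
    """
    variants = list(variants)
    j = len(variants)
    if j < 4:
        raise EstimationError("the pleiotropy RSS test requires at least 4 variants")
    if n_sim < 100:
        raise EstimationError("n_sim must be at least 100")
    bx = np.array([v.beta_exp for v in variants], dtype=float)
    by = np.array([v.beta_out for v in variants], dtype=float)
    sx = np.array([v.se_exp for v in variants], dtype=float)
    sy = np.array([v.se_out for v in variants], dtype=float)
    ids = [v.snp_id for v in variants]

    resid2_obs, rss_obs = _presso_residuals(bx, by, sy)
    slopes_loo = _loo_slopes(bx, by, sy**-2.0)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(slopes_loo * bx, sy, size=(n_sim, j))
    resid2_star, rss_star = _presso_residuals(bx_star, by_star, sy)
    global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))

    outlier_pvals = None
    outliers: list[str] = []
    distortion_pval = None
    corrected = None
    if global_pval < outlier_alpha:
        raw = (1 + np.sum(resid2_star >= resid2_obs, axis=0)) / (n_sim + 1)
        adj = np.minimum(raw * j, 1.0)
        outlier_pvals = dict(zip(ids, adj.tolist()))
        outliers = [s for s, p in outlier_pvals.items() if p < outlier_alpha]
        if outliers and j - len(outliers) >= 2:
            keep = [v for v in variants if v.snp_id not in outliers]
            corrected = ivw(keep)
            delta_obs = corrected.beta - ivw(variants).beta
            k = len(outliers)
            candidates = [i for i, s in enumerate(ids) if s not in outliers]
            deltas = np.empty(n_sim)
            full = ivw(variants).beta
            for b in range(n_sim):
                drop = rng.choice(candidates, size=min(k, len(candidates) - 2), replace=False)
                mask = np.ones(j, dtype=bool)
                mask[drop] = False
                inv_sy2 = sy[mask] ** -2.0
                deltas[b] = (
                    np.sum(bx[mask] * by[mask] * inv_sy2) / np.sum(bx[mask] ** 2 * inv_sy2)
                    - full
                )
            distortion_pval = float(
                (1 + np.sum(np.abs(deltas) >= abs(delta_obs))) / (n_sim + 1)
            )
    return PressoResult(
        rss_obs=float(rss_obs),
        global_pval=global_pval,
        n_sim=n_sim,
        seed=seed,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        distortion_pval=distortion_pval,
        corrected_estimate=corrected,
    )


_SENS_COLUMNS = ["label", "nsnp", "beta", "se", "lci", "uci", "pval"]


def leave_one_out(
    variants,
    model: str = "multiplicative_random_effects",
    se_method: str = "first_order",
) -> pd.DataFrame:
    """IVW estimate after removing each variant in turn (one row each)."""
    variants = list(variants)
    if len(variants) < 3:
        raise EstimationError("leave-one-out requires at least 3 variants")
    rows = []
    for left_out in variants:
        rest = [v for v in variants if v.snp_id != left_out.snp_id]
        est = ivw(rest, model=model, se_method=se_method)
        rows.append(
            {
                "label": left_out.snp_id,
                "nsnp": est.nsnp,
                "beta": est.beta,
                "se": est.se,
                "lci": est.beta - _Z95 * est.se,
                "uci": est.beta + _Z95 * est.se,
                "pval": est.pval,
            }
        )
    return pd.DataFrame(rows, columns=_SENS_COLUMNS)


def single_snp_table(
    variants,
    se_method: str = "first_order",
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-variant Wald ratios with 95% CIs, plus IVW and weighted-median
    summary rows (suppressed when too few variants support them)."""
    variants = sorted(variants, key=lambda v: v.snp_id)
    if not variants:
        raise EstimationError("single-variant table requires at least 1 variant")
    rows = []
    for v in variants:
        r = wald_ratio(v, se_method)
        pval = 2.0 * stats.norm.sf(abs(r.theta) / r.se_theta)
        rows.append(
            {
                "label": v.snp_id,
                "nsnp": 1,
                "beta": r.theta,
                "se": r.se_theta,
                "lci": r.theta - _Z95 * r.se_theta,
                "uci": r.theta + _Z95 * r.se_theta,
                "pval": pval,
            }
        )
    summaries = []
    if len(variants) >= 2:
        summaries.append(("All - IVW", ivw(variants, se_method=se_method)))
    if len(variants) >= 3:
        kwargs = {"seed": seed} if seed is not None else {}
        summaries.append(
            ("All - Weighted median", weighted_median(variants, n_boot=n_boot, se_method=se_method, **kwargs))
        )
    for label, est in summaries:
        rows.append(
            {
                "label": label,
                "nsnp": est.nsnp,
                "beta": est.beta,
                "se": est.se,
                "lci": est.beta - _Z95 * est.se,
                "uci": est.beta + _Z95 * est.se,
                "pval": est.pval,
            }
        )
    return pd.DataFrame(rows, columns=_SENS_COLUMNS)
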