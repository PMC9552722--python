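"""Model/Results interface for a two-sample MR analysis.

:class:`MRModel` wraps a set of harmonized instrument-outcome pairs;
``fit()`` runs the estimators (IVW, weighted median, MR-Egger) together
with the heterogeneity and pleiotropy diagnostics and returns an
:class:`MRResults` carrying the estimates, their uncertainties and a
``summary()`` table.  Sensitivity analyses (leave-one-out, single-variant
forest tables) hang off the results object.

Example
-------
>>> from tsmr import MRModel, load_fixture
>>> model = MRModel.from_summary_stats(
...     load_fixture("pyroglutamine_exposure"), load_fixture("covid19_outcome"))
>>> res = model.fit(seed=1)
>>> round(res.estimates["IVW"].beta, 2)
-0.63
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import estimators as est
from .gwas_io import SummaryStatSet
from .harmonize import HarmonizedData, HarmonizedVariant, ProxyMap, harmonize

__all__ = ["MRModel", "MRResults"]


class MRModel:
    """Two-sample Mendelian-randomization model on harmonized variants.

    Parameters
    ----------
    variants : sequence of HarmonizedVariant or HarmonizedData
        Exposure/outcome pairs already aligned to a common effect allele.
    exposure_label, outcome_label : str
        Trait names used in the summary output.
    """

    def __init__(
        self,
        variants: Sequence[HarmonizedVariant] | HarmonizedData,
        exposure_label: str = "exposure",
        outcome_label: str = "outcome",
    ):
        self.data = (
            variants
            if isinstance(variants, HarmonizedData)
            else HarmonizedData(list(variants), [])
        )
        if len(self.data) < 2:
            raise ValueError("an MR model needs at least 2 harmonized variants")
        self.exposure_label = exposure_label
        self.outcome_label = outcome_label

    @classmethod
    def from_summary_stats(
        cls,
        exposure: SummaryStatSet,
        outcome: SummaryStatSet,
        proxies: ProxyMap | None = None,
        palindromic_policy: str = "keep_if_eaf_informative",
        eaf_ambiguity_band: float = 0.08,
    ) -> "MRModel":
        """Harmonize two summary-statistic sets and build the model."""
        data = harmonize(
            exposure,
            outcome,
            proxies=proxies,
            palindromic_policy=palindromic_policy,
            eaf_ambiguity_band=eaf_ambiguity_band,
        )
        return cls(data, exposure.trait_label, outcome.trait_label)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        exposure_label: str = "exposure",
        outcome_label: str = "outcome",
    ) -> "MRModel":
        """Build from a frame with columns SNP, EA, NEA, beta_exp, se_exp,
        beta_out, se_out (optionally eaf_exp, eaf_out, action)."""
        variants = [
            HarmonizedVariant(
                snp_id=str(row["SNP"]),
                effect_allele=str(row["EA"]),
                other_allele=str(row["NEA"]),
                beta_exp=float(row["beta_exp"]),
                se_exp=float(row["se_exp"]),
                beta_out=float(row["beta_out"]),
                se_out=float(row["se_out"]),
                eaf_exp=_opt(row.get("eaf_exp")),
                eaf_out=_opt(row.get("eaf_out")),
                action=str(row.get("action", "none")),
            )
            for _, row in df.iterrows()
        ]
        return cls(variants, exposure_label, outcome_label)

    @property
    def nsnp(self) -> int:
        return len(self.data)

    def fit(
        self,
        se_method: str = "first_order",
        ivw_model: str = "multiplicative_random_effects",
        n_boot: int = 1000,
        seed: int | None = est.DEFAULT_BOOT_SEED,
        presso_n_sim: int = 1000,
        outlier_alpha: float = diag.PLEIOTROPY_ALPHA,
        run_presso: bool = True,
    ) -> "MRResults":
        """Estimate the causal effect and run the diagnostic battery.

        ``seed`` drives both the weighted-median bootstrap and the
        pleiotropy RSS simulation, so refitting with the same seed
        reproduces the results exactly.  The RSS (PRESSO-style) test
        needs >= 4 variants and is skipped (with a note) below that.
        """
        variants = self.data.variants
        estimates: dict[str, est.MREstimate] = {}
        estimates["IVW"] = est.ivw(variants, model=ivw_model, se_method=se_method)
        notes: list[str] = []
        egger_fit = None
        intercept_test = None
        heterogeneity = {"IVW": diag.cochran_q(variants, "ivw_fixed", se_method)}
        if self.nsnp >= 3:
            estimates["WeightedMedian"] = est.weighted_median(
                variants, n_boot=n_boot, seed=seed, se_method=se_method
            )
            egger_fit = est.egger(variants, se_method=se_method)
            intercept_test = diag.egger_intercept_test(egger_fit, alpha=outlier_alpha)
            heterogeneity["MR_Egger"] = diag.cochran_q(variants, "egger", se_method)
        else:
            notes.append("fewer than 3 variants: weighted median and MR-Egger skipped")
        presso = None
        if run_presso:
            if self.nsnp >= 4:
                presso = diag.mr_presso(
                    variants, n_sim=presso_n_sim, seed=seed, outlier_alpha=outlier_alpha
                )
            else:
                notes.append("fewer than 4 variants: pleiotropy RSS test skipped")
        return MRResults(
            model=self,
            estimates=estimates,
            egger_fit=egger_fit,
            intercept_test=intercept_test,
            heterogeneity=heterogeneity,
            presso=presso,
            settings={
                "se_method": se_method,
                "ivw_model": ivw_model,
                "n_boot": n_boot,
                "seed": seed,
                "presso_n_sim": presso_n_sim,
                "outlier_alpha": outlier_alpha,
            },
            notes=notes,
        )


def _opt(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


@dataclass
class MRResults:
    """Fitted estimates, diagnostics and sensitivity analyses."""

    model: MRModel
    estimates: dict
    egger_fit: est.EggerFit | None
    intercept_test: diag.EggerInterceptTest | None
    heterogeneity: dict
    presso: diag.PressoResult | None
    settings: dict
    notes: list = field(default_factory=list)

    # -- tabular views -------------------------------------------------

    def estimates_frame(self, include_egger: bool = False) -> pd.DataFrame:
        """Causal-estimate table (method, nsnp, beta, SE, p, OR, 95% CI)."""
        rows = []
        shown = dict(self.estimates)
        if include_egger and self.egger_fit is not None:
            shown["MR_Egger"] = self.egger_fit.slope
        label = {"IVW": "IVW", "WeightedMedian": "Weighted median", "MR_Egger": "MR Egger"}
        for key, e in shown.items():
            rows.append(
                {
                    "Method": label.get(key, key),
                    "nsnp": e.nsnp,
                    "Beta": e.beta,
                    "SE": e.se,
                    "p_val": e.pval,
                    "OR": e.or_,
                    "OR_lci95": e.or_lci95,
                    "OR_uci95": e.or_uci95,
                }
            )
        return pd.DataFrame(rows)

    def diagnostics_frame(self) -> pd.DataFrame:
        """Pleiotropy / heterogeneity table (one row per test)."""
        rows = []
        if self.intercept_test is not None:
            rows.append(
                {
                    "test": "MR_Egger intercept",
                    "statistic": self.intercept_test.intercept,
                    "se": self.intercept_test.se,
                    "df": self.egger_fit.df,
                    "p_val": self.intercept_test.pval,
                    "verdict": self.intercept_test.verdict,
                }
            )
        if self.presso is not None:
            rows.append(
                {
                    "test": "Pleiotropy RSS (PRESSO) global",
                    "statistic": self.presso.rss_obs,
                    "se": np.nan,
                    "df": np.nan,
                    "p_val": self.presso.global_pval,
                    "verdict": (
                        "no significant pleiotropy"
                        if self.presso.global_pval > self.settings["outlier_alpha"]
                        else f"outliers: {self.presso.outliers or 'none identified'}"
                    ),
                }
            )
        for key, het in self.heterogeneity.items():
            rows.append(
                {
                    "test": f"Cochran Q ({key})",
                    "statistic": het.q,
                    "se": np.nan,
                    "df": het.q_df,
                    "p_val": het.q_pval,
                    "verdict": (
                        "no significant heterogeneity"
                        if het.q_pval > 0.05
                        else "significant heterogeneity"
                    ),
                }
            )
        return pd.DataFrame(rows)

    # -- sensitivity ---------------------------------------------------

    def leave_one_out(self) -> pd.DataFrame:
        return diag.leave_one_out(
            self.model.data.variants,
            model=self.settings["ivw_model"],
            se_method=self.settings["se_method"],
        )

    def single_snp(self) -> pd.DataFrame:
        return diag.single_snp_table(
            self.model.data.variants,
            se_method=self.settings["se_method"],
            n_boot=self.settings["n_boot"],
            seed=self.settings["seed"],
        )

    @property
    def any_pleiotropy_flag(self) -> bool:
        flagged = (
            self.intercept_test is not None
            and self.intercept_test.pval <= self.settings["outlier_alpha"]
        )
        if self.presso is not None:
            flagged = flagged or self.presso.global_pval <= self.settings["outlier_alpha"]
        return bool(flagged)

    def summary(self) -> str:
        """Human-readable report of estimates and diagnostics."""
        lines = [
            "Two-sample Mendelian randomization",
            f"  exposure: {self.model.exposure_label}   outcome: {self.model.outcome_label}",
            f"  instruments: {self.model.nsnp}",
            "",
            "Causal estimates (log-OR scale)",
            self.estimates_frame(include_egger=True).to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
            "",
            "Diagnostics",
            self.diagnostics_frame().to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
        ]
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)
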