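"""Instrument selection and strength for Mendelian randomization.

Genetic instruments are chosen by (1) genome-wide significance
(p < 5e-8 by default), (2) approximate linkage-equilibrium via greedy
clumping at a pairwise r-squared threshold (default 0.001), and
(3) removal of variants on a user-supplied confounder exclusion list
(e.g. variants also associated with BMI, smoking or blood pressure).

Instrument strength is summarised per variant by the proportion of
exposure variance explained (R^2) and the F-statistic
F = R^2 (N - 2) / (1 - R^2); F < 10 conventionally flags a weak
instrument.  Two R^2 estimators are provided: ``z_based``
(z^2 / (z^2 + N - 2), from beta/SE/N alone) and ``af_beta``
(2 p (1-p) beta^2, assuming a unit-variance phenotype).  Published
R^2 columns computed from unrounded source data rarely match either
recipe exactly at printed precision, so :func:`f_statistic` also accepts
externally supplied R^2 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .gwas_io import SummaryStatRecord, SummaryStatSet

__all__ = [
    "InstrumentCriteria",
    "InstrumentStrength",
    "StrengthReport",
    "LDTable",
    "MissingLDError",
    "NoInstrumentsError",
    "select_instruments",
    "variance_explained",
    "f_statistic",
    "strength_report",
    "WEAK_F_THRESHOLD",
]

WEAK_F_THRESHOLD = 10.0


class MissingLDError(KeyError):
    """Pairwise r^2 requested for a variant pair absent from the LD table."""


class NoInstrumentsError(ValueError):
    """Selection criteria left no instruments."""


@dataclass(frozen=True)
class InstrumentCriteria:
    """Selection thresholds for genetic instruments."""

    pval_threshold: float = 5e-8
    ld_r2_max: float = 0.001
    exclusion_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 < self.pval_threshold < 1):
            raise ValueError("pval_threshold must be in (0, 1)")
        if not (0 <= self.ld_r2_max <= 1):
            raise ValueError("ld_r2_max must be in [0, 1]")
        object.__setattr__(self, "exclusion_ids", frozenset(self.exclusion_ids))


class LDTable:
    """Symmetric pairwise r^2 lookup.

    Self-pairs return 1.0; a missing pair raises :class:`MissingLDError`
    rather than being assumed independent.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset[str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValueError(f"r2 must be in [0, 1], got {r2} for ({a}, {b})")
        if a != b:
            self._r2[frozenset((a, b))] = float(r2)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = frozenset((a, b))
        if key not in self._r2:
            raise MissingLDError(f"no LD r2 for pair ({a}, {b})")
        return self._r2[key]

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_file(cls, path, sep: str = r"\s+") -> "LDTable":
        """Load a 3-column (snp_a, snp_b, r2) table; symmetric closure applied."""
        df = pd.read_csv(path, sep=sep, engine="python")
        if df.shape[1] < 3:
            raise ValueError("LD table needs 3 columns: snp_a, snp_b, r2")
        table = cls()
        for a, b, r2 in df.iloc[:, :3].itertuples(index=False):
            table.set(str(a), str(b), float(r2))
        return table

    @classmethod
    def independent(cls, snp_ids: Iterable[str]) -> "LDTable":
        """All-zero r^2 table for variants already known to be mutually
        independent (e.g. pre-clumped published instrument sets)."""
        ids = list(snp_ids)
        table = cls()
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                table.set(a, b, 0.0)
        return table


def select_instruments(
    exposure: SummaryStatSet,
    criteria: InstrumentCriteria | None = None,
    ld: LDTable | None = None,
) -> SummaryStatSet:
    """Apply significance, confounder-exclusion and clumping filters.

    Survivors of the p-value and exclusion filters are clumped greedily:
    sorted by ascending p-value (ties broken lexicographically by ID for
    determinism), a variant is accepted iff its r^2 with every
    already-accepted variant is below ``criteria.ld_r2_max``.  The result
    is therefore independent of input row order.
    """
    criteria = criteria or InstrumentCriteria()
    candidates = [
        r
        for r in exposure
        if r.pval < criteria.pval_threshold and r.snp_id not in criteria.exclusion_ids
    ]
    if not candidates:
        raise NoInstrumentsError(
            f"no variants pass p < {criteria.pval_threshold:g} "
            f"after exclusions in {exposure.trait_label!r}"
        )
    if ld is None:
        ld = LDTable()
    candidates.sort(key=lambda r: (r.pval, r.snp_id))
    accepted: list[SummaryStatRecord] = []
    for rec in candidates:
        if all(ld.get(rec.snp_id, kept.snp_id) < criteria.ld_r2_max for kept in accepted):
            accepted.append(rec)
    if not accepted:  # pragma: no cover - greedy always keeps the top hit
        raise NoInstrumentsError("clumping removed every candidate")
    out = exposure.subset([r.snp_id for r in accepted])
    out.meta["instrument_criteria"] = criteria
    return out


def variance_explained(record: SummaryStatRecord, method: str = "z_based") -> float:
    """Proportion of exposure variance explained by one variant.

    ``z_based`` uses R^2 = z^2 / (z^2 + N - 2) with z = beta / SE;
    ``af_beta`` uses R^2 = 2 EAF (1 - EAF) beta^2, which assumes the
    exposure has unit variance and requires EAF.
    """
    if method == "z_based":
        z2 = record.zscore**2
        return z2 / (z2 + record.n - 2)
    if method == "af_beta":
        if record.eaf is None:
            raise ValueError(f"{record.snp_id}: af_beta R^2 requires EAF")
        r2 = 2.0 * record.eaf * (1.0 - record.eaf) * record.beta**2
        return min(r2, 1.0 - 1e-12)
    raise ValueError(f"unknown R^2 method {method!r}")


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F-statistic, F = R^2 (N - 2) / (1 - R^2)."""
    if not (0 <= r2 < 1):
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


@dataclass(frozen=True)
class InstrumentStrength:
    snp_id: str
    r2: float
    f_stat: float
    n: int

    @property
    def weak(self) -> bool:
        return self.f_stat < WEAK_F_THRESHOLD


@dataclass
class StrengthReport:
    """Per-instrument R^2 / F with the summed variance explained."""

    strengths: list[InstrumentStrength]
    total_r2: float
    method: str
    weak_instruments: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "SNP": s.snp_id,
                    "N": s.n,
                    "R2_pct": 100.0 * s.r2,
                    "F": s.f_stat,
                    "weak": s.weak,
                }
                for s in self.strengths
            ]
        )


def strength_report(exposure: SummaryStatSet, method: str = "z_based") -> StrengthReport:
    """Per-SNP R^2 and F plus total R^2; flags any instrument with F < 10."""
    if len(exposure) == 0:
        raise NoInstrumentsError("strength report requires a nonempty instrument set")
    strengths = []
    for rec in exposure:
        r2 = variance_explained(rec, method=method)
        strengths.append(InstrumentStrength(rec.snp_id, r2, f_statistic(r2, rec.n), rec.n))
    return StrengthReport(
        strengths=strengths,
        total_r2=sum(s.r2 for s in strengths),
        method=method,
        weak_instruments=[s.snp_id for s in strengths if s.weak],
    )
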