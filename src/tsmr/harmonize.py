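"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR combines per-variant effects estimated in two different
GWAS, so both effects must refer to the same effect allele.  For each
exposure instrument the outcome record (matched by ID, or substituted
from a user-supplied LD proxy when absent) is aligned by:

* direct allele match — used as is;
* swapped alleles (outcome effect allele equals the exposure's other
  allele), possibly after strand complementation (A<->T, C<->G) — the
  outcome beta is negated and its EAF replaced by 1 - EAF;
* irreconcilable allele sets (e.g. A/C vs A/G) — the variant is dropped
  with the reason recorded.

Palindromic variants (A/T or C/G) are strand-ambiguous: the same printed
alleles can describe either orientation.  The ``palindromic_policy``
decides their fate; the default ``keep_if_eaf_informative`` keeps them
only when both allele frequencies are known, both are outside
0.5 +/- ``eaf_ambiguity_band``, and orientation can be inferred from
frequency concordance.  When a frequency is missing the check degrades
gracefully: a palindromic pair whose printed alleles already match the
exposure orientation exactly (the convention for pre-oriented published
tables) is kept, otherwise it is dropped as unresolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .gwas_io import SummaryStatSet

__all__ = [
    "HarmonizedVariant",
    "HarmonizedData",
    "ProxyEntry",
    "ProxyMap",
    "HarmonizationError",
    "harmonize",
    "orient_to_positive_exposure",
    "PALINDROMIC_POLICIES",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_POLICIES = ("drop", "keep_if_eaf_informative", "keep_all")


class HarmonizationError(ValueError):
    """No variant survived harmonization, or inputs are unusable."""


@dataclass(frozen=True)
class HarmonizedVariant:
    """An exposure/outcome pair aligned to a common effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    action: str = "none"  # none | flipped | proxy_substituted | dropped_palindromic

    def __post_init__(self) -> None:
        if self.se_exp <= 0 or self.se_out <= 0:
            raise HarmonizationError(f"{self.snp_id}: standard errors must be > 0")

    @property
    def wald_ratio(self) -> float:
        return self.beta_out / self.beta_exp


@dataclass
class HarmonizedData:
    """Harmonized variants plus an audit trail of dropped instruments."""

    variants: list[HarmonizedVariant]
    dropped: list[tuple[str, str]]  # (snp_id, reason)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def __getitem__(self, i):
        return self.variants[i]

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "SNP": v.snp_id,
                    "EA": v.effect_allele,
                    "NEA": v.other_allele,
                    "beta_exp": v.beta_exp,
                    "se_exp": v.se_exp,
                    "beta_out": v.beta_out,
                    "se_out": v.se_out,
                    "eaf_exp": v.eaf_exp,
                    "eaf_out": v.eaf_out,
                    "action": v.action,
                }
                for v in self.variants
            ]
        )


@dataclass(frozen=True)
class ProxyEntry:
    """LD proxy for an instrument missing from the outcome GWAS."""

    target_snp: str
    proxy_snp: str
    r2: float
    effect_allele_matches_target: bool

    def __post_init__(self) -> None:
        if not (0 <= self.r2 <= 1):
            raise ValueError(f"proxy r2 must be in [0, 1], got {self.r2}")


class ProxyMap:
    """Lookup of proxies, enforcing a minimum r^2 (default 0.8)."""

    def __init__(self, entries: Iterable[ProxyEntry] = (), r2_min: float = 0.8):
        self.r2_min = r2_min
        self._entries: dict[str, ProxyEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: ProxyEntry) -> None:
        if entry.r2 < self.r2_min:
            raise ValueError(
                f"proxy {entry.proxy_snp} for {entry.target_snp} has "
                f"r2 = {entry.r2} < required {self.r2_min}"
            )
        self._entries[entry.target_snp] = entry

    def get(self, target_snp: str) -> ProxyEntry | None:
        return self._entries.get(target_snp)

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_file(cls, path, sep: str = r"\s+", r2_min: float = 0.8) -> "ProxyMap":
        """Columns: target_snp, proxy_snp, r2, effect_allele_match (yes/no)."""
        df = pd.read_csv(path, sep=sep, engine="python")
        entries = [
            ProxyEntry(
                str(row.iloc[0]),
                str(row.iloc[1]),
                float(row.iloc[2]),
                str(row.iloc[3]).strip().lower() in ("yes", "true", "1"),
            )
            for _, row in df.iterrows()
        ]
        return cls(entries, r2_min=r2_min)


def _is_palindromic(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def _flip(beta: float, eaf: float | None) -> tuple[float, float | None]:
    return -beta, (None if eaf is None else 1.0 - eaf)


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    proxies: ProxyMap | None = None,
    palindromic_policy: str = "keep_if_eaf_informative",
    eaf_ambiguity_band: float = 0.08,
) -> HarmonizedData:
    """Align outcome statistics to each exposure instrument's effect allele.

    Returns a :class:`HarmonizedData` whose ``variants`` plus ``dropped``
    partition the exposure instruments.  Raises
    :class:`HarmonizationError` if the exposure set is empty or no
    variant survives.
    """
    if palindromic_policy not in PALINDROMIC_POLICIES:
        raise ValueError(
            f"palindromic_policy must be one of {PALINDROMIC_POLICIES}"
        )
    if len(exposure) == 0:
        raise HarmonizationError("exposure set is empty")

    variants: list[HarmonizedVariant] = []
    dropped: list[tuple[str, str]] = []

    for exp in exposure:
        action = "none"
        out = outcome.records.get(exp.snp_id)
        if out is None and proxies is not None:
            entry = proxies.get(exp.snp_id)
            if entry is not None and entry.proxy_snp in outcome:
                proxy_rec = outcome[entry.proxy_snp]
                beta_out, eaf_out = proxy_rec.beta, proxy_rec.eaf
                if not entry.effect_allele_matches_target:
                    beta_out, eaf_out = _flip(beta_out, eaf_out)
                # proxy statistics adopted verbatim at the target's alleles
                out = replace(
                    proxy_rec,
                    snp_id=exp.snp_id,
                    effect_allele=exp.effect_allele,
                    other_allele=exp.other_allele,
                    beta=beta_out,
                    eaf=eaf_out,
                    pval=proxy_rec.pval,
                )
                action = "proxy_substituted"
        if out is None:
            dropped.append((exp.snp_id, "absent from outcome GWAS and no proxy"))
            continue

        ea_x, oa_x = exp.effect_allele, exp.other_allele
        ea_o, oa_o = out.effect_allele, out.other_allele
        beta_out, eaf_out = out.beta, out.eaf

        if _is_palindromic(ea_x, oa_x):
            if {ea_o, oa_o} != {ea_x, oa_x}:
                dropped.append((exp.snp_id, f"irreconcilable alleles {ea_o}/{oa_o} vs {ea_x}/{oa_x}"))
                continue
            if (ea_o, oa_o) == (oa_x, ea_x):
                beta_out, eaf_out = _flip(beta_out, eaf_out)
                action = "flipped"
            if palindromic_policy == "drop":
                dropped.append((exp.snp_id, "palindromic (policy drop)"))
                continue
            if palindromic_policy == "keep_if_eaf_informative":
                if exp.eaf is not None and eaf_out is not None:
                    band_lo, band_hi = 0.5 - eaf_ambiguity_band, 0.5 + eaf_ambiguity_band
                    informative = not (band_lo <= exp.eaf <= band_hi) and not (
                        band_lo <= eaf_out <= band_hi
                    )
                    concordant = (exp.eaf - 0.5) * (eaf_out - 0.5) > 0
                    if not (informative and concordant):
                        dropped.append(
                            (exp.snp_id, "palindromic with ambiguous allele frequencies")
                        )
                        continue
                elif action != "none":
                    # frequency missing and orientation cannot be inferred
                    dropped.append(
                        (exp.snp_id, "palindromic, EAF missing, alleles not pre-oriented")
                    )
                    continue
                # frequency missing but printed alleles already match the
                # exposure orientation: treated as pre-oriented and kept
        else:
            comp = (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o])
            if (ea_o, oa_o) == (ea_x, oa_x) or comp == (ea_x, oa_x):
                pass
            elif (ea_o, oa_o) == (oa_x, ea_x) or comp == (oa_x, ea_x):
                beta_out, eaf_out = _flip(beta_out, eaf_out)
                action = "flipped" if action == "none" else action
            else:
                dropped.append(
                    (exp.snp_id, f"irreconcilable alleles {ea_o}/{oa_o} vs {ea_x}/{oa_x}")
                )
                continue

        variants.append(
            HarmonizedVariant(
                snp_id=exp.snp_id,
                effect_allele=ea_x,
                other_allele=oa_x,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
                action=action,
            )
        )

    if not variants:
        reasons = "; ".join(f"{s}: {r}" for s, r in dropped)
        raise HarmonizationError(f"every instrument was dropped ({reasons})")
    return HarmonizedData(variants=variants, dropped=dropped)


def orient_to_positive_exposure(
    variants: Sequence[HarmonizedVariant] | HarmonizedData,
) -> list[HarmonizedVariant]:
    """Re-express every variant so its exposure beta is non-negative.

    Flipping the designated effect allele negates both betas and
    complements both frequencies, leaving each Wald ratio unchanged.
    MR-Egger requires this conventional orientation for its intercept to
    be interpretable.
    """
    out = []
    for v in variants:
        if v.beta_exp < 0:
            v = replace(
                v,
                effect_allele=v.other_allele,
                other_allele=v.effect_allele,
                beta_exp=-v.beta_exp,
                beta_out=-v.beta_out,
                eaf_exp=None if v.eaf_exp is None else 1.0 - v.eaf_exp,
                eaf_out=None if v.eaf_out is None else 1.0 - v.eaf_out,
            )
        out.append(v)
    return out
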