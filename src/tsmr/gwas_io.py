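"""Data model and delimited-text I/O for GWAS summary statistics.

A summary-statistics set is one row per variant: the per-allele effect of a
designated *effect allele* on a trait (log odds ratio for binary traits,
SD or raw units for quantitative traits) together with its standard error,
association p-value, effect-allele frequency and sample size.

The canonical on-disk format is tab-separated text with the header
``SNP  EA  NEA  EAF  BETA  SE  P  N``; arbitrary source headers are
supported through a ``column_map``.  Unicode minus signs (``−``), as
printed in many journal tables, are normalised to ASCII on read.  EAF may
be missing (``NA``): some outcome GWAS exports omit it, and downstream
operations that need frequencies (palindromic-allele checks) degrade
gracefully when it is absent.

Two small study datasets ship with the package (see :func:`load_fixture`):
the four genome-wide-significant blood-pyroglutamine instruments from a
7,354-sample European metabolite GWAS, and the same four variants' effects
in the COVID-19 Host Genetics Initiative release-4 meta-analysis
(14,134 cases / 1,284,876 controls), pre-oriented to the
pyroglutamine-raising allele.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "SummaryStatRecord",
    "SummaryStatSet",
    "SummaryStatError",
    "FieldMapError",
    "DuplicateSnpError",
    "RejectedRow",
    "read_summary_stats",
    "write_summary_stats",
    "load_fixture",
    "FIXTURE_NAMES",
    "CANONICAL_COLUMNS",
]

VALID_ALLELES = frozenset("ACGT")

#: canonical file header -> record field
CANONICAL_COLUMNS: dict[str, str] = {
    "SNP": "snp_id",
    "EA": "effect_allele",
    "NEA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}

_MISSING_TOKENS = {"", "NA", "NAN", "NONE", "."}


class SummaryStatError(ValueError):
    """Invalid summary-statistics content."""


class FieldMapError(SummaryStatError):
    """A mapped column is absent from the input file."""


class DuplicateSnpError(SummaryStatError):
    """The same variant ID occurs more than once in one set."""


@dataclass(frozen=True)
class RejectedRow:
    """A data row that failed validation, kept for reporting."""

    line_number: int
    snp_id: str | None
    reason: str


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association with one trait.

    Parameters
    ----------
    snp_id : str
        Variant identifier (typically an rsID).
    effect_allele, other_allele : str
        Single-base alleles in {A, C, G, T}; ``beta`` is per copy of
        ``effect_allele``.
    beta : float
        Per-allele effect estimate.
    se : float
        Standard error of ``beta``; strictly positive.
    pval : float
        Two-sided association p-value in (0, 1].
    n : int
        Sample size (>= 2).
    eaf : float, optional
        Effect-allele frequency in (0, 1); ``None`` when the source does
        not report it.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise SummaryStatError("snp_id must be non-empty")
        for name in ("effect_allele", "other_allele"):
            allele = getattr(self, name)
            if allele not in VALID_ALLELES:
                raise SummaryStatError(
                    f"{self.snp_id}: {name} {allele!r} not one of A/C/G/T"
                )
        if self.effect_allele == self.other_allele:
            raise SummaryStatError(
                f"{self.snp_id}: effect and other allele are both "
                f"{self.effect_allele!r}"
            )
        if not math.isfinite(self.beta):
            raise SummaryStatError(f"{self.snp_id}: beta is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise SummaryStatError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise SummaryStatError(
                f"{self.snp_id}: pval must be in (0, 1], got {self.pval}"
            )
        if int(self.n) != self.n or self.n < 2:
            raise SummaryStatError(f"{self.snp_id}: n must be an integer >= 2")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise SummaryStatError(
                f"{self.snp_id}: eaf must be in (0, 1) or missing, got {self.eaf}"
            )

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class SummaryStatSet:
    """A keyed collection of :class:`SummaryStatRecord` for one trait."""

    trait_label: str
    records: dict[str, SummaryStatRecord] = field(default_factory=dict)
    ancestry_label: str | None = None
    meta: dict = field(default_factory=dict)
    rejected_rows: list[RejectedRow] = field(default_factory=list)

    @classmethod
    def from_records(
        cls,
        trait_label: str,
        records: Iterable[SummaryStatRecord],
        ancestry_label: str | None = None,
        **meta,
    ) -> "SummaryStatSet":
        out = cls(trait_label=trait_label, ancestry_label=ancestry_label, meta=meta)
        for rec in records:
            out.add(rec)
        return out

    def add(self, record: SummaryStatRecord) -> None:
        if record.snp_id in self.records:
            raise DuplicateSnpError(f"duplicate snp_id {record.snp_id!r}")
        self.records[record.snp_id] = record

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryStatRecord]:
        return iter(self.records.values())

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def __getitem__(self, snp_id: str) -> SummaryStatRecord:
        return self.records[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.records)

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStatSet":
        return SummaryStatSet(
            trait_label=self.trait_label,
            records={s: self.records[s] for s in snp_ids},
            ancestry_label=self.ancestry_label,
            meta=dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": r.snp_id,
                "EA": r.effect_allele,
                "NEA": r.other_allele,
                "EAF": r.eaf,
                "BETA": r.beta,
                "SE": r.se,
                "P": r.pval,
                "N": r.n,
            }
            for r in self
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryStatSet):
            return NotImplemented
        return (
            self.trait_label == other.trait_label
            and self.records == other.records
        )


def _normalise_number(token: object) -> str:
    # journal tables print U+2212 and stray spaces inside signed numbers
    return str(token).replace("−", "-").replace(" ", "").strip()


def _parse_float(token: object, what: str) -> float:
    text = _normalise_number(token)
    try:
        return float(text)
    except ValueError as exc:
        raise SummaryStatError(f"non-numeric {what}: {token!r}") from exc


def _parse_optional_float(token: object, what: str) -> float | None:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    text = _normalise_number(token)
    if text.upper() in _MISSING_TOKENS:
        return None
    return _parse_float(text, what)


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str | None = None,
    sep: str = "\t",
    on_invalid: str = "collect",
) -> SummaryStatSet:
    """Read a delimited summary-statistics file.

    Parameters
    ----------
    path : path-like or file-like
        Delimited text with a header row.
    column_map : mapping, optional
        Source header -> canonical field (``snp_id``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``).
        Defaults to the canonical ``SNP/EA/NEA/EAF/BETA/SE/P/N`` header.
    trait_label : str, optional
        Defaults to the file stem.
    sep : str
        Field delimiter; ``r"\\s+"`` accepts whitespace-delimited input.
    on_invalid : {"collect", "raise"}
        Rows that fail validation are rejected either into
        ``SummaryStatSet.rejected_rows`` (with a warning), or by raising a
        :class:`SummaryStatError` listing every bad line.

    Notes
    -----
    A missing mapped column is a configuration error and always raises
    :class:`FieldMapError`; a duplicated variant ID always raises
    :class:`DuplicateSnpError` naming the ID.
    """
    if column_map is None:
        column_map = CANONICAL_COLUMNS
    if on_invalid not in ("collect", "raise"):
        raise ValueError("on_invalid must be 'collect' or 'raise'")

    df = pd.read_csv(path, sep=sep, dtype=str, engine="python")
    missing = [src for src in column_map if src not in df.columns]
    if missing:
        raise FieldMapError(
            f"mapped column(s) {missing} not found in header {list(df.columns)}"
        )
    inverse = {canonical: src for src, canonical in column_map.items()}
    required = {"snp_id", "effect_allele", "other_allele", "beta", "se", "pval", "n"}
    absent = required - set(inverse)
    if absent:
        raise FieldMapError(f"column_map does not cover required field(s) {sorted(absent)}")

    if trait_label is None:
        trait_label = getattr(path, "stem", None) or str(getattr(path, "name", path))

    out = SummaryStatSet(trait_label=trait_label)
    rejected: list[RejectedRow] = []
    for idx, row in df.iterrows():
        line_number = int(idx) + 2  # header occupies line 1
        snp_id = None
        try:
            snp_id = str(row[inverse["snp_id"]]).strip()
            record = SummaryStatRecord(
                snp_id=snp_id,
                effect_allele=str(row[inverse["effect_allele"]]).strip().upper(),
                other_allele=str(row[inverse["other_allele"]]).strip().upper(),
                beta=_parse_float(row[inverse["beta"]], "beta"),
                se=_parse_float(row[inverse["se"]], "se"),
                pval=_parse_float(row[inverse["pval"]], "pval"),
                n=int(round(_parse_float(row[inverse["n"]], "n"))),
                eaf=(
                    _parse_optional_float(row[inverse["eaf"]], "eaf")
                    if "eaf" in inverse
                    else None
                ),
            )
        except DuplicateSnpError:
            raise
        except SummaryStatError as exc:
            rejected.append(RejectedRow(line_number, snp_id, str(exc)))
            continue
        out.add(record)

    if rejected:
        summary = "; ".join(f"line {r.line_number}: {r.reason}" for r in rejected)
        if on_invalid == "raise":
            raise SummaryStatError(f"invalid rows rejected: {summary}")
        warnings.warn(f"rejected {len(rejected)} invalid row(s): {summary}", stacklevel=2)
        out.rejected_rows = rejected
    return out


def write_summary_stats(sset: SummaryStatSet, path) -> None:
    """Write ``sset`` in the canonical tab-separated format.

    Floats are written with up to 10 significant digits, so
    ``read_summary_stats(write_summary_stats(S)) == S`` at printed
    precision; missing EAF is written as ``NA``.
    """
    df = sset.to_dataframe()
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


FIXTURE_NAMES = ("pyroglutamine_exposure", "covid19_outcome")


def load_fixture(name: str) -> SummaryStatSet:
    """Load a packaged study dataset.

    ``"pyroglutamine_exposure"`` is the four-instrument blood-pyroglutamine
    set (European metabolite GWAS, n = 7,354 per variant);
    ``"covid19_outcome"`` holds the same variants' effects in the COVID-19
    HGI release-4 GWAS (n = 14,134 + 1,284,876 = 1,299,010), with betas
    pre-oriented to the pyroglutamine effect allele and no reported EAF.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = resources.files("tsmr").joinpath("fixtures", f"{name}.tsv")
    with resources.as_file(ref) as fp:
        sset = read_summary_stats(fp, trait_label=name, on_invalid="raise")
    sset.ancestry_label = "European"
    if name == "covid19_outcome":
        sset.trait_label = "COVID-19"
        sset.meta.update(ncase=14134, ncontrol=1284876, gwas_release="HGI release 4")
    else:
        sset.trait_label = "pyroglutamine"
        sset.meta.update(gwas="blood metabolite GWAS")
    return sset
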