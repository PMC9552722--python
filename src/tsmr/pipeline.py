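"""End-to-end orchestration: instruments -> harmonize -> diagnostics -> MR.

A :class:`RunConfig` (usually a YAML file) names the exposure/outcome
inputs (file paths or packaged fixtures), the selection, harmonization,
estimation and diagnostic settings, and an output directory.
:func:`run_pipeline` executes the stages in a fixed order and returns a
:class:`RunReport` with the instrument-strength table, the harmonized
pair table, the diagnostics table, the causal-estimate table, the
sensitivity tables, and a reproducibility manifest (package and library
versions, seeds, config hash).

Diagnostic alarms (significant pleiotropy or heterogeneity) are
prominently flagged but do not abort the run — the estimates are
reported alongside their checks, as in standard MR reporting; a
``strict`` mode that raises instead is available.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimators import DEFAULT_BOOT_SEED
from .gwas_io import load_fixture, read_summary_stats
from .harmonize import ProxyMap
from .instruments import InstrumentCriteria, LDTable, select_instruments, strength_report
from .model import MRModel

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline", "paper_run_config"]

logger = logging.getLogger("tsmr")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative description of one MR analysis run."""

    exposure: str = "fixture:pyroglutamine_exposure"
    outcome: str = "fixture:covid19_outcome"
    ld_table: str | None = None  # path; None + assume_independent for pre-clumped sets
    assume_independent: bool = True
    proxy_map: str | None = None
    pval_threshold: float = 5e-8
    ld_r2_max: float = 0.001
    exclusion_ids: list[str] = field(default_factory=list)
    r2_method: str = "z_based"
    palindromic_policy: str = "keep_if_eaf_informative"
    eaf_ambiguity_band: float = 0.08
    se_method: str = "first_order"
    ivw_model: str = "multiplicative_random_effects"
    n_boot: int = 1000
    seed: int = DEFAULT_BOOT_SEED
    presso_n_sim: int = 1000
    outlier_alpha: float = 0.05
    strict: bool = False
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def paper_run_config(**overrides) -> RunConfig:
    """Config whose defaults reproduce the packaged pyroglutamine ->
    COVID-19 analysis end to end."""
    return RunConfig(**overrides)


@dataclass
class RunReport:
    """All tables produced by one pipeline run, plus the manifest."""

    instrument_table: pd.DataFrame
    harmonized_table: pd.DataFrame
    diagnostics_table: pd.DataFrame
    estimates_table: pd.DataFrame
    single_snp_table: pd.DataFrame
    leave_one_out_table: pd.DataFrame
    manifest: dict
    flags: list = field(default_factory=list)
    results: object = None  # the fitted MRResults, for programmatic use

    _TABLES = (
        "instrument_table",
        "harmonized_table",
        "diagnostics_table",
        "estimates_table",
        "single_snp_table",
        "leave_one_out_table",
    )

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        if self.flags:
            (out / "FLAGS.txt").write_text("\n".join(self.flags) + "\n")


def _load_input(spec: str, role: str):
    if spec.startswith("fixture:"):
        return load_fixture(spec.split(":", 1)[1])
    return read_summary_stats(spec, trait_label=role)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Stage order: input loading, instrument selection, strength report,
    harmonization, model fit (estimators + heterogeneity + pleiotropy
    tests), sensitivity tables, manifest.  A stage's hard error raises
    :class:`PipelineError` naming the stage.
    """
    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    exposure = stage("load_exposure", _load_input, config.exposure, "exposure")
    outcome = stage("load_outcome", _load_input, config.outcome, "outcome")

    criteria = InstrumentCriteria(
        pval_threshold=config.pval_threshold,
        ld_r2_max=config.ld_r2_max,
        exclusion_ids=frozenset(config.exclusion_ids),
    )
    if config.ld_table:
        ld = stage("load_ld", LDTable.from_file, config.ld_table)
    elif config.assume_independent:
        ld = LDTable.independent(exposure.snp_ids)
    else:
        ld = LDTable()
    instruments = stage("select_instruments", select_instruments, exposure, criteria, ld)
    strength = stage("strength_report", strength_report, instruments, config.r2_method)

    proxies = (
        stage("load_proxies", ProxyMap.from_file, config.proxy_map)
        if config.proxy_map
        else None
    )
    model = stage(
        "harmonize",
        MRModel.from_summary_stats,
        instruments,
        outcome,
        proxies=proxies,
        palindromic_policy=config.palindromic_policy,
        eaf_ambiguity_band=config.eaf_ambiguity_band,
    )
    results = stage(
        "fit",
        model.fit,
        se_method=config.se_method,
        ivw_model=config.ivw_model,
        n_boot=config.n_boot,
        seed=config.seed,
        presso_n_sim=config.presso_n_sim,
        outlier_alpha=config.outlier_alpha,
    )

    flags = []
    if results.any_pleiotropy_flag:
        flags.append("SIGNIFICANT PLEIOTROPY flagged by intercept and/or RSS test")
    for key, het in results.heterogeneity.items():
        if het.q_pval <= 0.05:
            flags.append(f"SIGNIFICANT HETEROGENEITY (Cochran Q, {key}, p = {het.q_pval:.3g})")
    if strength.weak_instruments:
        flags.append(f"WEAK INSTRUMENTS (F < 10): {strength.weak_instruments}")
    for flag in flags:
        logger.warning(flag)
    if config.strict and flags:
        raise PipelineError("diagnostics", "; ".join(flags))

    strength_df = strength.to_dataframe()
    exp_df = instruments.to_dataframe()
    instrument_table = exp_df.merge(strength_df.drop(columns=["N"]), on="SNP")

    report = RunReport(
        instrument_table=instrument_table,
        harmonized_table=model.data.to_dataframe(),
        diagnostics_table=results.diagnostics_frame(),
        estimates_table=results.estimates_frame(),
        single_snp_table=stage("single_snp", results.single_snp),
        leave_one_out_table=stage("leave_one_out", results.leave_one_out),
        manifest=_manifest(config, model),
        flags=flags,
        results=results,
    )
    if config.out_dir:
        stage("write_outputs", report.write, config.out_dir)
    return report


def _manifest(config: RunConfig, model: MRModel) -> dict:
    import numpy
    import scipy

    return {
        "tsmr_version": __version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "nsnp": model.nsnp,
        "dropped": model.data.dropped,
    }
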