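"""Config-driven orchestration: many exposures against one outcome.

The analysis shape mirrors the hypothesis-driven design this package
supports: a single disease outcome GWAS and a list of candidate exposure
GWAS, each run through harmonisation, instrument selection, the three
estimators and odds-ratio reporting, with Bonferroni bookkeeping across the
IVW tests actually performed (threshold α/m).

Everything is deterministic given the configuration (which embeds the
bootstrap seed): rerunning a config produces byte-identical output files.
An exposure that ends with fewer than three usable instruments is marked
``insufficient instruments`` and the run continues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import estimators as est
from . import instruments as inst
from .io import (
    ConfigError,
    HarmonizationResult,
    harmonize,
    read_summary_stats,
)

logger = logging.getLogger(__name__)

MIN_INSTRUMENTS = 3
STATUS_OK = "ok"
STATUS_INSUFFICIENT = "insufficient instruments"


@dataclass
class TableInput:
    """One summary-statistic table: path, label and optional column map."""

    path: str
    label: str
    column_map: dict[str, str] | None = None


@dataclass
class AnalysisConfig:
    """Full specification of one multi-exposure MR run."""

    outcome: TableInput
    exposures: list[TableInput]
    gwas_threshold: float = 5e-8
    f_threshold: float = 10.0
    confidence: float = 0.95
    palindromic_policy: str = "drop_ambiguous"
    frequency_window: float = 0.08
    ivw_model: str = "random"
    apply_steiger: bool = True
    n_boot: int = 10_000
    seed: int = 20_210_101
    alpha: float = 0.05
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.exposures:
            raise ConfigError("at least one exposure is required")
        labels = [e.label for e in self.exposures]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"exposure labels must be unique, got {labels}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, Mapping):
            raise ConfigError(f"config {path} is not a mapping")
        doc = dict(doc)
        try:
            outcome = TableInput(**doc.pop("outcome"))
            exposures = [TableInput(**e) for e in doc.pop("exposures")]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad outcome/exposures section in {path}: {exc}") from exc
        return cls(outcome=outcome, exposures=exposures, **doc)


@dataclass
class ExposureAnalysis:
    """Everything computed for one exposure: selection bookkeeping, the
    three estimates, pleiotropy and heterogeneity diagnostics."""

    label: str
    status: str
    harmonization: HarmonizationResult | None = None
    instrument_set: inst.InstrumentSet | None = None
    diagnostics: list[inst.InstrumentDiagnostics] = field(default_factory=list)
    ivw: est.MREstimate | None = None
    heterogeneity: est.HeterogeneityResult | None = None
    egger: est.EggerResult | None = None
    simple_median: est.MREstimate | None = None


@dataclass
class RunReport:
    """The assembled multi-exposure run, with multiple-testing bookkeeping
    (bonferroni_threshold = α / number of IVW tests performed)."""

    analyses: list[ExposureAnalysis]
    bonferroni_threshold: float
    significant_after_bonferroni: list[str]
    provenance: dict


def run_analysis(config: AnalysisConfig) -> RunReport:
    """Run every exposure against the outcome and assemble the report.

    Per exposure: harmonise → significance filter → Steiger filter →
    diagnostics → IVW + MR-Egger + simple median → odds-ratio transform.
    Writes report files under ``config.output_dir`` when set.
    """
    outcome = read_summary_stats(
        config.outcome.path, config.outcome.column_map, config.outcome.label
    )
    analyses: list[ExposureAnalysis] = []
    for entry in config.exposures:
        analyses.append(_analyse_exposure(entry, outcome, config))

    tested = [a for a in analyses if a.ivw is not None]
    m = len(tested)
    threshold = config.alpha / m if m else float("nan")
    significant = [a.label for a in tested if a.ivw.pvalue < threshold]
    report = RunReport(
        analyses=analyses,
        bonferroni_threshold=threshold,
        significant_after_bonferroni=significant,
        provenance={
            "package": "mrkit",
            "version": __version__,
            "seed": config.seed,
            "ivw_model": config.ivw_model,
            "gwas_threshold": config.gwas_threshold,
            "palindromic_policy": config.palindromic_policy,
            "alpha": config.alpha,
            "n_ivw_tests": m,
        },
    )
    if config.output_dir is not None:
        render_tables(report, config.output_dir)
    return report


def _analyse_exposure(
    entry: TableInput, outcome, config: AnalysisConfig
) -> ExposureAnalysis:
    exposure = read_summary_stats(entry.path, entry.column_map, entry.label)
    harmonized = harmonize(
        exposure,
        outcome,
        palindromic_policy=config.palindromic_policy,
        frequency_window=config.frequency_window,
    )
    iset = inst.build_instrument_set(
        harmonized.instruments,
        exposure_label=entry.label,
        outcome_label=config.outcome.label,
        gwas_threshold=config.gwas_threshold,
        apply_steiger=config.apply_steiger,
    )
    diagnostics = inst.diagnose(
        harmonized.instruments,
        f_threshold=config.f_threshold,
        gwas_threshold=config.gwas_threshold,
    )
    logger.info(
        "%s: %d harmonised, %d selected (%d failed significance, %d failed "
        "directionality), overall F %.1f",
        entry.label, len(harmonized), iset.n_selected,
        iset.n_rejected_significance, iset.n_rejected_steiger, iset.overall_f,
    )
    analysis = ExposureAnalysis(
        label=entry.label,
        status=STATUS_OK,
        harmonization=harmonized,
        instrument_set=iset,
        diagnostics=diagnostics,
    )
    if iset.n_selected < MIN_INSTRUMENTS:
        analysis.status = STATUS_INSUFFICIENT
        return analysis
    selected = iset.instruments
    analysis.ivw, analysis.heterogeneity = est.ivw(
        selected, model=config.ivw_model, confidence=config.confidence
    )
    analysis.egger = est.egger(
        selected, model=config.ivw_model, confidence=config.confidence
    )
    analysis.simple_median = est.simple_median(
        selected, n_boot=config.n_boot, seed=config.seed, confidence=config.confidence
    )
    return analysis


# ---------------------------------------------------------------------------
# publication-style rendering

def format_estimate(x: float) -> str:
    return f"{x:.4f}"


def format_p(p: float) -> str:
    """Scientific notation below 0.001, three decimals otherwise — the
    formatting convention of published MR results tables."""
    return f"{p:.2E}" if p < 1e-3 else f"{p:.3f}"


def _estimate_row(label: str, theta: float, se: float, pvalue: float,
                  or_point: float | None = None, ci_low: float | None = None,
                  ci_high: float | None = None) -> dict[str, str]:
    row = {
        "method": label,
        "ln_or": format_estimate(theta),
        "se": format_estimate(se),
        "pvalue": format_p(pvalue),
        "or": "" if or_point is None else f"{or_point:.2f}",
        "ci_low": "" if ci_low is None else f"{ci_low:.2f}",
        "ci_high": "" if ci_high is None else f"{ci_high:.2f}",
    }
    return row


def render_rows(analysis: ExposureAnalysis) -> list[dict[str, str]]:
    """Rows Simple median / IVW / MR-Egger / (intercept) for one exposure,
    or a single placeholder row when too few instruments survived."""
    if analysis.status != STATUS_OK:
        return [
            {
                "method": STATUS_INSUFFICIENT,
                "ln_or": "", "se": "", "pvalue": "",
                "or": "", "ci_low": "", "ci_high": "",
            }
        ]
    sm_, iv, eg = analysis.simple_median, analysis.ivw, analysis.egger
    return [
        _estimate_row("Simple median", sm_.theta, sm_.se, sm_.pvalue,
                      sm_.or_point, sm_.ci_low, sm_.ci_high),
        _estimate_row("IVW", iv.theta, iv.se, iv.pvalue,
                      iv.or_point, iv.ci_low, iv.ci_high),
        _estimate_row("MR-Egger", eg.slope.theta, eg.slope.se, eg.slope.pvalue,
                      eg.slope.or_point, eg.slope.ci_low, eg.slope.ci_high),
        _estimate_row("(intercept)", eg.intercept, eg.intercept_se,
                      eg.intercept_pvalue),
    ]


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in label)


def render_tables(report: RunReport, outdir: str | Path) -> dict[str, Path]:
    """Write per-exposure results (TSV + JSON, field-identical rows),
    scatter data, diagnostics, harmonisation logs, and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    columns = ["method", "ln_or", "se", "pvalue", "or", "ci_low", "ci_high"]
    for analysis in report.analyses:
        stem = _safe(analysis.label)
        rows = render_rows(analysis)
        tsv = outdir / f"{stem}_results.tsv"
        pd.DataFrame(rows, columns=columns).to_csv(tsv, sep="\t", index=False)
        written[f"{analysis.label}:results_tsv"] = tsv

        payload = {"exposure": analysis.label, "status": analysis.status, "rows": rows}
        if analysis.status == STATUS_OK:
            payload["raw"] = {
                "ivw": {"theta": analysis.ivw.theta, "se": analysis.ivw.se,
                        "pvalue": analysis.ivw.pvalue},
                "egger_intercept": {
                    "estimate": analysis.egger.intercept,
                    "se": analysis.egger.intercept_se,
                    "pvalue": analysis.egger.intercept_pvalue,
                },
                "heterogeneity": {
                    "q": analysis.heterogeneity.q_stat,
                    "df": analysis.heterogeneity.df,
                    "pvalue": analysis.heterogeneity.pvalue,
                },
                "overall_f": analysis.instrument_set.overall_f,
                "n_selected": analysis.instrument_set.n_selected,
            }
        js = outdir / f"{stem}_results.json"
        js.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written[f"{analysis.label}:results_json"] = js

        if analysis.instrument_set is not None and analysis.instrument_set.n_selected:
            scatter = pd.DataFrame(
                [
                    {
                        "variant_id": i.variant_id,
                        "beta_exposure": i.beta_exposure,
                        "beta_outcome": i.beta_outcome,
                        "se_outcome": i.se_outcome,
                    }
                    for i in analysis.instrument_set
                ]
            )
            sp = outdir / f"{stem}_scatter.tsv"
            scatter.to_csv(sp, sep="\t", index=False)
            written[f"{analysis.label}:scatter"] = sp
        if analysis.diagnostics:
            dp = outdir / f"{stem}_diagnostics.tsv"
            inst.diagnostics_frame(analysis.diagnostics).to_csv(dp, sep="\t", index=False)
            written[f"{analysis.label}:diagnostics"] = dp
        if analysis.harmonization is not None:
            written[f"{analysis.label}:harmonization_log"] = (
                analysis.harmonization.write_log(outdir / f"{stem}_harmonization_log.tsv")
            )

    manifest = {
        "provenance": report.provenance,
        "bonferroni_threshold": report.bonferroni_threshold,
        "significant_after_bonferroni": sorted(report.significant_after_bonferroni),
        "analyses": {
            a.label: {
                "status": a.status,
                "n_selected": 0 if a.instrument_set is None else a.instrument_set.n_selected,
            }
            for a in report.analyses
        },
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = mp
    return written
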