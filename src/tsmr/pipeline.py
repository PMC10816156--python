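"""End-to-end orchestration: select -> harmonize -> estimate -> sensitivity.

The pipeline is a pure function of (input files, configuration, seed):
re-running with the same inputs produces byte-identical reports.  Output
is a JSON report mirroring the usual TSMR reporting layout plus
tab-delimited tables (estimates, instruments, sensitivity, plot data).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import PipelineError
from .gwas_io import HarmonizedDataset, harmonize, read_summary_stats
from .selection import (
    LDMatrix,
    SelectionParams,
    instrument_strength,
    read_confounder_table,
    select_instruments,
)
from .estimators import ModeSettings, run_all_methods, wald_ratio
from .sensitivity import sensitivity_report

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def to_odds_ratio(beta_hat: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: OR and 95% CI exp(beta -/+ 1.96 se)."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    return (
        float(np.exp(beta_hat)),
        float(np.exp(beta_hat - 1.96 * se)),
        float(np.exp(beta_hat + 1.96 * se)),
    )


@dataclass
class RunConfig:
    """Serializable configuration for one pipeline run."""

    exposure_path: str
    outcome_path: str
    ld_path: str
    confounder_path: str | None = None
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    selection: SelectionParams = field(default_factory=SelectionParams)
    mode_settings: ModeSettings = field(default_factory=ModeSettings)
    presso_n_sim: int = 1000
    presso_threshold: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    out_dir: str | None = None
    ld_format: str = "long"  # "long" triples or "square" matrix

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selection"] = self.selection.to_dict()
        d["mode_settings"] = asdict(self.mode_settings)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("selection"), dict):
            d["selection"] = SelectionParams.from_dict(d["selection"])
        if isinstance(d.get("mode_settings"), dict):
            d["mode_settings"] = ModeSettings(**d["mode_settings"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def analysis_dict(self) -> dict:
        """Config fields that determine the analysis (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.analysis_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Everything one pipeline run produced, serializable to JSON."""

    exposure_label: str
    outcome_label: str
    instruments: pd.DataFrame          # per-SNP gamma/Gamma/F/ratio table
    estimates: list                    # five MREstimate in reporting order
    sensitivity: object                # SensitivityReport
    audit: object                      # SelectionAudit
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "exposure": self.exposure_label,
            "outcome": self.outcome_label,
            "instruments": self.instruments.to_dict(orient="records"),
            "estimates": [e.to_dict() for e in self.estimates],
            "sensitivity": self.sensitivity.to_dict(),
            "selection_audit": self.audit.to_dict(),
            "metadata": self.metadata,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)


def _instrument_table(dataset: HarmonizedDataset, selected: pd.DataFrame) -> pd.DataFrame:
    strengths = instrument_strength(selected).set_index("snp")
    rows = []
    for i, snp in enumerate(dataset.snp):
        ratio = wald_ratio(dataset.gamma[i], dataset.se_gamma[i],
                           dataset.Gamma[i], dataset.se_Gamma[i], snp=str(snp))
        rows.append({
            "snp": str(snp),
            "gamma": float(dataset.gamma[i]),
            "se_gamma": float(dataset.se_gamma[i]),
            "Gamma": float(dataset.Gamma[i]),
            "se_Gamma": float(dataset.se_Gamma[i]),
            "f_stat": float(strengths.loc[snp, "f_stat"]),
            "ratio_beta": ratio.beta,
            "ratio_se": ratio.se,
            "sign_flipped": bool(dataset.sign_flipped[i]),
            "strand_complemented": bool(dataset.strand_complemented[i]),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> AnalysisReport:
    """Execute the full analysis described by ``config``.

    Stage order: read inputs, five-stage instrument selection, allele
    harmonization against the outcome, the five MR estimators, the
    sensitivity suite.  Raises :class:`PipelineError` naming the failing
    stage; an empty instrument set is an explicit diagnostic, not a
    partial report.
    """
    try:
        exposure = read_summary_stats(config.exposure_path)
        outcome = read_summary_stats(config.outcome_path)
        if config.ld_format == "long":
            ld = LDMatrix.from_long_tsv(config.ld_path)
        else:
            ld = LDMatrix.from_square_tsv(config.ld_path)
        confounders = (
            read_confounder_table(config.confounder_path)
            if config.confounder_path else None
        )
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    try:
        selected, audit = select_instruments(exposure, ld, confounders, config.selection)
    except Exception as exc:
        raise PipelineError("selection", str(exc)) from exc
    if len(selected) == 0:
        raise PipelineError(
            "selection",
            f"no instruments survive screening (stage counts: {audit.counts})",
        )

    try:
        dataset = harmonize(selected, outcome)
    except Exception as exc:
        raise PipelineError("harmonization", str(exc)) from exc
    if dataset.n_snps == 0:
        raise PipelineError("harmonization", "no instruments survive harmonization")

    try:
        estimates = run_all_methods(
            dataset, settings=config.mode_settings, seed=config.seed,
            n_boot=config.n_boot,
        )
    except Exception as exc:
        raise PipelineError("estimation", str(exc)) from exc

    try:
        sens = sensitivity_report(
            dataset, n_sim=config.presso_n_sim,
            signif_threshold=config.presso_threshold, seed=config.seed,
        )
    except Exception as exc:
        raise PipelineError("sensitivity", str(exc)) from exc

    selected_in_dataset = selected[selected["snp"].isin(set(map(str, dataset.snp)))]
    report = AnalysisReport(
        exposure_label=config.exposure_label,
        outcome_label=config.outcome_label,
        instruments=_instrument_table(dataset, selected_in_dataset),
        estimates=estimates,
        sensitivity=sens,
        audit=audit,
        metadata={
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.analysis_dict(),
            "harmonization_dropped": [list(t) for t in dataset.dropped],
        },
    )
    logger.info("pipeline: %d instruments, stage counts %s",
                dataset.n_snps, audit.counts)

    if write_outputs and config.out_dir:
        write_report(report, config.out_dir)
    return report


def write_report(report: AnalysisReport, out_dir) -> dict[str, str]:
    """Write report.json plus the tab-delimited tables and plot data."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"report": out / "report.json"}
    paths["report"].write_text(report.to_json())

    est = pd.DataFrame([e.to_dict() for e in report.estimates])
    est = est.rename(columns={"or_": "odds_ratio"})
    paths["estimates"] = out / "estimates.tsv"
    est.to_csv(paths["estimates"], sep="\t", index=False)

    paths["instruments"] = out / "instruments.tsv"
    report.instruments.to_csv(paths["instruments"], sep="\t", index=False)

    sens_rows = []
    for h in report.sensitivity.heterogeneity:
        sens_rows.append(("cochran_q", h.method, h.q, h.pvalue))
    if report.sensitivity.intercept_test is not None:
        it = report.sensitivity.intercept_test
        sens_rows.append(("egger_intercept", "MR Egger", it.alpha, it.pvalue))
    if report.sensitivity.presso is not None:
        pr = report.sensitivity.presso
        sens_rows.append(("presso_global", f"outliers={len(pr.outliers)}",
                          pr.rss_obs, pr.global_p))
    paths["sensitivity"] = out / "sensitivity.tsv"
    pd.DataFrame(sens_rows, columns=["test", "detail", "statistic", "pvalue"]).to_csv(
        paths["sensitivity"], sep="\t", index=False
    )

    plot_dir = out / "plotdata"
    plot_dir.mkdir(exist_ok=True)
    for name, table in make_plot_data(report).items():
        paths[f"plotdata/{name}"] = plot_dir / f"{name}.tsv"
        table.to_csv(paths[f"plotdata/{name}"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def make_plot_data(report: AnalysisReport) -> dict[str, pd.DataFrame]:
    """Plot-ready tables: scatter, per-SNP forest, leave-one-out, method forest.

    ``scatter`` carries the per-SNP effects and SEs plus one fitted line per
    method (slope, intercept); ``forest_snp`` the Wald ratios with 95% CIs
    and the pooled IVW row; ``leave_one_out`` the re-estimates; and
    ``forest_methods`` one pooled row per method.
    """
    inst = report.instruments
    scatter = inst[["snp", "gamma", "se_gamma", "Gamma", "se_Gamma"]].copy()

    lines = []
    for e in report.estimates:
        intercept = 0.0
        if e.method == "MR Egger" and report.sensitivity.intercept_test is not None:
            intercept = report.sensitivity.intercept_test.alpha
        lines.append((e.method, e.beta_hat, intercept))
    fitted = pd.DataFrame(lines, columns=["method", "slope", "intercept"])

    forest_rows = [
        (str(r["snp"]), r["ratio_beta"], r["ratio_se"],
         r["ratio_beta"] - 1.96 * r["ratio_se"], r["ratio_beta"] + 1.96 * r["ratio_se"])
        for _, r in inst.iterrows()
    ]
    for e in report.estimates:
        if e.method == "IVW":
            forest_rows.append(("All - IVW", e.beta_hat, e.se,
                                e.beta_hat - 1.96 * e.se, e.beta_hat + 1.96 * e.se))
    forest_snp = pd.DataFrame(
        forest_rows, columns=["label", "beta", "se", "ci_low", "ci_high"]
    )

    method_rows = [
        (e.method, e.n_snp, e.beta_hat, e.se, e.pvalue, e.or_, e.ci_low, e.ci_high)
        for e in report.estimates
    ]
    forest_methods = pd.DataFrame(
        method_rows,
        columns=["method", "n_snp", "beta", "se", "pvalue", "odds_ratio",
                 "or_ci_low", "or_ci_high"],
    )

    out = {
        "scatter": scatter,
        "fitted_lines": fitted,
        "forest_snp": forest_snp,
        "forest_methods": forest_methods,
    }
    if report.sensitivity.leave_one_out is not None:
        out["leave_one_out"] = report.sensitivity.leave_one_out
    return out
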