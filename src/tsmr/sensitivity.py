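"""Sensitivity analyses for two-sample MR.

Covers heterogeneity (Cochran's Q under the IVW and Egger fits), the
Monte-Carlo residual-sum-of-squares pleiotropy framework (global test,
per-SNP outlier test with Bonferroni correction, and distortion test),
leave-one-out re-estimation, and the Egger-intercept test of directional
pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateCorrectionError, InsufficientInstrumentsError
from .gwas_io import HarmonizedDataset
from .estimators import EggerEstimator, EggerResult, IVWEstimator


@dataclass
class HeterogeneityResult:
    """Cochran's Q for one fit (IVW: df = J-1; Egger: df = J-2)."""

    method: str
    q: float
    df: int
    pvalue: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PressoResult:
    """Global, outlier, and distortion tests of the RSS pleiotropy framework."""

    rss_obs: float
    global_p: float
    n_sim: int
    outlier_pvalues: dict[str, float]  # Bonferroni-adjusted, per SNP
    outliers: list[str]
    beta_raw: float
    beta_corrected: float | None = None
    distortion_p: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class InterceptTest:
    """Egger-intercept test of average directional pleiotropy."""

    alpha: float
    se: float
    pvalue: float
    verdict: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SensitivityReport:
    """Bundle of all sensitivity results for one analysis."""

    heterogeneity: list[HeterogeneityResult]
    intercept_test: InterceptTest | None
    presso: PressoResult | None
    leave_one_out: pd.DataFrame | None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "heterogeneity": [h.to_dict() for h in self.heterogeneity],
            "intercept_test": self.intercept_test.to_dict() if self.intercept_test else None,
            "presso": self.presso.to_dict() if self.presso else None,
            "leave_one_out": (
                self.leave_one_out.to_dict(orient="records")
                if self.leave_one_out is not None else None
            ),
            "notes": self.notes,
        }


def cochran_q(dataset: HarmonizedDataset, method: str = "IVW") -> HeterogeneityResult:
    """Weighted heterogeneity statistic about the IVW or Egger fit.

    IVW: Q = sum(w_j (Gamma_j - beta_hat gamma_j)^2), df = J - 1.
    Egger: weighted residual sum about the two-parameter fit, df = J - 2.
    The p-value is the upper chi-square tail.
    """
    j = dataset.n_snps
    if method.upper() == "IVW":
        if j < 2:
            raise InsufficientInstrumentsError("IVW Q needs at least 2 SNPs")
        est = IVWEstimator().fit_dataset(dataset)
        q, df = est.q_statistic_, est.q_df_
        label = "IVW"
    elif method.upper() in ("EGGER", "MR EGGER"):
        if j < 3:
            raise InsufficientInstrumentsError("Egger Q needs at least 3 SNPs")
        est = EggerEstimator().fit_dataset(dataset)
        q, df = est.q_statistic_, est.q_df_
        label = "MR Egger"
    else:
        raise ValueError(f"unknown heterogeneity method {method!r}")
    return HeterogeneityResult(
        method=label, q=float(q), df=int(df), pvalue=float(stats.chi2.sf(q, df))
    )


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes via running totals."""
    sxy = np.sum(w * x * y)
    sxx = np.sum(w * x * x)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    dataset: HarmonizedDataset,
    n_sim: int = 1000,
    signif_threshold: float = 0.05,
    seed: int | None = None,
    n_distortion: int = 1000,
) -> PressoResult:
    """Monte-Carlo residual-sum-of-squares test for horizontal pleiotropy.

    The observed statistic is RSS = sum_j w_j (Gamma_j - beta_{-j} gamma_j)^2
    with beta_{-j} the leave-one-out IVW slope and w_j = se_Gamma_j^-2.  Each
    of ``n_sim`` replicates redraws gamma*_j ~ N(gamma_j, se_gamma_j) and
    Gamma*_j ~ N(beta_{-j} gamma_j, se_Gamma_j) and recomputes the statistic;
    the global p-value is the add-one Monte-Carlo tail
    (1 + #{RSS* >= RSS_obs}) / (n_sim + 1).

    Per-SNP outlier p-values compare each SNP's observed weighted residual to
    its own simulated distribution (add-one), Bonferroni-adjusted across the
    J SNPs; adjusted p < ``signif_threshold`` flags an outlier.  When outliers
    exist, the IVW slope is recomputed without them (``beta_corrected``) and a
    distortion test compares the raw-vs-corrected shift against slopes from
    ``n_distortion`` random subsets of the same size.
    """
    j = dataset.n_snps
    if j < 4:
        raise InsufficientInstrumentsError("the outlier test needs at least 4 SNPs")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")

    x, y = dataset.gamma, dataset.Gamma
    sx, sy = dataset.se_gamma, dataset.se_Gamma
    w = sy ** -2.0

    beta_loo = _loo_slopes(x, y, w)
    res_obs = w * (y - beta_loo * x) ** 2
    rss_obs = float(np.sum(res_obs))

    rng = np.random.default_rng(seed)
    x_star = rng.normal(x, sx, size=(n_sim, j))
    y_star = rng.normal(beta_loo * x, sy, size=(n_sim, j))
    res_star = w * (y_star - beta_loo * x_star) ** 2
    rss_star = res_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))

    p_raw = (1 + np.sum(res_star >= res_obs[None, :], axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, j * p_raw)
    outlier_pvalues = {str(s): float(p) for s, p in zip(dataset.snp, p_adj)}
    out_mask = p_adj < signif_threshold
    outliers = [str(s) for s in dataset.snp[out_mask]]

    beta_raw = float(IVWEstimator().fit_dataset(dataset).beta_)
    beta_corrected = None
    distortion_p = None
    if outliers:
        if out_mask.all():
            raise DegenerateCorrectionError("every instrument was flagged as an outlier")
        kept = dataset.subset(~out_mask)
        beta_corrected = float(IVWEstimator().fit_dataset(kept).beta_)
        k = int((~out_mask).sum())
        d_obs = abs(beta_raw - beta_corrected)
        d_sub = np.empty(n_distortion)
        idx_all = np.arange(j)
        for s in range(n_distortion):
            sub = rng.choice(idx_all, size=k, replace=False)
            ws, xs, ys = w[sub], x[sub], y[sub]
            d_sub[s] = beta_raw - np.sum(ws * xs * ys) / np.sum(ws * xs * xs)
        distortion_p = float((1 + np.sum(np.abs(d_sub) >= d_obs)) / (n_distortion + 1))

    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        outlier_pvalues=outlier_pvalues,
        outliers=outliers,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
        distortion_p=distortion_p,
    )


def leave_one_out(dataset: HarmonizedDataset) -> pd.DataFrame:
    """IVW re-estimates excluding each SNP in turn.

    Returns one row per excluded SNP with columns
    ``snp, beta, se, pvalue, or_, ci_low, ci_high``.
    """
    j = dataset.n_snps
    if j < 3:
        raise InsufficientInstrumentsError("leave-one-out needs at least 3 SNPs")
    rows = []
    for i in range(j):
        mask = np.ones(j, dtype=bool)
        mask[i] = False
        est = IVWEstimator().fit_dataset(dataset.subset(mask))
        rows.append(
            (str(dataset.snp[i]), est.beta_, est.se_, est.pvalue_,
             est.odds_ratio_, est.ci_low_, est.ci_high_)
        )
    return pd.DataFrame(
        rows, columns=["snp", "beta", "se", "pvalue", "or_", "ci_low", "ci_high"]
    )


def egger_intercept_test(egger_result: EggerResult, alpha_level: float = 0.05) -> InterceptTest:
    """Summarize the Egger intercept as a directional-pleiotropy test.

    The verdict is "no directional pleiotropy" when the intercept p-value is
    at or above ``alpha_level``; otherwise "directional pleiotropy".
    """
    p = egger_result.intercept_pvalue
    verdict = "no directional pleiotropy" if p >= alpha_level else "directional pleiotropy"
    return InterceptTest(
        alpha=egger_result.intercept,
        se=egger_result.intercept_se,
        pvalue=p,
        verdict=verdict,
    )


def sensitivity_report(
    dataset: HarmonizedDataset,
    n_sim: int = 1000,
    signif_threshold: float = 0.05,
    seed: int | None = None,
) -> SensitivityReport:
    """Run the full sensitivity suite, skipping tests the arity cannot support."""
    notes: list[str] = []
    het: list[HeterogeneityResult] = []
    j = dataset.n_snps

    if j >= 2:
        het.append(cochran_q(dataset, "IVW"))
    else:
        notes.append("heterogeneity skipped: fewer than 2 SNPs")
    if j >= 3:
        het.append(cochran_q(dataset, "Egger"))
        intercept = egger_intercept_test(EggerEstimator().fit_dataset(dataset).result_())
        loo = leave_one_out(dataset)
    else:
        intercept = None
        loo = None
        notes.append("Egger intercept and leave-one-out skipped: fewer than 3 SNPs")
    if j >= 4:
        presso = mr_presso(dataset, n_sim=n_sim, signif_threshold=signif_threshold, seed=seed)
    else:
        presso = None
        notes.append("outlier test skipped: fewer than 4 SNPs")

    return SensitivityReport(
        heterogeneity=het,
        intercept_test=intercept,
        presso=presso,
        leave_one_out=loo,
        notes=notes,
    )
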