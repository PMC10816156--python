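"""Causal-effect estimators for two-sample MR, in scikit-learn style.

Each estimator fits the per-SNP model ``Gamma_j ~ beta * gamma_j`` where
``gamma_j`` is the SNP-exposure effect and ``Gamma_j`` the SNP-outcome
effect, weighting by the inverse outcome variance.  The API follows the
scikit-learn estimator contract: keyword-only constructor parameters,
``fit(X, y, ...)`` with per-SNP effects, fitted attributes with a trailing
underscore (``beta_``, ``se_``, ``pvalue_``, ...), ``predict`` of the
fitted line, and ``get_params``/``set_params`` so instances compose with
scikit-learn tooling.

Estimators:

* :class:`IVWEstimator` — inverse-variance-weighted regression through the
  origin, with Cochran's Q and an automatic multiplicative random-effects
  standard error when heterogeneity is detected (Q p < 0.05).
* :class:`EggerEstimator` — weighted regression with a free intercept; the
  intercept estimates average directional pleiotropy.
* :class:`WeightedMedianEstimator` — weighted median of per-SNP Wald
  ratios, consistent when valid instruments carry > 50% of the weight.
* :class:`ModeEstimator` — kernel-smoothed mode of the Wald ratios
  (weighted or simple), consistent under the ZEMPA assumption.

All point estimates live on the log-odds scale; odds ratios and 95% CIs
are attached at reporting time.
"""

from __future__ import annotations

import inspect
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError
from .gwas_io import HarmonizedDataset

logger = logging.getLogger(__name__)

#: Reporting order for the five methods.
METHOD_ORDER = ("IVW", "Weighted median", "Weighted mode", "Simple mode", "MR Egger")


@dataclass
class RatioEstimate:
    """Single-SNP Wald ratio beta_j = Gamma_j / gamma_j with first-order SE."""

    snp: str
    beta: float
    se: float


@dataclass
class MREstimate:
    """One method's pooled causal estimate on the log-odds scale."""

    method: str
    beta_hat: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    n_snp: int
    model_variant: str | None = None  # "fixed" | "random" (IVW only)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EggerResult:
    """MR-Egger slope plus the pleiotropy intercept and its test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope.to_dict(),
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_pvalue": self.intercept_pvalue,
        }


@dataclass
class ModeSettings:
    """Bandwidth and bootstrap configuration for the mode-based estimators."""

    phi: float = 1.0
    n_boot: int = 1000
    kernel: str = "normal"

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.n_boot < 1:
            raise ValueError("n_boot must be at least 1")
        if self.kernel != "normal":
            raise ValueError("only the normal kernel is supported")


def wald_ratio(gamma_j: float, sigma_gamma_j: float, Gamma_j: float,
               sigma_Gamma_j: float, snp: str = "") -> RatioEstimate:
    """Per-SNP ratio estimate Gamma_j / gamma_j, SE by first-order delta method."""
    if gamma_j == 0:
        raise ZeroDivisionError("Wald ratio undefined for gamma_j = 0")
    return RatioEstimate(snp=snp, beta=Gamma_j / gamma_j, se=sigma_Gamma_j / abs(gamma_j))


def _to_1d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("X must be a 1-d array of per-SNP exposure effects")
    return X


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _ci(beta: float, se: float) -> tuple[float, float, float]:
    return (
        float(np.exp(beta)),
        float(np.exp(beta - 1.96 * se)),
        float(np.exp(beta + 1.96 * se)),
    )


class BaseMREstimator:
    """Minimal scikit-learn-compatible base (get/set_params, repr)."""

    method_name: str = ""

    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [p for p in sig.parameters if p != "self"]

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params) -> "BaseMREstimator":
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"invalid parameter {key!r} for {type(self).__name__}")
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"

    # -- shared fitting plumbing -------------------------------------------

    def _validate(self, X, y, se_exposure, se_outcome, min_snps: int):
        x = _to_1d(X)
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise ValueError("X and y must have the same length")
        j = len(x)
        if j < min_snps:
            raise InsufficientInstrumentsError(
                f"{type(self).__name__} needs at least {min_snps} SNPs, got {j}"
            )
        if se_outcome is None:
            sy = np.ones(j)
        else:
            sy = np.asarray(se_outcome, dtype=float)
            if sy.shape != x.shape or np.any(sy <= 0):
                raise ValueError("se_outcome must be positive and match X")
        if se_exposure is None:
            sx = np.zeros(j)
        else:
            sx = np.asarray(se_exposure, dtype=float)
            if sx.shape != x.shape or np.any(sx < 0):
                raise ValueError("se_exposure must be non-negative and match X")
        return x, y, sx, sy

    def fit_dataset(self, dataset: HarmonizedDataset) -> "BaseMREstimator":
        """Fit from a :class:`HarmonizedDataset` instead of raw arrays."""
        return self.fit(
            dataset.gamma,
            dataset.Gamma,
            se_exposure=dataset.se_gamma,
            se_outcome=dataset.se_Gamma,
        )

    def predict(self, X) -> np.ndarray:
        """Fitted outcome effects for exposure effects ``X``."""
        x = _to_1d(X)
        intercept = getattr(self, "intercept_", 0.0)
        return intercept + self.beta_ * x

    def _finalize(self) -> None:
        self.odds_ratio_, self.ci_low_, self.ci_high_ = _ci(self.beta_, self.se_)

    def to_estimate(self) -> MREstimate:
        """Package the fitted attributes as an :class:`MREstimate`."""
        return MREstimate(
            method=self.method_name,
            beta_hat=float(self.beta_),
            se=float(self.se_),
            pvalue=float(self.pvalue_),
            or_=self.odds_ratio_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            n_snp=int(self.n_snp_),
            model_variant=getattr(self, "model_variant_", None),
        )


class IVWEstimator(BaseMREstimator):
    """Inverse-variance-weighted MR: WLS of Gamma on gamma through the origin.

    With weights w_j = se_Gamma_j^-2:

        beta_hat = sum(w gamma Gamma) / sum(w gamma^2)
        SE_fixed = sum(w gamma^2)^-1/2
        Q        = sum(w (Gamma - beta_hat * gamma)^2)  ~  chi2(J - 1)

    If the Q test rejects homogeneity at ``q_alpha`` the standard error is
    inflated multiplicatively to SE_fixed * sqrt(Q / (J - 1)) (never below
    the fixed-effects SE); otherwise the fixed-effects SE is reported.
    P-values are two-sided normal.
    """

    method_name = "IVW"

    def __init__(self, q_alpha: float = 0.05):
        self.q_alpha = q_alpha

    def fit(self, X, y, se_exposure=None, se_outcome=None) -> "IVWEstimator":
        x, y, _, sy = self._validate(X, y, se_exposure, se_outcome, min_snps=1)
        j = len(x)
        w = sy ** -2.0
        sxx = float(np.sum(w * x * x))
        if sxx == 0:
            raise ValueError("all exposure effects are zero; slope undefined")
        self.beta_ = float(np.sum(w * x * y) / sxx)
        se_fixed = sxx ** -0.5
        self.se_fixed_ = float(se_fixed)
        self.n_snp_ = j

        if j >= 2:
            resid = y - self.beta_ * x
            self.q_statistic_ = float(np.sum(w * resid * resid))
            self.q_df_ = j - 1
            self.q_pvalue_ = float(stats.chi2.sf(self.q_statistic_, self.q_df_))
            if self.q_pvalue_ < self.q_alpha:
                self.model_variant_ = "random"
                self.se_ = float(se_fixed * max(1.0, np.sqrt(self.q_statistic_ / self.q_df_)))
            else:
                self.model_variant_ = "fixed"
                self.se_ = float(se_fixed)
        else:
            # single instrument: reduces to the Wald ratio, Q undefined
            self.q_statistic_ = float("nan")
            self.q_df_ = 0
            self.q_pvalue_ = float("nan")
            self.model_variant_ = "fixed"
            self.se_ = float(se_fixed)

        self.pvalue_ = _normal_p(self.beta_ / self.se_)
        self._finalize()
        return self


class EggerEstimator(BaseMREstimator):
    """MR-Egger: weighted regression of Gamma on gamma with a free intercept.

    SNPs are first oriented so every gamma_j >= 0 (negating gamma_j and
    Gamma_j jointly), which makes the intercept identifiable as average
    directional pleiotropy under InSIDE.  Standard errors are scaled by
    max(1, sqrt(Q_E / (J - 2))) where Q_E is the weighted residual sum of
    squares; inference uses the t distribution with J - 2 df.
    """

    method_name = "MR Egger"

    def __init__(self, min_snps: int = 3):
        self.min_snps = min_snps

    def fit(self, X, y, se_exposure=None, se_outcome=None) -> "EggerEstimator":
        x, y, _, sy = self._validate(X, y, se_exposure, se_outcome,
                                     min_snps=max(3, self.min_snps))
        j = len(x)
        sign = np.where(x < 0, -1.0, 1.0)
        xo = sign * x
        yo = sign * y
        w = sy ** -2.0

        sw = float(np.sum(w))
        swx = float(np.sum(w * xo))
        swxx = float(np.sum(w * xo * xo))
        swy = float(np.sum(w * yo))
        swxy = float(np.sum(w * xo * yo))
        det = sw * swxx - swx * swx
        if det <= 0:
            raise ValueError("degenerate design: exposure effects have no spread")

        slope = (sw * swxy - swx * swy) / det
        intercept = (swxx * swy - swx * swxy) / det
        resid = yo - intercept - slope * xo
        q_e = float(np.sum(w * resid * resid))
        scale = max(1.0, np.sqrt(q_e / (j - 2)))
        se_slope = scale * np.sqrt(sw / det)
        se_intercept = scale * np.sqrt(swxx / det)

        self.beta_ = float(slope)
        self.se_ = float(se_slope)
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_intercept)
        self.q_statistic_ = q_e
        self.q_df_ = j - 2
        self.scale_ = float(scale)
        self.n_snp_ = j
        self.pvalue_ = float(2.0 * stats.t.sf(abs(slope / se_slope), j - 2))
        self.intercept_pvalue_ = float(
            2.0 * stats.t.sf(abs(intercept / se_intercept), j - 2)
        )
        self._finalize()
        return self

    def result_(self) -> EggerResult:
        return EggerResult(
            slope=self.to_estimate(),
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            intercept_pvalue=self.intercept_pvalue_,
        )


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratios ``b`` with weights ``w``.

    Ratios are sorted ascending; with normalized weights w', the cumulative
    midpoints s_j = sum_{k<=j} w'_k - w'_j / 2 bracket the 0.5 quantile,
    which is found by linear interpolation of (s_j, b_(j)).
    """
    order = np.argsort(b, kind="stable")
    bs = b[order]
    ws = w[order] / np.sum(w)
    s = np.cumsum(ws) - 0.5 * ws
    return float(np.interp(0.5, s, bs))


def _weighted_median_rows(b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (B, J) bootstrap arrays."""
    order = np.argsort(b, axis=1, kind="stable")
    bs = np.take_along_axis(b, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    ws = ws / ws.sum(axis=1, keepdims=True)
    s = np.cumsum(ws, axis=1) - 0.5 * ws
    out = np.empty(b.shape[0])
    for i in range(b.shape[0]):
        out[i] = np.interp(0.5, s[i], bs[i])
    return out


class WeightedMedianEstimator(BaseMREstimator):
    """Weighted median of per-SNP Wald ratios.

    Consistent as long as valid instruments contribute more than half of
    the total inverse-variance weight.  The standard error comes from a
    parametric bootstrap: per replicate, gamma_j and Gamma_j are resampled
    from Normal(gamma_j, se_gamma_j) and Normal(Gamma_j, se_Gamma_j), the
    median recomputed, and the SE taken as the standard deviation of the
    replicate estimates.
    """

    method_name = "Weighted median"

    def __init__(self, n_boot: int = 1000, seed: int | None = None):
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y, se_exposure=None, se_outcome=None) -> "WeightedMedianEstimator":
        x, y, sx, sy = self._validate(X, y, se_exposure, se_outcome, min_snps=3)
        if np.any(x == 0):
            raise ZeroDivisionError("Wald ratio undefined for gamma_j = 0")
        b = y / x
        se_b = sy / np.abs(x)
        w = se_b ** -2.0
        self.beta_ = _weighted_median(b, w)
        self.n_snp_ = len(x)

        rng = np.random.default_rng(self.seed)
        xb = rng.normal(x, sx, size=(self.n_boot, len(x)))
        yb = rng.normal(y, sy, size=(self.n_boot, len(x)))
        xb = np.where(xb == 0, np.finfo(float).tiny, xb)
        bb = yb / xb
        wb = (sy / np.abs(xb)) ** -2.0
        boots = _weighted_median_rows(bb, wb)
        self.boot_estimates_ = boots
        self.se_ = float(np.std(boots, ddof=1))
        if self.se_ == 0:
            self.se_ = float(np.finfo(float).tiny)
        self.pvalue_ = _normal_p(self.beta_ / self.se_)
        self._finalize()
        return self


def _mode_bandwidth(b: np.ndarray, phi: float) -> float:
    """Modified Silverman bandwidth: phi * 0.9 * min(sd, 1.4826 mad) * J^(-1/5)."""
    j = len(b)
    sd = float(np.std(b, ddof=1))
    mad = float(np.median(np.abs(b - np.median(b))))
    candidates = [v for v in (sd, 1.4826 * mad) if v > 0]
    if not candidates:
        return 0.0
    return phi * 0.9 * min(candidates) * j ** (-1.0 / 5.0)


def _mode_point(b: np.ndarray, w: np.ndarray, phi: float, grid_size: int = 512) -> float:
    """Argmax of the normal-kernel weighted density of the ratios on a grid."""
    h = _mode_bandwidth(b, phi)
    if h == 0.0:
        # all ratios identical (or no dispersion): the mode is that value
        return float(np.median(b))
    grid = np.linspace(b.min() - h, b.max() + h, grid_size)
    z = (grid[:, None] - b[None, :]) / h
    dens = np.exp(-0.5 * z * z) @ (w / np.sum(w))
    return float(grid[int(np.argmax(dens))])


def _mode_point_rows(bb: np.ndarray, wb: np.ndarray, phi: float,
                     grid_size: int = 512, chunk: int = 128) -> np.ndarray:
    """Row-wise kernel-mode for (B, J) bootstrap arrays, chunked for memory.

    The density is accumulated in float32 — the argmax over a 512-point grid
    is insensitive to that precision, and the bootstrap replicates only feed
    a standard deviation.
    """
    n, j = bb.shape
    sd = np.std(bb, axis=1, ddof=1)
    med = np.median(bb, axis=1)
    mad = np.median(np.abs(bb - med[:, None]), axis=1)
    robust = 1.4826 * mad
    cand = np.where(robust > 0, np.minimum(sd, robust), sd)
    h = phi * 0.9 * cand * j ** (-1.0 / 5.0)
    out = np.empty(n)
    degenerate = h <= 0
    out[degenerate] = med[degenerate]
    idx = np.nonzero(~degenerate)[0]
    for start in range(0, len(idx), chunk):
        rows = idx[start:start + chunk]
        b = bb[rows]
        w = (wb[rows] / wb[rows].sum(axis=1, keepdims=True)).astype(np.float32)
        hh = h[rows][:, None, None].astype(np.float32)
        lo = (b.min(axis=1) - h[rows])[:, None]
        hi = (b.max(axis=1) + h[rows])[:, None]
        grid = lo + (hi - lo) * np.linspace(0, 1, grid_size)[None, :]
        z = (grid[:, :, None].astype(np.float32) - b[:, None, :].astype(np.float32)) / hh
        dens = np.einsum("bgj,bj->bg", np.exp(-0.5 * z * z), w)
        out[rows] = np.take_along_axis(
            grid, np.argmax(dens, axis=1)[:, None], axis=1
        )[:, 0]
    return out


class ModeEstimator(BaseMREstimator):
    """Mode-based estimate: kernel-density mode of the per-SNP Wald ratios.

    ``weighted=True`` weights each ratio by its inverse variance
    (weighted mode); ``weighted=False`` weights equally (simple mode).
    The density is evaluated on a fixed 512-point grid spanning
    [min(b) - h, max(b) + h] so the argmax is platform-deterministic.
    SE by the same parametric bootstrap as the weighted median.
    """

    def __init__(self, weighted: bool = True, phi: float = 1.0,
                 n_boot: int = 1000, seed: int | None = None,
                 grid_size: int = 512):
        self.weighted = weighted
        self.phi = phi
        self.n_boot = n_boot
        self.seed = seed
        self.grid_size = grid_size

    @property
    def method_name(self) -> str:  # type: ignore[override]
        return "Weighted mode" if self.weighted else "Simple mode"

    def fit(self, X, y, se_exposure=None, se_outcome=None) -> "ModeEstimator":
        x, y, sx, sy = self._validate(X, y, se_exposure, se_outcome, min_snps=3)
        if np.any(x == 0):
            raise ZeroDivisionError("Wald ratio undefined for gamma_j = 0")
        b = y / x
        se_b = sy / np.abs(x)
        w = se_b ** -2.0 if self.weighted else np.ones_like(b)
        self.beta_ = _mode_point(b, w, self.phi, self.grid_size)
        self.n_snp_ = len(x)

        rng = np.random.default_rng(self.seed)
        xb = rng.normal(x, sx, size=(self.n_boot, len(x)))
        yb = rng.normal(y, sy, size=(self.n_boot, len(x)))
        xb = np.where(xb == 0, np.finfo(float).tiny, xb)
        bb = yb / xb
        wb = (sy / np.abs(xb)) ** -2.0 if self.weighted else np.ones_like(bb)
        boots = _mode_point_rows(bb, wb, self.phi, self.grid_size)
        self.boot_estimates_ = boots
        self.se_ = float(np.std(boots, ddof=1))
        if self.se_ == 0:
            self.se_ = float(np.finfo(float).tiny)
        self.pvalue_ = _normal_p(self.beta_ / self.se_)
        self._finalize()
        return self


# -- functional wrappers ----------------------------------------------------

def ivw(dataset: HarmonizedDataset, q_alpha: float = 0.05) -> MREstimate:
    """IVW estimate from a harmonized dataset (thin wrapper)."""
    return IVWEstimator(q_alpha=q_alpha).fit_dataset(dataset).to_estimate()


def egger(dataset: HarmonizedDataset) -> EggerResult:
    """MR-Egger slope and intercept from a harmonized dataset."""
    est = EggerEstimator().fit_dataset(dataset)
    return est.result_()


def weighted_median(dataset: HarmonizedDataset, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    return WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit_dataset(dataset).to_estimate()


def mode_estimator(dataset: HarmonizedDataset, settings: ModeSettings | None = None,
                   weighted: bool = True, seed: int | None = None) -> MREstimate:
    settings = settings or ModeSettings()
    est = ModeEstimator(weighted=weighted, phi=settings.phi,
                        n_boot=settings.n_boot, seed=seed)
    return est.fit_dataset(dataset).to_estimate()


def run_all_methods(dataset: HarmonizedDataset, settings: ModeSettings | None = None,
                    seed: int | None = None, n_boot: int | None = None
                    ) -> list[MREstimate]:
    """All five estimates in reporting order (IVW, WM, W mode, S mode, Egger).

    Bootstrap-based methods share the given ``seed``.  With fewer than three
    instruments only IVW is computed; skipped methods are logged.
    """
    settings = settings or ModeSettings()
    if n_boot is None:
        n_boot = settings.n_boot
    estimates = [ivw(dataset)]
    if dataset.n_snps >= 3:
        estimates.append(weighted_median(dataset, n_boot=n_boot, seed=seed))
        estimates.append(mode_estimator(dataset, settings, weighted=True, seed=seed))
        estimates.append(mode_estimator(dataset, settings, weighted=False, seed=seed))
        estimates.append(egger(dataset).slope)
    else:
        for name in METHOD_ORDER[1:]:
            logger.info("run_all_methods: skipped %s (needs >= 3 SNPs, have %d)",
                        name, dataset.n_snps)
    return estimates
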