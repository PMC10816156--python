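"""Synthetic two-sample GWAS summary statistics.

Generates paired exposure/outcome summary statistics with the structure the
MR pipeline assumes: a panel of mostly-null SNPs carrying a set of true,
genome-wide-significant instruments; optional horizontally pleiotropic
(invalid) instruments with directional or balanced direct effects; a
block-diagonal LD structure; strand-ambiguous (palindromic) variants;
allele frames that differ between the two studies (swapped and
strand-complemented records) so harmonization has real work to do; and a
confounder-association table.

The effect model per instrument j is

    gamma_j  ~ half-Normal(0, tau^2)          (SNP-exposure effect)
    alpha_j  =  0                              for valid instruments
    alpha_j  ~ Normal(mu_alpha, sigma_alpha^2) for the invalid fraction
    Gamma_j  =  beta * gamma_j + alpha_j       (SNP-outcome effect)

with observed effects gamma_hat ~ N(gamma, se_exp^2) and
Gamma_hat ~ N(Gamma, se_out^2).  Binary-trait standard errors follow the
case-fraction approximation se^2 = 1 / (n * v * 2 * maf * (1 - maf)) with
v = case_fraction * (1 - case_fraction), which matches the order of
magnitude of per-SNP SEs in large biobank case-control GWAS without
simulating individual-level genotypes.  Exposure effects are coded on the
risk allele (gamma_j >= 0), the usual orientation for reported instrument
lists.  Instruments are rejection-sampled until the *observed* exposure
association passes the genome-wide threshold, so the selection stage of
the pipeline retains them by construction.

Default sample sizes mirror a large biobank exposure GWAS (9,481 cases /
446,987 controls) and a rare-outcome GWAS (464 cases / 213,592 controls).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import HarmonizedDataset, write_summary_stats, complement_alleles
from .selection import CONFOUNDER_PHENOTYPES, LDMatrix

TRUTH_SCHEMA_VERSION = 1

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-sample design.

    ``n_snps_total`` is deliberately desk-scale (500, not the tens of
    millions of a real panel); panel scale is emulated in structure, not
    cardinality.
    """

    n_snps_total: int = 500
    n_instruments: int = 30
    beta_causal: float = 0.72          # log-odds per unit exposure liability
    tau: float = 0.15                  # sd of true instrument effects
    pleiotropy_frac: float = 0.0       # fraction of invalid instruments
    pleiotropy_by_weight: bool = False # interpret the fraction as an IVW-weight share
    pleiotropy_mean: float = 0.0       # mu_alpha (directional when nonzero)
    pleiotropy_sd: float = 0.0         # sigma_alpha
    inside_violation: bool = False     # couple alpha_j to gamma_j (negative tests)
    n_exposure: int = 456_468
    n_cases_exposure: int = 9_481
    n_outcome: int = 214_056
    n_cases_outcome: int = 464
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 5
    ld_decay: float = 0.7              # within-block r^2 = decay^|i-j|
    palindromic_frac: float = 0.15
    allele_swap_frac: float = 0.3      # outcome rows reported on swapped alleles
    strand_flip_frac: float = 0.1      # outcome rows reported on opposite strand
    p_significance: float = 5e-8       # instrument guarantee threshold
    seed: int = 0

    def __post_init__(self):
        for name in ("pleiotropy_frac", "palindromic_frac",
                     "allele_swap_frac", "strand_flip_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if min(self.n_exposure, self.n_outcome) <= 0:
            raise ValueError("sample sizes must be positive")
        if self.n_instruments > self.n_snps_total:
            raise ValueError("more instruments than SNPs")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must lie in [0, 1)")
        n_blocks = -(-self.n_snps_total // self.ld_block_size)
        if self.n_instruments > n_blocks:
            raise ValueError(
                "need at least one LD block per instrument: "
                f"{self.n_instruments} instruments, {n_blocks} blocks"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class SyntheticStudy:
    """A generated study: both summary-stat tables, LD, confounders, truth."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: LDMatrix
    confounders: pd.DataFrame
    truth: dict
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _streams(seed: int | None, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Named independent substreams derived from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _binary_trait_se(maf: np.ndarray, n: int, n_cases: int) -> np.ndarray:
    cf = n_cases / n
    v = cf * (1.0 - cf)
    return np.sqrt(1.0 / (n * v * 2.0 * maf * (1.0 - maf)))


def _draw_instrument_effects(
    rng: np.random.Generator,
    se_exp: np.ndarray,
    tau: float,
    p_significance: float,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """True and observed exposure effects, rejection-sampled for significance."""
    z_crit = stats.norm.isf(p_significance / 2.0)
    gamma = np.empty_like(se_exp)
    gamma_hat = np.empty_like(se_exp)
    for i, se in enumerate(se_exp):
        for _ in range(max_tries):
            g = abs(rng.normal(0.0, tau))
            g_hat = rng.normal(g, se)
            if abs(g_hat) / se > z_crit:
                gamma[i] = g
                gamma_hat[i] = g_hat
                break
        else:  # pragma: no cover - astronomically unlikely at sane tau
            raise RuntimeError("could not draw a significant instrument; increase tau")
    return gamma, gamma_hat


def _choose_invalid(
    rng: np.random.Generator,
    weights: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Designate invalid instruments.

    By count (default): round(frac * J) instruments chosen uniformly.  By
    weight share (``pleiotropy_by_weight``): instruments accumulated in a
    random order until their share of the total inverse-variance ratio
    weight is as close as possible to ``pleiotropy_frac`` — the relevant
    breakdown quantity for the weighted median.
    """
    j = len(weights)
    invalid = np.zeros(j, dtype=bool)
    if config.pleiotropy_frac == 0:
        return invalid
    if not config.pleiotropy_by_weight:
        n_invalid = int(round(config.pleiotropy_frac * j))
        if n_invalid:
            invalid[rng.choice(j, size=n_invalid, replace=False)] = True
        return invalid
    target = config.pleiotropy_frac * float(np.sum(weights))
    order = rng.permutation(j)
    acc = 0.0
    for idx in order:
        w = float(weights[idx])
        if abs(acc + w - target) < abs(acc - target):
            invalid[idx] = True
            acc += w
    if not invalid.any():  # degenerate: take the single closest weight
        invalid[order[int(np.argmin(np.abs(weights[order] - target)))]] = True
    return invalid


def _draw_pleiotropy(
    rng: np.random.Generator,
    gamma: np.ndarray,
    invalid: np.ndarray,
    config: SimulationConfig,
    max_tries: int = 200,
) -> np.ndarray:
    """Direct (pleiotropic) effects alpha_j; zero for valid instruments.

    Under InSIDE, alpha is drawn independently of gamma; with at least three
    invalid instruments the draw is repeated until the sample correlation
    between gamma and alpha (over invalid instruments) is below 0.2, so the
    generated data satisfy the assumption not just in expectation.  The
    ``inside_violation`` switch instead couples alpha to gamma for negative
    tests.
    """
    alpha = np.zeros_like(gamma)
    idx = np.nonzero(invalid)[0]
    if idx.size == 0 or (config.pleiotropy_sd == 0 and config.pleiotropy_mean == 0):
        return alpha
    g = gamma[idx]
    if config.inside_violation:
        centered = g - g.mean()
        alpha[idx] = (config.pleiotropy_mean + centered
                      + rng.normal(0.0, config.pleiotropy_sd / 10.0 + 1e-12, idx.size))
        return alpha
    draw = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, idx.size)
    if idx.size >= 3 and config.pleiotropy_sd > 0 and np.std(g) > 0:
        for _ in range(max_tries):
            if np.std(draw) == 0:
                break
            r = np.corrcoef(g, draw)[0, 1]
            if abs(r) < 0.2:
                break
            draw = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, idx.size)
    alpha[idx] = draw
    return alpha


def simulate_harmonized(
    config: SimulationConfig, seed: int | None = None
) -> tuple[HarmonizedDataset, dict]:
    """Fast path: draw the instruments directly as a harmonized dataset.

    Bypasses alleles, the null panel, LD, and file formats — the effect
    model is identical to :func:`simulate_two_sample_study` restricted to
    its instruments.  Intended for calibration and power studies that need
    thousands of replicates.  Returns the dataset and the truth record.
    """
    if seed is None:
        seed = config.seed
    rng = _streams(seed, ("effects",))["effects"]
    j = config.n_instruments

    maf = rng.uniform(*config.maf_range, size=j)
    se_exp = _binary_trait_se(maf, config.n_exposure, config.n_cases_exposure)
    se_out = _binary_trait_se(maf, config.n_outcome, config.n_cases_outcome)

    gamma, gamma_hat = _draw_instrument_effects(
        rng, se_exp, config.tau, config.p_significance
    )
    invalid = _choose_invalid(rng, (gamma_hat / se_out) ** 2, config)
    alpha = _draw_pleiotropy(rng, gamma, invalid, config)
    Gamma = config.beta_causal * gamma + alpha
    Gamma_hat = rng.normal(Gamma, se_out)

    snp = np.array([f"rs{1_000_001 + i}" for i in range(j)], dtype=object)
    dataset = HarmonizedDataset(
        snp=snp, gamma=gamma_hat, se_gamma=se_exp, Gamma=Gamma_hat, se_Gamma=se_out
    )
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "beta_causal": config.beta_causal,
        "instruments": list(snp),
        "invalid_instruments": list(snp[invalid]),
        "gamma_true": gamma.tolist(),
        "alpha_true": alpha.tolist(),
    }
    return dataset, truth


def _assign_alleles(rng: np.random.Generator, n: int, palindromic_frac: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    pal = rng.random(n) < palindromic_frac
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for i in range(n):
        pool = _PALINDROMIC_PAIRS if pal[i] else _NONPALINDROMIC_PAIRS
        ea[i], oa[i] = pool[rng.integers(len(pool))]
    return ea, oa


def simulate_two_sample_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full synthetic study (panel, LD, alleles, confounder table).

    The SNP panel is laid out in LD blocks of ``ld_block_size`` consecutive
    SNPs assigned round-robin to chromosomes 1-22; within a block
    r^2(i, j) = ld_decay^|i-j| and blocks are independent.  Each instrument
    occupies the first position of its own block, so clumping retains it as
    the index SNP of the block.  Outcome rows are re-expressed on a swapped
    allele frame or the opposite strand for random fractions of the panel,
    which harmonization must undo (recorded in the truth record).
    """
    streams = _streams(config.seed, ("effects", "alleles", "frames", "confounders"))
    rng = streams["effects"]
    n = config.n_snps_total
    j = config.n_instruments
    block = config.ld_block_size

    n_blocks = -(-n // block)
    block_of = np.arange(n) // block
    chrom = np.array([str(b % 22 + 1) for b in block_of], dtype=object)
    # consecutive blocks on the same chromosome sit 20 Mb apart; SNPs within
    # a block 50 kb apart
    pos = np.empty(n, dtype=np.int64)
    for i in range(n):
        b = block_of[i]
        pos[i] = 1_000_000 + (b // 22) * 20_000_000 + (i - b * block) * 50_000

    snp = np.array([f"rs{1_000_001 + i}" for i in range(n)], dtype=object)
    is_instrument = np.zeros(n, dtype=bool)
    is_instrument[np.arange(j) * block] = True  # one instrument per leading block

    maf = rng.uniform(*config.maf_range, size=n)
    se_exp = _binary_trait_se(maf, config.n_exposure, config.n_cases_exposure)
    se_out = _binary_trait_se(maf, config.n_outcome, config.n_cases_outcome)

    gamma = np.zeros(n)
    gamma_hat = rng.normal(0.0, se_exp)
    inst = np.nonzero(is_instrument)[0]
    g_true, g_obs = _draw_instrument_effects(
        rng, se_exp[inst], config.tau, config.p_significance
    )
    gamma[inst] = g_true
    gamma_hat[inst] = g_obs

    invalid_inst = _choose_invalid(rng, (g_obs / se_out[inst]) ** 2, config)
    alpha = np.zeros(n)
    alpha[inst] = _draw_pleiotropy(rng, gamma[inst], invalid_inst, config)

    Gamma = config.beta_causal * gamma + alpha
    Gamma_hat = rng.normal(Gamma, se_out)

    p_exp = 2.0 * stats.norm.sf(np.abs(gamma_hat) / se_exp)
    p_out = 2.0 * stats.norm.sf(np.abs(Gamma_hat) / se_out)

    ea, oa = _assign_alleles(streams["alleles"], n, config.palindromic_frac)
    eaf = np.where(streams["alleles"].random(n) < 0.5, maf, 1.0 - maf)

    exposure = pd.DataFrame({
        "snp": snp, "chrom": chrom, "pos": pos, "ea": ea, "oa": oa,
        "eaf": eaf, "beta": gamma_hat, "se": se_exp, "pvalue": p_exp,
        "n": config.n_exposure, "n_cases": config.n_cases_exposure,
    })

    # outcome rows: same variants, possibly on a swapped frame / other strand
    frames = streams["frames"]
    swap = frames.random(n) < config.allele_swap_frac
    flip = frames.random(n) < config.strand_flip_frac
    o_ea, o_oa = ea.copy(), oa.copy()
    o_beta = Gamma_hat.copy()
    o_eaf = eaf.copy()
    for i in range(n):
        if swap[i]:
            o_ea[i], o_oa[i] = o_oa[i], o_ea[i]
            o_beta[i] = -o_beta[i]
            o_eaf[i] = 1.0 - o_eaf[i]
        if flip[i]:
            o_ea[i], o_oa[i] = complement_alleles(o_ea[i], o_oa[i])

    outcome = pd.DataFrame({
        "snp": snp, "chrom": chrom, "pos": pos, "ea": o_ea, "oa": o_oa,
        "eaf": o_eaf, "beta": o_beta, "se": se_out, "pvalue": p_out,
        "n": config.n_outcome, "n_cases": config.n_cases_outcome,
    })

    r2 = np.eye(n)
    for b in range(n_blocks):
        lo, hi = b * block, min((b + 1) * block, n)
        for i in range(lo, hi):
            for k in range(i + 1, hi):
                r2[i, k] = r2[k, i] = config.ld_decay ** (k - i)
    ld = LDMatrix(snp_ids=list(snp), r2=r2)

    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "beta_causal": config.beta_causal,
        "instruments": list(snp[inst]),
        "invalid_instruments": list(snp[inst][invalid_inst]),
        "gamma_true": gamma[inst].tolist(),
        "alpha_true": alpha[inst].tolist(),
        "swapped_outcome_rows": list(snp[swap]),
        "strand_flipped_outcome_rows": list(snp[flip]),
    }
    study = SyntheticStudy(
        exposure=exposure, outcome=outcome, ld=ld,
        confounders=pd.DataFrame(columns=["snp", "phenotype", "pvalue"]),
        truth=truth, config=config,
    )
    return study


def simulate_confounder_table(
    study: SyntheticStudy, frac_confounded: float, seed: int | None = None
) -> pd.DataFrame:
    """Attach confounder associations (p < 1e-5) to a fraction of instruments.

    Phenotype labels are drawn from the documented confounder vocabulary.
    """
    rng = np.random.default_rng(seed)
    instruments = list(study.truth["instruments"])
    n_conf = int(round(frac_confounded * len(instruments)))
    rows = []
    if n_conf:
        chosen = rng.choice(len(instruments), size=n_conf, replace=False)
        for i in sorted(chosen):
            phen = CONFOUNDER_PHENOTYPES[rng.integers(len(CONFOUNDER_PHENOTYPES))]
            pval = 10.0 ** rng.uniform(-9.0, -6.0)  # always < 1e-5
            rows.append((instruments[i], phen, pval))
    return pd.DataFrame(rows, columns=["snp", "phenotype", "pvalue"])


def write_fixture_bundle(study: SyntheticStudy, directory) -> dict[str, str]:
    """Write a study as the text files the IO and selection modules consume.

    Emits ``exposure.tsv``, ``outcome.tsv``, ``ld.tsv`` (long format),
    ``confounders.tsv``, and ``truth.json``; returns name -> path.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": directory / "exposure.tsv",
        "outcome": directory / "outcome.tsv",
        "ld": directory / "ld.tsv",
        "confounders": directory / "confounders.tsv",
        "truth": directory / "truth.json",
    }
    write_summary_stats(study.exposure, paths["exposure"])
    write_summary_stats(study.outcome, paths["outcome"])
    study.ld.to_long_tsv(paths["ld"])
    study.confounders.to_csv(paths["confounders"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def selection_demo_study() -> tuple[pd.DataFrame, LDMatrix, pd.DataFrame, list[int]]:
    """Deterministic 100-SNP exposure set exercising all five filters.

    Constructed so the screening cascade produces the stage counts
    [100, 20, 12, 12, 10, 9]: 20 genome-wide-significant SNPs of which 8
    are LD satellites of stronger index SNPs, 12 independent indices (all
    strong), 2 of them palindromic, and 1 of the remainder carrying a
    confounder association.  Returns (exposure, ld, confounders,
    expected stage counts).
    """
    n_total, n_index, n_satellite = 100, 12, 8
    se = 0.016
    n_samples = 456_468
    rows = []
    ld_pairs = []

    for i in range(n_index):
        p = (i + 1) * 1e-12
        z = stats.norm.isf(p / 2.0)
        if i < 10:
            ea, oa = "A", "G"
        else:
            ea, oa = ("A", "T") if i == 10 else ("C", "G")  # palindromic pair
        pos = 1_000_000 + i * 25_000_000
        rows.append((f"rs{i + 1:04d}", "1", pos, ea, oa, 0.3, z * se, se, p, n_samples))

    for i in range(n_satellite):
        index_row = rows[i]
        p = (i + 1) * 1e-11  # weaker than its index SNP
        z = stats.norm.isf(p / 2.0)
        pos = index_row[2] + 50_000
        rows.append((f"rs{100 + i:04d}", "1", pos, "A", "G", 0.3, z * se, se, p, n_samples))
        ld_pairs.append((index_row[0], f"rs{100 + i:04d}", 0.5))

    for i in range(n_total - n_index - n_satellite):
        p = 1e-4
        z = stats.norm.isf(p / 2.0)
        rows.append((f"rs{200 + i:04d}", "2", 1_000_000 + i * 100_000, "A", "G",
                     0.3, z * se, se, p, n_samples))

    exposure = pd.DataFrame(
        rows, columns=["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se",
                       "pvalue", "n"]
    )
    exposure["n_cases"] = np.nan

    ids = list(exposure["snp"])
    index = {s: i for i, s in enumerate(ids)}
    r2 = np.eye(n_total)
    for a, b, val in ld_pairs:
        r2[index[a], index[b]] = r2[index[b], index[a]] = val
    ld = LDMatrix(snp_ids=ids, r2=r2)

    confounders = pd.DataFrame(
        [("rs0001", CONFOUNDER_PHENOTYPES[0], 1e-6)],
        columns=["snp", "phenotype", "pvalue"],
    )
    return exposure, ld, confounders, [100, 20, 12, 12, 10, 9]
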