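"""Shared fixtures: published instrument tables and hand-built datasets."""

import numpy as np
import pandas as pd
import pytest

from tsmr.gwas_io import HarmonizedDataset

# 11 genome-wide-significant instruments for unstable angina
# (ebi-a-GCST90018932 extract; exposure GWAS n = 456,468).
UA_INSTRUMENTS = [
    # snp, chrom, pos, ea, oa, beta, se, pvalue
    ("rs10305838", "4", 148400256, "C", "T", 0.130, 0.016, 1.28e-16),
    ("rs11206803", "1", 56877509, "T", "C", 0.070, 0.013, 2.61e-8),
    ("rs11584234", "1", 115907009, "G", "T", -0.095, 0.017, 9.79e-9),
    ("rs17637472", "17", 47461433, "A", "G", 0.081, 0.015, 2.79e-8),
    ("rs2240191", "12", 113335731, "T", "G", 0.104, 0.018, 3.30e-9),
    ("rs2288873", "19", 41852979, "G", "A", -0.070, 0.013, 3.35e-8),
    ("rs28720373", "4", 148291242, "T", "C", -0.083, 0.015, 3.09e-8),
    ("rs4409766", "10", 104616663, "C", "T", -0.108, 0.017, 3.30e-10),
    ("rs7176070", "15", 79033489, "C", "T", -0.083, 0.013, 7.16e-10),
    ("rs75346744", "2", 21520627, "G", "A", 0.219, 0.040, 3.28e-8),
    ("rs79780963", "10", 104952499, "T", "C", -0.105, 0.018, 5.53e-9),
]
UA_N = 456_468


def ua_instruments_frame() -> pd.DataFrame:
    df = pd.DataFrame(
        UA_INSTRUMENTS,
        columns=["snp", "chrom", "pos", "ea", "oa", "beta", "se", "pvalue"],
    )
    df["eaf"] = np.nan
    df["n"] = UA_N
    df["n_cases"] = np.nan
    return df


@pytest.fixture
def ua_instruments() -> pd.DataFrame:
    return ua_instruments_frame()


@pytest.fixture
def ua_instruments_tsv(tmp_path):
    path = tmp_path / "ua_instruments.tsv"
    lines = ["SNP\tCHR\tPOS\tEA\tOA\tBETA\tSE\tP\tN"]
    for snp, chrom, pos, ea, oa, beta, se, p in UA_INSTRUMENTS:
        lines.append(f"{snp}\t{chrom}\t{pos}\t{ea}\t{oa}\t{beta}\t{se}\t{p}\t{UA_N}")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_dataset(gamma, Gamma, se_gamma=None, se_Gamma=None) -> HarmonizedDataset:
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    if se_gamma is None:
        se_gamma = np.full_like(gamma, 0.01)
    if se_Gamma is None:
        se_Gamma = np.full_like(gamma, 0.05)
    return HarmonizedDataset(
        snp=np.array([f"rs{i + 1}" for i in range(len(gamma))], dtype=object),
        gamma=gamma,
        se_gamma=np.asarray(se_gamma, dtype=float),
        Gamma=Gamma,
        se_Gamma=np.asarray(se_Gamma, dtype=float),
    )


@pytest.fixture
def two_snp_dataset() -> HarmonizedDataset:
    """Hand-worked IVW instance: beta = 2, SE_fixed = 1/sqrt(2), Q = 2."""
    return make_dataset(
        gamma=[0.1, 0.2], Gamma=[0.1, 0.6], se_gamma=[0.01, 0.01],
        se_Gamma=[0.1, 0.2],
    )


@pytest.fixture
def exact_line_dataset() -> HarmonizedDataset:
    """Points on Gamma = 0.10 + 1.5 * gamma exactly (zero residuals)."""
    return make_dataset(
        gamma=[0.1, 0.2, 0.3], Gamma=[0.25, 0.40, 0.55],
        se_gamma=[0.01, 0.01, 0.01], se_Gamma=[0.05, 0.04, 0.06],
    )


def random_dataset(rng: np.random.Generator, j: int) -> HarmonizedDataset:
    """A generic random instance for oracle-equivalence checks."""
    gamma = rng.uniform(0.05, 0.4, j) * rng.choice([-1.0, 1.0], j)
    se_gamma = rng.uniform(0.005, 0.03, j)
    se_Gamma = rng.uniform(0.02, 0.15, j)
    Gamma = rng.normal(0.5 * gamma, se_Gamma)
    return make_dataset(gamma, Gamma, se_gamma, se_Gamma)
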