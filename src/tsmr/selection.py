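"""Instrument-variable selection for two-sample MR.

Five screening stages, applied in order: genome-wide significance, LD
clumping, instrument-strength F-statistics, palindrome exclusion, and
confounder-association exclusion.  Each stage is a contraction on the
input table and the whole cascade is recorded in a :class:`SelectionAudit`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, LDLookupError
from .gwas_io import is_palindromic

#: Confounder phenotypes screened against (example vocabulary for a liver
#: outcome: viral hepatitides, alcohol, metabolic and autoimmune liver
#: disease, lipid traits).  Shipped as data, not logic.
CONFOUNDER_PHENOTYPES: tuple[str, ...] = (
    "hepatitis A", "hepatitis B", "hepatitis C", "hepatitis D", "hepatitis E",
    "alcohol consumption", "diabetes", "obesity", "autoimmune hepatitis",
    "primary biliary cholangitis", "primary sclerosing cholangitis",
    "Wilson's disease", "rheumatoid arthritis", "hypercholesterolemia",
    "cholesterol-lowering medication",
)


@dataclass
class SelectionParams:
    """Thresholds for the five instrument-screening stages.

    Defaults follow the conventional genome-wide pipeline: significance
    p < 5e-8, clumping at r^2 < 0.01 within a 10,000 kb window, per-SNP
    F >= 10, palindromes excluded, confounder associations at p < 1e-5.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    confounder_p: float = 1e-5
    r2_mode: str = "zscore"  # per-SNP R^2 estimator: "zscore" or "frequency"

    def __post_init__(self):
        if min(self.p_threshold, self.clump_window_kb, self.f_min, self.confounder_p) < 0:
            raise ConfigurationError("selection thresholds must be non-negative")
        if not 0 < self.clump_r2 < 1:
            raise ConfigurationError("clump_r2 must lie in (0, 1)")
        if self.r2_mode not in ("zscore", "frequency"):
            raise ConfigurationError("r2_mode must be 'zscore' or 'frequency'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionParams":
        return cls(**d)


@dataclass
class LDMatrix:
    """Pairwise r^2 among an ordered set of SNPs.

    ``r2`` is square and symmetric with a unit diagonal and entries in
    [0, 1].  Built either from a square matrix file (SNP-id header row and
    column) or from long-format ``(snp_a, snp_b, r2)`` triples, in which
    case unlisted pairs default to r^2 = 0.
    """

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("LD matrix shape does not match SNP count")
        if n:
            if not np.allclose(self.r2, self.r2.T, atol=1e-8):
                raise ValueError("LD matrix is not symmetric")
            if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
                raise ValueError("LD matrix diagonal must be 1")
            if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
                raise ValueError("LD r^2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def r2_between(self, snp_a: str, snp_b: str) -> float:
        try:
            return float(self.r2[self._index[snp_a], self._index[snp_b]])
        except KeyError as exc:
            raise LDLookupError(f"SNP {exc.args[0]!r} missing from LD matrix") from exc

    @classmethod
    def from_square_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("square LD matrix must have matching row/column ids")
        return cls(snp_ids=list(df.columns), r2=df.to_numpy(dtype=float))

    @classmethod
    def from_long_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        ids: list[str] = []
        seen = set()
        for s in pd.concat([df["snp_a"], df["snp_b"]]):
            if s not in seen:
                seen.add(s)
                ids.append(s)
        index = {s: i for i, s in enumerate(ids)}
        mat = np.eye(len(ids))
        for a, b, r2 in df.itertuples(index=False):
            i, j = index[a], index[b]
            mat[i, j] = mat[j, i] = float(r2)
        return cls(snp_ids=ids, r2=mat)

    def to_square_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t"
        )

    def to_long_tsv(self, path) -> None:
        """Write diagonal plus nonzero off-diagonal pairs as triples."""
        rows = [(s, s, 1.0) for s in self.snp_ids]
        n = len(self.snp_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.r2[i, j] > 0:
                    rows.append((self.snp_ids[i], self.snp_ids[j], float(self.r2[i, j])))
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class SelectionAudit:
    """Per-stage instrument counts and drop reasons for one selection run."""

    stages: list[str] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)  # snp -> reason

    def record(self, stage: str, kept: pd.DataFrame, previous: pd.DataFrame | None = None,
               reason: str | None = None) -> None:
        self.stages.append(stage)
        self.counts.append(len(kept))
        if previous is not None and reason is not None:
            lost = set(previous["snp"]) - set(kept["snp"])
            for snp in lost:
                self.dropped.setdefault(snp, reason)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "counts": self.counts, "dropped": self.dropped}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def filter_significance(records: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Retain rows with association p strictly below ``p_threshold``."""
    return records[records["pvalue"] < p_threshold].reset_index(drop=True)


def _clump_order_key(records: pd.DataFrame) -> np.ndarray:
    # deterministic index order: smallest p, ties by position then snp id
    order = sorted(
        range(len(records)),
        key=lambda i: (
            records["pvalue"].iat[i],
            records["pos"].iat[i],
            records["snp"].iat[i],
        ),
    )
    return np.array(order, dtype=int)


def clump(
    records: pd.DataFrame,
    ld: LDMatrix,
    clump_r2: float = 0.01,
    clump_window_kb: float = 10_000.0,
) -> pd.DataFrame:
    """Greedy LD clumping of summary statistics.

    Repeatedly takes the remaining SNP with the smallest p-value as an index
    SNP and removes every other remaining SNP on the same chromosome within
    +/- ``clump_window_kb`` kilobases whose r^2 with the index is >=
    ``clump_r2``.  Returns the index SNPs sorted by p-value (ties broken by
    position, then SNP id).

    Raises
    ------
    LDLookupError
        If any record's SNP is absent from the LD matrix.
    """
    for snp in records["snp"]:
        if snp not in ld:
            raise LDLookupError(f"SNP {snp!r} missing from LD matrix")

    window_bp = clump_window_kb * 1000.0
    order = _clump_order_key(records)
    alive = np.ones(len(records), dtype=bool)
    kept: list[int] = []
    chrom = records["chrom"].to_numpy()
    pos = records["pos"].to_numpy()
    snps = records["snp"].to_numpy()

    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        for j in np.nonzero(alive)[0]:
            if (
                chrom[j] == chrom[i]
                and abs(float(pos[j]) - float(pos[i])) <= window_bp
                and ld.r2_between(snps[i], snps[j]) >= clump_r2
            ):
                alive[j] = False
    return records.iloc[kept].reset_index(drop=True)


def per_snp_r2(record, mode: str = "zscore") -> float:
    """Fraction of exposure variance explained by one SNP.

    ``zscore`` mode uses R^2 = z^2 / (z^2 + n - 2) with z = beta/se and needs
    only printed summary statistics; ``frequency`` mode uses
    R^2 = 2 * eaf * (1 - eaf) * beta^2 and needs the effect-allele frequency
    (beta on a standardized trait scale).
    """
    if mode == "zscore":
        z = float(record["beta"]) / float(record["se"])
        n = float(record["n"])
        return z * z / (z * z + n - 2.0)
    if mode == "frequency":
        eaf = record["eaf"]
        if eaf is None or pd.isna(eaf):
            raise ValueError("frequency-mode R^2 requires the effect-allele frequency")
        beta = float(record["beta"])
        return 2.0 * float(eaf) * (1.0 - float(eaf)) * beta * beta
    raise ConfigurationError(f"unknown R^2 mode {mode!r}")


def f_statistic(r_squared: float, n: float, k: int = 1) -> float:
    """Instrument-strength F = (n - k - 1)/k * R^2 / (1 - R^2)."""
    if n <= k + 1:
        raise ValueError(f"sample size n={n} must exceed k+1={k + 1}")
    if not 0 <= r_squared < 1:
        raise ValueError("R^2 must lie in [0, 1)")
    return (n - k - 1.0) / k * r_squared / (1.0 - r_squared)


def instrument_strength(records: pd.DataFrame, mode: str = "zscore", k: int = 1) -> pd.DataFrame:
    """Per-SNP R^2 and F (k = 1) for every record.

    Returns a DataFrame with columns ``snp, r_squared, f_stat, n, k``.
    """
    rows = []
    for _, rec in records.iterrows():
        r2 = per_snp_r2(rec, mode=mode)
        rows.append((rec["snp"], r2, f_statistic(r2, float(rec["n"]), k), float(rec["n"]), k))
    return pd.DataFrame(rows, columns=["snp", "r_squared", "f_stat", "n", "k"])


def filter_weak(records: pd.DataFrame, strengths: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Exclude weak instruments: retain records whose F >= ``f_min``."""
    fmap = dict(zip(strengths["snp"], strengths["f_stat"]))
    missing = [s for s in records["snp"] if s not in fmap]
    if missing:
        raise ValueError(f"no F-statistic for SNP(s) {missing}")
    keep = records["snp"].map(lambda s: fmap[s] >= f_min)
    return records[keep].reset_index(drop=True)


def filter_palindromic(records: pd.DataFrame) -> pd.DataFrame:
    """Exclude strand-ambiguous (A/T, C/G) variants."""
    if len(records) == 0:
        return records.reset_index(drop=True)
    keep = ~records.apply(lambda r: is_palindromic(r["ea"], r["oa"]), axis=1)
    return records[keep].reset_index(drop=True)


def filter_confounders(
    records: pd.DataFrame,
    confounder_table: pd.DataFrame | None,
    confounder_p: float = 1e-5,
) -> pd.DataFrame:
    """Exclude SNPs associated with a known confounder at p < ``confounder_p``.

    ``confounder_table`` has columns ``snp, phenotype, pvalue``; matching is
    by exact SNP id.
    """
    if confounder_table is None or len(confounder_table) == 0:
        return records.reset_index(drop=True)
    hits = confounder_table[confounder_table["pvalue"] < confounder_p]
    bad = set(hits["snp"])
    return records[~records["snp"].isin(bad)].reset_index(drop=True)


def read_confounder_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["snp", "phenotype", "pvalue"]
    df["pvalue"] = pd.to_numeric(df["pvalue"])
    return df


def select_instruments(
    exposure: pd.DataFrame,
    ld: LDMatrix,
    confounder_table: pd.DataFrame | None = None,
    params: SelectionParams | None = None,
) -> tuple[pd.DataFrame, SelectionAudit]:
    """Run the full five-stage screening cascade on exposure statistics.

    Stage order: significance -> LD clumping -> weak-instrument F filter ->
    palindrome exclusion -> confounder exclusion.  Returns the surviving
    records and an audit of per-stage counts and drop reasons.
    """
    params = params or SelectionParams()
    audit = SelectionAudit()
    audit.record("input", exposure)

    sig = filter_significance(exposure, params.p_threshold)
    audit.record("significance", sig, exposure, "not_genome_wide_significant")

    clumped = clump(sig, ld, params.clump_r2, params.clump_window_kb)
    audit.record("clumping", clumped, sig, "in_ld_with_index_snp")

    strengths = instrument_strength(clumped, mode=params.r2_mode) if len(clumped) else (
        pd.DataFrame(columns=["snp", "r_squared", "f_stat", "n", "k"])
    )
    strong = filter_weak(clumped, strengths, params.f_min) if len(clumped) else clumped
    audit.record("f_statistic", strong, clumped, "weak_instrument")

    nonpal = filter_palindromic(strong)
    audit.record("palindrome", nonpal, strong, "palindromic")

    final = filter_confounders(nonpal, confounder_table, params.confounder_p)
    audit.record("confounder", final, nonpal, "confounder_associated")

    return final, audit
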