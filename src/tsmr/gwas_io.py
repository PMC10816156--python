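"""Reading, writing, and harmonizing GWAS summary statistics.

Summary statistics live in pandas DataFrames with standardized columns
(one row per SNP)::

    snp, chrom, pos, ea, oa, eaf, beta, se, pvalue, n, n_cases

``ea``/``oa`` are the effect and other allele; ``beta`` is the additive
per-effect-allele association (log-odds for binary traits) with standard
error ``se``.  ``eaf`` (effect-allele frequency) and ``n_cases`` are
optional and may be missing (NaN).

Harmonization aligns an exposure and an outcome dataset onto the exposure's
effect-allele frame so that per-SNP effects (gamma_j, Gamma_j) refer to the
same allele.  Strand-ambiguous (palindromic) variants are excluded outright
because their orientation cannot be resolved without reliable frequency
information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyIntersectionError,
    InvalidAlleleError,
    RowParseError,
)

logger = logging.getLogger(__name__)

#: Standard internal column names -> default file header names.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "ea": "EA",
    "oa": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
    "n_cases": "NCASES",
}

#: Columns that must be present in every summary-statistics file.
MANDATORY_COLUMNS = ("snp", "chrom", "pos", "ea", "oa", "beta", "se", "pvalue", "n")

_NUMERIC_COLUMNS = ("pos", "eaf", "beta", "se", "pvalue", "n", "n_cases")

VALID_ALLELES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _check_allele(allele: str) -> str:
    allele = str(allele).upper()
    if allele not in VALID_ALLELES:
        raise InvalidAlleleError(f"allele {allele!r} is not one of A/C/G/T")
    return allele


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    ea = _check_allele(effect_allele)
    oa = _check_allele(other_allele)
    return _COMPLEMENT[ea] == oa


def complement_alleles(effect_allele: str, other_allele: str) -> tuple[str, str]:
    """Map both alleles to the opposite strand (A<->T, C<->G)."""
    return (
        _COMPLEMENT[_check_allele(effect_allele)],
        _COMPLEMENT[_check_allele(other_allele)],
    )


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    delimiter: str = "\t",
) -> pd.DataFrame:
    """Read delimited summary statistics into a standard-column DataFrame.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    column_map:
        Mapping from internal names (keys of :data:`DEFAULT_COLUMN_MAP`) to
        the file's header names.  Unspecified keys fall back to the default
        header names; ``eaf`` and ``n_cases`` are optional.
    delimiter:
        Field separator (tab by default, matching OpenGWAS-style exports).

    Raises
    ------
    ConfigurationError
        If a mandatory column is absent from the file.
    RowParseError
        If a numeric field fails to parse; the error names the 1-based file
        line (header = line 1).

    Notes
    -----
    Alleles are upper-cased.  Rows violating record invariants (se <= 0,
    alleles outside A/C/G/T, identical alleles, eaf outside [0, 1]) are
    dropped with a logged count rather than aborting the read.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMN_MAP)
        if unknown:
            raise ConfigurationError(f"unknown column-map keys: {sorted(unknown)}")
        cmap.update(column_map)

    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]

    missing = [cmap[k] for k in MANDATORY_COLUMNS if cmap[k] not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"mandatory column(s) {missing} not found in {path}; "
            f"header is {list(raw.columns)}"
        )

    df = pd.DataFrame(index=raw.index)
    for internal, header in cmap.items():
        if header in raw.columns:
            df[internal] = raw[header]
        else:
            df[internal] = ""

    for col in _NUMERIC_COLUMNS:
        text = df[col].replace({"": None, "NA": None, "nan": None})
        values = pd.to_numeric(text, errors="coerce")
        bad = values.isna() & text.notna()
        if bad.any():
            idx = int(bad.idxmax())
            raise RowParseError(
                f"unparsable value {df[col].iloc[idx]!r} for column "
                f"{cmap[col]!r} at file line {idx + 2}",
                line_number=idx + 2,
            )
        if col in MANDATORY_COLUMNS and values.isna().any():
            idx = int(values.isna().idxmax())
            raise RowParseError(
                f"missing value for mandatory column {cmap[col]!r} "
                f"at file line {idx + 2}",
                line_number=idx + 2,
            )
        df[col] = values

    df["snp"] = df["snp"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["ea"] = df["ea"].str.upper()
    df["oa"] = df["oa"].str.upper()

    n_in = len(df)
    ok = (
        (df["se"] > 0)
        & df["ea"].isin(VALID_ALLELES)
        & df["oa"].isin(VALID_ALLELES)
        & (df["ea"] != df["oa"])
        & (df["eaf"].isna() | df["eaf"].between(0.0, 1.0))
        & (df["pos"] >= 1)
    )
    dropped = n_in - int(ok.sum())
    if dropped:
        logger.warning("read_summary_stats(%s): rejected %d invalid row(s)", path, dropped)
    df = df[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    return df


def write_summary_stats(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a standard-column DataFrame using the default header names."""
    out = df.rename(columns=DEFAULT_COLUMN_MAP)
    out.to_csv(path, sep=delimiter, index=False, na_rep="")


def validate_summary_stats(df: pd.DataFrame) -> None:
    """Assert the per-record invariants on a standard-column DataFrame."""
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(f"summary statistics lack column {col!r}")
    if not (df["se"] > 0).all():
        raise ValueError("non-positive standard error present")
    if (df["ea"] == df["oa"]).any():
        raise ValueError("identical effect/other allele present")
    eaf = df["eaf"].dropna()
    if not eaf.between(0, 1).all():
        raise ValueError("effect-allele frequency outside [0, 1]")
    if df["snp"].duplicated().any():
        raise ValueError("duplicate SNP ids present")


@dataclass
class HarmonizedDataset:
    """Per-SNP aligned exposure/outcome effects ready for MR estimation.

    Vectors (all length ``J``): exposure effects ``gamma`` with SE
    ``se_gamma``, outcome effects ``Gamma`` with SE ``se_Gamma``, both
    expressed per copy of the exposure's effect allele.
    """

    snp: np.ndarray
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    sign_flipped: np.ndarray = field(default=None)  # type: ignore[assignment]
    strand_complemented: np.ndarray = field(default=None)  # type: ignore[assignment]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.snp = np.asarray(self.snp, dtype=object)
        for name in ("gamma", "se_gamma", "Gamma", "se_Gamma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        j = len(self.snp)
        if self.sign_flipped is None:
            self.sign_flipped = np.zeros(j, dtype=bool)
        if self.strand_complemented is None:
            self.strand_complemented = np.zeros(j, dtype=bool)
        self.sign_flipped = np.asarray(self.sign_flipped, dtype=bool)
        self.strand_complemented = np.asarray(self.strand_complemented, dtype=bool)
        lengths = {
            len(v)
            for v in (
                self.snp, self.gamma, self.se_gamma, self.Gamma,
                self.se_Gamma, self.sign_flipped, self.strand_complemented,
            )
        }
        if lengths != {j}:
            raise ValueError("harmonized vectors have unequal lengths")
        if j and (not np.all(self.se_gamma > 0) or not np.all(self.se_Gamma > 0)):
            raise ValueError("harmonized standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.snp)

    def subset(self, mask_or_index) -> "HarmonizedDataset":
        """Return a new dataset restricted to a boolean mask or index array."""
        idx = np.asarray(mask_or_index)
        return HarmonizedDataset(
            snp=self.snp[idx],
            gamma=self.gamma[idx],
            se_gamma=self.se_gamma[idx],
            Gamma=self.Gamma[idx],
            se_Gamma=self.se_Gamma[idx],
            sign_flipped=self.sign_flipped[idx],
            strand_complemented=self.strand_complemented[idx],
        )

    def drop_snps(self, snp_ids) -> "HarmonizedDataset":
        snp_ids = set(snp_ids)
        mask = np.array([s not in snp_ids for s in self.snp])
        return self.subset(mask)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp,
                "gamma": self.gamma,
                "se_gamma": self.se_gamma,
                "Gamma": self.Gamma,
                "se_Gamma": self.se_Gamma,
                "sign_flipped": self.sign_flipped,
                "strand_complemented": self.strand_complemented,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "HarmonizedDataset":
        kwargs = {}
        for flag in ("sign_flipped", "strand_complemented"):
            if flag in df.columns:
                kwargs[flag] = df[flag].to_numpy(dtype=bool)
        return cls(
            snp=df["snp"].to_numpy(dtype=object),
            gamma=df["gamma"].to_numpy(dtype=float),
            se_gamma=df["se_gamma"].to_numpy(dtype=float),
            Gamma=df["Gamma"].to_numpy(dtype=float),
            se_Gamma=df["se_Gamma"].to_numpy(dtype=float),
            **kwargs,
        )


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> HarmonizedDataset:
    """Align outcome effects onto the exposure's effect-allele frame.

    For each SNP present in both datasets:

    * identical allele pair -> outcome effect copied as-is;
    * swapped alleles (outcome EA = exposure OA and vice versa) -> outcome
      beta negated, eaf replaced by 1 - eaf, ``sign_flipped`` set;
    * a match only after complementing the outcome alleles to the opposite
      strand -> complement applied first, then the two rules above,
      ``strand_complemented`` set;
    * palindromic exposure variants are dropped unconditionally (orientation
      unresolvable); any other allele mismatch is dropped.

    Every exclusion is recorded as ``(snp, reason)`` in ``dropped``.

    Raises
    ------
    EmptyIntersectionError
        If the two datasets share no SNP ids.
    """
    exp = exposure.set_index("snp", drop=False)
    out = outcome.set_index("snp", drop=False)
    shared = [s for s in exp.index if s in out.index]
    if not shared:
        raise EmptyIntersectionError("exposure and outcome share no SNPs")

    rows = []
    dropped: list[tuple[str, str]] = []
    for snp in shared:
        e = exp.loc[snp]
        o = out.loc[snp]
        e_ea, e_oa = _check_allele(e["ea"]), _check_allele(e["oa"])
        o_ea, o_oa = _check_allele(o["ea"]), _check_allele(o["oa"])

        if is_palindromic(e_ea, e_oa):
            dropped.append((snp, "palindromic"))
            continue

        flipped = False
        complemented = False
        if (o_ea, o_oa) == (e_ea, e_oa):
            pass
        elif (o_ea, o_oa) == (e_oa, e_ea):
            flipped = True
        else:
            c_ea, c_oa = complement_alleles(o_ea, o_oa)
            if (c_ea, c_oa) == (e_ea, e_oa):
                complemented = True
            elif (c_ea, c_oa) == (e_oa, e_ea):
                complemented = True
                flipped = True
            else:
                dropped.append((snp, "allele_mismatch"))
                continue

        Gamma = -float(o["beta"]) if flipped else float(o["beta"])
        rows.append(
            (snp, float(e["beta"]), float(e["se"]), Gamma, float(o["se"]),
             flipped, complemented)
        )
        if flipped or complemented:
            logger.debug("harmonize: %s flipped=%s complemented=%s", snp, flipped, complemented)

    for snp, reason in dropped:
        logger.info("harmonize: dropped %s (%s)", snp, reason)

    if rows:
        snp_ids, gamma, se_g, Gamma, se_G, flips, comps = map(np.array, zip(*rows))
    else:
        snp_ids = np.array([], dtype=object)
        gamma = se_g = Gamma = se_G = np.array([], dtype=float)
        flips = comps = np.array([], dtype=bool)

    return HarmonizedDataset(
        snp=snp_ids,
        gamma=gamma.astype(float) if len(rows) else gamma,
        se_gamma=se_g.astype(float) if len(rows) else se_g,
        Gamma=Gamma.astype(float) if len(rows) else Gamma,
        se_Gamma=se_G.astype(float) if len(rows) else se_G,
        sign_flipped=flips.astype(bool) if len(rows) else flips,
        strand_complemented=comps.astype(bool) if len(rows) else comps,
        dropped=dropped,
    )
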