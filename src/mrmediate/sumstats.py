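"""Reading, validating and writing GWAS summary statistics and LD tables.

All analyses in this package consume per-variant association records
exchanged as tab-separated text with a fixed ten-column header::

    variant_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pvalue  n

Positions are 1-based, following GWAS summary-statistic convention.
Only biallelic SNPs are accepted: alleles must be single uppercase
bases, so indels and multi-allelic records are rejected at parse time.
Effect sizes are log-odds for binary traits and trait-SD units for
continuous traits.  A missing effect-allele frequency is written ``NA``.

Validation is total: a file either yields a fully valid
:class:`SummaryStats` or raises a located error — no partially
validated object escapes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

TRAIT_TYPES = ("continuous", "binary")


class SumstatsError(ValueError):
    """Base class for summary-statistics I/O and validation errors."""


class SumstatsFormatError(SumstatsError):
    """The file does not conform to the expected dialect (e.g. missing column)."""


class SumstatsValidationError(SumstatsError):
    """A row violates a field invariant; the message cites the offending line."""


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and G/C allele pairs, whose strand cannot be resolved."""
    return COMPLEMENT.get(a1) == a2


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics.

    ``records`` is a DataFrame with the canonical columns; ``variant_id``
    is unique within one instance.  Construction validates every row.
    """

    trait_name: str
    trait_type: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise SumstatsValidationError(
                f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}"
            )
        self.records = _validate_records(self.records, source=self.trait_name)

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def lookup(self, variant_ids: Iterable[str]) -> pd.DataFrame:
        """Rows for the requested ids, indexed by variant_id (missing ids absent)."""
        idx = self.records.set_index("variant_id")
        found = [v for v in variant_ids if v in idx.index]
        return idx.loc[found]

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStats":
        keep = set(variant_ids)
        df = self.records[self.records["variant_id"].isin(keep)].reset_index(drop=True)
        return SummaryStats(self.trait_name, self.trait_type, df)


def _validate_records(df: pd.DataFrame, source: str = "") -> pd.DataFrame:
    """Validate and coerce a records frame; raise a located error on violation.

    Line numbers in messages assume the frame came from a file with a
    header on line 1, so data row i maps to line i + 2.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(
            f"{source}: missing required column(s): {', '.join(missing)}"
        )
    df = df[CANONICAL_COLUMNS].copy().reset_index(drop=True)

    dupes = df["variant_id"][df["variant_id"].duplicated()].unique()
    if len(dupes):
        raise SumstatsValidationError(
            f"{source}: duplicate variant_id(s): {', '.join(map(str, dupes[:10]))}"
        )

    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col, dtype in [("pos", np.int64), ("n", np.int64)]:
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise SumstatsValidationError(f"{source}: column {col} not integer: {exc}")
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    def _bad(mask: pd.Series, what: str) -> None:
        if mask.any():
            line = int(mask.idxmax()) + 2
            raise SumstatsValidationError(f"{source}: {what} on line {line}")

    _bad(df["pos"] < 1, "pos < 1")
    _bad(df["n"] < 2, "sample size n < 2")
    ea, oa = df["effect_allele"].astype(str), df["other_allele"].astype(str)
    df["effect_allele"], df["other_allele"] = ea, oa
    _bad(~ea.isin(VALID_ALLELES), "effect_allele not a single base A/C/G/T")
    _bad(~oa.isin(VALID_ALLELES), "other_allele not a single base A/C/G/T")
    _bad(ea == oa, "effect_allele equals other_allele")
    _bad(df["beta"].isna(), "missing beta")
    _bad(df["se"].isna() | (df["se"] <= 0), "se <= 0")
    _bad(df["pvalue"].isna() | (df["pvalue"] <= 0) | (df["pvalue"] > 1), "pvalue not in (0,1]")
    eaf_bad = df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1))
    _bad(eaf_bad, "eaf not in (0,1)")
    return df


def read_sumstats(path: str | Path, trait_name: str, trait_type: str) -> SummaryStats:
    """Read one trait's summary statistics from tab-separated text.

    The header must name the ten canonical columns (any order).  Rows
    violating a field invariant raise :class:`SumstatsValidationError`
    citing the line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str},
                     na_values=["NA"], keep_default_na=False)
    stats = SummaryStats(trait_name, trait_type, df)
    logger.info("read %d records for %s from %s", stats.n_variants, trait_name, path)
    return stats


def write_sumstats(stats: SummaryStats, path: str | Path) -> Path:
    """Write summary statistics; round-trips exactly (17 significant digits)."""
    path = Path(path)
    df = stats.records.copy()
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = df[col].map(lambda v: "NA" if pd.isna(v) else format(v, ".17g"))
    df.to_csv(path, sep="\t", index=False)
    return path


class LDTable:
    """Pairwise linkage-disequilibrium r-squared lookup.

    Keys are unordered variant-id pairs; a pair absent from the table is
    treated as r-squared 0 (unlinked).
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), r2 in entries.items():
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise SumstatsValidationError(f"r2 outside [0,1] for pair ({a}, {b}): {r2}")
        self._r2[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)


def read_ld_table(path: str | Path) -> LDTable:
    """Read a three-column (id1, id2, r2) tab-separated LD table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id1", "id2", "r2"],
                     dtype={"id1": str, "id2": str})
    # tolerate a header row
    if len(df) and str(df.iloc[0]["r2"]).lower() in {"r2", "r^2", "rsq"}:
        df = df.iloc[1:]
    table = LDTable()
    for row in df.itertuples(index=False):
        table.set(row.id1, row.id2, float(row.r2))
    return table


def write_ld_table(table: LDTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for (a, b), r2 in sorted(table._r2.items()):
            fh.write(f"{a}\t{b}\t{format(r2, '.17g')}\n")
    return path
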