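"""Reading, validating and writing GWAS summary statistics.

The canonical in-memory container is a :class:`pandas.DataFrame` with columns

    snp, effect_allele, other_allele, eaf, beta, se, pval, n

one row per variant, in file order.  ``eaf`` and ``n`` are optional and held
as NaN when absent; on disk a missing value is an empty field, never 0.
Betas are on the log-odds scale for binary traits and in native/SD units for
continuous traits — units are opaque to the pipeline and travel in
:class:`StudyMeta.trait_name`.

The reader is dialect tolerant (tab or comma, case-insensitive headers via a
column map); the writer emits a single canonical tab-delimited dialect with
enough digits for lossless float round-trips.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import DuplicateSNPError, ParameterError, SchemaError, ValidationError

CANONICAL_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
REQUIRED_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]
VALID_ALLELES = frozenset("ACGT")


class SummaryStatRecord(NamedTuple):
    """One SNP's association with one trait."""

    snp: str
    effect_allele: str
    other_allele: str
    eaf: float  # NaN when missing
    beta: float
    se: float
    pval: float
    n: float  # NaN when missing


@dataclass
class StudyMeta:
    """Provenance of one GWAS: trait, consortium, ancestry, sample sizes."""

    trait_name: str
    consortium: str = ""
    ancestry: str = ""
    n_total: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self):
        if (
            self.n_cases is not None
            and self.n_controls is not None
            and self.n_total is not None
            and self.n_cases + self.n_controls != self.n_total
        ):
            raise ValidationError(
                f"n_cases ({self.n_cases}) + n_controls ({self.n_controls}) "
                f"!= n_total ({self.n_total}) for trait {self.trait_name!r}"
            )


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a canonical-column DataFrame row by row.

    Returns the validated frame (alleles uppercased, optional columns added
    as NaN).  Raises :class:`ValidationError` citing the 1-based data row of
    the first violation, or :class:`DuplicateSNPError` on repeated IDs.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]
    df["snp"] = df["snp"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    dup = df["snp"].duplicated()
    if dup.any():
        first = df.loc[dup, "snp"].iloc[0]
        raise DuplicateSNPError(
            f"duplicate snp id {first!r}", row=int(np.flatnonzero(dup)[0]) + 1
        )

    for i, rec in enumerate(df.itertuples(index=False), start=1):
        if rec.effect_allele not in VALID_ALLELES or rec.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"alleles must be single bases A/C/G/T, got "
                f"{rec.effect_allele!r}/{rec.other_allele!r} for {rec.snp}",
                row=i,
            )
        if rec.effect_allele == rec.other_allele:
            raise ValidationError(f"effect and other allele identical for {rec.snp}", row=i)
        if not (math.isfinite(rec.beta)):
            raise ValidationError(f"non-finite beta for {rec.snp}", row=i)
        if not (math.isfinite(rec.se) and rec.se > 0):
            raise ValidationError(f"se must be > 0, got {rec.se} for {rec.snp}", row=i)
        if not (math.isfinite(rec.pval) and 0 < rec.pval <= 1):
            raise ValidationError(f"pval must be in (0,1], got {rec.pval} for {rec.snp}", row=i)
        if not math.isnan(rec.eaf) and not 0 <= rec.eaf <= 1:
            raise ValidationError(f"eaf must be in [0,1], got {rec.eaf} for {rec.snp}", row=i)
    return df.reset_index(drop=True)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_sumstats(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read one GWAS summary-statistics table into canonical form.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with one header row.
    column_map
        Maps file headers to canonical field names, e.g.
        ``{"variant": "snp", "minor_AF": "eaf"}``.  Matching is
        case-insensitive; canonical headers need no mapping.

    Row order is preserved; every row is validated and duplicate SNP IDs are
    rejected.
    """
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]

    rename = {}
    if column_map:
        lower_map = {k.lower(): v for k, v in column_map.items()}
        for col in raw.columns:
            if col.lower() in lower_map:
                rename[col] = lower_map[col.lower()]
        unmatched = set(column_map.values()) - set(rename.values())
        # a mapped canonical name may also already be present verbatim
        unmatched -= {c.lower() for c in raw.columns}
        if unmatched:
            raise SchemaError(
                f"column_map target(s) not found in {path}: {', '.join(sorted(unmatched))}"
            )
    for col in raw.columns:
        if col not in rename and col.lower() in CANONICAL_COLUMNS:
            rename[col] = col.lower()
    df = raw.rename(columns=rename)
    df = df.replace({"": np.nan})
    return validate_sumstats(df)


def write_table(records: pd.DataFrame, path) -> None:
    """Write any tabular result in the canonical tab-delimited dialect.

    Floats are written with 17 significant digits (repr-exact), so the
    read/write round trip is lossless.  Missing values become empty fields.
    """
    if records is None or len(records) == 0:
        raise ParameterError("refusing to write an empty table")
    records.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="")


def to_records(df: pd.DataFrame) -> list[SummaryStatRecord]:
    """Row-level view of a canonical frame."""
    return [SummaryStatRecord(*row) for row in df[CANONICAL_COLUMNS].itertuples(index=False)]


def from_records(records: list[SummaryStatRecord]) -> pd.DataFrame:
    return validate_sumstats(pd.DataFrame(records, columns=CANONICAL_COLUMNS))
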