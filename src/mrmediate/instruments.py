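"""Instrument selection and exposure/outcome harmonization.

Selection keeps genome-wide-significant SNPs (default p < 5e-8) with minor
allele frequency above a floor (default 0.01), drops a user-supplied
exclusion list (the stand-in for a manual confounder-lookup screen), then
prunes to approximate independence by greedy p-value-ranked clumping against
a user-supplied r^2 matrix (default window 10,000 kb, r^2 < 0.001).  Without
an LD matrix the survivors are treated as already independent, which matches
simulated instruments drawn without LD.

Harmonization re-orients every outcome association onto the exposure's
effect allele: swapped alleles flip the outcome beta's sign and complement
its frequency; strand flips are resolved through base complement; palindromic
SNPs (A/T, C/G) are aligned by allele frequency when both sides are away
from 0.5, and otherwise dropped (or kept flagged) as ambiguous.  Every drop
is counted, and the counts ledger reconciles exactly:

    retained = candidates - below_threshold - maf_filtered - excluded
             - pruned - missing_in_outcome - irreconcilable
             - ambiguous_palindromic
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .sumstats import validate_sumstats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


@dataclass
class LDInfo:
    """Pairwise r^2 with optional genomic positions.

    ``r2`` is a square symmetric DataFrame indexed by SNP id.  ``positions``
    (optional) has columns ``snp, chrom, pos``; without it the physical
    window constraint is vacuous and only r^2 applies.
    """

    r2: pd.DataFrame
    positions: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.r2.index.equals(self.r2.columns):
            raise ParameterError("LD matrix must have identical row and column SNP labels")

    def within_window(self, a: str, b: str, window_kb: float) -> bool:
        if self.positions is None:
            return True
        pos = self.positions.set_index("snp")
        if a not in pos.index or b not in pos.index:
            return True
        ra, rb = pos.loc[a], pos.loc[b]
        if "chrom" in pos.columns and ra["chrom"] != rb["chrom"]:
            return False
        return abs(float(ra["pos"]) - float(rb["pos"])) <= window_kb * 1000.0

    def r2_between(self, a: str, b: str) -> float:
        if a in self.r2.index and b in self.r2.index:
            return float(self.r2.loc[a, b])
        return 0.0


@dataclass
class InstrumentSet:
    """Harmonized per-SNP exposure and outcome effects, ready for MR.

    ``data`` columns: snp, effect_allele, other_allele, eaf,
    beta_exposure, se_exposure, beta_outcome, se_outcome, pval_exposure,
    palindromic (bool), flipped (bool).  The outcome columns are NaN in the
    exposure-side skeleton produced by :func:`select_instruments`.
    ``counts`` is the filtering ledger; ``params`` records thresholds used.
    """

    data: pd.DataFrame
    counts: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    def __len__(self) -> int:
        return len(self.data)

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.data["beta_exposure"].to_numpy(float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.data["se_exposure"].to_numpy(float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.data["beta_outcome"].to_numpy(float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.data["se_outcome"].to_numpy(float)

    @property
    def snp_ids(self) -> list[str]:
        return self.data["snp"].tolist()

    def subset(self, mask) -> "InstrumentSet":
        return InstrumentSet(
            data=self.data.loc[mask].reset_index(drop=True),
            counts=dict(self.counts), params=dict(self.params),
            exposure_name=self.exposure_name, outcome_name=self.outcome_name,
        )

    def ledger_balances(self) -> bool:
        c = self.counts
        spent = sum(c.get(k, 0) for k in (
            "below_threshold", "maf_filtered", "excluded", "pruned",
            "missing_in_outcome", "irreconcilable", "ambiguous_palindromic"))
        return c.get("candidates", 0) - spent == len(self)


def select_instruments(
    exposure: pd.DataFrame,
    p_threshold: float = 5e-8,
    ld: LDInfo | None = None,
    window_kb: float = 10_000.0,
    r2_limit: float = 0.001,
    maf_min: float = 0.01,
    exclude: set[str] | None = None,
    exposure_name: str = "exposure",
) -> InstrumentSet:
    """Select exposure instruments; returns an exposure-side skeleton.

    Threshold filters are set operations (order-insensitive); pruning is the
    deterministic greedy clump: survivors sorted by ascending p-value (SNP id
    as tiebreak), each accepted unless it has r^2 >= ``r2_limit`` with an
    already-accepted SNP within ``window_kb``.
    """
    if not 0 < p_threshold < 1:
        raise ParameterError(f"p_threshold must be in (0,1), got {p_threshold}")
    if len(exposure) == 0:
        raise ParameterError("exposure summary statistics are empty")
    exposure = validate_sumstats(exposure)
    exclude = set(exclude or ())
    counts = {"candidates": len(exposure)}

    sig = exposure["pval"] < p_threshold
    counts["below_threshold"] = int((~sig).sum())
    df = exposure[sig]

    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    maf_ok = (maf > maf_min) | df["eaf"].isna()  # missing eaf kept, flagged below
    counts["maf_filtered"] = int((~maf_ok).sum())
    df = df[maf_ok]

    excl = df["snp"].isin(exclude)
    counts["excluded"] = int(excl.sum())
    df = df[~excl]

    # greedy clumping
    pruned = 0
    if ld is not None and len(df):
        order = df.sort_values(["pval", "snp"], kind="mergesort")
        accepted: list[str] = []
        keep_ids = []
        for rec in order.itertuples(index=False):
            clash = any(
                ld.r2_between(rec.snp, a) >= r2_limit and ld.within_window(rec.snp, a, window_kb)
                for a in accepted
            )
            if clash:
                pruned += 1
            else:
                accepted.append(rec.snp)
                keep_ids.append(rec.snp)
        df = df[df["snp"].isin(keep_ids)]
    counts["pruned"] = pruned

    data = pd.DataFrame({
        "snp": df["snp"].to_numpy(),
        "effect_allele": df["effect_allele"].to_numpy(),
        "other_allele": df["other_allele"].to_numpy(),
        "eaf": df["eaf"].to_numpy(float),
        "beta_exposure": df["beta"].to_numpy(float),
        "se_exposure": df["se"].to_numpy(float),
        "pval_exposure": df["pval"].to_numpy(float),
        "beta_outcome": np.nan,
        "se_outcome": np.nan,
        "palindromic": [
            _is_palindromic(e, o)
            for e, o in zip(df["effect_allele"], df["other_allele"])
        ],
        "flipped": False,
        "eaf_missing": df["eaf"].isna().to_numpy(),
    }).reset_index(drop=True)

    params = {"p_threshold": p_threshold, "window_kb": window_kb,
              "r2_limit": r2_limit, "maf_min": maf_min,
              "n_excluded_listed": len(exclude)}
    return InstrumentSet(data=data, counts=counts, params=params,
                         exposure_name=exposure_name)


def harmonize(
    exposure_side: InstrumentSet,
    outcome: pd.DataFrame,
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
    drop_palindromic_ambiguous: bool = True,
    outcome_name: str = "outcome",
) -> InstrumentSet:
    """Align outcome effects onto the exposure's effect allele.

    Returns a full InstrumentSet; drops (with counts) SNPs missing from the
    outcome, irreconcilable allele pairs, and ambiguous palindromes.
    """
    outcome = validate_sumstats(outcome).set_index("snp")
    lo, hi = palindrome_eaf_band
    counts = dict(exposure_side.counts)
    counts.setdefault("missing_in_outcome", 0)
    counts.setdefault("irreconcilable", 0)
    counts.setdefault("ambiguous_palindromic", 0)

    rows = []
    for rec in exposure_side.data.itertuples(index=False):
        if rec.snp not in outcome.index:
            counts["missing_in_outcome"] += 1
            continue
        orec = outcome.loc[rec.snp]
        o_ea, o_oa = orec["effect_allele"], orec["other_allele"]
        o_beta, o_se, o_eaf = float(orec["beta"]), float(orec["se"]), float(orec["eaf"])

        exp_pair = (rec.effect_allele, rec.other_allele)
        flipped = False
        if rec.palindromic:
            # alleles always "match"; orientation must come from frequency
            if (o_ea, o_oa) not in (exp_pair, exp_pair[::-1]):
                counts["irreconcilable"] += 1
                continue
            e_eaf = rec.eaf
            inferable = (
                not np.isnan(e_eaf) and not np.isnan(o_eaf)
                and not (lo <= e_eaf <= hi) and not (lo <= o_eaf <= hi)
            )
            if inferable:
                # same minor/major orientation on both sides -> aligned;
                # opposite -> the outcome file reports the complement strand's
                # "same" allele, i.e. effectively the other allele
                if (e_eaf < 0.5) != (o_eaf < 0.5):
                    o_beta, o_eaf, flipped = -o_beta, 1 - o_eaf, True
            else:
                if drop_palindromic_ambiguous:
                    counts["ambiguous_palindromic"] += 1
                    continue
                # kept as-is, flagged ambiguous
        else:
            if (o_ea, o_oa) == exp_pair:
                pass
            elif (o_ea, o_oa) == exp_pair[::-1]:
                o_beta, o_eaf, flipped = -o_beta, 1 - o_eaf, True
            else:
                comp = (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa])
                if comp == exp_pair:
                    pass  # strand flip only
                elif comp == exp_pair[::-1]:
                    o_beta, o_eaf, flipped = -o_beta, 1 - o_eaf, True
                else:
                    counts["irreconcilable"] += 1
                    continue
        rows.append({
            "snp": rec.snp, "effect_allele": rec.effect_allele,
            "other_allele": rec.other_allele, "eaf": rec.eaf,
            "beta_exposure": rec.beta_exposure, "se_exposure": rec.se_exposure,
            "pval_exposure": rec.pval_exposure,
            "beta_outcome": o_beta, "se_outcome": o_se,
            "palindromic": rec.palindromic, "flipped": flipped,
            "eaf_missing": rec.eaf_missing,
        })

    data = pd.DataFrame(rows, columns=list(exposure_side.data.columns))
    return InstrumentSet(
        data=data.reset_index(drop=True), counts=counts,
        params=dict(exposure_side.params,
                    palindrome_eaf_band=list(palindrome_eaf_band),
                    drop_palindromic_ambiguous=drop_palindromic_ambiguous),
        exposure_name=exposure_side.exposure_name, outcome_name=outcome_name,
    )


def from_simulated(exposure: pd.DataFrame, outcome: pd.DataFrame,
                   p_threshold: float = 5e-8, maf_min: float = 0.01,
                   exposure_name: str = "exposure",
                   outcome_name: str = "outcome") -> InstrumentSet:
    """Select + harmonize in one step for LD-free (simulated) panels."""
    skel = select_instruments(exposure, p_threshold=p_threshold, maf_min=maf_min,
                              exposure_name=exposure_name)
    return harmonize(skel, outcome, outcome_name=outcome_name)
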