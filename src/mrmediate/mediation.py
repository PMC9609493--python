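"""Multivariable MR and the two-step mediation decomposition.

Multivariable MR (MVMR) regresses per-SNP outcome effects on the matrix of
exposure effects (no intercept, weights se_y^-2): each coefficient is the
direct effect of that exposure holding the others fixed.  Instruments are
the union of the single-trait instrument sets, intersected with
availability in every dataset.

The two-step mediation decomposition for exposure X, mediators M_k and
outcome Y:

    beta1_k : X -> M_k   univariable IVW on X's instruments
    beta2_k : M_k -> Y   coefficient of M_k in the MVMR of Y on (X, M_1..)
    beta3   : X -> Y     coefficient of X in the same MVMR (direct effect)
    total   : X -> Y     univariable IVW

Product method:    indirect = sum_k beta1_k * beta2_k,
                   E% = indirect / (beta3 + indirect)
Difference method: indirect = total - beta3, E% = indirect / total

The product-of-coefficients E% is the default: the sum in its denominator
reconstructs the total from the fitted path coefficients, so it is internally
consistent even when the two univariable fits disagree slightly.  Both
methods agree asymptotically for a single mediator with valid instruments.
Indirect-effect SEs use the delta method
sqrt(beta1^2 se(beta2)^2 + beta2^2 se(beta1)^2); the E% interval propagates
the indirect CI against a fixed denominator and is reported as approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, InsufficientInstrumentsError, ParameterError
from .estimators import MRResult, Z975, ivw
from .instruments import _COMPLEMENT, from_simulated
from .sumstats import validate_sumstats


@dataclass
class MVMRResult:
    """Joint direct-effect estimates for a set of exposures."""

    exposures: list[str]
    beta: dict[str, float]
    se: dict[str, float]
    pval: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_snps: int
    conditional_f: dict[str, float]
    dropped_missing: int = 0

    def or_scale(self, name: str) -> tuple[float, float, float]:
        return (math.exp(self.beta[name]), math.exp(self.ci_low[name]),
                math.exp(self.ci_high[name]))

    def to_rows(self) -> list[dict]:
        rows = []
        for name in self.exposures:
            orr, lo, hi = self.or_scale(name)
            rows.append({
                "exposure": name, "beta": self.beta[name], "se": self.se[name],
                "ci_low": self.ci_low[name], "ci_high": self.ci_high[name],
                "pval": self.pval[name], "or": orr, "or_ci_low": lo,
                "or_ci_high": hi, "n_snps": self.n_snps,
                "conditional_f": self.conditional_f[name],
            })
        return rows


@dataclass
class MediationDecomposition:
    """Path coefficients and the proportion mediated (E%)."""

    mediators: list[str]
    beta1: dict[str, float]
    beta1_se: dict[str, float]
    beta2: dict[str, float]
    beta2_se: dict[str, float]
    beta3: float
    beta3_se: float
    total: float
    total_se: float
    indirect: dict[str, float]          # per-mediator beta1*beta2
    indirect_se: dict[str, float]       # delta method
    indirect_sum: float
    indirect_sum_se: float
    proportion_mediated: float          # E% on the 0-100 scale, chosen method
    proportion_ci: tuple[float, float]  # approximate, propagated
    method: str                         # "product" | "difference"
    inconsistent: bool = False          # total and indirect of opposite sign
    proportion_by_method: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "mediators": "+".join(self.mediators),
            "beta3": self.beta3, "beta3_se": self.beta3_se,
            "total": self.total, "total_se": self.total_se,
            "indirect_sum": self.indirect_sum,
            "indirect_sum_se": self.indirect_sum_se,
            "proportion_mediated_pct": self.proportion_mediated,
            "proportion_ci_low_pct": self.proportion_ci[0],
            "proportion_ci_high_pct": self.proportion_ci[1],
            "method": self.method, "inconsistent": self.inconsistent,
        }


def _aligned_beta(ref_ea: str, ref_oa: str, ea: str, oa: str,
                  beta: float) -> float | None:
    """Orient one trait's beta onto the reference effect allele, or None."""
    if (ea, oa) == (ref_ea, ref_oa):
        return beta
    if (ea, oa) == (ref_oa, ref_ea):
        return -beta
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return beta
    if (cea, coa) == (ref_oa, ref_ea):
        return -beta
    return None


def build_mvmr_design(exposures: dict[str, pd.DataFrame], outcome: pd.DataFrame,
                      snps: list[str]) -> tuple[pd.DataFrame, int]:
    """Per-SNP effect matrix for all exposures plus the outcome.

    Alleles are oriented onto the first exposure's effect allele; SNPs
    missing from any dataset or with irreconcilable alleles are dropped and
    counted.  Returns (design frame, n dropped).
    """
    names = list(exposures)
    frames = {n: validate_sumstats(df).set_index("snp") for n, df in exposures.items()}
    out = validate_sumstats(outcome).set_index("snp")
    ref = frames[names[0]]
    rows, dropped = [], 0
    for snp in snps:
        if snp not in out.index or any(snp not in f.index for f in frames.values()):
            dropped += 1
            continue
        ref_ea = ref.loc[snp, "effect_allele"]
        ref_oa = ref.loc[snp, "other_allele"]
        row = {"snp": snp}
        ok = True
        for n in names:
            r = frames[n].loc[snp]
            b = _aligned_beta(ref_ea, ref_oa, r["effect_allele"],
                              r["other_allele"], float(r["beta"]))
            if b is None:
                ok = False
                break
            row[f"beta_{n}"] = b
            row[f"se_{n}"] = float(r["se"])
        r = out.loc[snp]
        b = _aligned_beta(ref_ea, ref_oa, r["effect_allele"], r["other_allele"],
                          float(r["beta"]))
        if ok and b is not None:
            row["beta_outcome"] = b
            row["se_outcome"] = float(r["se"])
            rows.append(row)
        else:
            dropped += 1
    return pd.DataFrame(rows), dropped


def mvmr_ivw(exposures: dict[str, pd.DataFrame], outcome: pd.DataFrame,
             snps: list[str], model: str = "random") -> MVMRResult:
    """Multivariable IVW: weighted least squares with no intercept.

    ``snps`` is the union instrument list.  SEs carry the same multiplicative
    overdispersion scaling as univariable random-effects IVW.  A per-exposure
    conditional instrument-strength statistic (F-like: mean squared
    instrument signal left after projecting out the other exposures, scaled
    by that exposure's measurement variance) is reported.
    """
    names = list(exposures)
    K = len(names)
    if K < 2:
        raise ParameterError("MVMR needs at least two exposures")
    design, dropped = build_mvmr_design(exposures, outcome, snps)
    J = len(design)
    if J < K + 1:
        raise InsufficientInstrumentsError(
            f"MVMR needs >= {K + 1} SNPs with complete data, got {J}")

    X = design[[f"beta_{n}" for n in names]].to_numpy(float)
    y = design["beta_outcome"].to_numpy(float)
    w = design["se_outcome"].to_numpy(float) ** -2.0

    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < K:
        norms = np.linalg.norm(Xw, axis=0)
        degenerate = [n for n, v in zip(names, norms) if v < 1e-12 * max(norms.max(), 1)]
        if degenerate:
            detail = f"exposure(s) with no instrument signal: {', '.join(map(repr, degenerate))}"
        else:
            c = np.corrcoef(X, rowvar=False)
            np.fill_diagonal(c, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(c)), c.shape)
            detail = f"most collinear pair: {names[i]!r} and {names[j]!r}"
        raise CollinearityError(
            f"exposure effect matrix is rank deficient (rank {rank} < {K}); {detail}")

    xtwx = X.T @ (X * w[:, None])
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    rss = float(np.sum(w * resid**2))
    sigma2 = max(1.0, rss / (J - K)) if model == "random" else rss / (J - K)
    cov = np.linalg.inv(xtwx) * sigma2
    ses = np.sqrt(np.diag(cov))

    cond_f = {}
    for k, name in enumerate(names):
        others = [i for i in range(K) if i != k]
        xk = X[:, k]
        se_k = design[f"se_{name}"].to_numpy(float)
        if others:
            Xo = X[:, others] * sw[:, None]
            delta, *_ = np.linalg.lstsq(Xo, xk * sw, rcond=None)
            e = xk - X[:, others] @ delta
        else:
            e = xk
        cond_f[name] = float(np.mean(e**2 / se_k**2))

    beta = {n: float(b) for n, b in zip(names, coef)}
    se = {n: float(s) for n, s in zip(names, ses)}
    pval = {n: float(2 * stats.norm.sf(abs(beta[n] / se[n]))) for n in names}
    return MVMRResult(
        exposures=names, beta=beta, se=se, pval=pval,
        ci_low={n: beta[n] - Z975 * se[n] for n in names},
        ci_high={n: beta[n] + Z975 * se[n] for n in names},
        n_snps=J, conditional_f=cond_f, dropped_missing=dropped,
    )


def _union_instruments(traits: dict[str, pd.DataFrame], p_threshold: float,
                       maf_min: float) -> list[str]:
    union: set[str] = set()
    for df in traits.values():
        sub = validate_sumstats(df)
        maf = np.minimum(sub["eaf"], 1 - sub["eaf"])
        keep = (sub["pval"] < p_threshold) & ((maf > maf_min) | sub["eaf"].isna())
        union |= set(sub.loc[keep, "snp"])
    return sorted(union)


def two_step_mediation(
    exposure: pd.DataFrame,
    mediators: dict[str, pd.DataFrame],
    outcome: pd.DataFrame,
    method: str = "product",
    p_threshold: float = 5e-8,
    maf_min: float = 0.01,
    ivw_model: str = "random",
    exposure_name: str = "exposure",
) -> MediationDecomposition:
    """Two-step MR mediation of one exposure through one or more mediators.

    ``method`` is ``"product"``, ``"difference"`` or ``"both"`` (headline =
    product, the other reported in ``proportion_by_method``).
    """
    if method not in ("product", "difference", "both"):
        raise ParameterError(f"method must be product|difference|both, got {method!r}")
    med_names = list(mediators)
    if not med_names:
        raise ParameterError("at least one mediator is required")

    # step 1: exposure -> mediator, univariable IVW on the exposure's instruments
    beta1, beta1_se = {}, {}
    for name, mdf in mediators.items():
        iv_xm = from_simulated(exposure, mdf, p_threshold=p_threshold,
                               maf_min=maf_min, exposure_name=exposure_name,
                               outcome_name=name)
        fit = ivw(iv_xm, model=ivw_model)
        beta1[name], beta1_se[name] = fit.beta, fit.se

    # total effect: exposure -> outcome, univariable IVW
    iv_xy = from_simulated(exposure, outcome, p_threshold=p_threshold,
                           maf_min=maf_min, exposure_name=exposure_name)
    total_fit = ivw(iv_xy, model=ivw_model)

    # step 2: joint MVMR of outcome on exposure + all mediators
    traits = {exposure_name: exposure, **mediators}
    union = _union_instruments(traits, p_threshold, maf_min)
    mv = mvmr_ivw(traits, outcome, union, model=ivw_model)
    beta2 = {n: mv.beta[n] for n in med_names}
    beta2_se = {n: mv.se[n] for n in med_names}
    beta3, beta3_se = mv.beta[exposure_name], mv.se[exposure_name]

    indirect = {n: beta1[n] * beta2[n] for n in med_names}
    indirect_se = {
        n: math.sqrt(beta1[n] ** 2 * beta2_se[n] ** 2
                     + beta2[n] ** 2 * beta1_se[n] ** 2)
        for n in med_names
    }
    ind_sum = sum(indirect.values())
    ind_sum_se = math.sqrt(sum(s**2 for s in indirect_se.values()))

    denom_prod = beta3 + ind_sum
    prop_prod = 100.0 * ind_sum / denom_prod if denom_prod != 0 else math.nan
    ind_diff = total_fit.beta - beta3
    prop_diff = 100.0 * ind_diff / total_fit.beta if total_fit.beta != 0 else math.nan

    by_method = {"product": prop_prod, "difference": prop_diff}
    headline_method = "difference" if method == "difference" else "product"
    headline = by_method[headline_method]

    if headline_method == "product":
        ind, ind_se, denom = ind_sum, ind_sum_se, denom_prod
    else:
        ind = ind_diff
        ind_se = math.sqrt(total_fit.se**2 + beta3_se**2)
        denom = total_fit.beta
    if denom != 0:
        ci = (100.0 * (ind - Z975 * ind_se) / denom,
              100.0 * (ind + Z975 * ind_se) / denom)
        ci = (min(ci), max(ci))
    else:
        ci = (math.nan, math.nan)

    inconsistent = (total_fit.beta * ind_sum) < 0
    return MediationDecomposition(
        mediators=med_names, beta1=beta1, beta1_se=beta1_se,
        beta2=beta2, beta2_se=beta2_se, beta3=beta3, beta3_se=beta3_se,
        total=total_fit.beta, total_se=total_fit.se,
        indirect=indirect, indirect_se=indirect_se,
        indirect_sum=ind_sum, indirect_sum_se=ind_sum_se,
        proportion_mediated=headline, proportion_ci=ci,
        method=headline_method, inconsistent=inconsistent,
        proportion_by_method=by_method if method == "both" else {headline_method: headline},
    )
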