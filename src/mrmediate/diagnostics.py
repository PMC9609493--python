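"""Heterogeneity, pleiotropy, influence and outlier diagnostics.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the IVW
mean on a chi-square(J-1) reference; I^2 = max(0, (Q - df)/Q) expresses the
excess as a fraction.  The Egger intercept test reads average directional
pleiotropy off the MR-Egger fit.  Leave-one-out recomputes IVW with each
SNP removed and flags influential variants.  MR-PRESSO simulates the null
distribution of the residual sum of squares built from leave-one-out slopes
(so an outlier cannot mask itself), flags per-SNP outliers with a Bonferroni
correction, re-estimates without them, and tests whether removal distorts
the causal slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError, ParameterError
from .estimators import MRResult, _ratios, ivw, mr_egger
from .instruments import InstrumentSet


@dataclass
class HeterogeneityReport:
    """Cochran's Q and Egger-intercept pleiotropy summary for one edge."""

    method: str
    cochran_q: float
    df: int
    pval: float
    i_squared: float
    egger_intercept: float = math.nan
    egger_intercept_se: float = math.nan
    egger_intercept_ci: tuple[float, float] = (math.nan, math.nan)
    egger_intercept_pval: float = math.nan

    def to_row(self) -> dict:
        return {
            "method": self.method, "cochran_q": self.cochran_q, "df": self.df,
            "q_pval": self.pval, "i_squared": self.i_squared,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_ci_low": self.egger_intercept_ci[0],
            "egger_intercept_ci_high": self.egger_intercept_ci[1],
            "egger_intercept_pval": self.egger_intercept_pval,
        }


@dataclass
class PressoReport:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_observed: float
    global_pval: float
    global_pval_label: str
    outlier_pvals: pd.Series        # per-SNP, Bonferroni-adjusted
    outlier_ids: list[str]
    raw_estimate: MRResult
    corrected_estimate: MRResult | None
    distortion_pval: float
    n_sim: int
    seed: int


def cochran_q(iv: InstrumentSet) -> HeterogeneityReport:
    """Cochran's Q of the Wald ratios with first-order IVW weights."""
    if len(iv) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    theta, se = _ratios(iv)
    w = se**-2
    mean = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - mean) ** 2))
    df = len(iv) - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityReport("IVW", q, df, max(p, np.nextafter(0, 1)), i2)


def egger_intercept_test(iv: InstrumentSet) -> HeterogeneityReport:
    """Directional-pleiotropy test from the MR-Egger intercept (t, J-2 df)."""
    fit = mr_egger(iv)
    # Q on J-2 df around the Egger fit
    theta, se = _ratios(iv)
    base = cochran_q(iv)
    ex = fit.extras
    return HeterogeneityReport(
        "MR-Egger", base.cochran_q, len(iv) - 2,
        float(stats.chi2.sf(base.cochran_q, len(iv) - 2)), base.i_squared,
        egger_intercept=ex["intercept"], egger_intercept_se=ex["intercept_se"],
        egger_intercept_ci=(ex["intercept_ci_low"], ex["intercept_ci_high"]),
        egger_intercept_pval=ex["intercept_pval"],
    )


def leave_one_out(iv: InstrumentSet, ivw_model: str = "random",
                  alpha: float = 0.05) -> pd.DataFrame:
    """IVW re-estimated with each SNP removed, plus the all-SNP row.

    Flags SNPs whose removal moves the estimate across zero or the p-value
    across ``alpha``.
    """
    if len(iv) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 instruments")
    full = ivw(iv, model=ivw_model)
    rows = []
    n = len(iv)
    for j in range(n):
        mask = np.ones(n, dtype=bool)
        mask[j] = False
        fit = ivw(iv.subset(mask), model=ivw_model)
        rows.append({
            "snp": iv.snp_ids[j], "beta": fit.beta, "se": fit.se,
            "ci_low": fit.ci_low, "ci_high": fit.ci_high, "pval": fit.pval,
            "crosses_zero": (fit.beta * full.beta) < 0,
            "crosses_alpha": (fit.pval < alpha) != (full.pval < alpha),
        })
    rows.append({
        "snp": "ALL", "beta": full.beta, "se": full.se,
        "ci_low": full.ci_low, "ci_high": full.ci_high, "pval": full.pval,
        "crosses_zero": False, "crosses_alpha": False,
    })
    return pd.DataFrame(rows)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out zero-intercept WLS slopes, O(J) via sum subtraction."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def mr_presso(iv: InstrumentSet, n_sim: int = 5000, outlier_alpha: float = 0.05,
              seed: int = 0, ivw_model: str = "random") -> PressoReport:
    """MR-PRESSO global heterogeneity, outlier and distortion tests.

    The observed statistic is RSS = sum_j w_j (beta_y_j - slope_(-j) *
    beta_x_j)^2 with leave-one-out slopes; its null distribution comes from
    ``n_sim`` parametric draws beta_y* ~ N(slope_(-j) beta_x_j, se_y^2),
    beta_x* ~ N(beta_x_j, se_x^2), each re-analysed with leave-one-out
    slopes.  Per-SNP outlier p-values are Bonferroni-adjusted; the corrected
    estimate is IVW on the non-flagged subset; the distortion p-value
    compares the observed raw-vs-corrected slope shift against shifts from
    removing equally many random SNPs.
    """
    J = len(iv)
    if J < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 1000:
        raise ParameterError(f"n_sim must be >= 1000, got {n_sim}")
    rng = np.random.default_rng(seed)
    bx, sx = iv.beta_exposure, iv.se_exposure
    by, sy = iv.beta_outcome, iv.se_outcome
    w = sy**-2.0

    slopes_loo = _loo_slopes(bx, by, w)
    obs_terms = w * (by - slopes_loo * bx) ** 2
    obs_rss = float(np.sum(obs_terms))

    # parametric null, fully vectorized over simulations
    bx_sim = rng.normal(bx, sx, size=(n_sim, J))
    by_sim = rng.normal(slopes_loo * bx, sy, size=(n_sim, J))
    s_xy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_sim * bx_sim, axis=1, keepdims=True)
    slopes_sim = (s_xy - w * bx_sim * by_sim) / (s_xx - w * bx_sim * bx_sim)
    sim_terms = w * (by_sim - slopes_sim * bx_sim) ** 2
    sim_rss = np.sum(sim_terms, axis=1)

    exceed = int(np.sum(sim_rss >= obs_rss))
    if exceed == 0:
        global_pval = 1.0 / n_sim
        label = f"< {1.0 / n_sim:g}"
    else:
        global_pval = exceed / n_sim
        label = f"{global_pval:g}"

    per_snp_p = np.mean(sim_terms >= obs_terms, axis=0)
    adj = np.minimum(1.0, per_snp_p * J)
    outlier_pvals = pd.Series(adj, index=iv.snp_ids, name="presso_outlier_pval")
    out_mask = adj < outlier_alpha
    outlier_ids = [s for s, m in zip(iv.snp_ids, out_mask) if m]

    raw = ivw(iv, model=ivw_model)
    corrected = None
    distortion_pval = math.nan
    n_out = int(out_mask.sum())
    if n_out and J - n_out >= 2:
        corrected = ivw(iv.subset(~out_mask), model=ivw_model)
        if corrected.beta != 0:
            d_obs = (raw.beta - corrected.beta) / abs(corrected.beta)
            n_draw = min(n_sim, 2000)
            d_null = np.empty(n_draw)
            for i in range(n_draw):
                drop = rng.choice(J, size=n_out, replace=False)
                keep = np.ones(J, dtype=bool)
                keep[drop] = False
                slope = (np.sum(w[keep] * bx[keep] * by[keep])
                         / np.sum(w[keep] * bx[keep] ** 2))
                d_null[i] = (slope - corrected.beta) / abs(corrected.beta)
            distortion_pval = float(np.mean(np.abs(d_null) >= abs(d_obs)))

    return PressoReport(
        global_rss_observed=obs_rss, global_pval=global_pval,
        global_pval_label=label, outlier_pvals=outlier_pvals,
        outlier_ids=outlier_ids, raw_estimate=raw,
        corrected_estimate=corrected, distortion_pval=distortion_pval,
        n_sim=n_sim, seed=seed,
    )


def plot_data(iv: InstrumentSet, results: list[MRResult]) -> dict[str, pd.DataFrame]:
    """Tidy coordinate tables for scatter, forest and funnel plots.

    Rendering is left to any plotting layer; these tables carry everything
    the standard MR figures show.
    """
    if not results:
        raise ParameterError("results must be non-empty")
    theta, se = _ratios(iv)
    scatter = pd.DataFrame({
        "snp": iv.snp_ids,
        "beta_exposure": iv.beta_exposure, "se_exposure": iv.se_exposure,
        "beta_outcome": iv.beta_outcome, "se_outcome": iv.se_outcome,
    })
    lines = pd.DataFrame([
        {"method": r.method, "slope": r.beta,
         "intercept": r.extras.get("intercept", 0.0)}
        for r in results
    ])
    z = stats.norm.ppf(0.975)
    forest_rows = [
        {"label": s, "kind": "snp", "beta": t, "ci_low": t - z * e,
         "ci_high": t + z * e}
        for s, t, e in zip(iv.snp_ids, theta, se)
    ] + [
        {"label": r.method, "kind": "summary", "beta": r.beta,
         "ci_low": r.ci_low, "ci_high": r.ci_high}
        for r in results
    ]
    funnel = pd.DataFrame({
        "snp": iv.snp_ids, "theta": theta, "precision": 1.0 / se,
    })
    return {
        "scatter": scatter, "scatter_lines": lines,
        "forest": pd.DataFrame(forest_rows), "funnel": funnel,
    }


def funnel_asymmetry(iv: InstrumentSet) -> float:
    """Precision-weighted mean deviation of Wald ratios from the IVW summary.

    Near zero for balanced pleiotropy; signed away from zero when small
    (imprecise) instruments drift in one direction.
    """
    theta, se = _ratios(iv)
    w = se**-2
    summary = np.sum(w * theta) / np.sum(w)
    return float(np.mean(theta - summary))
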