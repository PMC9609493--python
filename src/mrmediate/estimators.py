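"""Univariable two-sample MR estimators.

All estimators consume a harmonized :class:`~mrmediate.instruments.InstrumentSet`
and return an :class:`MRResult` on the log scale with an odds-ratio view.

Per-SNP Wald ratio: theta_j = beta_y_j / beta_x_j with first-order SE
se_y_j / |beta_x_j| (second-order optional).  IVW is the inverse-variance
weighted mean of the Wald ratios, identical to the zero-intercept weighted
least-squares slope of beta_y on beta_x with weights se_y^-2; the default
multiplicative random-effects model inflates the fixed-effect SE by
max(1, sqrt(Q / (J - 1))).  MR-Egger frees the intercept (average
directional pleiotropy) after orienting all exposure betas positive and uses
a t(J-2) reference.  The weighted median interpolates the Wald-ratio order
statistics at cumulative weight 1/2, with a seeded parametric bootstrap SE,
and is consistent when under half the weight is on invalid instruments.
Maximum likelihood profiles a bivariate normal measurement model in the
causal slope; RAPS solves the adjusted profile score with optional Huber
robustification and an overdispersion variance tau^2 for systematic
pleiotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError, InsufficientInstrumentsError, ParameterError
from .instruments import InstrumentSet

Z975 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    """One estimator's causal estimate on the log(-odds) scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    ci_low: float = math.nan
    ci_high: float = math.nan
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - Z975 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + Z975 * self.se

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) = elementwise exp of the log-scale triple."""
        return (math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high))

    def to_row(self) -> dict:
        orr, lo, hi = self.or_scale
        row = {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "pval": self.pval,
            "or": orr, "or_ci_low": lo, "or_ci_high": hi, "n_snps": self.n_snps,
        }
        row.update(self.extras)
        return row


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               second_order: bool = False) -> tuple[float, float]:
    """Per-SNP causal estimate theta = beta_y / beta_x and its SE."""
    if beta_x == 0:
        raise ParameterError("Wald ratio undefined for beta_x = 0")
    theta = beta_y / beta_x
    if second_order:
        var = se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4
        return theta, math.sqrt(var)
    return theta, se_y / abs(beta_x)


def _ratios(iv: InstrumentSet, second_order: bool = False):
    bx, sx = iv.beta_exposure, iv.se_exposure
    by, sy = iv.beta_outcome, iv.se_outcome
    if np.any(bx == 0):
        raise ParameterError("Wald ratio undefined for beta_exposure = 0")
    theta = by / bx
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / np.abs(bx)
    return theta, se


def _require(iv: InstrumentSet, n_min: int, method: str):
    if len(iv) < n_min:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {n_min} instruments, got {len(iv)}")


def cochran_q_stat(iv: InstrumentSet, second_order: bool = False) -> tuple[float, int]:
    """Cochran's Q over the Wald ratios with inverse-variance weights."""
    theta, se = _ratios(iv, second_order)
    w = se**-2
    mean = np.sum(w * theta) / np.sum(w)
    return float(np.sum(w * (theta - mean) ** 2)), len(iv) - 1


def ivw(iv: InstrumentSet, model: str = "random", second_order: bool = False) -> MRResult:
    """Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios.

    ``model="fixed"`` uses se = (sum w_j)^-1/2; ``"random"`` (default) is the
    multiplicative random-effects model, inflating by max(1, sqrt(Q/(J-1))).
    """
    _require(iv, 2, "IVW")
    if model not in ("fixed", "random"):
        raise ParameterError(f"model must be fixed|random, got {model!r}")
    theta, se = _ratios(iv, second_order)
    w = se**-2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q, df = cochran_q_stat(iv, second_order)
    scale = max(1.0, math.sqrt(q / df)) if (model == "random" and df > 0) else 1.0
    se_hat = se_fixed * scale
    p = 2 * stats.norm.sf(abs(beta / se_hat))
    return MRResult("IVW", beta, se_hat, float(p), len(iv),
                    extras={"cochran_q": q, "q_df": df, "model": model})


def mr_egger(iv: InstrumentSet, model: str = "random") -> MRResult:
    """MR-Egger regression: WLS of beta_y on beta_x with a free intercept.

    Rows are first oriented so every exposure beta is non-negative (the
    estimator is defined up to that orientation); the intercept estimates
    average directional pleiotropy.  Inference uses t(J-2).
    """
    _require(iv, 3, "MR-Egger")
    bx = iv.beta_exposure.copy()
    by = iv.beta_outcome.copy()
    sy = iv.se_outcome
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = sy**-2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    J = len(bx)
    rss = float(np.sum(w * resid**2))
    sigma2 = max(1.0, rss / (J - 2)) if model == "random" else rss / (J - 2)
    cov = np.linalg.inv(xtwx) * sigma2
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    tdist = stats.t(J - 2)
    p_slope = 2 * tdist.sf(abs(coef[1] / se_slope))
    p_int = 2 * tdist.sf(abs(coef[0] / se_int))
    tcrit = tdist.ppf(0.975)
    return MRResult(
        "MR-Egger", float(coef[1]), se_slope, float(p_slope), J,
        ci_low=float(coef[1] - tcrit * se_slope),
        ci_high=float(coef[1] + tcrit * se_slope),
        extras={
            "intercept": float(coef[0]), "intercept_se": se_int,
            "intercept_pval": float(p_int),
            "intercept_ci_low": float(coef[0] - tcrit * se_int),
            "intercept_ci_high": float(coef[0] + tcrit * se_int),
        },
    )


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: cumulative normalized weights, with the
    j-th order statistic placed at s_j - w_j/2 (midpoint convention)."""
    order = np.argsort(theta, kind="mergesort")
    t, ww = theta[order], w[order] / np.sum(w)
    s = np.cumsum(ww) - ww / 2
    return float(np.interp(0.5, s, t))


def weighted_median(iv: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap SE (seeded)."""
    import warnings

    _require(iv, 3, "weighted-median")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is below 100; bootstrap SE will be noisy",
                      stacklevel=2)
    theta, se = _ratios(iv)
    w = se**-2
    est = _weighted_median(theta, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se, size=(n_boot, len(theta)))
    boots = np.array([_weighted_median(d, w) for d in draws])
    se_hat = float(np.std(boots, ddof=1))
    p = 2 * stats.norm.sf(abs(est / se_hat))
    return MRResult("weighted-median", est, se_hat, float(p), len(iv),
                    extras={"n_boot": n_boot})


def _profile_negloglik(theta: float, bx, sx, by, sy) -> float:
    """Negative profile log-likelihood in the causal slope.

    The per-SNP true instrument strengths are profiled out analytically
    (gamma_j_hat is a precision-weighted blend of beta_x_j and beta_y_j/theta),
    leaving 0.5 * sum (beta_y - theta beta_x)^2 / (se_y^2 + theta^2 se_x^2);
    the normalization constants do not involve theta.
    """
    v = sy**2 + theta**2 * sx**2
    return float(0.5 * np.sum((by - theta * bx) ** 2 / v))


def max_likelihood(iv: InstrumentSet, tol: float = 1e-10) -> MRResult:
    """Maximum-likelihood estimate under the bivariate normal error model."""
    _require(iv, 2, "maximum-likelihood")
    bx, sx = iv.beta_exposure, iv.se_exposure
    by, sy = iv.beta_outcome, iv.se_outcome
    start = ivw(iv, model="fixed").beta
    span = max(1.0, 10 * abs(start))
    res = optimize.minimize_scalar(
        _profile_negloglik, args=(bx, sx, by, sy),
        bounds=(start - span, start + span), method="bounded",
        options={"xatol": tol},
    )
    if not res.success:
        raise ConvergenceError("profile likelihood optimization failed", trace=[res])
    est = float(res.x)
    # observed information from the profile curvature
    h = max(1e-6, 1e-6 * abs(est))
    f0 = _profile_negloglik(est, bx, sx, by, sy)
    fp = _profile_negloglik(est + h, bx, sx, by, sy)
    fm = _profile_negloglik(est - h, bx, sx, by, sy)
    info = (fp - 2 * f0 + fm) / h**2
    if info <= 0:
        raise ConvergenceError("non-positive profile curvature at optimum", trace=[res])
    se_hat = info**-0.5
    p = 2 * stats.norm.sf(abs(est / se_hat))
    return MRResult("maximum-likelihood", est, se_hat, float(p), len(iv),
                    extras={"loglik": -f0})


_HUBER_C = 1.345
# E[psi(Z) * Z] for standard normal Z: 1 for identity, 2*Phi(c)-1 for Huber
_HUBER_DELTA = 2 * stats.norm.cdf(_HUBER_C) - 1


def _psi(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "squared":
        return t
    return np.clip(t, -_HUBER_C, _HUBER_C)


def _raps_score(theta: float, tau2: float, bx, sx, by, sy, loss: str) -> float:
    """Adjusted profile score in theta at fixed tau^2.

    With identity psi this is exactly the derivative of the profile
    log-likelihood (overdispersed by tau^2), so squared-loss RAPS with
    tau^2 = 0 matches the ML profile estimate.
    """
    v = sy**2 + theta**2 * sx**2 + tau2
    s = np.sqrt(v)
    t = (by - theta * bx) / s
    return float(np.sum(_psi(t, loss) * (bx / s + theta * sx**2 * t / v)))


def _tau2_moment(theta: float, tau2: float, bx, sx, by, sy, loss: str) -> float:
    v = sy**2 + theta**2 * sx**2 + tau2
    t = (by - theta * bx) / np.sqrt(v)
    delta = 1.0 if loss == "squared" else _HUBER_DELTA
    return float(np.mean(_psi(t, loss) * t) - delta)


def raps(iv: InstrumentSet, loss: str = "squared",
         overdispersion: bool = False) -> MRResult:
    """Robust adjusted profile score estimator.

    Solves the adjusted profile estimating equation for the causal slope;
    with ``overdispersion`` a pleiotropy variance tau^2 (floored at 0) is
    solved jointly from its moment equation.  ``loss`` is ``"squared"`` or
    ``"huber"`` (constant 1.345).  SE by sandwich formula.
    """
    _require(iv, 3, "RAPS")
    if loss not in ("squared", "huber"):
        raise ParameterError(f"loss must be squared|huber, got {loss!r}")
    bx, sx = iv.beta_exposure, iv.se_exposure
    by, sy = iv.beta_outcome, iv.se_outcome

    def rho_loss(theta: float, tau2: float) -> float:
        # integrated loss whose stationary point is the score root
        v = sy**2 + theta**2 * sx**2 + tau2
        t = (by - theta * bx) / np.sqrt(v)
        if loss == "squared":
            r = 0.5 * t**2
        else:
            a = np.abs(t)
            r = np.where(a <= _HUBER_C, 0.5 * t**2,
                         _HUBER_C * a - 0.5 * _HUBER_C**2)
        return float(np.sum(r))

    def solve_theta(tau2: float) -> float:
        center = ivw(iv, model="fixed").beta
        width = max(0.5, 5 * abs(center))
        for _ in range(12):
            lo, hi = center - width, center + width
            flo = _raps_score(lo, tau2, bx, sx, by, sy, loss)
            fhi = _raps_score(hi, tau2, bx, sx, by, sy, loss)
            if flo * fhi < 0:
                return float(optimize.brentq(
                    _raps_score, lo, hi, args=(tau2, bx, sx, by, sy, loss),
                    xtol=1e-12))
            # bounded psi can deny a sign change; fall back to minimizing the
            # integrated loss (the score is its negative derivative)
            res = optimize.minimize_scalar(rho_loss, args=(tau2,),
                                           bounds=(lo, hi), method="bounded",
                                           options={"xatol": 1e-12})
            margin = 1e-6 * width
            if res.success and lo + margin < res.x < hi - margin:
                return float(res.x)
            width *= 2
        raise ConvergenceError("no RAPS score root or interior loss minimum "
                               "found after bracket expansion")

    tau2 = 0.0
    theta = solve_theta(tau2)
    if overdispersion:
        for _ in range(50):
            # tau2 moment equation at the current slope
            f0 = _tau2_moment(theta, 0.0, bx, sx, by, sy, loss)
            if f0 <= 0:
                tau2_new = 0.0
            else:
                hi = float(np.var(by - theta * bx)) + 1.0
                tau2_new = float(optimize.brentq(
                    lambda t2: _tau2_moment(theta, t2, bx, sx, by, sy, loss),
                    0.0, hi, xtol=1e-14))
            theta_new = solve_theta(tau2_new)
            if abs(theta_new - theta) < 1e-12 and abs(tau2_new - tau2) < 1e-14:
                theta, tau2 = theta_new, tau2_new
                break
            theta, tau2 = theta_new, tau2_new

    # sandwich: var = B / A^2 with A = d score/d theta, B = sum of squared
    # per-SNP score contributions
    h = max(1e-7, 1e-7 * abs(theta))
    A = (_raps_score(theta + h, tau2, bx, sx, by, sy, loss)
         - _raps_score(theta - h, tau2, bx, sx, by, sy, loss)) / (2 * h)
    v = sy**2 + theta**2 * sx**2 + tau2
    s = np.sqrt(v)
    t = (by - theta * bx) / s
    contrib = _psi(t, loss) * (bx / s + theta * sx**2 * t / v)
    B = float(np.sum(contrib**2))
    if A == 0:
        raise ConvergenceError("flat RAPS score; cannot form sandwich variance")
    se_hat = math.sqrt(B) / abs(A)
    p = 2 * stats.norm.sf(abs(theta / se_hat))
    return MRResult("RAPS", float(theta), se_hat, float(p), len(iv),
                    extras={"tau2": tau2, "loss": loss,
                            "overdispersion": overdispersion})


ALL_METHODS = {
    "IVW": ivw,
    "MR-Egger": mr_egger,
    "weighted-median": weighted_median,
    "maximum-likelihood": max_likelihood,
    "RAPS": raps,
}


def run_all(iv: InstrumentSet, n_boot: int = 1000, seed: int = 0,
            ivw_model: str = "random") -> list[MRResult]:
    """All five estimators on one instrument set, in a fixed order."""
    return [
        ivw(iv, model=ivw_model),
        mr_egger(iv),
        weighted_median(iv, n_boot=n_boot, seed=seed),
        max_likelihood(iv),
        raps(iv, overdispersion=True),
    ]
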