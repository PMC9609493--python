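"""Univariable estimators against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate import (
    InsufficientInstrumentsError,
    ParameterError,
    ivw,
    max_likelihood,
    mr_egger,
    raps,
    wald_ratio,
    weighted_median,
)
from conftest import make_iv


# ---------------------------------------------------------------- Wald ratio

def test_wald_ratio_hand_arithmetic():
    theta, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
    assert theta == pytest.approx(0.5)
    assert se == pytest.approx(0.2)


def test_wald_ratio_null_numerator():
    theta, se = wald_ratio(0.1, 0.01, 0.0, 0.02)
    assert theta == 0.0 and se == pytest.approx(0.2)


def test_wald_ratio_second_order():
    theta, se = wald_ratio(0.1, 0.01, 0.05, 0.02, second_order=True)
    expected = math.sqrt(0.02**2 / 0.1**2 + 0.05**2 * 0.01**2 / 0.1**4)
    assert se == pytest.approx(expected)


def test_wald_ratio_zero_exposure_is_error():
    with pytest.raises(ParameterError):
        wald_ratio(0.0, 0.01, 0.05, 0.02)


def test_wald_ratio_units_covariance():
    t1, _ = wald_ratio(0.1, 0.01, 0.05, 0.02)
    t2, _ = wald_ratio(0.3, 0.03, 0.05, 0.02)
    assert t2 == pytest.approx(t1 / 3)


# ------------------------------------------------------------------- IVW

def test_ivw_closed_form_weighted_mean():
    iv = make_iv(bx=[1, 1, 1], sx=[0.01] * 3, by=[0.2, 0.4, 0.6], sy=[0.1] * 3)
    res = ivw(iv, model="fixed")
    assert res.beta == pytest.approx(0.4)
    assert res.se == pytest.approx(0.1 / math.sqrt(3))


def test_ivw_degenerate_homogeneity():
    iv = make_iv(bx=[0.1, 0.2, 0.4], sx=[0.01] * 3,
                 by=[0.05, 0.10, 0.20], sy=[0.02, 0.04, 0.08])
    res = ivw(iv)
    assert res.beta == pytest.approx(0.5)
    assert res.extras["cochran_q"] == pytest.approx(0.0, abs=1e-20)


def test_ivw_equals_zero_intercept_wls():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = rng.integers(3, 40)
        bx = rng.normal(0.1, 0.05, n)
        bx[bx == 0] = 0.01
        iv = make_iv(bx=bx, sx=rng.uniform(0.005, 0.02, n),
                     by=rng.normal(0, 0.05, n), sy=rng.uniform(0.01, 0.1, n))
        w = iv.se_outcome**-2.0
        slope = np.sum(w * iv.beta_exposure * iv.beta_outcome) / np.sum(
            w * iv.beta_exposure**2)
        assert ivw(iv).beta == pytest.approx(slope, abs=1e-10)


def test_ivw_random_effects_inflates_se():
    iv = make_iv(bx=[1, 1, 1, 1], sx=[0.01] * 4,
                 by=[0.1, 0.5, -0.3, 0.9], sy=[0.05] * 4)
    fixed, random = ivw(iv, model="fixed"), ivw(iv, model="random")
    assert random.beta == fixed.beta
    q = fixed.extras["cochran_q"]
    assert random.se == pytest.approx(fixed.se * math.sqrt(q / 3))


def test_ivw_insufficient_instruments():
    iv = make_iv(bx=[0.1], sx=[0.01], by=[0.05], sy=[0.02])
    with pytest.raises(InsufficientInstrumentsError):
        ivw(iv)


def test_or_scale_is_exp_of_log_scale():
    iv = make_iv(bx=[0.1, 0.2, 0.3], sx=[0.01] * 3,
                 by=[0.03, 0.05, 0.09], sy=[0.02] * 3)
    res = ivw(iv)
    orr, lo, hi = res.or_scale
    assert orr == pytest.approx(math.exp(res.beta), rel=1e-12)
    assert lo == pytest.approx(math.exp(res.ci_low), rel=1e-12)
    assert hi == pytest.approx(math.exp(res.ci_high), rel=1e-12)
    assert res.ci_low < res.beta < res.ci_high


# ------------------------------------------------------------------ Egger

def _wls_with_intercept(bx, by, w):
    X = np.column_stack([np.ones_like(bx), bx])
    return np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * by))


def test_egger_equals_wls_oracle():
    rng = np.random.default_rng(3)
    bx = np.abs(rng.normal(0.1, 0.05, 15))
    by = 0.016 + 0.4 * bx + rng.normal(0, 0.01, 15)
    sy = rng.uniform(0.01, 0.05, 15)
    iv = make_iv(bx=bx, sx=[0.005] * 15, by=by, sy=sy)
    res = mr_egger(iv)
    intercept, slope = _wls_with_intercept(bx, by, sy**-2.0)
    assert res.beta == pytest.approx(slope, abs=1e-10)
    assert res.extras["intercept"] == pytest.approx(intercept, abs=1e-10)


def test_egger_matches_ivw_when_fitted_intercept_is_zero():
    """Removing the fitted intercept from the outcome betas makes the free-
    intercept slope and the zero-intercept slope coincide exactly."""
    rng = np.random.default_rng(4)
    bx = np.abs(rng.normal(0.1, 0.04, 12))
    sy = np.full(12, 0.03)
    by = 0.3 * bx + rng.normal(0, 0.03, 12)
    a, _ = _wls_with_intercept(bx, by, sy**-2.0)
    by_centered = by - a
    iv = make_iv(bx=bx, sx=[0.005] * 12, by=by_centered, sy=sy)
    assert mr_egger(iv).beta == pytest.approx(ivw(iv, model="fixed").beta, abs=1e-9)


def test_egger_orientation_invariance():
    """Flipping a SNP's exposure and outcome signs together is a no-op."""
    rng = np.random.default_rng(5)
    bx = rng.normal(0.1, 0.05, 10)
    by = 0.01 + 0.4 * bx + rng.normal(0, 0.02, 10)
    iv1 = make_iv(bx=bx, sx=[0.005] * 10, by=by, sy=[0.03] * 10)
    flip = np.resize([1.0, -1.0], 10)
    iv2 = make_iv(bx=bx * flip, sx=[0.005] * 10, by=by * flip, sy=[0.03] * 10)
    assert mr_egger(iv1).beta == pytest.approx(mr_egger(iv2).beta, abs=1e-12)


def test_egger_recovers_injected_directional_pleiotropy():
    """Intercept estimates the common direct effect on the outcome."""
    from mrmediate import SimTruth, from_simulated, simulate_two_sample

    intercepts = []
    for s in range(150):
        sim = simulate_two_sample(SimTruth(
            n_snps=40, theta_xm=(0.0,), theta_my=(0.0,), theta_xy_direct=0.1,
            prop_invalid=1.0, pleiotropy_mean=0.02, pleiotropy_sd=0.002,
            seed=s))
        iv = from_simulated(sim["exposure"], sim["outcome"])
        intercepts.append(mr_egger(iv).extras["intercept"])
    assert np.mean(intercepts) == pytest.approx(0.02, abs=0.004)


# --------------------------------------------------------- weighted median

def _median_oracle(theta, w):
    """Brute-force cumulative-weight walk with midpoint interpolation."""
    pairs = sorted(zip(theta, w))
    total = sum(p[1] for p in pairs)
    cum = 0.0
    xs, ys = [], []
    for t, wt in pairs:
        xs.append((cum + wt / 2) / total)
        ys.append(t)
        cum += wt
    if 0.5 <= xs[0]:
        return ys[0]
    for i in range(1, len(xs)):
        if xs[i] >= 0.5:
            frac = (0.5 - xs[i - 1]) / (xs[i] - xs[i - 1])
            return ys[i - 1] + frac * (ys[i] - ys[i - 1])
    return ys[-1]


def test_weighted_median_cumulative_weight_oracle():
    # theta 0.1, 0.2, 0.9 with weights 1, 1, 2
    sy = np.array([1.0, 1.0, 1 / math.sqrt(2)])
    iv = make_iv(bx=[1, 1, 1], sx=[0.001] * 3, by=[0.1, 0.2, 0.9], sy=sy)
    res = weighted_median(iv, n_boot=200, seed=0)
    assert res.beta == pytest.approx(_median_oracle([0.1, 0.2, 0.9], [1, 1, 2]))


def test_weighted_median_equal_weights_reduces_to_median():
    iv = make_iv(bx=[1] * 5, sx=[0.001] * 5,
                 by=[0.3, 0.1, 0.9, 0.2, 0.4], sy=[0.05] * 5)
    res = weighted_median(iv, n_boot=200, seed=0)
    assert res.beta == pytest.approx(0.3)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=10, deadline=None)
def test_weighted_median_matches_oracle_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 25))
    theta = rng.normal(0, 1, n)
    sy = rng.uniform(0.01, 0.5, n)
    iv = make_iv(bx=[1] * n, sx=[0.001] * n, by=theta, sy=sy)
    res = weighted_median(iv, n_boot=100, seed=0)
    assert res.beta == pytest.approx(_median_oracle(theta, sy**-2.0), abs=1e-12)


def test_weighted_median_bootstrap_is_seeded():
    iv = make_iv(bx=[1] * 5, sx=[0.001] * 5,
                 by=[0.3, 0.1, 0.9, 0.2, 0.4], sy=[0.05] * 5)
    a = weighted_median(iv, n_boot=300, seed=42)
    b = weighted_median(iv, n_boot=300, seed=42)
    c = weighted_median(iv, n_boot=300, seed=43)
    assert a.se == b.se and a.se != c.se


def test_weighted_median_small_bootstrap_warns():
    iv = make_iv(bx=[1] * 3, sx=[0.001] * 3, by=[0.1, 0.2, 0.3], sy=[0.05] * 3)
    with pytest.warns(UserWarning, match="n_boot"):
        weighted_median(iv, n_boot=50, seed=0)


# ------------------------------------------------------- maximum likelihood

def _grid_profile_oracle(iv, grid):
    """Maximize the full joint likelihood over the per-SNP instrument
    strengths numerically at each grid value of the slope."""
    from scipy.optimize import minimize

    bx, sx = iv.beta_exposure, iv.se_exposure
    by, sy = iv.beta_outcome, iv.se_outcome

    def negll(gamma, theta):
        return float(np.sum((bx - gamma) ** 2 / (2 * sx**2)
                            + (by - theta * gamma) ** 2 / (2 * sy**2)))

    best = None
    for theta in grid:
        r = minimize(negll, x0=bx, args=(theta,), method="BFGS")
        if best is None or r.fun < best[1]:
            best = (theta, r.fun)
    return best[0]


def test_max_likelihood_matches_grid_oracle():
    iv = make_iv(bx=[0.08, 0.12, 0.10], sx=[0.01] * 3,
                 by=[0.03, 0.02, 0.045], sy=[0.01, 0.012, 0.009])
    est = max_likelihood(iv).beta
    grid = np.linspace(est - 0.2, est + 0.2, 401)
    assert est == pytest.approx(_grid_profile_oracle(iv, grid), abs=1e-3)


def test_max_likelihood_small_sx_limit_equals_ivw():
    rng = np.random.default_rng(6)
    bx = rng.normal(0.1, 0.03, 20)
    by = 0.3 * bx + rng.normal(0, 0.02, 20)
    iv = make_iv(bx=bx, sx=[1e-8] * 20, by=by, sy=[0.02] * 20)
    assert max_likelihood(iv).beta == pytest.approx(
        ivw(iv, model="fixed").beta, abs=1e-6)


def test_max_likelihood_recovers_truth():
    from mrmediate import SimTruth, from_simulated, simulate_two_sample

    ests = []
    for s in range(100):
        sim = simulate_two_sample(SimTruth(
            n_snps=50, theta_xm=(0.0,), theta_my=(0.0,), theta_xy_direct=0.3,
            seed=s))
        ests.append(max_likelihood(from_simulated(sim["exposure"],
                                                  sim["outcome"])).beta)
    assert np.mean(ests) == pytest.approx(0.3, abs=0.02)


# ------------------------------------------------------------------- RAPS

def test_raps_squared_matches_max_likelihood():
    rng = np.random.default_rng(8)
    bx = rng.normal(0.1, 0.03, 25)
    by = 0.25 * bx + rng.normal(0, 0.01, 25)
    iv = make_iv(bx=bx, sx=[0.01] * 25, by=by, sy=[0.01] * 25)
    assert raps(iv, loss="squared", overdispersion=False).beta == pytest.approx(
        max_likelihood(iv).beta, abs=1e-6)


def test_raps_overdispersion_detects_balanced_pleiotropy():
    from mrmediate import SimTruth, from_simulated, simulate_two_sample

    tau_pos, bias_raps, bias_ivw = 0, [], []
    n_rep = 100
    for s in range(n_rep):
        sim = simulate_two_sample(SimTruth(
            n_snps=60, theta_xm=(0.0,), theta_my=(0.0,), theta_xy_direct=0.2,
            prop_invalid=1.0, pleiotropy_mean=0.0, pleiotropy_sd=0.01, seed=s))
        iv = from_simulated(sim["exposure"], sim["outcome"])
        r = raps(iv, overdispersion=True)
        tau_pos += r.extras["tau2"] > 0
        bias_raps.append(r.beta - 0.2)
        bias_ivw.append(ivw(iv).beta - 0.2)
    assert tau_pos >= 0.9 * n_rep
    assert abs(np.mean(bias_raps)) <= abs(np.mean(bias_ivw)) + 0.005


def test_raps_huber_resists_outlier_cluster():
    """A directional cluster of large pleiotropic effects drags the
    squared-loss fit outside 2 SE of truth while the Huber fit stays in."""
    rng = np.random.default_rng(9)
    n, k = 24, 6
    bx = rng.uniform(0.05, 0.15, n)
    by = 0.3 * bx + rng.normal(0, 0.005, n)
    by[:k] += 0.15  # ~30x the outcome SE, one direction
    iv = make_iv(bx=bx, sx=[0.003] * n, by=by, sy=[0.005] * n)
    hub = raps(iv, loss="huber")
    sq = raps(iv, loss="squared")
    assert abs(hub.beta - 0.3) < 2 * hub.se
    assert abs(sq.beta - 0.3) > 2 * sq.se
    assert abs(hub.beta - 0.3) < abs(sq.beta - 0.3) / 5


# ------------------------------------------------------------ equivariance

@pytest.mark.parametrize("method", ["ivw", "egger", "ml", "raps", "median"])
def test_sign_flip_equivariance(method):
    """Flipping all exposure and outcome betas leaves estimates unchanged."""
    rng = np.random.default_rng(10)
    bx = rng.normal(0.1, 0.03, 15)
    by = 0.3 * bx + rng.normal(0, 0.01, 15)
    iv1 = make_iv(bx=bx, sx=[0.01] * 15, by=by, sy=[0.02] * 15)
    iv2 = make_iv(bx=-bx, sx=[0.01] * 15, by=-by, sy=[0.02] * 15)
    fits = {
        "ivw": lambda iv: ivw(iv).beta,
        "egger": lambda iv: mr_egger(iv).beta,
        "ml": lambda iv: max_likelihood(iv).beta,
        "raps": lambda iv: raps(iv).beta,
        "median": lambda iv: weighted_median(iv, n_boot=100, seed=0).beta,
    }
    assert fits[method](iv1) == pytest.approx(fits[method](iv2), abs=1e-6)


@pytest.mark.parametrize("method", ["ivw", "egger", "ml", "raps", "median"])
def test_exposure_scaling_equivariance(method):
    """Scaling exposure betas and SEs by c scales every estimate by 1/c."""
    c = 2.5
    rng = np.random.default_rng(11)
    bx = rng.normal(0.1, 0.03, 15)
    by = 0.3 * bx + rng.normal(0, 0.01, 15)
    iv1 = make_iv(bx=bx, sx=[0.01] * 15, by=by, sy=[0.02] * 15)
    iv2 = make_iv(bx=c * bx, sx=[0.01 * c] * 15, by=by, sy=[0.02] * 15)
    fits = {
        "ivw": lambda iv: ivw(iv).beta,
        "egger": lambda iv: mr_egger(iv).beta,
        "ml": lambda iv: max_likelihood(iv).beta,
        "raps": lambda iv: raps(iv).beta,
        "median": lambda iv: weighted_median(iv, n_boot=100, seed=0).beta,
    }
    assert fits[method](iv1) == pytest.approx(fits[method](iv2) * c, rel=1e-4)


def test_ivw_ci_coverage_under_clean_generator():
    """95% interval covers the true total effect at close to nominal rate."""
    from mrmediate import SimTruth, from_simulated, simulate_two_sample

    covered = 0
    n_rep = 400
    for s in range(n_rep):
        t = SimTruth(n_snps=30, theta_xm=(0.1,), theta_my=(0.25,),
                     theta_xy_direct=0.17, seed=s)
        sim = simulate_two_sample(t)
        r = ivw(from_simulated(sim["exposure"], sim["outcome"]))
        covered += r.ci_low <= t.total_effect <= r.ci_high
    assert 0.92 <= covered / n_rep <= 0.975
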