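"""Synthetic two-sample GWAS summary statistics with known ground truth.

The structural model: independent biallelic instruments j = 1..J with minor
allele frequency maf_j and true per-allele effect gamma_j on the exposure X.
Each mediator M_k receives gamma_j * theta_xm[k] (plus optional mediator-side
pleiotropy), and the binary outcome Y receives, on the log-odds scale,

    gamma_j * theta_xy_direct
      + sum_k (gamma_j * theta_xm[k]) * theta_my[k]
      + alpha_j

where alpha_j ~ Normal(pleiotropy_mean, pleiotropy_sd^2) for a configurable
fraction of invalid instruments and 0 otherwise.  Observed betas add
Normal(0, se^2) estimation noise with the standard GWAS approximation
se = (2 * maf * (1 - maf) * n)^(-1/2) per trait; each trait uses an
independent random stream, which is exactly the non-overlapping two-sample
design.  The implied true total effect is

    theta_xy_direct + sum_k theta_xm[k] * theta_my[k]

by construction, so every downstream estimate has an analytic target.

Betas for the binary outcome are generated directly on the log-odds scale;
individual-level logistic sampling is deliberately out of scope — the whole
pipeline consumes only summary statistics.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .sumstats import validate_sumstats

# non-palindromic allele pairs only, so default harmonization is exact
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters of one synthetic two-sample scenario.

    Defaults emulate the study conditions this package targets: a lipid-like
    continuous exposure instrumented by a few hundred genome-wide-significant
    SNPs (UK-Biobank scale n), cytokine-like mediators at consortium scale,
    and a rare binary outcome (biobank case-control, log-odds scale).
    Instrument strength gamma_j ~ Normal(0.08, 0.02^2) gives mean F >> 10.
    """

    n_snps: int = 100
    theta_xm: tuple[float, ...] = (0.10,)        # exposure -> each mediator
    theta_my: tuple[float, ...] = (0.25,)        # mediator -> outcome (direct, log-odds)
    theta_xy_direct: float = 0.17                # exposure -> outcome direct (log-odds)
    pleiotropy_mean: float = 0.0                 # directional when != 0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0                    # fraction of SNPs given alpha_j
    n_exposure: int = 440_000
    n_outcome: int = 218_000
    n_mediator: int = 21_758
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_mean: float = 0.08
    gamma_sd: float = 0.02
    pleiotropy_mediator_sd: float = 0.0
    prop_mediator_specific: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.theta_xm) != len(self.theta_my):
            raise ParameterError("theta_xm and theta_my must have one entry per mediator")
        if not 0 <= self.prop_invalid <= 1:
            raise ParameterError("prop_invalid must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must be a non-empty interval within (0, 0.5]")
        if self.n_snps < 3:
            raise ParameterError("need at least 3 instruments")
        if min(self.n_exposure, self.n_outcome, self.n_mediator) <= 0:
            raise ParameterError("sample sizes must be positive")
        if not 0 <= self.prop_mediator_specific <= 1:
            raise ParameterError("prop_mediator_specific must be in [0, 1]")
        if self.n_mediators * self.prop_mediator_specific >= 1:
            raise ParameterError("mediator-specific blocks would exhaust the SNP panel")

    @property
    def n_mediators(self) -> int:
        return len(self.theta_xm)

    @property
    def total_effect(self) -> float:
        """Analytic exposure->outcome total effect (log-odds per exposure unit)."""
        return self.theta_xy_direct + float(
            np.dot(self.theta_xm, self.theta_my)
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["theta_xm"] = list(self.theta_xm)
        d["theta_my"] = list(self.theta_my)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        d = dict(d)
        for key in ("theta_xm", "theta_my", "maf_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _observe(rng: np.random.Generator, true_beta: np.ndarray, maf: np.ndarray,
             n: int, snp: np.ndarray, ea: np.ndarray, oa: np.ndarray) -> pd.DataFrame:
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta = true_beta + rng.normal(0.0, se)
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    # p-values live in (0,1]; underflow to 0 is clamped to the smallest float
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return validate_sumstats(pd.DataFrame({
        "snp": snp, "effect_allele": ea, "other_allele": oa,
        "eaf": maf, "beta": beta, "se": se, "pval": pval,
        "n": float(n),
    }))


def simulate_two_sample(truth: SimTruth) -> dict:
    """Generate summary statistics for exposure, mediator(s) and outcome.

    Returns a dict with keys ``"exposure"``, ``"mediator_1"``.. and
    ``"outcome"`` (canonical DataFrames) plus ``"truth"`` (the SimTruth echo)
    and ``"alpha"`` (the realized per-SNP pleiotropic effects, for tests).
    Output is a pure function of ``truth`` including its seed.
    """
    J = truth.n_snps
    root = np.random.SeedSequence(truth.seed)
    # one child stream per trait + one for the shared genetic architecture
    n_streams = 3 + truth.n_mediators
    streams = [np.random.Generator(np.random.PCG64(s)) for s in root.spawn(n_streams)]
    rng_arch, rng_x, rng_y, *rng_m = streams

    maf = rng_arch.uniform(truth.maf_range[0], truth.maf_range[1], size=J)
    gamma = rng_arch.normal(truth.gamma_mean, truth.gamma_sd, size=J)
    pair_idx = rng_arch.integers(0, len(_ALLELE_PAIRS), size=J)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    snp = np.array([f"rs{j + 1:07d}" for j in range(J)])

    n_invalid = int(round(truth.prop_invalid * J))
    alpha = np.zeros(J)
    if n_invalid > 0:
        invalid = rng_arch.choice(J, size=n_invalid, replace=False)
        alpha[invalid] = rng_arch.normal(truth.pleiotropy_mean, truth.pleiotropy_sd,
                                         size=n_invalid)

    # mediator-specific instrument blocks: disjoint runs of SNPs at the end of
    # the panel lose their exposure effect and gain a strong direct mediator
    # effect, emulating each cytokine's own GWAS hits
    n_spec = int(round(truth.prop_mediator_specific * J))
    specific = np.zeros((truth.n_mediators, J))
    if n_spec > 0:
        pos = J
        for k in range(truth.n_mediators):
            pos -= n_spec
            block = slice(pos, pos + n_spec)
            gamma[block] = 0.0
            specific[k, block] = rng_arch.normal(truth.gamma_mean, truth.gamma_sd,
                                                 size=n_spec)

    out = {"truth": truth, "alpha": alpha}
    out["exposure"] = _observe(rng_x, gamma, maf, truth.n_exposure, snp, ea, oa)

    true_y = gamma * truth.theta_xy_direct + alpha
    for k in range(truth.n_mediators):
        true_m = gamma * truth.theta_xm[k] + specific[k]
        if truth.pleiotropy_mediator_sd > 0:
            true_m = true_m + rng_arch.normal(0.0, truth.pleiotropy_mediator_sd, size=J)
        true_y = true_y + true_m * truth.theta_my[k]
        out[f"mediator_{k + 1}"] = _observe(rng_m[k], true_m, maf, truth.n_mediator,
                                            snp, ea, oa)
    out["outcome"] = _observe(rng_y, true_y, maf, truth.n_outcome, snp, ea, oa)
    return out


def inject_outliers(records: pd.DataFrame, k: int, magnitude: float,
                    seed: int) -> tuple[pd.DataFrame, list[str]]:
    """Shift k random SNPs' outcome betas by ``magnitude``.

    Creates known horizontal-pleiotropy outliers for scoring outlier-detection
    power.  Returns the modified frame and the altered SNP IDs.
    """
    n = len(records)
    if k >= n:
        raise ParameterError(f"k ({k}) must be smaller than the number of records ({n})")
    if k < 0:
        raise ParameterError("k must be non-negative")
    out = records.copy()
    if k == 0:
        return out, []
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    out.iloc[idx, out.columns.get_loc("beta")] += magnitude
    return out, sorted(out.iloc[idx]["snp"].tolist())
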