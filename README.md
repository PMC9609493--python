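# mrmediate

Two-sample, multivariable and two-step-mediation **Mendelian randomization**
(MR) on GWAS summary statistics, for epidemiologists asking not just *does an
exposure cause an outcome* but *how much of that effect flows through a
measured mediator*.  The motivating setting is lipid traits (e.g.
triglycerides), inflammatory cytokines (e.g. IL-1β, IL-17) as candidate
mediators, and a rare binary disease outcome such as nonalcoholic fatty
liver disease, analysed purely from published per-SNP association tables —
no individual-level data required.

## The statistics

For each instrument SNP *j* with exposure effect β<sub>Xj</sub> (SE
σ<sub>Xj</sub>) and outcome effect β<sub>Yj</sub> (SE σ<sub>Yj</sub>), the
Wald ratio is θ̂<sub>j</sub> = β<sub>Yj</sub>/β<sub>Xj</sub> with first-order
SE σ<sub>Yj</sub>/|β<sub>Xj</sub>|.  The **IVW** estimate is the
inverse-variance-weighted mean of the θ̂<sub>j</sub> — equivalently the
zero-intercept weighted regression of β<sub>Y</sub> on β<sub>X</sub> — with
a multiplicative random-effects SE inflated by max(1, √(Q/(J−1))) from
Cochran's Q.  Pleiotropy-robust companions: **MR-Egger** (free intercept =
average directional pleiotropy, t reference on J−2 df), the **weighted
median** (consistent with up to half the weight on invalid instruments;
parametric-bootstrap SE), profile **maximum likelihood**, and **RAPS**
(adjusted profile score with optional Huber loss and overdispersion τ²).
**MR-PRESSO** simulates the null of its leave-one-out residual sum of
squares to flag and remove outlier SNPs.

**Multivariable MR** regresses β<sub>Y</sub> on several exposures' effects
jointly (no intercept, weights σ<sub>Y</sub><sup>−2</sup>), giving each
exposure's *direct* effect.  The **two-step mediation decomposition**
combines β1 (exposure→mediator, univariable), β2 (mediator→outcome adjusted
for the exposure, from MVMR) and β3 (the exposure's direct effect) into the
proportion mediated

E% = Σ<sub>k</sub> β1<sub>k</sub>β2<sub>k</sub> / (β3 + Σ<sub>k</sub> β1<sub>k</sub>β2<sub>k</sub>)  (product method),  or  (total − β3)/total  (difference method).

A synthetic-data module generates two-sample summary statistics under a
known structural model (configurable direct/indirect effects, pleiotropy,
mediator-specific instruments), so every estimator can be validated against
ground truth.

## Worked example

```python
from mrmediate import SimTruth, simulate_two_sample, from_simulated, ivw, two_step_mediation

truth = SimTruth(n_snps=150, theta_xm=(0.10,), theta_my=(0.25,),
                 theta_xy_direct=0.17, prop_mediator_specific=0.2,
                 n_exposure=500_000, n_outcome=500_000, n_mediator=500_000,
                 seed=1)
sim = simulate_two_sample(truth)

iv = from_simulated(sim["exposure"], sim["outcome"])
total = ivw(iv)
print(f"total OR {total.or_scale[0]:.3f} "
      f"({total.or_scale[1]:.3f}-{total.or_scale[2]:.3f})")

dec = two_step_mediation(sim["exposure"], {"IL": sim["mediator_1"]},
                         sim["outcome"], method="both")
print(f"direct log-OR {dec.beta3:.3f}, indirect {dec.indirect_sum:.4f}, "
      f"mediated {dec.proportion_mediated:.1f}%")
```

prints

```
total OR 1.213 (1.206-1.220)
direct log-OR 0.169, indirect 0.0244, mediated 12.6%
```

The simulated truth implies a total log-odds effect of
0.17 + 0.10×0.25 = 0.195 (OR 1.215) and an analytic mediated proportion of
0.025/0.195 = 12.8%; the estimates above recover both within sampling error.

The same analysis runs from the shell via a config file:

```bash
mrmediate simulate --scenario scenario.yaml --out-dir sim/
mrmediate run config.yaml
mrmediate report results/
```

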