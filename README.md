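# icie

Two-sample hypothesis tests for **interval-censored survival data in the
presence of an intermediate clinical event (IE)**, via non-iterative
multiple imputation.

## The problem

In trials and cohorts a subject may experience an intermediate clinical
event — a second-line therapy, a transplant — at an exactly observed
waiting time `W` before the event of interest at time `T`, and the IE may
change the subsequent hazard. Subjects who experience the IE must survive
at least until `W`, so naive comparisons (log-rank, or log-rank stratified
by IE occurrence) are length-biased and can badly over-reject or lose
power. On top of this, `T` is often only known to lie in a visit interval
`(L, R]` (interval censoring), with `R = ∞` for right-censored subjects.

Write `Z = I(W ≤ T)`, let `Q₀` and `Q₁` be the survival functions of the
event time before and after the IE, and model the two arms A/B under
stratum-specific proportional hazards `Q_kA(t) = Q_kB(t)^{β_k}`, `k = 0, 1`.
The null of interest is `H₀: β₀ = β₁ = 0`. On complete data the score
statistics are, with `z_j(t) = I(W_j ≤ t)`, risk indicator
`R_j(t) = I(T_j ≥ t)` and `x = I(arm A)`:

    S₁ = Σᵢ xᵢ zᵢ(tᵢ) dNᵢ − Σᵢ pᵢ dNᵢ,     pᵢ = nᵢ / Nᵢ,
    V(S₁) = Σᵢ pᵢ (1 − pᵢ) dNᵢ,

where `nᵢ`, `Nᵢ` count arm-A and all at-risk subjects that are post-IE at
the i-th event time; `S₀`, `V(S₀)` are the pre-IE analogues using `1 − z`.
`χ² = S₀²/V(S₀) + S₁²/V(S₁)` is referred to chi-square with 2 df; the
hypothesis is separable, so each component is also a 1-df test. (At tied
event times the variance carries the standard log-rank multiplicity factor
`(N − dN)/(N − 1)`.)

To use these statistics with interval-censored records, each of `M = 10`
imputations completes the dataset twice: a **pre-IE** dataset in which IE
subjects are right-censored at `W`, and a **post-IE** dataset of IE
subjects left-truncated at `W`, with event times drawn from the candidate
points inside each `(L, R]` either **uniformly** or **weighted by the
Turnbull NPMLE** of the stratum's survival distribution (truncation-aware).
Scores are pooled across imputations with within/between variance
combination in an additive form `V₁ = within + (1 + 1/M)·between` and a
subtractive form `V₂ = within − between`.

## Worked example

```python
import numpy as np
from icie import ScenarioConfig, generate_cohort, mi_test

# two arms of 100; both arms: IE probability 0.5, pre-IE hazard 1;
# post-IE mean survival 2.0 in arm A but 1.0 in arm B; 30% censoring
cfg = ScenarioConfig(theta_A=0.5, theta_B=0.5, m1_A=2.0, m1_B=1.0,
                     c_p=0.3, n_per_group=100, seed=7)
cohort = generate_cohort(cfg)                      # columns id,group,L,R,delta,Z,W,T_true

res = mi_test(cohort, method="weighted", M=10, rng=np.random.default_rng(7))
print(f"S0 = {res.S_bar_0:.3f}  S1 = {res.S_bar_1:.3f}")
print(f"chi2_add = {res.chi2_add:.3f} (p = {res.p_add:.4f})")
print(f"chi2_sub = {res.chi2_sub:.3f} (p = {res.p_sub:.4f})")
print(f"separable beta1: chi2 = {res.summary_add.chi1_beta1:.3f} "
      f"(p = {res.summary_add.p_beta1:.4f})")
```

prints

```
S0 = 2.030  S1 = -11.271
chi2_add = 9.590 (p = 0.0083)
chi2_sub = 9.922 (p = 0.0070)
separable beta1: chi2 = 9.259 (p = 0.0023)
```

The composite 2-df test rejects at the 1% level, and the separable 1-df
tests localize the difference where it was built in: the post-IE stratum
(`β₁`, strongly significant) rather than the pre-IE stratum (`β₀`,
p ≈ 0.57). A negative `S1` means arm A saw fewer post-IE events than
expected under the null, i.e. longer post-IE survival.

The same analysis from the shell:

```sh
icie simulate --config configs/scenario_null.yaml --out cohort.csv
icie test --input cohort.csv --method weighted --M 10 --seed 7
icie tables --config configs/tables_power.yaml --reps 1000 --seed 7 --out power.csv
```

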