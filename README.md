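# psmcea

A partitioned-survival cost-effectiveness model comparing **lenvatinib +
pembrolizumab (LP)** with single-agent **chemotherapy** (50/50
doxorubicin / paclitaxel) in previously treated, mismatch-repair-proficient
(pMMR) advanced endometrial cancer, from a Chinese payer perspective.
It is written for health-economics researchers who want a transparent,
scriptable re-implementation of this comparison: every parameter of the
published evaluation's input table is in one YAML file, and every analysis
(base case, one-way sensitivity, probabilistic sensitivity, survival-curve
fitting) is a pure function of that configuration.

## The model

Three health states — progression-free disease (PFD), progressed disease
(PD), death — over a 10-year horizon in 174 cycles of 21 days.  State
occupancy is read directly off the overall-survival (OS) and
progression-free-survival (PFS) curves at each cycle start *t* (months):

```
pfd(t)  = min(S_pfs(t), S_os(t))
dead(t) = 1 − S_os(t)
pd(t)   = 1 − pfd(t) − dead(t)
```

Both endpoints use log-logistic survival laws, `S(t) = 1 / (1 + λ tᵞ)`,
with the shape/scale pairs of the published input table (median
`(1/λ)^{1/γ}`).  Per cycle, the model accrues drug acquisition and
expected adverse-event management costs while on treatment (LP: 11
cycles; chemotherapy: 5 cycles, from the median treatment durations),
routine follow-up for everyone alive, best supportive care in PD, and
utility-weighted life years (PFD 0.817, PD 0.779, minus
incidence-weighted adverse-event disutilities on treatment), all
discounted at 5%/year.  The decision statistic is the incremental
cost-effectiveness ratio ΔC/ΔE against a willingness-to-pay threshold of
$37,663.26/QALY (3× 2021 Chinese per-capita GDP).

The package also contains the full evidence-preparation pipeline the
evaluation describes: simulate right-censored patient records from a
known law, estimate the Kaplan–Meier curve (via *lifelines*), emulate a
graph digitiser, rebuild pseudo individual-patient data from the
digitised coordinates, fit six parametric families (log-logistic,
Weibull, log-normal, Gompertz, exponential, gamma) by censored maximum
likelihood and select by AIC/BIC.

## Worked example

```python
>>> import psmcea
>>> res = psmcea.run_base_case()
>>> print(f"{res.icer:,.2f}")
124,188.10
```

Or from the shell (`analysis/02_base_case.py` does the same and writes
`results/base_case/`):

```
Lenvatinib plus Pembrolizumab  cost $ 69,979.72  LY 2.036  QALY 1.601
Chemotherapy                   cost $  9,940.37  LY 1.428  QALY 1.117
incremental cost $60,039.35, incremental QALY 0.4835, ICER $124,188.10/QALY
LP is NOT cost-effective at a WTP of $37,663.26/QALY (NMB $-41,830.86)
```

LP buys 0.48 extra discounted QALYs for an extra $60k — about $124k per
QALY, more than three times the willingness-to-pay threshold, so LP is
not cost-effective at its list prices.  The one-way tornado
(`analysis/03_one_way_dsa.py`) shows the pembrolizumab price is the
dominant driver, followed by the number of LP treatment cycles:

```
drug_prices.pembrolizumab   ICER  80,437 .. 124,188  (width 43,751)
LP treatment cycles         ICER 100,823 .. 142,546  (width 41,723)
pembrolizumab at $4.936/mg -> ICER $53,311.09/QALY (above the WTP threshold)
```

and the 10,000-draw PSA (`analysis/04_psa.py`) gives LP essentially zero
probability of being cost-effective at the threshold.  The remaining
drivers (`analysis/01_survival_curves.py`, `05_curve_fit_pipeline.py`,
`06_structural_variants.py`) print the modelled medians (6.7/16.2 months
LP PFS/OS, 4.1/11.8 chemotherapy), demonstrate that the
digitise-reconstruct-refit pipeline recovers the generating log-logistic
family in 25/25 replicates at n=500, and quantify how strongly the
totals depend on the occupancy convention.

A CLI wraps the same functions:

```sh
psmcea run --analysis base --out results/base --seed 1
psmcea run --analysis psa --out results/psa --seed 1
psmcea run --analysis base --set drug_prices.pembrolizumab=4.936 --out results/cut
```

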