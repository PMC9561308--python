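# Methods

## Model structure and assumptions

The comparison is a cohort-level partitioned survival model (PSM) with
three mutually exclusive states: progression-free disease (PFD),
progressed disease (PD) and death.  Unlike a state-transition Markov
model, a PSM never constructs transition probabilities: membership is
read directly from the two endpoint curves at each cycle-start time
*t* in months,

    pfd(t)  = min(S_pfs(t), S_os(t)),
    dead(t) = 1 − S_os(t),
    pd(t)   = 1 − pfd(t) − dead(t)  (floored at 0).

The `min` guards against a digitisation or fitting artefact placing
S_pfs above S_os.  The implicit assumptions are the usual PSM ones: the
curves fully determine occupancy, there is no tunnel-state memory, and
post-progression survival is whatever the OS curve implies.

Both endpoints in both arms use the log-logistic law
`S(t) = 1/(1 + λ tᵞ)` (scale λ, shape γ, median `(1/λ)^{1/γ}`).  Time is
in **months** (one month = 30.4375 days); under that unit the four
curves' medians — 6.7 / 16.2 months (LP PFS/OS) and 4.1 / 11.8 months
(chemotherapy) — land on the clinically reported medians for this
population, which is the only internal evidence available for the unit.

## Economic accumulation

* **Horizon / cycle:** 10 years in 21-day cycles; the cycle count is
  `round(10 × 365.25 / 21) = 174`.
* **Discounting:** 5 %/year, annual compounding, evaluated at
  cycle-start time `k × 21 / 365.25` years, applied to costs, life
  years and QALYs alike.
* **Half-cycle correction:** off by default (occupancy at cycle start);
  `EconParams(half_cycle_correction=True)` averages cycle start/end
  occupancy instead, moving totals by ~1–2 %.
* **Drug costs:** lenvatinib 20 mg/day × 21 days; pembrolizumab 200 mg
  per cycle; doxorubicin 60 mg/m² once per cycle; paclitaxel 80 mg/m²
  weekly 3-on/1-off, mapped onto the 21-day cycle as 3 doses / 28 days =
  2.25 administrations per cycle (dose intensity preserved).  BSA
  1.64 m².  The chemotherapy arm mixes doxorubicin and paclitaxel
  50/50 (the receipt probability, exposed to sensitivity analysis).
* **Treatment duration:** drug acquisition and adverse-event costs stop
  after `ceil(median treatment duration / 21)` cycles — 11 for LP
  (231 days) and 5 for chemotherapy (104.5 days) — and are weighted by
  PFD occupancy while they run.
* **Other costs:** follow-up $337.50/cycle for everyone alive; best
  supportive care $55.60/cycle in PD only (supportive care is the
  assumed post-progression intervention).
* **Utilities:** PFD 0.817, PD 0.779 per cycle (scaled by cycle length
  in years).  Grade ≥3 adverse events (hypertension, anaemia,
  neutropenia) contribute an incidence-weighted expected cost and an
  incidence-weighted utility decrement during on-treatment cycles only,
  since the incidences are treatment-emergent.  Whether the original
  evaluation applied the listed disutilities at all is not stated; here
  they are applied, and their effect is small (≈0.02 QALY).
* **Decision rule:** ICER = ΔC/ΔE when the QALY difference exceeds
  1e-9 and neither arm dominates; dominant/dominated situations are
  reported as flags, never as negative ratios.  Net monetary benefit is
  `WTP × ΔE − ΔC` at WTP $37,663.26/QALY.

## Survival toolkit

Six families share one `(family, shape, scale)` container: log-logistic
(γ, λ as above), Weibull `S = exp(−(λt)ᵞ)`, log-normal (σ, median
exp(μ)), Gompertz (hazard growth a, baseline hazard b), exponential
(rate; shape fixed at 1) and gamma (shape, rate).  Fitting maximises the
right-censored log-likelihood over log-transformed parameters
(Nelder–Mead, then a BFGS polish; method-of-moments starting values from
the uncensored records).  Model choice is lowest AIC, ties broken by
lowest BIC and then by the fixed family order — a deterministic stand-in
for "visual inspection" criteria.  Kaplan–Meier estimation delegates to
`lifelines`; the log-logistic MLE is cross-checked against
`lifelines.LogLogisticFitter` in the tests.

Parameter recovery at n=5000 with ~20 % censoring succeeds (both
parameters within 10 %) in ≥ 45/50 seeded replicates for every family.
Note that the log-logistic **scale** is an ill-conditioned coordinate:
λ = median^(−γ), so a 3 % error in γ propagates to a ~10 % error in λ at
a 16-month median.  At n=500 the λ MLE's sampling spread exceeds ±10 %
in roughly half of replicates even when fitting the raw records
directly; shape and median are far more stable summaries.

## Synthetic data and curve reconstruction

No patient-level data for this comparison are public, so the fitting
stage runs on synthetic cohorts:

* `generate_pseudo_ipd` draws event times by inverse-CDF from any of
  the six laws; subjects are censored at the administrative cut-off,
  and a Bernoulli(`random_censor_rate`) subset instead at a
  Uniform(0, cut-off) time (early loss to follow-up).
* `digitize` emulates reading coordinates off a plotted KM curve.  The
  default places the n sampling times at step times splitting the total
  survival drop evenly (a plot reader clicks where the curve moves);
  `spacing="time"` gives a coarser evenly-spaced-in-time read, and
  `at_steps=True` records every visible step corner.  Uniform reading
  noise of half-width ε is added, clipped to [0, 1] and made monotone
  by a running minimum, which keeps every coordinate within ε of the
  true curve.
* `reconstruct_ipd` converts survival drops between consecutive
  coordinates into event records at the later coordinate's time — the
  only placement under which digitise→reconstruct round-trips exactly
  when coordinates sit on the step corners — with largest-remainder
  rounding so exactly `assumed_n` records emerge; survivors are
  censored at the last coordinate, or distributed per interval when a
  numbers-at-risk table is available.

What this emulates — and what it does not: the generator reproduces the
*statistical* structure the analysis assumes (a known parametric truth,
administrative plus random right-censoring, bounded coordinate-reading
error).  It does not emulate rendering artefacts of real figures (axis
rasterisation, overlapping censoring ticks), informative censoring, or
covariate heterogeneity, so a passing pipeline shows the machinery is
correct, not that any particular published figure was digitised
faithfully.  Coarse reads lose information in a structured way: with 60
evenly spaced times, early steps aggregate and every event shifts to
its interval's end, which biases refitted scales low and can flip
AIC-based selection toward the log-normal; with one coordinate per
visible step, selection recovers the generating log-logistic family in
25/25 replicates at n=500.

## Sensitivity machinery

One-way DSA re-runs the full two-arm model at each parameter's range
limits, using the table's explicit minima/maxima where given and
base × (1 ± 0.25) otherwise; the pembrolizumab price's low is 50 % of
base, the LP cycle count varies over 8–14, and the chemotherapy mix
weight over 0.375–0.625 (its complement kept normalised).  Bars are
ordered by ICER-interval width.

PSA draws each tabulated parameter from its assigned family with
moments matched to mean = base and sd = (high − low)/3.92 (the range
read as a 95 % interval): gamma for costs and prices; beta rescaled to
[low, high] for utilities, disutilities, BSA and the discount rate,
since several of those ranges do not sit inside [0, 1].  A parameter
whose base coincides with a range endpoint (the hypertension
disutility) has no symmetric beta and degenerates to its base.
Survival-curve parameters and adverse-event incidences carry no ranges
or distributions and stay fixed.  Each of the 10,000 draws re-runs both
arms; outputs are the (ΔC, ΔE) cloud, its 95 % covariance ellipse, and
the CEAC (fraction of draws with positive NMB) over a WTP grid that
includes the threshold.  All randomness flows through a single seeded
`numpy` generator, so identical seeds give identical results.

## Sensitivity to unstated accumulation conventions

The published evaluation this package re-implements leaves several
accumulation conventions unstated (half-cycle correction, duration
rounding, how per-cycle probabilities were derived in the original
implementation).  `analysis/06_structural_variants.py`
quantifies them.  Half-cycle correction and duration rounding move
totals by a few per cent.  One variant is qualitatively different: a
Markov chain whose per-cycle transition probabilities are the
*unconditional* survival increments `S(t_k) − S(t_{k+1})` — a known
implementation pitfall, since the probability of an event in a cycle
must be conditioned on having survived to that cycle.  That scheme
leaves `exp(−(1 − S(∞))) ≈ e⁻¹` of the cohort alive (and partly
progression-free) forever and roughly **doubles** life years and QALYs
in both arms (LP 3.89 vs 2.04 LY; chemotherapy 3.60 vs 1.43).  It is
provided as `EconParams(occupancy="markov_unconditional")` purely for
this structural comparison; the default, and every headline number this
package reports, uses the correct partitioned-survival accumulation.
This one convention dwarfs all parameter uncertainty in the tornado,
which is why reported cohort-model totals can be impossible to match
without knowing it.

## Known limitations

* The two OS curves cross near 2.5 months (LP's smaller shape implies a
  higher early hazard), so LP's survival dominance holds beyond ~3
  months and in the totals, not pointwise from zero.
* Treatment duration is extrapolated from medians; durable responders
  treated far longer would raise LP's cost.
* No tunnel states, treatment switching, or covariate adjustment; PD is
  a single homogeneous state.
* The ICER is undefined (flagged) for dominance quadrants; the
  cost-effectiveness verdict in the cheaper-and-less-effective quadrant
  follows the simple ICER ≤ WTP rule, which is conservative there.
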