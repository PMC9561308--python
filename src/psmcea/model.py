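"""Partitioned-survival cohort model with per-cycle cost and QALY accrual.

Three health states — progression-free disease (PFD), progressed disease
(PD) and death — over a 10-year horizon in 21-day cycles.  Occupancy is
read directly off the OS and PFS curves at each cycle-start time:

    pfd(t)  = min(S_pfs(t), S_os(t))
    dead(t) = 1 - S_os(t)
    pd(t)   = 1 - pfd(t) - dead(t)        (floored at zero)

Costs accrued each cycle: drug acquisition and expected adverse-event
management while on treatment (weighted by PFD occupancy), routine
follow-up for everyone alive, and best supportive care in PD.  QALYs
weight PFD occupancy by the PFD utility minus the expected on-treatment
adverse-event disutility, and PD occupancy by the PD utility.  Costs and
outcomes are discounted at the annual rate with the cycle-start
convention; a half-cycle-correction switch (averaging cycle-start and
cycle-end occupancy) is available and off by default.

An alternative occupancy mode, ``markov_unconditional``, advances a
Markov chain whose per-cycle transition probabilities are the
*unconditional* survival increments S(t_k) - S(t_{k+1}).  That scheme is
a documented implementation pitfall (it leaves part of the cohort
immortal) and exists only so its structural impact can be quantified; it
is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .survival import ParametricSurvival

__all__ = [
    "EconParams",
    "DrugComponent",
    "AdverseEvent",
    "AEProfile",
    "Strategy",
    "UtilitySet",
    "CostSet",
    "Trace",
    "ArmResult",
    "compute_trace",
    "discount_factor",
    "drug_cost_per_cycle",
    "run_arm",
]

DOSE_RULES = ("per_day_fixed_mg", "per_cycle_fixed_mg", "per_admin_bsa_mg_per_m2")


@dataclass(frozen=True)
class EconParams:
    """Global economic settings (defaults are the base case)."""

    cycle_length_days: float = 21.0
    horizon_years: float = 10.0
    annual_discount_rate: float = 0.05
    wtp_per_qaly: float = 37663.26
    bsa_m2: float = 1.64
    month_days: float = 30.4375
    half_cycle_correction: bool = False
    occupancy: str = "partitioned"

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_discount_rate <= 1.0:
            raise ValueError("discount rate must be in [0, 1]")
        if self.occupancy not in ("partitioned", "markov_unconditional"):
            raise ValueError(f"unknown occupancy mode {self.occupancy!r}")

    @property
    def n_cycles(self) -> int:
        """Cycle count covering the horizon: 174 21-day cycles for 10 years."""
        return int(round(self.horizon_years * 365.25 / self.cycle_length_days))

    def cycle_start_months(self) -> np.ndarray:
        return np.arange(self.n_cycles + 1) * self.cycle_length_days / self.month_days

    def cycle_start_years(self) -> np.ndarray:
        return np.arange(self.n_cycles) * self.cycle_length_days / 365.25


def discount_factor(t_years, econ: EconParams):
    """1 / (1 + r)**t with annual compounding; vectorised."""
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = (1.0 + econ.annual_discount_rate) ** (-t)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DrugComponent:
    """One drug with its per-mg price and dosing rule.

    dose_rule:
      * ``per_day_fixed_mg``       — ``dose`` mg every day of the cycle
      * ``per_cycle_fixed_mg``     — ``dose`` mg once per model cycle
      * ``per_admin_bsa_mg_per_m2``— ``dose`` mg/m2 per administration,
        ``administrations_per_cycle`` administrations per model cycle
    """

    name: str
    price_per_mg: float
    dose_rule: str
    dose: float
    administrations_per_cycle: float = 1.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.dose_rule not in DOSE_RULES:
            raise ValueError(f"unknown dose rule {self.dose_rule!r}")
        if self.price_per_mg < 0:
            raise ValueError(f"{self.name}: price_per_mg must be non-negative")
        if self.dose <= 0 or self.administrations_per_cycle <= 0:
            raise ValueError(f"{self.name}: dose parameters must be positive")

    def mg_per_cycle(self, econ: EconParams) -> float:
        if self.dose_rule == "per_day_fixed_mg":
            return self.dose * econ.cycle_length_days
        if self.dose_rule == "per_cycle_fixed_mg":
            return self.dose
        return self.dose * econ.bsa_m2 * self.administrations_per_cycle


@dataclass(frozen=True)
class AdverseEvent:
    """A grade >=3 adverse event: incidence, per-cycle cost, utility decrement."""

    name: str
    incidence: float
    cost_per_cycle: float
    disutility: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError(f"{self.name}: incidence must be in [0, 1]")
        if self.cost_per_cycle < 0:
            raise ValueError(f"{self.name}: cost must be non-negative")
        if not 0.0 <= self.disutility <= 1.0:
            raise ValueError(f"{self.name}: disutility must be in [0, 1]")


@dataclass(frozen=True)
class AEProfile:
    events: tuple[AdverseEvent, ...] = ()

    @property
    def expected_cost_per_cycle(self) -> float:
        return sum(e.incidence * e.cost_per_cycle for e in self.events)

    @property
    def expected_disutility(self) -> float:
        return sum(e.incidence * e.disutility for e in self.events)


@dataclass(frozen=True)
class Strategy:
    """A treatment arm: drugs, treatment duration, AE profile, survival laws."""

    name: str
    components: tuple[DrugComponent, ...]
    treatment_duration_cycles: int
    ae_profile: AEProfile
    os_model: ParametricSurvival
    pfs_model: ParametricSurvival

    def __post_init__(self) -> None:
        if self.treatment_duration_cycles < 0:
            raise ValueError("treatment duration must be non-negative")
        # weight = probability a patient receives the component; mutually
        # exclusive alternatives (weight < 1) must partition the cohort,
        # co-administered drugs each carry weight 1
        mixed = [c.weight for c in self.components if c.weight < 1.0]
        for c in self.components:
            if not 0.0 < c.weight <= 1.0:
                raise ValueError(f"{c.name}: weight must be in (0, 1]")
        if mixed and abs(sum(mixed) - 1.0) > 1e-9:
            raise ValueError(f"mixing weights must sum to 1 (got {sum(mixed)})")


@dataclass(frozen=True)
class UtilitySet:
    u_pfd: float = 0.817
    u_pd: float = 0.779

    # u_pd may exceed u_pfd transiently in sensitivity runs (the PD utility's
    # upper range crosses the PFD base value), so only bounds are enforced
    def __post_init__(self) -> None:
        if not (0.0 <= self.u_pfd <= 1.0 and 0.0 <= self.u_pd <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")


@dataclass(frozen=True)
class CostSet:
    followup_per_cycle: float = 337.50
    bsc_per_cycle: float = 55.6

    def __post_init__(self) -> None:
        if self.followup_per_cycle < 0 or self.bsc_per_cycle < 0:
            raise ValueError("costs must be non-negative")


@dataclass(frozen=True)
class Trace:
    """Per-cycle state occupancy at cycle-start times."""

    t_months: np.ndarray
    pfd: np.ndarray
    pd: np.ndarray
    dead: np.ndarray

    def __post_init__(self) -> None:
        total = self.pfd + self.pd + self.dead
        if np.max(np.abs(total - 1.0)) > 1e-9:
            raise AssertionError("occupancy must sum to 1 at every cycle")
        if np.any(np.diff(self.dead) < -1e-12):
            raise AssertionError("dead occupancy must be non-decreasing")
        if np.any(np.diff(self.pfd) > 1e-12):
            raise AssertionError("PFD occupancy must be non-increasing")

    def __len__(self) -> int:
        return self.t_months.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_months": self.t_months, "pfd": self.pfd, "pd": self.pd, "dead": self.dead}
        )


def compute_trace(
    os_model: ParametricSurvival,
    pfs_model: ParametricSurvival,
    econ: EconParams,
) -> Trace:
    """State occupancy at each cycle start over the horizon."""
    t = econ.cycle_start_months()
    s_os = os_model.sf(t)
    s_pfs = pfs_model.sf(t)
    if econ.occupancy == "partitioned":
        pfd = np.minimum(s_pfs, s_os)
        dead = 1.0 - s_os
        pd_ = np.maximum(1.0 - pfd - dead, 0.0)
    else:  # markov_unconditional — see module docstring
        n = t.size
        pfd = np.empty(n)
        pd_ = np.empty(n)
        dead = np.empty(n)
        pfd[0], pd_[0], dead[0] = 1.0, 0.0, 0.0
        for k in range(n - 1):
            p_die = s_os[k] - s_os[k + 1]
            p_leave = max((s_pfs[k] - s_pfs[k + 1]) - p_die, 0.0)
            prog = pfd[k] * p_leave
            die = pfd[k] * p_die + pd_[k] * p_die
            pfd[k + 1] = pfd[k] - prog - pfd[k] * p_die
            pd_[k + 1] = pd_[k] + prog - pd_[k] * p_die
            dead[k + 1] = dead[k] + die
    return Trace(t_months=t, pfd=pfd, pd=pd_, dead=dead)


def drug_cost_per_cycle(strategy: Strategy, econ: EconParams) -> float:
    """Weighted acquisition cost of one model cycle's drug supply."""
    return sum(
        c.weight * c.price_per_mg * c.mg_per_cycle(econ) for c in strategy.components
    )


@dataclass(frozen=True)
class ArmResult:
    """Discounted and undiscounted per-arm totals with a cost breakdown."""

    strategy: str
    total_cost: float
    total_life_years: float
    total_qalys: float
    undiscounted_cost: float
    undiscounted_life_years: float
    undiscounted_qalys: float
    cost_breakdown: dict = field(default_factory=dict)
    trace: Trace | None = field(default=None, compare=False, repr=False)

    def to_frame(self):
        import pandas as pd

        row = {
            "strategy": self.strategy,
            "total_cost": self.total_cost,
            "total_life_years": self.total_life_years,
            "total_qalys": self.total_qalys,
            "undiscounted_cost": self.undiscounted_cost,
            "undiscounted_life_years": self.undiscounted_life_years,
            "undiscounted_qalys": self.undiscounted_qalys,
        }
        row.update({f"cost_{k}": v for k, v in self.cost_breakdown.items()})
        return pd.DataFrame([row])


def run_arm(
    strategy: Strategy,
    costs: CostSet,
    utilities: UtilitySet,
    econ: EconParams,
) -> ArmResult:
    """Accumulate one arm's discounted costs, life years and QALYs."""
    trace = compute_trace(strategy.os_model, strategy.pfs_model, econ)
    n = econ.n_cycles
    if n == 0:
        return ArmResult(strategy.name, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, {}, trace)

    pfd, pd_ = trace.pfd, trace.pd
    if econ.half_cycle_correction:
        pfd_c = 0.5 * (pfd[:-1] + pfd[1:])
        pd_c = 0.5 * (pd_[:-1] + pd_[1:])
    else:
        pfd_c = pfd[:n]
        pd_c = pd_[:n]
    alive = pfd_c + pd_c

    disc = discount_factor(econ.cycle_start_years(), econ)
    on_tx = (np.arange(n) < strategy.treatment_duration_cycles).astype(float)
    cycle_years = econ.cycle_length_days / 365.25

    drug_pc = drug_cost_per_cycle(strategy, econ)
    ae_cost_pc = strategy.ae_profile.expected_cost_per_cycle
    ae_disutil = strategy.ae_profile.expected_disutility

    comp = {
        "drug": drug_pc * pfd_c * on_tx,
        "adverse_events": ae_cost_pc * pfd_c * on_tx,
        "followup": costs.followup_per_cycle * alive,
        "bsc": costs.bsc_per_cycle * pd_c,
    }
    ly_cycle = alive * cycle_years
    q_cycle = (
        (utilities.u_pfd - ae_disutil * on_tx) * pfd_c + utilities.u_pd * pd_c
    ) * cycle_years

    breakdown = {k: float((v * disc).sum()) for k, v in comp.items()}
    total_cost = sum(breakdown.values())
    undisc_cost = float(sum(v.sum() for v in comp.values()))
    return ArmResult(
        strategy=strategy.name,
        total_cost=total_cost,
        total_life_years=float((ly_cycle * disc).sum()),
        total_qalys=float((q_cycle * disc).sum()),
        undiscounted_cost=undisc_cost,
        undiscounted_life_years=float(ly_cycle.sum()),
        undiscounted_qalys=float(q_cycle.sum()),
        cost_breakdown=breakdown,
        trace=trace,
    )
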