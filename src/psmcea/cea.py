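"""Incremental cost-effectiveness analysis against a willingness-to-pay threshold."""

from __future__ import annotations

from dataclasses import dataclass

from .model import ArmResult, EconParams

__all__ = ["CEResult", "incremental_analysis"]

_QALY_EPS = 1e-9


@dataclass(frozen=True)
class CEResult:
    """Incremental statistics for intervention vs comparator.

    ``icer`` is None when the QALY difference is negligible or when one
    strategy dominates (a negative ratio has no decision meaning; the
    ``dominance`` flag carries that information instead).
    """

    intervention: ArmResult
    comparator: ArmResult
    delta_cost: float
    delta_qaly: float
    delta_life_years: float
    icer: float | None
    nmb: float
    wtp: float
    dominance: str  # none | dominant | dominated
    cost_effective: bool

    def to_frame(self):
        import pandas as pd

        rows = []
        for arm, dc, dq, icer in (
            (self.intervention, self.delta_cost, self.delta_qaly, self.icer),
            (self.comparator, None, None, None),
        ):
            rows.append(
                {
                    "strategy": arm.strategy,
                    "total_cost": arm.total_cost,
                    "total_life_years": arm.total_life_years,
                    "total_qalys": arm.total_qalys,
                    "incremental_cost": dc,
                    "incremental_qaly": dq,
                    "icer": icer,
                }
            )
        return pd.DataFrame(rows)


def incremental_analysis(
    intervention: ArmResult,
    comparator: ArmResult,
    econ: EconParams,
) -> CEResult:
    """Deltas, ICER, net monetary benefit and the cost-effectiveness verdict."""
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qalys - comparator.total_qalys
    dly = intervention.total_life_years - comparator.total_life_years

    if dc < 0 and dq > 0:
        dominance = "dominant"
    elif dc > 0 and dq < 0:
        dominance = "dominated"
    else:
        dominance = "none"

    icer = dc / dq if abs(dq) >= _QALY_EPS and dominance == "none" else None
    nmb = econ.wtp_per_qaly * dq - dc
    cost_effective = dominance == "dominant" or (
        dominance == "none" and icer is not None and icer <= econ.wtp_per_qaly
    )
    return CEResult(
        intervention=intervention,
        comparator=comparator,
        delta_cost=dc,
        delta_qaly=dq,
        delta_life_years=dly,
        icer=icer,
        nmb=nmb,
        wtp=econ.wtp_per_qaly,
        dominance=dominance,
        cost_effective=cost_effective,
    )
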