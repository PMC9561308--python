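"""One-way deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the full two-arm model at each parameter's low and
high value (everything else at base) and orders parameters by the width
of the resulting ICER interval (tornado order).  Ranges come from the
parameter table where it lists explicit minima/maxima, and default to
base x (1 +/- 0.25) otherwise; the pembrolizumab price low is 50% of
base, and the LP treatment-duration bar varies the cycle count over
round(11 x 0.75) .. round(11 x 1.25).

The PSA draws parameters from gamma (costs) or beta (utilities, BSA,
discount rate; rescaled to [low, high]) distributions whose moments are
matched to mean = base and sd = (high - low) / (2 x 1.96), runs the full
model per draw, and summarises the (delta cost, delta QALY) cloud as a
cost-effectiveness acceptability curve over a willingness-to-pay grid
plus a 95% covariance ellipse.  Survival-curve parameters are fixed (no
range or distribution is listed for them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import config as cfgmod
from .cea import incremental_analysis
from .config import apply_overrides, base_value, build_costs, build_econ, build_strategy, build_utilities, get_path
from .model import run_arm

__all__ = [
    "DSAParamSpec",
    "default_dsa_params",
    "one_way_dsa",
    "PSADistribution",
    "default_psa_distributions",
    "sample_psa_params",
    "run_psa",
    "PSAResult",
]

_Z95 = 2.0 * 1.959963984540054  # range-to-sd divisor (high - low) / 3.92


# ---------------------------------------------------------------------------
# One-way DSA


@dataclass(frozen=True)
class DSAParamSpec:
    """One tornado bar: a config path with its base, low and high values.

    ``linked_complement`` names a second path kept equal to ``1 - value``
    (used for the doxorubicin/paclitaxel mixing probability).
    """

    path: str
    label: str
    base: float
    low: float
    high: float
    linked_complement: str | None = None

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.path}: need low <= base <= high")

    def overrides(self, value: float) -> dict[str, Any]:
        out: dict[str, Any] = {self.path: value}
        if self.linked_complement:
            out[self.linked_complement] = 1.0 - value
        return out


def _ranged_leaves(cfg: Mapping, prefix: str = "") -> list[tuple[str, Mapping]]:
    out = []
    for key, node in cfg.items():
        path = f"{prefix}{key}"
        if isinstance(node, Mapping):
            if "base" in node and "low" in node and "high" in node:
                out.append((path, node))
            else:
                out.extend(_ranged_leaves(node, prefix=path + "."))
    return out


def default_dsa_params(cfg: Mapping) -> list[DSAParamSpec]:
    """The standard one-way parameter set for the packaged configuration."""
    specs = [
        DSAParamSpec(path, path, float(node["base"]), float(node["low"]), float(node["high"]))
        for path, node in _ranged_leaves(cfg)
        if not path.startswith("metadata")
    ]
    # +/- 25% defaults for parameters the table lists without a range
    for arm in ("lp", "chemo"):
        for ae, inc in cfg["strategies"][arm].get("ae_incidence", {}).items():
            v = float(base_value(inc))
            specs.append(
                DSAParamSpec(
                    f"strategies.{arm}.ae_incidence.{ae}",
                    f"{ae} incidence ({arm})",
                    v, 0.75 * v, min(1.25 * v, 1.0),
                )
            )
    dur = int(cfgmod.get_path(cfg, "strategies.lp.treatment_duration_cycles"))
    specs.append(
        DSAParamSpec(
            "strategies.lp.treatment_duration_cycles",
            "LP treatment cycles",
            dur, round(0.75 * dur), round(1.25 * dur),
        )
    )
    specs.append(
        DSAParamSpec(
            "strategies.chemo.components.doxorubicin.weight",
            "doxorubicin/paclitaxel mix",
            0.5, 0.375, 0.625,
            linked_complement="strategies.chemo.components.paclitaxel.weight",
        )
    )
    return specs


def _icer_or_nan(res) -> float:
    return math.nan if res.icer is None else res.icer


def one_way_dsa(
    base_config: Mapping,
    params: Sequence[DSAParamSpec] | None = None,
) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low and high, widest first."""
    if params is None:
        params = default_dsa_params(base_config)
    rows = []
    for spec in params:
        get_path(base_config, spec.path)  # fail fast on bad paths
        lo = cfgmod.run_base_case(base_config, spec.overrides(spec.low))
        hi = cfgmod.run_base_case(base_config, spec.overrides(spec.high))
        icer_lo, icer_hi = _icer_or_nan(lo), _icer_or_nan(hi)
        rows.append(
            {
                "param": spec.path,
                "label": spec.label,
                "low_value": spec.low,
                "high_value": spec.high,
                "icer_at_low": icer_lo,
                "icer_at_high": icer_hi,
                "width": abs(icer_hi - icer_lo),
            }
        )
    df = pd.DataFrame(rows).sort_values("width", ascending=False, ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSADistribution:
    """A sampling distribution for one parameter, moment-matched to its range.

    Gamma (costs, prices): mean = base, sd = (high - low)/3.92.
    Beta (utilities, BSA, discount rate): fitted on [low, high] with the
    same moment rule after rescaling.  A parameter whose base sits on the
    edge of its support, or whose sd is zero, degenerates to the base.
    """

    path: str
    family: str  # gamma | beta
    base: float
    low: float
    high: float
    sd_divisor: float = _Z95
    linked_complement: str | None = None

    @property
    def sd(self) -> float:
        return (self.high - self.low) / self.sd_divisor

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd <= 0:
            return np.full(size, self.base)
        if self.family == "gamma":
            shape = (self.base / self.sd) ** 2
            scale = self.sd**2 / self.base
            return rng.gamma(shape, scale, size=size)
        if self.family == "beta":
            span = self.high - self.low
            m = (self.base - self.low) / span
            s = self.sd / span
            if m <= 0.0 or m >= 1.0:
                # base on the support edge: no symmetric beta exists
                return np.full(size, self.base)
            if s**2 >= m * (1.0 - m):
                raise ValueError(
                    f"{self.path}: sd {self.sd:g} infeasible for beta support "
                    f"[{self.low:g}, {self.high:g}]"
                )
            nu = m * (1.0 - m) / s**2 - 1.0
            return self.low + span * rng.beta(m * nu, (1.0 - m) * nu, size=size)
        raise ValueError(f"{self.path}: unknown distribution family {self.family!r}")


def default_psa_distributions(cfg: Mapping) -> list[PSADistribution]:
    """One distribution per parameter the table tags gamma or beta."""
    out = []
    for path, node in _ranged_leaves(cfg):
        if path.startswith("metadata") or "dist" not in node:
            continue
        out.append(
            PSADistribution(
                path=path,
                family=str(node["dist"]),
                base=float(node["base"]),
                low=float(node["low"]),
                high=float(node["high"]),
            )
        )
    return out


def sample_psa_params(
    distributions: Sequence[PSADistribution],
    seed: int | np.random.Generator,
    size: int = 1,
) -> dict[str, np.ndarray]:
    """Deterministic draws for every parameter, keyed by config path."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return {d.path: d.sample(rng, size) for d in distributions}


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration incremental outcomes plus CEAC summaries."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    wtp_grid: np.ndarray
    ceac: np.ndarray  # P(intervention cost-effective) at each WTP
    seed: int
    n: int
    ellipse: dict = field(default_factory=dict)

    def prob_cost_effective(self, wtp: float) -> float:
        nmb = wtp * self.delta_qaly - self.delta_cost
        return float(np.mean(nmb > 0))

    def iterations_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly})

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.ceac})


def _ce_ellipse(dc: np.ndarray, dq: np.ndarray) -> dict:
    """95% covariance ellipse of the (delta QALY, delta cost) cloud."""
    from scipy import stats

    xy = np.column_stack([dq, dc])
    mean = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    r2 = stats.chi2.ppf(0.95, df=2)
    return {
        "mean_dq": float(mean[0]),
        "mean_dc": float(mean[1]),
        "semi_axis_minor": float(np.sqrt(r2 * evals[0])),
        "semi_axis_major": float(np.sqrt(r2 * evals[1])),
        "angle_deg": float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1]))),
    }


def run_psa(
    base_config: Mapping,
    distributions: Sequence[PSADistribution] | None = None,
    n: int = 10000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Monte-Carlo PSA: ``n`` model evaluations under sampled parameters."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if distributions is None:
        distributions = default_psa_distributions(base_config)
    base_econ = build_econ(base_config)
    if wtp_grid is None:
        wtp_grid = np.unique(
            np.concatenate([np.linspace(0.0, 150000.0, 76), [base_econ.wtp_per_qaly]])
        )
    draws = sample_psa_params(distributions, seed, size=n)
    dc = np.empty(n)
    dq = np.empty(n)
    for i in range(n):
        overrides = {path: float(vals[i]) for path, vals in draws.items()}
        res = cfgmod.run_base_case(base_config, overrides)
        dc[i] = res.delta_cost
        dq[i] = res.delta_qaly
    nmb = wtp_grid[:, None] * dq[None, :] - dc[None, :]
    ceac = (nmb > 0).mean(axis=1)
    return PSAResult(
        delta_cost=dc,
        delta_qaly=dq,
        wtp_grid=np.asarray(wtp_grid, float),
        ceac=ceac,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        n=n,
        ellipse=_ce_ellipse(dc, dq),
    )
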