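"""Synthetic pseudo-IPD, digitised-curve emulation and IPD reconstruction.

The published survival evidence for this comparison exists only as
Kaplan-Meier figures, so the fitting stage is exercised end-to-end on
synthetic data: draw patient records from a known parametric law, build
the KM curve, sample noisy plot coordinates the way a graph digitiser
would, and rebuild pseudo individual-patient data from those coordinates
by interval allocation.  With zero reading noise and the true cohort size
the digitise -> reconstruct round trip is exact at every step time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survival import KMCurve, ParametricSurvival, PseudoIPD, km_estimate

__all__ = [
    "SimSpec",
    "DigitizedCurve",
    "generate_pseudo_ipd",
    "digitize",
    "reconstruct_ipd",
]


@dataclass(frozen=True)
class SimSpec:
    """Recipe for one simulated cohort.

    ``random_censor_rate`` is the per-subject probability of early
    (non-administrative) loss to follow-up; such subjects receive a
    Uniform(0, admin_censor_time) censoring time.  Everyone else is
    administratively censored at ``admin_censor_time`` months.
    """

    model: ParametricSurvival
    n: int
    admin_censor_time: float = 60.0
    random_censor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be positive")
        if not 0.0 <= self.random_censor_rate <= 1.0:
            raise ValueError("random_censor_rate must be in [0, 1]")


def generate_pseudo_ipd(spec: SimSpec) -> PseudoIPD:
    """Draw right-censored records from ``spec.model`` (inverse-CDF sampling)."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    t_event = np.maximum(spec.model.ppf(u), 1e-9)
    censor = np.full(spec.n, spec.admin_censor_time)
    lost = rng.uniform(size=spec.n) < spec.random_censor_rate
    censor[lost] = rng.uniform(0.0, spec.admin_censor_time, size=int(lost.sum()))
    event = t_event <= censor
    time = np.where(event, t_event, censor)
    return PseudoIPD(time, event)


@dataclass(frozen=True)
class DigitizedCurve:
    """Plot-reader coordinates: (time, survival) pairs, optionally a risk table."""

    time: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.shape != s.shape:
            raise ValueError("time and survival must have equal length")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival coordinates must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival coordinates must be non-increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "survival", s)
        if self.n_risk is not None:
            object.__setattr__(self, "n_risk", np.asarray(self.n_risk, dtype=float))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.time, "survival": self.survival})


def digitize(
    curve: KMCurve,
    n_points: int,
    noise: float = 0.0,
    seed: int = 0,
    at_steps: bool = False,
    spacing: str = "survival",
) -> DigitizedCurve:
    """Emulate reading ``n_points`` coordinates off a plotted KM curve.

    A plot reader clicks where the curve visibly moves, so the default
    ``spacing="survival"`` places the ``n_points`` sampling times at step
    times chosen so consecutive coordinates split the total survival drop
    evenly; ``spacing="time"`` uses evenly spaced times instead (a
    coarser read that aggregates early steps), and ``at_steps=True``
    records every visible step corner, ignoring ``n_points``.  Values are
    perturbed by bounded uniform noise of half-width ``noise``, clipped
    to [0, 1] and made non-increasing by a running-minimum pass.  The
    first coordinate is pinned at (0, 1): the plotted curve is anchored
    there.
    """
    if n_points < 2:
        raise ValueError("digitising needs at least 2 points")
    if at_steps:
        times = curve.time
    elif spacing == "survival":
        targets = np.linspace(1.0, curve.survival[-1], n_points)
        idx = np.searchsorted(-curve.survival, -targets, side="left")
        times = np.unique(curve.time[np.clip(idx, 0, curve.time.size - 1)])
    elif spacing == "time":
        times = np.linspace(0.0, curve.time[-1], n_points)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    values = curve.evaluate(times).astype(float).copy()
    if noise > 0:
        rng = np.random.default_rng(seed)
        values[1:] += rng.uniform(-noise, noise, size=values.size - 1)
    values = np.clip(values, 0.0, 1.0)
    values[0] = 1.0
    values = np.minimum.accumulate(values)
    n_risk = None
    if curve.n_risk is not None:
        # carry the numbers-at-risk through: risk set just before each
        # sampled time (right-continuous step lookup)
        idx = np.clip(np.searchsorted(curve.time, times, side="right") - 1, 0, None)
        n_risk = curve.n_risk[idx]
    return DigitizedCurve(times, values, n_risk=n_risk)


def reconstruct_ipd(curve: DigitizedCurve, assumed_n: int) -> PseudoIPD:
    """Rebuild pseudo-IPD from digitised coordinates by interval allocation.

    The survival drop between consecutive coordinates is converted into
    ``assumed_n * (S_i - S_{i+1})`` event records placed at the later
    coordinate's time (the step-function drop is observed there), with
    fractional counts resolved by largest-remainder rounding so exactly
    ``assumed_n`` records come out.  Subjects still alive after the last
    coordinate are censored at that time.  When a risk table accompanies
    the curve, per-interval censoring is calibrated so the implied risk
    set matches it (censored records placed mid-interval).
    """
    if assumed_n < 1:
        raise ValueError("assumed_n must be at least 1")
    t = np.asarray(curve.time, dtype=float)
    s = np.asarray(curve.survival, dtype=float)
    if t.size < 2:
        raise ValueError("reconstruction needs at least 2 coordinates")

    drops = np.maximum(s[:-1] - s[1:], 0.0)
    raw = assumed_n * drops
    events = np.floor(raw).astype(int)
    # largest-remainder: distribute the leftover integer mass over intervals
    target_events = int(round(assumed_n * (s[0] - s[-1])))
    short = target_events - int(events.sum())
    if short > 0:
        order = np.argsort(-(raw - events))
        events[order[:short]] += 1
    elif short < 0:
        order = np.argsort(raw - events)
        take = 0
        for idx in order:
            if take == -short:
                break
            if events[idx] > 0:
                events[idx] -= 1
                take += 1

    times: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    event_times = t[1:]
    for i, cnt in enumerate(events):
        if cnt > 0:
            times.append(np.full(cnt, event_times[i]))
            flags.append(np.ones(cnt, dtype=bool))

    n_censored = assumed_n - int(events.sum())
    if curve.n_risk is not None:
        risk = np.asarray(curve.n_risk, dtype=float)
        implied = assumed_n - np.concatenate(([0], np.cumsum(events)))
        for i in range(min(risk.size, t.size) - 1):
            cens_i = int(round(implied[i] - events[i] - risk[i + 1]))
            cens_i = int(np.clip(cens_i, 0, n_censored))
            if cens_i > 0:
                times.append(np.full(cens_i, 0.5 * (t[i] + t[i + 1])))
                flags.append(np.zeros(cens_i, dtype=bool))
                n_censored -= cens_i
                implied[i + 1 :] -= cens_i
    if n_censored > 0:
        times.append(np.full(n_censored, t[-1]))
        flags.append(np.zeros(n_censored, dtype=bool))

    time = np.concatenate(times)
    event = np.concatenate(flags)
    time = np.maximum(time, 1e-9)
    order = np.argsort(time, kind="stable")
    return PseudoIPD(time[order], event[order])
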