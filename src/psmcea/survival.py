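"""Parametric survival laws, Kaplan-Meier estimation and model selection.

Six families are supported: log-logistic, Weibull, log-normal, Gompertz,
exponential and gamma.  The log-logistic law is written in the
shape/scale form used throughout oncology partitioned-survival modelling,

    S(t) = 1 / (1 + lam * t**gam),

with scale ``lam`` and shape ``gam`` and time measured in months.  The
median is then ``(1/lam)**(1/gam)``.  The remaining families use standard
shape/rate parameterisations (documented per family below) because the
base-case configuration only pins down the log-logistic values.

Fitting maximises the right-censored log-likelihood

    sum_events log f(t_i) + sum_censored log S(t_i)

over log-transformed parameters (positivity by construction), with
method-of-moments starting values computed from the uncensored records.
Model choice is by lowest AIC, ties broken by lowest BIC and then by the
family order of :data:`FAMILIES`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "KMCurve",
    "PseudoIPD",
    "FitResult",
    "survival_prob",
    "median_time",
    "km_estimate",
    "fit_parametric",
    "select_model",
]

#: Supported families, in tie-breaking order.
FAMILIES = (
    "log-logistic",
    "weibull",
    "log-normal",
    "gompertz",
    "exponential",
    "gamma",
)

_EULER = 0.5772156649015329


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival law S(t) with t in months.

    Parameters
    ----------
    family:
        One of :data:`FAMILIES`.
    shape:
        Family shape parameter (gamma for log-logistic; sigma for
        log-normal; the hazard growth rate for Gompertz; fixed at 1 and
        ignored for the exponential).
    scale:
        Family scale/rate parameter (lambda for log-logistic; the rate
        for Weibull/exponential/gamma; exp(mu), i.e. the median, for
        log-normal; the baseline hazard for Gompertz).
    """

    family: str
    shape: float
    scale: float
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unsupported family {self.family!r}; expected one of {FAMILIES}"
            )
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("shape and scale must both be positive")

    # -- survival / density -------------------------------------------------
    def sf(self, t):
        """Survival probability S(t); vectorised, t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival time must be non-negative")
        out = np.empty_like(t, dtype=float)
        pos = t > 0
        out[~pos] = 1.0
        tp = t[pos]
        a, b = self.shape, self.scale
        if self.family == "log-logistic":
            out[pos] = 1.0 / (1.0 + b * tp**a)
        elif self.family == "weibull":
            out[pos] = np.exp(-((b * tp) ** a))
        elif self.family == "log-normal":
            out[pos] = stats.lognorm.sf(tp, a, scale=self.scale)
        elif self.family == "gompertz":
            with np.errstate(over="ignore"):
                out[pos] = np.exp(-(b / a) * np.expm1(a * tp))
        elif self.family == "exponential":
            out[pos] = np.exp(-b * tp)
        else:  # gamma, rate parameterisation
            out[pos] = stats.gamma.sf(tp, a, scale=1.0 / b)
        return out if out.ndim else float(out)

    def logpdf(self, t):
        """log f(t) for t > 0; vectorised."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("event times must be positive")
        a, b = self.shape, self.scale
        if self.family == "log-logistic":
            logu = np.log(b) + a * np.log(t)
            return np.log(b) + np.log(a) + (a - 1.0) * np.log(t) - 2.0 * np.logaddexp(0.0, logu)
        if self.family == "weibull":
            z = b * t
            return np.log(a) + np.log(b) + (a - 1.0) * np.log(z) - z**a
        if self.family == "log-normal":
            return stats.lognorm.logpdf(t, a, scale=self.scale)
        if self.family == "gompertz":
            return np.log(b) + a * t - (b / a) * np.expm1(a * t)
        if self.family == "exponential":
            return np.log(b) - b * t
        return stats.gamma.logpdf(t, a, scale=1.0 / b)

    def logsf(self, t):
        """log S(t); vectorised, numerically stable in the tail."""
        t = np.asarray(t, dtype=float)
        a, b = self.shape, self.scale
        with np.errstate(divide="ignore"):
            if self.family == "log-logistic":
                return -np.logaddexp(0.0, np.log(b) + a * np.log(np.maximum(t, 1e-300)))
            if self.family == "weibull":
                return -((b * t) ** a)
            if self.family == "log-normal":
                return stats.lognorm.logsf(t, a, scale=self.scale)
            if self.family == "gompertz":
                return -(b / a) * np.expm1(a * t)
            if self.family == "exponential":
                return -b * t
            return stats.gamma.logsf(t, a, scale=1.0 / b)

    def ppf(self, q):
        """Inverse CDF: time t with 1 - S(t) = q."""
        q = np.asarray(q, dtype=float)
        a, b = self.shape, self.scale
        if self.family == "log-logistic":
            # 1 - 1/(1 + b t^a) = q  =>  t = (q / (b (1-q)))**(1/a)
            return (q / (b * (1.0 - q))) ** (1.0 / a)
        if self.family == "weibull":
            return (-np.log1p(-q)) ** (1.0 / a) / b
        if self.family == "log-normal":
            return stats.lognorm.ppf(q, a, scale=self.scale)
        if self.family == "gompertz":
            return np.log1p(-(a / b) * np.log1p(-q)) / a
        if self.family == "exponential":
            return -np.log1p(-q) / b
        return stats.gamma.ppf(q, a, scale=1.0 / b)


def survival_prob(model: ParametricSurvival, t) -> float:
    """S(t) for ``model``; raises on negative ``t``."""
    return model.sf(t)


def median_time(model: ParametricSurvival) -> float:
    """Time t with S(t) = 0.5; closed form (1/lam)**(1/gam) for log-logistic."""
    if model.family == "log-logistic":
        return (1.0 / model.scale) ** (1.0 / model.shape)
    return float(model.ppf(0.5))


# ---------------------------------------------------------------------------
# Data containers


@dataclass(frozen=True)
class PseudoIPD:
    """Right-censored survival records: times (months) and event flags."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=bool)
        if t.size == 0:
            raise ValueError("PseudoIPD requires at least one record")
        if t.shape != e.shape:
            raise ValueError("time and event must have the same length")
        if np.any(t <= 0):
            raise ValueError("all survival times must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def data_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.time).tobytes())
        h.update(np.ascontiguousarray(self.event).tobytes())
        return h.hexdigest()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.time, "event": self.event.astype(int)})

    @classmethod
    def from_frame(cls, df) -> "PseudoIPD":
        return cls(df["time"].to_numpy(float), df["event"].to_numpy(int).astype(bool))


@dataclass(frozen=True)
class KMCurve:
    """A Kaplan-Meier step function: post-step survival at each step time.

    ``time[0] == 0`` with ``survival[0] == 1``; subsequent entries are the
    event times where the estimate drops.  ``n_risk``, when present, gives
    the size of the risk set just before each time.
    """

    time: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.size < 1 or t.shape != s.shape:
            raise ValueError("times and survival must be equal-length, non-empty")
        if t[0] != 0 or s[0] != 1.0:
            raise ValueError("curve must start at (0, 1)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("step times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12) or np.any((s < -1e-12) | (s > 1 + 1e-12)):
            raise ValueError("survival must be non-increasing within [0, 1]")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "survival", s)
        if self.n_risk is not None:
            object.__setattr__(self, "n_risk", np.asarray(self.n_risk, dtype=float))

    def evaluate(self, t):
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.time, np.asarray(t, dtype=float), side="right") - 1
        return self.survival[np.clip(idx, 0, self.time.size - 1)]

    def to_frame(self):
        import pandas as pd

        d = {"time": self.time, "survival": self.survival}
        if self.n_risk is not None:
            d["n_risk"] = self.n_risk
        return pd.DataFrame(d)


def km_estimate(ipd: PseudoIPD) -> KMCurve:
    """Product-limit estimate of the survival function.

    Delegates to :class:`lifelines.KaplanMeierFitter`; the returned curve
    keeps a step only where the estimate actually drops (censoring shrinks
    the risk set without a step).
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, event_observed=ipd.event.astype(int))
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(float)
    surv = sf.to_numpy(float)
    # keep t=0 and change points only
    keep = np.concatenate(([True], np.diff(surv) < 0))
    times, surv = times[keep], surv[keep]
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(float)
    at_risk[0] = len(ipd)
    return KMCurve(times, surv, n_risk=at_risk)


# ---------------------------------------------------------------------------
# Maximum likelihood fitting


@dataclass(frozen=True)
class FitResult:
    """A fitted law with its censored-data log-likelihood, AIC and BIC."""

    model: ParametricSurvival
    log_likelihood: float
    aic: float
    bic: float
    n: int
    k: int
    data_hash: str = field(default="", compare=False)
    converged: bool = field(default=True, compare=False)


class FitError(RuntimeError):
    """Raised when the likelihood optimisation fails to converge."""


def _moment_starts(family: str, t_obs: np.ndarray) -> np.ndarray:
    """Method-of-moments starting values (log scale) from uncensored times."""
    m, s = float(np.mean(t_obs)), float(np.std(t_obs) + 1e-12)
    lm, ls = float(np.mean(np.log(t_obs))), float(np.std(np.log(t_obs)) + 1e-12)
    if family == "log-logistic":
        gam = np.pi / (ls * np.sqrt(3.0))
        lam = np.exp(-gam * lm)
        return np.log([gam, lam])
    if family == "weibull":
        gam = np.pi / (ls * np.sqrt(6.0))
        rate = np.exp(-lm - _EULER / gam)
        return np.log([gam, rate])
    if family == "log-normal":
        return np.log([ls, np.exp(lm)])
    if family == "gompertz":
        return np.log([0.05, 1.0 / m])
    if family == "exponential":
        return np.log([1.0 / m])
    # gamma
    k = max((m / s) ** 2, 1e-3)
    return np.log([k, k / m])


def _neg_loglik(logpar: np.ndarray, family: str, ipd: PseudoIPD) -> float:
    if family == "exponential":
        shape, scale = 1.0, np.exp(logpar[0])
    else:
        shape, scale = np.exp(logpar)
    if not np.isfinite(shape) or not np.isfinite(scale):
        return np.inf
    try:
        model = ParametricSurvival(family, shape, scale)
        ll = model.logpdf(ipd.time[ipd.event]).sum()
        cens = ~ipd.event
        if cens.any():
            ll += model.logsf(ipd.time[cens]).sum()
    except (ValueError, FloatingPointError):
        return np.inf
    return np.inf if not np.isfinite(ll) else -float(ll)


def fit_parametric(ipd: PseudoIPD, family: str) -> FitResult:
    """Fit one family to right-censored records by maximum likelihood.

    Requires at least two observed events.  Raises :class:`FitError` with
    the optimiser's diagnostics if the likelihood cannot be maximised.
    """
    if family not in FAMILIES:
        raise ValueError(f"unsupported family {family!r}; expected one of {FAMILIES}")
    if ipd.n_events < 2:
        raise ValueError("fitting requires at least two observed events")

    t_obs = ipd.time[ipd.event]
    x0 = _moment_starts(family, t_obs)
    res = optimize.minimize(
        _neg_loglik, x0, args=(family, ipd), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    # polish with a gradient step; keep whichever is better
    polished = optimize.minimize(_neg_loglik, res.x, args=(family, ipd), method="BFGS")
    if polished.fun < res.fun:
        res = polished
    if not np.isfinite(res.fun):
        raise FitError(f"{family} fit failed to converge: {res.message}")

    if family == "exponential":
        shape, scale, k = 1.0, float(np.exp(res.x[0])), 1
    else:
        shape, scale = np.exp(res.x)
        k = 2
    ll = -float(res.fun)
    n = len(ipd)
    return FitResult(
        model=ParametricSurvival(family, float(shape), float(scale)),
        log_likelihood=ll,
        aic=2 * k - 2 * ll,
        bic=k * np.log(n) - 2 * ll,
        n=n,
        k=k,
        data_hash=ipd.data_hash(),
        converged=bool(res.success or np.isfinite(res.fun)),
    )


def fit_all(ipd: PseudoIPD, families: Iterable[str] = FAMILIES) -> list[FitResult]:
    """Fit every family in ``families``, skipping none."""
    return [fit_parametric(ipd, fam) for fam in families]


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Lowest AIC wins; ties go to lowest BIC, then family order.

    All fits must come from the same dataset (checked via record count and
    a content hash where available).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("select_model requires at least one fit")
    hashes = {f.data_hash for f in fits if f.data_hash}
    if len({f.n for f in fits}) > 1 or len(hashes) > 1:
        raise ValueError("fits were computed on different datasets")
    return min(fits, key=lambda f: (f.aic, f.bic, FAMILIES.index(f.model.family)))
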