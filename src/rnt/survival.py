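"""Kaplan-Meier estimation, Greenwood variance, and restricted mean survival time.

These are the building blocks every survival effect measure in this package
consumes: the product-limit survival estimate S(t) with its pointwise
Greenwood variance, the step-function evaluation S(tau), and the restricted
mean survival time RMST(tau) — the area under the KM curve on [0, tau] —
with its Greenwood-type variance

    Var(RMST(tau)) = sum_{t_i <= tau} A(t_i, tau)^2 d_i / (n_i (n_i - d_i)),

where A(t_i, tau) is the area under the curve from t_i to tau, d_i the
events and n_i the number at risk at event time t_i.

Conventions: right-censoring only; at tied times events precede censorings
(censored subjects remain in the risk set for the tie); evaluation beyond
the largest observed time is an error, never an extrapolation.  When the
curve reaches zero (largest risk set exhausted by events) the Greenwood sum
is truncated at the last time with survivors and the variance is flagged as
a lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InestimableError

__all__ = [
    "SurvivalData",
    "KMCurve",
    "RMSTEstimate",
    "km_fit",
    "survival_at",
    "rmst",
    "read_survival_data",
    "split_arms",
    "km_table",
]


@dataclass(frozen=True)
class SurvivalData:
    """Per-subject follow-up for one arm: positive times and 1/0 event flags."""

    times: np.ndarray
    events: np.ndarray
    arm_label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        object.__setattr__(self, "times", times)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("times must be a non-empty 1-d array")
        if np.any(~np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("all follow-up times must be positive and finite")
        if events.shape != times.shape:
            raise ValueError("events must have the same length as times")
        ev = np.asarray(events, dtype=float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise ValueError("event indicators must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "events", ev.astype(np.int8))

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate over the distinct observed event times."""

    event_times: np.ndarray
    surv: np.ndarray
    var: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    max_follow_up: float
    var_truncated: bool = False
    arm_label: str = ""


@dataclass(frozen=True)
class RMSTEstimate:
    """Restricted mean survival time up to ``tau`` with its variance."""

    tau: float
    value: float
    variance: float
    var_truncated: bool = False


def km_fit(data: SurvivalData) -> KMCurve:
    """Fit the Kaplan-Meier estimator with Greenwood pointwise variance."""
    order = np.argsort(data.times, kind="stable")
    times = data.times[order]
    events = data.events[order]
    n = times.size

    is_event = events == 1
    if not np.any(is_event):
        return KMCurve(
            event_times=np.empty(0),
            surv=np.empty(0),
            var=np.empty(0),
            n_at_risk=np.empty(0, dtype=int),
            n_events=np.empty(0, dtype=int),
            max_follow_up=float(times[-1]),
            arm_label=data.arm_label,
        )

    uniq, counts = np.unique(times[is_event], return_counts=True)
    # subjects with time >= t are at risk at t (ties: censored stay at risk)
    n_risk = n - np.searchsorted(times, uniq, side="left")
    frac = counts / n_risk
    surv = np.cumprod(1.0 - frac)

    with np.errstate(divide="ignore"):
        terms = counts / (n_risk * (n_risk - counts))
    exhausted = n_risk == counts  # curve reaches 0 here; Greenwood term infinite
    var_truncated = bool(np.any(exhausted))
    terms = np.where(exhausted, 0.0, terms)
    var = surv**2 * np.cumsum(terms)

    return KMCurve(
        event_times=uniq,
        surv=surv,
        var=var,
        n_at_risk=n_risk.astype(int),
        n_events=counts.astype(int),
        max_follow_up=float(times[-1]),
        var_truncated=var_truncated,
        arm_label=data.arm_label,
    )


def _check_tau(curve: KMCurve, tau: float) -> None:
    if tau > curve.max_follow_up:
        raise InestimableError(
            f"tau={tau:g} exceeds the largest observed time "
            f"{curve.max_follow_up:g}; the survival curve is not estimable there"
        )


def survival_at(curve: KMCurve, tau: float) -> tuple[float, float]:
    """Evaluate (S(tau), Var(S(tau))) on the right-continuous step function."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    _check_tau(curve, tau)
    idx = int(np.searchsorted(curve.event_times, tau, side="right")) - 1
    if idx < 0:
        return 1.0, 0.0
    return float(curve.surv[idx]), float(curve.var[idx])


def rmst(curve: KMCurve, tau: float) -> RMSTEstimate:
    """Area under the KM step function on [0, tau], with Greenwood-type variance."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    _check_tau(curve, tau)
    k = int(np.searchsorted(curve.event_times, tau, side="right"))
    if k == 0:
        return RMSTEstimate(tau=tau, value=tau, variance=0.0)

    knots = curve.event_times[:k]
    surv = curve.surv[:k]
    # area of each step: S before the jump times the step width
    widths = np.diff(np.concatenate(([0.0], knots)))
    s_before = np.concatenate(([1.0], surv[:-1]))
    value = float(s_before @ widths + surv[-1] * (tau - knots[-1]))

    # A[i] = area under the curve from knots[i] to tau
    seg = np.concatenate((surv[:-1] * np.diff(knots), [surv[-1] * (tau - knots[-1])]))
    area_from = np.cumsum(seg[::-1])[::-1]

    d = curve.n_events[:k].astype(float)
    n_risk = curve.n_at_risk[:k].astype(float)
    exhausted = n_risk == d
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = area_from**2 * d / (n_risk * (n_risk - d))
    terms = np.where(exhausted, 0.0, terms)
    return RMSTEstimate(
        tau=tau,
        value=value,
        variance=float(terms.sum()),
        var_truncated=bool(np.any(exhausted)),
    )


_TRUTHY = {"1", "true", "t", "yes", "event", "dead", "death"}
_FALSY = {"0", "false", "f", "no", "censored", "censor", "alive"}


def _parse_events(values: pd.Series, event_value: str | None) -> np.ndarray:
    """Map an event column to 1/0, accepting booleans and common string dialects."""
    if event_value is not None:
        return (values.astype(str).str.strip() == str(event_value)).to_numpy(dtype=int)
    if values.dtype == bool:
        return values.to_numpy(dtype=int)
    if pd.api.types.is_numeric_dtype(values):
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isin(arr, (0.0, 1.0))):
            raise ValueError(
                "numeric event column must contain only 0/1; pass event_value "
                "to select the code that marks an event"
            )
        return arr.astype(int)
    lowered = values.astype(str).str.strip().str.lower()
    if not lowered.isin(_TRUTHY | _FALSY).all():
        unknown = sorted(set(lowered) - (_TRUTHY | _FALSY))
        raise ValueError(
            f"unrecognised event codes {unknown}; pass event_value to map them"
        )
    return lowered.isin(_TRUTHY).to_numpy(dtype=int)


def read_survival_data(
    path,
    time_col: str = "time",
    event_col: str = "event",
    arm_col: str = "arm",
    event_value: str | None = None,
    sep: str | None = None,
) -> dict[str, SurvivalData]:
    """Read subject-level two-arm survival data from delimited text.

    Returns a mapping from arm label to :class:`SurvivalData`.  The delimiter
    is sniffed (CSV/TSV) unless ``sep`` is given; ``event_value`` forces a
    specific code to mean "event observed".
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    for col in (time_col, event_col, arm_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {list(df.columns)}")
    out: dict[str, SurvivalData] = {}
    for label, grp in df.groupby(arm_col, sort=True):
        out[str(label)] = SurvivalData(
            times=grp[time_col].to_numpy(dtype=float),
            events=_parse_events(grp[event_col], event_value),
            arm_label=str(label),
        )
    return out


def split_arms(
    arms: dict[str, SurvivalData], control_label: str
) -> tuple[SurvivalData, SurvivalData]:
    """Split a two-arm mapping into (control, treatment) by the control label."""
    if control_label not in arms:
        raise ValueError(
            f"control label {control_label!r} not among arms {sorted(arms)}"
        )
    others = [k for k in arms if k != control_label]
    if len(others) != 1:
        raise ValueError(f"expected exactly two arms, found {sorted(arms)}")
    return arms[control_label], arms[others[0]]


def km_table(curve: KMCurve) -> pd.DataFrame:
    """The fitted curve as a tidy table (time, n_risk, n_event, survival, std_err)."""
    return pd.DataFrame(
        {
            "time": curve.event_times,
            "n_risk": curve.n_at_risk,
            "n_event": curve.n_events,
            "survival": curve.surv,
            "std_err": np.sqrt(curve.var),
        }
    )
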