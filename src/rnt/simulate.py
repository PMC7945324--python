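"""Synthetic two-arm trials for binary and survival endpoints.

Survival times follow piecewise-constant hazards, sampled by inverting the
cumulative hazard at a standard-exponential draw; the survival function,
its restricted mean and hence every effect measure in this package are
available in closed form from the same configuration, so estimators can be
checked for consistency against analytic truth.  Right censoring can be
administrative (a fixed study end), random (uniform or exponential), or
both.

Four scenario presets reproduce the canonical qualitative geometries of
two-arm survival comparisons:

* ``a`` — proportional hazards, treatment uniformly better;
* ``b`` — curves diverge then converge, meeting exactly at the horizon;
* ``c`` — a single interior crossing (treatment better early, worse late);
* ``d`` — two diverge/converge cycles, touching mid-follow-up and at the end.

Randomness uses one root seed with per-component child streams
(:class:`numpy.random.SeedSequence`), so adding a consumer does not perturb
existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binary import BinaryArm, rnt_bootstrap_ci, rnt_exact_ci, rnt_wald_ci
from .effects import perturbation_ci, rnt_rmst_wald_ci, rnt_surv_wald_ci
from .survival import SurvivalData, km_fit

__all__ = [
    "PiecewiseHazard",
    "CensoringSpec",
    "ScenarioConfig",
    "simulate_binary",
    "simulate_survival",
    "scenario_preset",
    "coverage_experiment",
    "config_from_dict",
]


@dataclass(frozen=True)
class PiecewiseHazard:
    """Piecewise-constant hazard: ``rates[i]`` on [breakpoints[i-1], breakpoints[i])."""

    rates: tuple[float, ...]
    breakpoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.rates)
        breaks = tuple(float(b) for b in self.breakpoints)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "breakpoints", breaks)
        if len(rates) == 0 or any(r <= 0 for r in rates):
            raise ValueError("hazard rates must be positive")
        if len(breaks) != len(rates) - 1:
            raise ValueError("need exactly len(rates) - 1 breakpoints")
        if any(b <= 0 for b in breaks) or any(
            b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])
        ):
            raise ValueError("breakpoints must be positive and strictly increasing")

    def _edges(self) -> np.ndarray:
        return np.concatenate(([0.0], self.breakpoints))

    def cum_hazard(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        edges = self._edges()
        widths = np.append(np.diff(edges), np.inf)
        dur = np.clip(t[..., None] - edges, 0.0, widths)
        return dur @ np.asarray(self.rates)

    def survival(self, t) -> np.ndarray:
        return np.exp(-self.cum_hazard(t))

    def quantile_time(self, h) -> np.ndarray:
        """Inverse cumulative hazard (event time for exponential draw ``h``)."""
        h = np.asarray(h, dtype=float)
        edges = self._edges()
        h_edges = self.cum_hazard(edges)
        idx = np.clip(np.searchsorted(h_edges, h, side="right") - 1, 0, len(self.rates) - 1)
        rates = np.asarray(self.rates)
        return edges[idx] + (h - h_edges[idx]) / rates[idx]

    def rmst(self, tau: float) -> float:
        """Restricted mean: integral of the survival function on [0, tau]."""
        if tau <= 0:
            raise ValueError("tau must be positive")
        edges = self._edges()
        widths = np.append(np.diff(edges), np.inf)
        dur = np.clip(tau - edges, 0.0, widths)
        s_start = np.exp(-self.cum_hazard(edges))
        rates = np.asarray(self.rates)
        return float(np.sum(s_start * (1.0 - np.exp(-rates * dur)) / rates))

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self.quantile_time(rng.exponential(1.0, size))


@dataclass(frozen=True)
class CensoringSpec:
    """Right-censoring: administrative cutoff and/or an independent random law.

    ``random`` is ``("uniform", low, high)`` or ``("exponential", rate)``.
    """

    admin_time: float | None = None
    random: tuple | None = None

    def __post_init__(self) -> None:
        if self.admin_time is not None and self.admin_time <= 0:
            raise ValueError("administrative censoring time must be positive")
        if self.random is not None:
            kind = self.random[0]
            if kind == "uniform":
                _, low, high = self.random
                if not 0 <= low < high:
                    raise ValueError("uniform censoring needs 0 <= low < high")
            elif kind == "exponential":
                _, rate = self.random
                if rate <= 0:
                    raise ValueError("exponential censoring rate must be positive")
            else:
                raise ValueError(f"unknown censoring law {kind!r}")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        c = np.full(size, np.inf)
        if self.random is not None:
            if self.random[0] == "uniform":
                c = rng.uniform(self.random[1], self.random[2], size)
            else:
                c = rng.exponential(1.0 / self.random[1], size)
        if self.admin_time is not None:
            c = np.minimum(c, self.admin_time)
        return c


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative description of a synthetic two-arm trial."""

    endpoint: str
    n_control: int
    n_treatment: int
    p_control: float | None = None
    p_treatment: float | None = None
    hazard_control: PiecewiseHazard | None = None
    hazard_treatment: PiecewiseHazard | None = None
    censoring: CensoringSpec | None = None
    horizon: float | None = None
    seed: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.endpoint not in ("binary", "survival"):
            raise ValueError("endpoint must be 'binary' or 'survival'")
        if self.n_control < 1 or self.n_treatment < 1:
            raise ValueError("arm sizes must be >= 1")
        if self.endpoint == "binary":
            for p in (self.p_control, self.p_treatment):
                if p is None or not 0.0 < p < 1.0:
                    raise ValueError("binary endpoint needs rates in (0, 1)")
        else:
            if self.hazard_control is None or self.hazard_treatment is None:
                raise ValueError("survival endpoint needs a hazard per arm")

    # ---- closed-form truths -------------------------------------------------

    def true_rnt(self) -> float:
        return 1.0 / self.p_control - 1.0 / self.p_treatment

    def true_survival(self, arm: str, t) -> np.ndarray:
        hz = self.hazard_control if arm == "control" else self.hazard_treatment
        return hz.survival(t)

    def true_rnt_surv(self, tau: float) -> float:
        s_c = float(self.hazard_control.survival(tau))
        s_e = float(self.hazard_treatment.survival(tau))
        return 1.0 / s_c - 1.0 / s_e

    def true_nnt_surv(self, tau: float) -> float:
        s_c = float(self.hazard_control.survival(tau))
        s_e = float(self.hazard_treatment.survival(tau))
        return np.inf if s_e == s_c else 1.0 / (s_e - s_c)

    def true_rmst(self, arm: str, tau: float) -> float:
        hz = self.hazard_control if arm == "control" else self.hazard_treatment
        return hz.rmst(tau)

    def true_rnt_rmst(self, tau: float) -> float:
        return tau * (
            1.0 / self.hazard_control.rmst(tau) - 1.0 / self.hazard_treatment.rmst(tau)
        )

    def true_nnt_rmst(self, tau: float) -> float:
        diff = self.hazard_treatment.rmst(tau) - self.hazard_control.rmst(tau)
        return np.inf if diff == 0.0 else tau / diff


def _seed_sequence(config: ScenarioConfig, seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if seed is None:
        seed = config.seed
    return np.random.SeedSequence(seed)


def simulate_binary(
    config: ScenarioConfig, seed=None
) -> tuple[BinaryArm, BinaryArm]:
    """Draw (control, treatment) responder counts from the configured rates."""
    if config.endpoint != "binary":
        raise ValueError("config does not describe a binary endpoint")
    ss = _seed_sequence(config, seed)
    rng_c, rng_e = (np.random.default_rng(s) for s in ss.spawn(2))
    control = BinaryArm(config.n_control, int(rng_c.binomial(config.n_control, config.p_control)))
    treatment = BinaryArm(
        config.n_treatment, int(rng_e.binomial(config.n_treatment, config.p_treatment))
    )
    return control, treatment


def simulate_survival(
    config: ScenarioConfig, seed=None
) -> tuple[SurvivalData, SurvivalData]:
    """Draw (control, treatment) subject-level survival data.

    Event times come from the piecewise-exponential inverse cumulative
    hazard; the observed time is the minimum of event and censoring times
    and the indicator marks whether the event was observed.
    """
    if config.endpoint != "survival":
        raise ValueError("config does not describe a survival endpoint")
    ss = _seed_sequence(config, seed)
    streams = ss.spawn(4)
    out = []
    for arm, hazard, n, ev_stream, cen_stream in (
        ("control", config.hazard_control, config.n_control, streams[0], streams[1]),
        ("treatment", config.hazard_treatment, config.n_treatment, streams[2], streams[3]),
    ):
        rng_ev = np.random.default_rng(ev_stream)
        rng_cen = np.random.default_rng(cen_stream)
        t = hazard.sample(n, rng_ev)
        c = (
            config.censoring.sample(n, rng_cen)
            if config.censoring is not None
            else np.full(n, np.inf)
        )
        observed = np.minimum(t, c)
        events = (t <= c).astype(int)
        out.append(SurvivalData(times=observed, events=events, arm_label=arm))
    return out[0], out[1]


_PRESETS = {
    "a": dict(
        hazard_control=PiecewiseHazard((0.25,)),
        hazard_treatment=PiecewiseHazard((0.125,)),
        horizon=4.0,
    ),
    "b": dict(
        hazard_control=PiecewiseHazard((0.5,)),
        hazard_treatment=PiecewiseHazard((0.25, 0.75), (1.0,)),
        horizon=2.0,
    ),
    "c": dict(
        hazard_control=PiecewiseHazard((0.5,)),
        hazard_treatment=PiecewiseHazard((0.15, 1.2), (1.0,)),
        horizon=2.5,
    ),
    "d": dict(
        hazard_control=PiecewiseHazard((0.5,)),
        hazard_treatment=PiecewiseHazard((0.25, 0.75, 0.25, 0.75), (0.5, 1.0, 1.5)),
        horizon=2.0,
    ),
}


def scenario_preset(name: str, n_per_arm: int = 200, seed: int | None = 0) -> ScenarioConfig:
    """Survival scenario preset ``a`` | ``b`` | ``c`` | ``d`` (see module docs).

    Administrative censoring is applied at the scenario horizon.  Preset
    ``b`` has equal cumulative hazards exactly at the horizon; preset ``c``
    has its crossing at t = 1.5; preset ``d`` touches at t = 1 and t = 2.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    p = _PRESETS[name]
    return ScenarioConfig(
        endpoint="survival",
        n_control=n_per_arm,
        n_treatment=n_per_arm,
        hazard_control=p["hazard_control"],
        hazard_treatment=p["hazard_treatment"],
        censoring=CensoringSpec(admin_time=p["horizon"]),
        horizon=p["horizon"],
        seed=seed,
        name=name,
    )


def survival_frame(control: SurvivalData, treatment: SurvivalData) -> pd.DataFrame:
    """Subject-level tidy table (time, event, arm) for the CSV round trip."""
    return pd.DataFrame(
        {
            "time": np.concatenate((control.times, treatment.times)),
            "event": np.concatenate((control.events, treatment.events)),
            "arm": ["control"] * len(control) + ["treatment"] * len(treatment),
        }
    )


def censoring_fraction(data: SurvivalData) -> float:
    return float(1.0 - data.events.mean())


def coverage_experiment(
    config: ScenarioConfig,
    measure: str,
    ci_methods,
    alpha: float = 0.05,
    n_sims: int = 1000,
    reps: int = 1000,
    seed: int | None = None,
    tau: float | None = None,
) -> pd.DataFrame:
    """Empirical coverage and width of CIs against the closed-form truth.

    For each simulated trial every requested method builds a level-(1-alpha)
    CI for ``measure`` (binary: RNT with wald / bootstrap / exact; survival:
    RNT_surv / RNT_RMST with wald / perturbation); the table reports, per
    method, the fraction of CIs containing the true value, the mean interval
    width and the number of simulations where estimation failed.
    """
    ci_methods = list(ci_methods)
    if config.endpoint == "binary":
        if measure != "RNT":
            raise ValueError("binary coverage supports measure 'RNT'")
        truth = config.true_rnt()
    else:
        if tau is None:
            raise ValueError("survival coverage needs a tau")
        truth = {
            "RNT_surv": config.true_rnt_surv,
            "RNT_RMST": config.true_rnt_rmst,
        }[measure](tau)

    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    covered = {m: 0 for m in ci_methods}
    widths = {m: 0.0 for m in ci_methods}
    n_ok = {m: 0 for m in ci_methods}
    failed = {m: 0 for m in ci_methods}

    for sim_ss in ss.spawn(n_sims):
        children = sim_ss.spawn(1 + len(ci_methods))
        if config.endpoint == "binary":
            control, treatment = simulate_binary(config, seed=children[0])
        else:
            control, treatment = simulate_survival(config, seed=children[0])
            curve_c = km_fit(control)
            curve_e = km_fit(treatment)
        for method, method_ss in zip(ci_methods, children[1:]):
            try:
                if config.endpoint == "binary":
                    if method == "wald":
                        est = rnt_wald_ci(control, treatment, alpha)
                    elif method == "bootstrap":
                        est = rnt_bootstrap_ci(
                            control,
                            treatment,
                            alpha,
                            reps=reps,
                            seed=np.random.default_rng(method_ss),
                        )
                    elif method == "exact":
                        est = rnt_exact_ci(control, treatment, alpha)
                    else:
                        raise ValueError(f"unknown binary CI method {method!r}")
                else:
                    if method == "wald":
                        fn = (
                            rnt_surv_wald_ci
                            if measure == "RNT_surv"
                            else rnt_rmst_wald_ci
                        )
                        est = fn(curve_c, curve_e, tau, alpha)
                    elif method == "perturbation":
                        est = perturbation_ci(
                            control,
                            treatment,
                            tau,
                            measure=measure,
                            alpha=alpha,
                            reps=reps,
                            seed=method_ss,
                        )
                    else:
                        raise ValueError(f"unknown survival CI method {method!r}")
            except ValueError as exc:
                if "unknown" in str(exc):
                    raise
                failed[method] += 1
                continue
            except RuntimeError:
                failed[method] += 1
                continue
            ci = est.ci
            n_ok[method] += 1
            if ci.lower <= truth <= ci.upper:
                covered[method] += 1
            if np.isfinite(ci.upper - ci.lower):
                widths[method] += ci.upper - ci.lower

    rows = []
    for m in ci_methods:
        rows.append(
            {
                "measure": measure,
                "method": m,
                "n_sims": n_sims,
                "n_evaluated": n_ok[m],
                "coverage": covered[m] / n_ok[m] if n_ok[m] else np.nan,
                "mean_width": widths[m] / n_ok[m] if n_ok[m] else np.nan,
                "n_failed": failed[m],
                "alpha": alpha,
                "true_value": truth,
            }
        )
    return pd.DataFrame(rows)


def config_from_dict(d: dict) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a plain (JSON-friendly) mapping."""
    d = dict(d)
    for key in ("hazard_control", "hazard_treatment"):
        if d.get(key) is not None and not isinstance(d[key], PiecewiseHazard):
            spec = d[key]
            d[key] = PiecewiseHazard(
                tuple(spec["rates"]), tuple(spec.get("breakpoints", ()))
            )
    if d.get("censoring") is not None and not isinstance(d["censoring"], CensoringSpec):
        spec = d["censoring"]
        random = tuple(spec["random"]) if spec.get("random") else None
        d["censoring"] = CensoringSpec(admin_time=spec.get("admin_time"), random=random)
    return ScenarioConfig(**d)
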