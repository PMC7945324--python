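"""Effect measures for time-to-event endpoints.

Two families, both available as point estimates with Wald (delta-method) or
perturbation-resampling confidence intervals:

* survival-rate based, at a prespecified follow-up time tau:
  ``NNT_surv = 1 / (S_E(tau) - S_C(tau))`` and
  ``RNT_surv = 1/S_C(tau) - 1/S_E(tau)``;
* RMST based, summarising the whole follow-up profile up to tau:
  ``NNT_RMST = tau / (RMST_E - RMST_C)`` and
  ``RNT_RMST = tau * (1/RMST_C - 1/RMST_E)``, i.e. the binary RNT applied
  to the tau-normalised rates ``RMST/tau``.

Survival-rate measures use only local information at tau: they flip sign at
a curve crossing and are erratic when both survival rates are small.  The
RMST measures are cumulative, so they vary smoothly in tau and keep their
sign across an interior crossing while the early benefit still dominates
the areas.

The delta-method variances are ``Var(S)/S^4`` per arm for RNT_surv and
``Var(RMST)/RMST^4`` (times tau^2) for RNT_RMST.  The perturbation
resampler reweights every subject's contribution to the risk and event
processes with independent standard-exponential multipliers (unit mean and
variance), recomputes the weighted Kaplan-Meier curve or RMST, and takes
percentile intervals — avoiding the discreteness of resampling subjects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import z_quantile
from .estimates import CIForm, EffectEstimate
from .exceptions import BoundaryRateError, UndefinedMeasureError, UnstableEstimateError
from .survival import KMCurve, SurvivalData, km_fit, rmst, survival_at

__all__ = [
    "nnt_surv",
    "rnt_surv",
    "nnt_rmst",
    "rnt_rmst",
    "rnt_surv_wald_ci",
    "rnt_rmst_wald_ci",
    "nnt_surv_ci",
    "nnt_rmst_ci",
    "perturbation_ci",
    "EffectProfile",
    "effect_profile",
    "SURVIVAL_MEASURES",
]

SURVIVAL_MEASURES = ("RNT_surv", "NNT_surv", "RNT_RMST", "NNT_RMST")

#: survival-rate measures are flagged unstable below this survival probability
UNSTABLE_SURVIVAL = 0.05


# ---------------------------------------------------------------- point estimates


def nnt_surv(control_curve: KMCurve, treatment_curve: KMCurve, tau: float) -> float:
    """``1 / (S_E(tau) - S_C(tau))``; signed infinity where the curves touch."""
    s_c, _ = survival_at(control_curve, tau)
    s_e, _ = survival_at(treatment_curve, tau)
    diff = s_e - s_c
    if diff == 0.0:
        return math.inf
    return 1.0 / diff


def rnt_surv(control_curve: KMCurve, treatment_curve: KMCurve, tau: float) -> float:
    """``1/S_C(tau) - 1/S_E(tau)``; zero exactly at curve crossings."""
    s_c, _ = survival_at(control_curve, tau)
    s_e, _ = survival_at(treatment_curve, tau)
    if s_c == 0.0 or s_e == 0.0:
        raise UndefinedMeasureError(
            f"RNT_surv is undefined at tau={tau:g}: estimated survival is zero "
            f"(S_C={s_c:.4g}, S_E={s_e:.4g})"
        )
    return 1.0 / s_c - 1.0 / s_e


def rnt_rmst(control_curve: KMCurve, treatment_curve: KMCurve, tau: float) -> float:
    """``tau * (1/RMST_C(tau) - 1/RMST_E(tau))``, in patients."""
    r_c = rmst(control_curve, tau).value
    r_e = rmst(treatment_curve, tau).value
    return tau * (1.0 / r_c - 1.0 / r_e)


def nnt_rmst(control_curve: KMCurve, treatment_curve: KMCurve, tau: float) -> float:
    """``tau / (RMST_E(tau) - RMST_C(tau))``; infinity when the RMSTs are equal."""
    diff = rmst(treatment_curve, tau).value - rmst(control_curve, tau).value
    if diff == 0.0:
        return math.inf
    return tau / diff


# ---------------------------------------------------------------- Wald intervals


def rnt_surv_wald_ci(
    control_curve: KMCurve,
    treatment_curve: KMCurve,
    tau: float,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Delta-method Wald CI for RNT_surv using Greenwood variances."""
    s_c, v_c = survival_at(control_curve, tau)
    s_e, v_e = survival_at(treatment_curve, tau)
    if not (0.0 < s_c < 1.0 and 0.0 < s_e < 1.0):
        raise BoundaryRateError(
            f"Wald CI for RNT_surv is undefined at tau={tau:g} where an "
            f"estimated survival rate is 0 or 1 (S_C={s_c:.4g}, S_E={s_e:.4g}); "
            "use the perturbation CI"
        )
    point = 1.0 / s_c - 1.0 / s_e
    half = z_quantile(alpha) * math.sqrt(v_c / s_c**4 + v_e / s_e**4)
    flags = ("unstable",) if min(s_c, s_e) < UNSTABLE_SURVIVAL else ()
    return EffectEstimate(
        "RNT_surv",
        point=point,
        ci=CIForm.regular(point - half, point + half),
        alpha=alpha,
        method="wald",
        flags=flags,
    )


def rnt_rmst_wald_ci(
    control_curve: KMCurve,
    treatment_curve: KMCurve,
    tau: float,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Delta-method Wald CI for RNT_RMST using the Greenwood-type RMST variances."""
    r_c = rmst(control_curve, tau)
    r_e = rmst(treatment_curve, tau)
    point = tau * (1.0 / r_c.value - 1.0 / r_e.value)
    half = (
        tau
        * z_quantile(alpha)
        * math.sqrt(r_c.variance / r_c.value**4 + r_e.variance / r_e.value**4)
    )
    return EffectEstimate(
        "RNT_RMST",
        point=point,
        ci=CIForm.regular(point - half, point + half),
        alpha=alpha,
        method="wald",
    )


def _invert_difference_ci(
    measure: str,
    scale: float,
    diff: float,
    lower_d: float,
    upper_d: float,
    alpha: float,
    flags: tuple[str, ...] = (),
) -> EffectEstimate:
    """CI for ``scale / difference`` by inverting the difference CI.

    Regular when the difference CI excludes zero; otherwise the irregular
    two-half-line NNT form.
    """
    point = math.inf if diff == 0.0 else scale / diff
    if lower_d > 0.0 or upper_d < 0.0:
        ci = CIForm.regular(*sorted((scale / lower_d, scale / upper_d)))
    else:
        benefit = math.inf if upper_d == 0.0 else scale / upper_d
        harm = math.inf if lower_d == 0.0 else -scale / lower_d
        ci = CIForm.irregular_nnt(benefit_bound=benefit, harm_bound=harm)
    return EffectEstimate(
        measure, point=point, ci=ci, alpha=alpha, method="wald", flags=flags
    )


def nnt_surv_ci(
    control_curve: KMCurve,
    treatment_curve: KMCurve,
    tau: float,
    alpha: float = 0.05,
) -> EffectEstimate:
    """NNT_surv with CI from inverting the Wald CI of S_E(tau) - S_C(tau)."""
    s_c, v_c = survival_at(control_curve, tau)
    s_e, v_e = survival_at(treatment_curve, tau)
    diff = s_e - s_c
    half = z_quantile(alpha) * math.sqrt(v_c + v_e)
    return _invert_difference_ci("NNT_surv", 1.0, diff, diff - half, diff + half, alpha)


def nnt_rmst_ci(
    control_curve: KMCurve,
    treatment_curve: KMCurve,
    tau: float,
    alpha: float = 0.05,
) -> EffectEstimate:
    """NNT_RMST with CI from inverting the Wald CI of the RMST difference."""
    r_c = rmst(control_curve, tau)
    r_e = rmst(treatment_curve, tau)
    diff = r_e.value - r_c.value
    half = z_quantile(alpha) * math.sqrt(r_c.variance + r_e.variance)
    return _invert_difference_ci("NNT_RMST", tau, diff, diff - half, diff + half, alpha)


# ------------------------------------------------------- perturbation resampling


def _sorted_arrays(data: SurvivalData) -> tuple[np.ndarray, np.ndarray]:
    """Times ascending; at tied times events come first (standard KM ties)."""
    order = np.lexsort((1 - data.events, data.times))
    return data.times[order], data.events[order]


def _weighted_km_replicates(
    times: np.ndarray,
    events: np.ndarray,
    tau: float,
    weights: np.ndarray,
    want_rmst: bool,
) -> np.ndarray:
    """S(tau) or RMST(tau) for each row of exponential weights.

    Weighted product-limit estimator processed subject by subject in time
    order (simulated times are continuous, so ties are negligible); the
    at-risk process is the reverse cumulative weight sum.
    """
    at_risk = np.cumsum(weights[:, ::-1], axis=1)[:, ::-1]
    ev = np.flatnonzero(events == 1)
    ev_in = ev[times[ev] <= tau]
    if ev_in.size == 0:
        n_reps = weights.shape[0]
        return np.full(n_reps, tau if want_rmst else 1.0)
    factors = 1.0 - weights[:, ev_in] / at_risk[:, ev_in]
    steps = np.cumprod(factors, axis=1)
    if not want_rmst:
        return steps[:, -1]
    knots = times[ev_in]
    widths = np.diff(np.concatenate(([0.0], knots)))
    s_before = np.concatenate(
        (np.ones((steps.shape[0], 1)), steps[:, :-1]), axis=1
    )
    return s_before @ widths + steps[:, -1] * (tau - knots[-1])


def perturbation_ci(
    control_data: SurvivalData,
    treatment_data: SurvivalData,
    tau: float,
    measure: str = "RNT_surv",
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> EffectEstimate:
    """Perturbation-resampling percentile CI for a survival effect measure.

    Each replicate draws independent standard-exponential weights per subject
    (unit mean, unit variance, non-negative), recomputes the weighted KM
    curve or RMST in each arm, and evaluates the measure at ``tau``.  The CI
    is the (alpha/2, 1 - alpha/2) empirical percentile interval.  Replicates
    where the measure is undefined (zero weighted survival for RNT_surv) are
    dropped with a warning; more than 10% undefined is an error.
    """
    if measure not in SURVIVAL_MEASURES:
        raise ValueError(f"measure must be one of {SURVIVAL_MEASURES}, got {measure!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    control_curve = km_fit(control_data)
    treatment_curve = km_fit(treatment_data)
    point_fn = {
        "RNT_surv": rnt_surv,
        "NNT_surv": nnt_surv,
        "RNT_RMST": rnt_rmst,
        "NNT_RMST": nnt_rmst,
    }[measure]
    point = point_fn(control_curve, treatment_curve, tau)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_c, rng_e = (np.random.default_rng(s) for s in ss.spawn(2))
    want_rmst = measure.endswith("RMST")

    t_c, e_c = _sorted_arrays(control_data)
    t_e, e_e = _sorted_arrays(treatment_data)
    stat_c = _weighted_km_replicates(
        t_c, e_c, tau, rng_c.exponential(1.0, (reps, len(control_data))), want_rmst
    )
    stat_e = _weighted_km_replicates(
        t_e, e_e, tau, rng_e.exponential(1.0, (reps, len(treatment_data))), want_rmst
    )

    flags: tuple[str, ...] = ()
    if measure == "RNT_surv":
        defined = (stat_c > 0.0) & (stat_e > 0.0)
        vals = np.full(reps, np.nan)
        vals[defined] = 1.0 / stat_c[defined] - 1.0 / stat_e[defined]
        s_c, _ = survival_at(control_curve, tau)
        s_e, _ = survival_at(treatment_curve, tau)
        if min(s_c, s_e) < UNSTABLE_SURVIVAL:
            flags = ("unstable",)
    elif measure == "NNT_surv":
        diff = stat_e - stat_c
        with np.errstate(divide="ignore"):
            vals = np.where(diff == 0.0, np.inf, 1.0 / np.where(diff == 0.0, 1.0, diff))
        defined = np.ones(reps, dtype=bool)
    elif measure == "RNT_RMST":
        vals = tau * (1.0 / stat_c - 1.0 / stat_e)
        defined = np.ones(reps, dtype=bool)
    else:  # NNT_RMST
        diff = stat_e - stat_c
        with np.errstate(divide="ignore"):
            vals = np.where(diff == 0.0, np.inf, tau / np.where(diff == 0.0, 1.0, diff))
        defined = np.ones(reps, dtype=bool)

    n_undef = int(reps - defined.sum())
    if n_undef > 0.10 * reps:
        raise UnstableEstimateError(
            f"{n_undef} of {reps} perturbation replicates left {measure} "
            f"undefined at tau={tau:g}; the measure is unstable here"
        )
    if n_undef:
        warnings.warn(
            f"dropped {n_undef} of {reps} perturbation replicates with "
            f"undefined {measure} at tau={tau:g}",
            stacklevel=2,
        )
        flags = flags + ("undefined_replicates_dropped",)
    kept = vals[defined]
    lower, upper = np.quantile(kept, [alpha / 2.0, 1.0 - alpha / 2.0])
    return EffectEstimate(
        measure,
        point=point,
        ci=CIForm.regular(float(lower), float(upper)),
        alpha=alpha,
        method="perturbation",
        flags=flags,
    )


# ------------------------------------------------------------------ profiles


@dataclass(frozen=True)
class ProfileEntry:
    tau: float
    measure: str
    estimate: EffectEstimate | None
    error: str | None = None


@dataclass(frozen=True)
class EffectProfile:
    """Effect measures with CIs evaluated over a grid of follow-up times."""

    entries: tuple[ProfileEntry, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row: dict = {"tau": e.tau, "measure": e.measure}
            if e.estimate is None:
                row.update(
                    point=np.nan,
                    ci_kind=None,
                    ci_lower=np.nan,
                    ci_upper=np.nan,
                    nntb=np.nan,
                    nnth=np.nan,
                    method=None,
                    flags=e.error,
                )
            else:
                est, ci = e.estimate, e.estimate.ci
                row.update(
                    point=est.point,
                    ci_kind=None if ci is None else ci.kind,
                    ci_lower=np.nan if ci is None or ci.kind != "regular" else ci.lower,
                    ci_upper=np.nan if ci is None or ci.kind != "regular" else ci.upper,
                    nntb=np.nan if ci is None or ci.kind == "regular" else ci.benefit_bound,
                    nnth=np.nan if ci is None or ci.kind == "regular" else ci.harm_bound,
                    method=est.method,
                    flags=",".join(est.flags) or None,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def default_tau_grid(
    control_data: SurvivalData, treatment_data: SurvivalData, max_points: int = 200
) -> np.ndarray:
    """Union of both arms' event times within shared follow-up, thinned to <= ``max_points``."""
    limit = min(control_data.times.max(), treatment_data.times.max())
    taus = np.unique(
        np.concatenate(
            (
                control_data.times[control_data.events == 1],
                treatment_data.times[treatment_data.events == 1],
            )
        )
    )
    taus = taus[taus <= limit]
    if taus.size > max_points:
        taus = taus[np.linspace(0, taus.size - 1, max_points).round().astype(int)]
    return taus


def effect_profile(
    control_data: SurvivalData,
    treatment_data: SurvivalData,
    taus=None,
    measures=SURVIVAL_MEASURES,
    ci_method: str = "wald",
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int | None = None,
) -> EffectProfile:
    """Evaluate the requested measures with CIs at each follow-up time.

    Per-tau failures (e.g. RNT_surv at a zero survival estimate) become
    flagged missing entries rather than aborting the profile.
    """
    if ci_method not in ("wald", "perturbation"):
        raise ValueError("ci_method must be 'wald' or 'perturbation'")
    for m in measures:
        if m not in SURVIVAL_MEASURES:
            raise ValueError(f"unknown measure {m!r}; choose from {SURVIVAL_MEASURES}")
    if taus is None:
        taus = default_tau_grid(control_data, treatment_data)
    control_curve = km_fit(control_data)
    treatment_curve = km_fit(treatment_data)
    wald_fn = {
        "RNT_surv": rnt_surv_wald_ci,
        "NNT_surv": nnt_surv_ci,
        "RNT_RMST": rnt_rmst_wald_ci,
        "NNT_RMST": nnt_rmst_ci,
    }
    ss = np.random.SeedSequence(seed)
    entries: list[ProfileEntry] = []
    for tau in np.atleast_1d(np.asarray(taus, dtype=float)):
        for measure in measures:
            try:
                if ci_method == "wald":
                    est = wald_fn[measure](control_curve, treatment_curve, float(tau), alpha)
                else:
                    est = perturbation_ci(
                        control_data,
                        treatment_data,
                        float(tau),
                        measure=measure,
                        alpha=alpha,
                        reps=reps,
                        seed=ss.spawn(1)[0],
                    )
                entries.append(ProfileEntry(float(tau), measure, est))
            except (UndefinedMeasureError, UnstableEstimateError, ValueError) as exc:
                entries.append(ProfileEntry(float(tau), measure, None, error=str(exc)))
    return EffectProfile(entries=tuple(entries))
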