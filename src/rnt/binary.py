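"""Effect measures for two-arm binary endpoints.

Given control and experimental response rates ``p_C`` and ``p_E``, the
classical measures are the absolute risk reduction ``ARR = p_E - p_C``, the
relative risk ``RR = p_E / p_C``, the relative risk reduction
``RRR = RR - 1`` and the number needed to treat ``NNT = 1 / ARR``.  NNT
depends only on the difference of the rates: trials with rates (0.1, 0.2)
and (0.4, 0.5) both give NNT = 10 even though the first treatment doubles
the response rate.  The reduction in number to treat reverses the order of
differencing and inverting,

    RNT = 1/p_C - 1/p_E = ARR / (p_E p_C) = RRR / p_E,

so it retains the baseline: RNT = 5 in the first trial and 0.5 in the
second.  RNT lives on the whole real line (0 when the arms are equal) and
its Wald CI is an ordinary interval, in contrast with NNT, whose CI becomes
the two-half-line form ``[NNTB b to`` ∞ ``to NNTH h]`` whenever the ARR CI
spans zero.

Intervals provided here: delta-method Wald, stratified bootstrap percentile,
and a conservative exact construction (per-arm Clopper-Pearson bounds
combined by the MOVER square-and-add rule on the reciprocal scale).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._utils import z_quantile
from .estimates import CIForm, EffectEstimate
from .exceptions import BoundaryRateError, UndefinedMeasureError

__all__ = [
    "BinaryArm",
    "arr",
    "rr",
    "rrr",
    "nnt",
    "rnt",
    "nnt_from_rates",
    "rnt_from_rates",
    "arr_wald_ci",
    "nnt_ci",
    "rnt_wald_ci",
    "rnt_bootstrap_ci",
    "rnt_exact_ci",
]


@dataclass(frozen=True)
class BinaryArm:
    """One arm of a trial with a binary endpoint: ``n`` subjects, ``responders`` responses."""

    n: int
    responders: int

    def __post_init__(self) -> None:
        if int(self.n) != self.n or int(self.responders) != self.responders:
            raise ValueError("n and responders must be integers")
        if self.n < 1:
            raise ValueError(f"arm size must be >= 1, got {self.n}")
        if not 0 <= self.responders <= self.n:
            raise ValueError(
                f"responders must lie in [0, n]; got {self.responders} of {self.n}"
            )

    @property
    def rate(self) -> float:
        """Observed response rate ``responders / n``."""
        return self.responders / self.n

    @classmethod
    def from_rate(cls, n: int, rate: float) -> "BinaryArm":
        """Build an arm from a (possibly rounded) published rate.

        The responder count is the nearest integer to ``rate * n``; a rate
        outside [0, 1] is rejected.
        """
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {rate}")
        return cls(n=n, responders=int(round(rate * n)))


def _rates(control: BinaryArm, treatment: BinaryArm) -> tuple[float, float]:
    return control.rate, treatment.rate


def arr(control: BinaryArm, treatment: BinaryArm) -> float:
    """Absolute risk reduction ``p_E - p_C``."""
    p_c, p_e = _rates(control, treatment)
    return p_e - p_c


def rr(control: BinaryArm, treatment: BinaryArm) -> float:
    """Relative risk ``p_E / p_C``; undefined when the control rate is zero."""
    p_c, p_e = _rates(control, treatment)
    if p_c == 0.0:
        raise UndefinedMeasureError(
            "relative risk is undefined: the control response rate is zero"
        )
    return p_e / p_c


def rrr(control: BinaryArm, treatment: BinaryArm) -> float:
    """Relative risk reduction ``RR - 1``."""
    return rr(control, treatment) - 1.0


def nnt(control: BinaryArm, treatment: BinaryArm) -> float:
    """Number needed to treat ``1 / (p_E - p_C)``; signed infinity at equal rates."""
    diff = arr(control, treatment)
    if diff == 0.0:
        return math.inf
    return 1.0 / diff


def rnt(control: BinaryArm, treatment: BinaryArm) -> float:
    """Reduction in number to treat ``1/p_C - 1/p_E``.

    Positive values favour the treatment arm; zero iff the rates are equal.
    """
    p_c, p_e = _rates(control, treatment)
    if p_c == 0.0 or p_e == 0.0:
        raise UndefinedMeasureError(
            "RNT is undefined when a response rate is zero "
            f"(p_C={p_c:.4g}, p_E={p_e:.4g})"
        )
    return 1.0 / p_c - 1.0 / p_e


def rnt_from_rates(p_control: float, p_treatment: float) -> float:
    """RNT ``1/p_C - 1/p_E`` directly from response rates.

    The same formula applies to any pair of rate-like quantities, e.g. the
    tau-normalised restricted means ``RMST/tau`` of two survival arms.
    """
    if p_control <= 0.0 or p_treatment <= 0.0:
        raise UndefinedMeasureError(
            f"RNT requires positive rates, got ({p_control:.4g}, {p_treatment:.4g})"
        )
    return 1.0 / p_control - 1.0 / p_treatment


def nnt_from_rates(p_control: float, p_treatment: float) -> float:
    """NNT ``1/(p_E - p_C)`` directly from response rates; infinity at equality."""
    diff = p_treatment - p_control
    if diff == 0.0:
        return math.inf
    return 1.0 / diff


def arr_wald_ci(
    control: BinaryArm, treatment: BinaryArm, alpha: float = 0.05
) -> tuple[float, float]:
    """Two-sided Wald CI for the risk difference ``p_E - p_C``."""
    p_c, p_e = _rates(control, treatment)
    se = math.sqrt(p_c * (1 - p_c) / control.n + p_e * (1 - p_e) / treatment.n)
    half = z_quantile(alpha) * se
    diff = p_e - p_c
    return diff - half, diff + half


def nnt_ci(
    control: BinaryArm, treatment: BinaryArm, alpha: float = 0.05
) -> EffectEstimate:
    """NNT with its CI obtained by inverting the Wald CI of the risk difference.

    When the difference CI excludes zero, the reciprocal bounds form an
    ordinary interval.  When it spans zero the confidence region is the union
    of two half-lines, reported as ``NNTB 1/ARR_upper to`` ∞ ``to NNTH
    -1/ARR_lower``.
    """
    lower_d, upper_d = arr_wald_ci(control, treatment, alpha)
    point = nnt(control, treatment)
    if lower_d > 0.0 or upper_d < 0.0:
        bounds = sorted((1.0 / lower_d, 1.0 / upper_d))
        ci = CIForm.regular(*bounds)
    else:
        benefit = math.inf if upper_d == 0.0 else 1.0 / upper_d
        harm = math.inf if lower_d == 0.0 else -1.0 / lower_d
        ci = CIForm.irregular_nnt(benefit_bound=benefit, harm_bound=harm)
    return EffectEstimate("NNT", point=point, ci=ci, alpha=alpha, method="wald")


def rnt_wald_ci(
    control: BinaryArm, treatment: BinaryArm, alpha: float = 0.05
) -> EffectEstimate:
    """Delta-method Wald CI for RNT.

    The reciprocal transform p -> 1/p has derivative -1/p^2, so the variance
    of the estimated RNT is (1-p_C)/(n_C p_C^3) + (1-p_E)/(n_E p_E^3); the
    interval is the point estimate +/- z_{1-alpha/2} times its square root.
    Requires both rates strictly inside (0, 1).
    """
    p_c, p_e = _rates(control, treatment)
    if not (0.0 < p_c < 1.0 and 0.0 < p_e < 1.0):
        raise BoundaryRateError(
            "the Wald variance of RNT is undefined at a boundary rate "
            f"(p_C={p_c:.4g}, p_E={p_e:.4g}); use rnt_bootstrap_ci or rnt_exact_ci"
        )
    point = rnt(control, treatment)
    se = math.sqrt(
        (1 - p_c) / (control.n * p_c**3) + (1 - p_e) / (treatment.n * p_e**3)
    )
    half = z_quantile(alpha) * se
    ci = CIForm.regular(point - half, point + half)
    return EffectEstimate("RNT", point=point, ci=ci, alpha=alpha, method="wald")


_MAX_REDRAW_ROUNDS = 1000


def rnt_bootstrap_ci(
    control: BinaryArm,
    treatment: BinaryArm,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> EffectEstimate:
    """Stratified nonparametric bootstrap percentile CI for RNT.

    Resampling subjects with replacement within an arm is equivalent to
    drawing the replicate responder count from Binomial(n, p-hat), which is
    how replicates are generated.  A replicate with zero responders in either
    arm leaves RNT undefined and is redrawn; a warning is issued if more than
    1% of replicates needed a redraw.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if control.responders == 0 or treatment.responders == 0:
        raise UndefinedMeasureError(
            "bootstrap CI for RNT requires at least one responder per arm"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_c = rng.binomial(control.n, control.rate, size=reps)
    r_e = rng.binomial(treatment.n, treatment.rate, size=reps)
    redraws = 0
    for _ in range(_MAX_REDRAW_ROUNDS):
        mask = (r_c == 0) | (r_e == 0)
        bad = int(mask.sum())
        if bad == 0:
            break
        redraws += bad
        r_c[mask] = rng.binomial(control.n, control.rate, size=bad)
        r_e[mask] = rng.binomial(treatment.n, treatment.rate, size=bad)
    else:  # pragma: no cover - requires pathological rates
        raise RuntimeError(
            "bootstrap redraw limit exceeded: the resampling distribution of "
            "RNT is degenerate for these arms"
        )
    flags: tuple[str, ...] = ()
    if redraws > 0.01 * reps:
        warnings.warn(
            f"{redraws} of {reps} bootstrap replicates had a zero-responder arm "
            "and were redrawn; the percentile CI may be unreliable",
            stacklevel=2,
        )
        flags = ("degenerate_replicates_redrawn",)
    vals = control.n / r_c - treatment.n / r_e
    lower, upper = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return EffectEstimate(
        "RNT",
        point=rnt(control, treatment),
        ci=CIForm.regular(float(lower), float(upper)),
        alpha=alpha,
        method="bootstrap",
        flags=flags,
    )


def _clopper_pearson(r: int, n: int, alpha: float) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided bounds on a binomial proportion."""
    lower = 0.0 if r == 0 else float(stats.beta.ppf(alpha / 2.0, r, n - r + 1))
    upper = 1.0 if r == n else float(stats.beta.ppf(1.0 - alpha / 2.0, r + 1, n - r))
    return lower, upper


def rnt_exact_ci(
    control: BinaryArm, treatment: BinaryArm, alpha: float = 0.05
) -> EffectEstimate:
    """Conservative exact-style CI for RNT via MOVER on Clopper-Pearson bounds.

    Per-arm exact bounds [l, u] on each rate map monotonically (and with roles
    reversed) to bounds [1/u, 1/l] on the reciprocal; the MOVER
    square-and-add rule then combines them for the difference
    ``1/p_C - 1/p_E``.  Zero responders in an arm give a one-sided infinite
    bound, flagged in the result.
    """
    p_c, p_e = _rates(control, treatment)
    lo_c, hi_c = _clopper_pearson(control.responders, control.n, alpha)
    lo_e, hi_e = _clopper_pearson(treatment.responders, treatment.n, alpha)
    # reciprocal-scale bounds: theta1 = 1/p_C in [1/hi_c, 1/lo_c], etc.
    l1, u1 = 1.0 / hi_c, (math.inf if lo_c == 0.0 else 1.0 / lo_c)
    l2, u2 = 1.0 / hi_e, (math.inf if lo_e == 0.0 else 1.0 / lo_e)
    flags: tuple[str, ...] = ()
    if p_c == 0.0 or p_e == 0.0:
        # Point estimate is infinite; fall back to plain interval differencing.
        point = math.inf if p_c == 0.0 and p_e > 0.0 else (-math.inf if p_e == 0.0 and p_c > 0.0 else math.nan)
        lower, upper = l1 - u2, u1 - l2
        flags = ("one_sided_infinite",)
    else:
        theta1, theta2 = 1.0 / p_c, 1.0 / p_e
        point = theta1 - theta2
        lower = point - math.sqrt((theta1 - l1) ** 2 + (u2 - theta2) ** 2)
        upper = point + math.sqrt((u1 - theta1) ** 2 + (theta2 - l2) ** 2)
        if math.isinf(upper):
            flags = ("one_sided_infinite",)
    return EffectEstimate(
        "RNT",
        point=point,
        ci=CIForm.regular(lower, upper),
        alpha=alpha,
        method="exact",
        flags=flags,
    )
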