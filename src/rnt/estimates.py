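"""Containers for effect estimates and their (possibly irregular) intervals.

A number-needed-to-treat style measure whose underlying risk-difference CI
spans zero has a confidence region that is the union of two half-lines,
conventionally written ``[NNTB b to `` ∞ `` to NNTH h]``.  ``CIForm``
represents both that irregular shape and the ordinary ``[lower, upper]`` form
so downstream code can render either losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

REGULAR = "regular"
IRREGULAR_NNT = "irregular_nnt"

#: Measures with NNT semantics (reciprocal-of-difference); reported at 1 d.p.
NNT_MEASURES = frozenset({"NNT", "NNT_surv", "NNT_RMST"})
#: Measures with RNT semantics (difference-of-reciprocals); reported at 2 d.p.
RNT_MEASURES = frozenset({"RNT", "RNT_surv", "RNT_RMST"})
ALL_MEASURES = NNT_MEASURES | RNT_MEASURES | {"ARR", "RR", "RRR"}


@dataclass(frozen=True)
class CIForm:
    """A confidence region: a regular interval or the two-half-line NNT form."""

    kind: str
    lower: float = math.nan
    upper: float = math.nan
    benefit_bound: float | None = None
    harm_bound: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (REGULAR, IRREGULAR_NNT):
            raise ValueError(f"unknown CI kind {self.kind!r}")
        if self.kind == REGULAR:
            if not self.lower <= self.upper:
                raise ValueError(
                    f"regular CI requires lower <= upper, got [{self.lower}, {self.upper}]"
                )
        else:
            if self.benefit_bound is None or self.harm_bound is None:
                raise ValueError("irregular_nnt CI requires both bounds")
            if self.benefit_bound <= 0 or self.harm_bound <= 0:
                raise ValueError("irregular_nnt bounds must be positive")

    @classmethod
    def regular(cls, lower: float, upper: float) -> "CIForm":
        return cls(REGULAR, lower=lower, upper=upper)

    @classmethod
    def irregular_nnt(cls, benefit_bound: float, harm_bound: float) -> "CIForm":
        """Region [benefit_bound, +inf) U (-inf, -harm_bound] in NNT units."""
        return cls(IRREGULAR_NNT, benefit_bound=benefit_bound, harm_bound=harm_bound)

    def render(self, ndigits: int | None = 2) -> str:
        def fmt(v: float) -> str:
            if math.isinf(v):
                return "∞" if v > 0 else "-∞"
            return f"{v}" if ndigits is None else f"{v:.{ndigits}f}"

        if self.kind == REGULAR:
            return f"[{fmt(self.lower)}, {fmt(self.upper)}]"
        return f"[NNTB {fmt(self.benefit_bound)} to ∞ to NNTH {fmt(self.harm_bound)}]"


@dataclass(frozen=True)
class EffectEstimate:
    """A named effect measure with its point estimate and confidence region.

    ``unit_scale`` changes the unit of response: with ``unit_scale=100`` an
    RNT of 0.074 is reported as 7.4 fewer patients per 100 responses.
    """

    measure: str
    point: float
    ci: CIForm | None = None
    alpha: float = 0.05
    method: str = "wald"
    unit_scale: int = 1
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.measure not in ALL_MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.unit_scale < 1:
            raise ValueError("unit_scale must be a positive integer")

    def with_unit_scale(self, unit_scale: int) -> "EffectEstimate":
        """Re-express the estimate per ``unit_scale`` responses (RNT-type only)."""
        if unit_scale == self.unit_scale:
            return self
        if self.measure not in RNT_MEASURES:
            raise ValueError(f"unit scaling applies to RNT-type measures, not {self.measure}")
        factor = unit_scale / self.unit_scale
        ci = self.ci
        if ci is not None and ci.kind == REGULAR:
            ci = CIForm.regular(ci.lower * factor, ci.upper * factor)
        return replace(self, point=self.point * factor, ci=ci, unit_scale=unit_scale)
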