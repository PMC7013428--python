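"""Concentration-response models for hormetic (J-shaped) curves.

Hormesis is a biphasic concentration-response pattern: low concentrations
stimulate (negative effect), high concentrations inhibit (positive effect),
giving a J-shaped concentration-response curve (J-CRC).  This module holds
the pure mathematical layer:

* the five-parameter biphasic model (BP) for the whole J-CRC,

      E(C) = m - m / (1 + 10^(b (C - a))) + (1 - m) / (1 + 10^(q (p - C)))

  where ``m`` is the bottom parameter (maximum stimulation magnitude,
  typically negative), ``a``/``b`` the median/slope of the left
  (stimulatory) phase and ``p``/``q`` the median/slope of the right
  (inhibitory) phase;

* the left (BPL) and right (BPR) segment sub-models derived from BP,
  satisfying the identity ``f_BP = f_BPL + f_BPR - m`` exactly, together
  with their closed-form inverses;

* the two-parameter Hill model ``E = d C / (k + C)`` used to describe the
  stimulatory (left) segment, with its inverse ``C = k E / (d - E)``;

* numerical characterisation of the hormetic minimum (EC_m, E_m) and a
  numerical inversion of the left branch of the BP curve.

Conventions used throughout the package: effects are signed fractions
(0.5 = 50 % inhibition, -0.2 = 20 % stimulation; percent appears only at
I/O), concentrations are molar (mol/L), and concentration enters the
sigmoids *linearly* -- the slope parameters b and q carry units of
1/(mol/L) and are therefore numerically large for micromolar-active
chemicals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "DomainError",
    "InvalidInputError",
    "BiphasicParams",
    "HillParams",
    "Side",
    "EffectLevel",
    "HormeticMinimum",
    "effect_from_luminescence",
    "bp_effect",
    "bpl_effect",
    "bpl_inverse",
    "bpr_effect",
    "bpr_inverse",
    "hill_effect",
    "hill_inverse",
    "bp_minimum",
    "bp_left_inverse",
]

#: Exponent clip applied before every ``10**z``; protects arbitrary user
#: input from overflow while never binding within realistic ranges
#: (|b*C| stays far below 300 for tested concentrations).
EXP_CLIP = 300.0


class DomainError(ValueError):
    """An effect level lies outside the domain of the requested inverse."""


class InvalidInputError(ValueError):
    """Structurally invalid input (non-positive control, bad ratio, ...)."""


def _p10(z):
    return np.power(10.0, np.clip(z, -EXP_CLIP, EXP_CLIP))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiphasicParams:
    """Parameters of the five-parameter biphasic (BP) model.

    m : bottom parameter (dimensionless effect; negative for hormetic
        curves, but no sign is enforced -- fitted values as extreme as
        m = -80 occur in practice when the two phases overlap strongly).
    a, b : median (mol/L) and slope (1/(mol/L)) of the left phase.
    p, q : median (mol/L) and slope (1/(mol/L)) of the right phase.
    Both slopes must be positive (each phase rises with concentration).
    """

    m: float
    a: float
    b: float
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.q > 0):
            raise InvalidInputError("slope parameters b and q must be positive")

    def to_dict(self) -> dict:
        return {"model": "BP", "m": self.m, "a": self.a, "b": self.b,
                "p": self.p, "q": self.q}

    @classmethod
    def from_dict(cls, d: dict) -> "BiphasicParams":
        return cls(m=float(d["m"]), a=float(d["a"]), b=float(d["b"]),
                   p=float(d["p"]), q=float(d["q"]))


@dataclass(frozen=True)
class HillParams:
    """Hill parameters for the left (stimulatory) segment.

    d : top parameter -- the limiting effect (negative for stimulation).
    k : median concentration (mol/L); E(k) = d/2.
    """

    d: float
    k: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise InvalidInputError("Hill median k must be positive")
        if self.d == 0:
            raise InvalidInputError("Hill top d must be nonzero")

    def to_dict(self) -> dict:
        return {"model": "Hill", "d": self.d, "k": self.k}

    @classmethod
    def from_dict(cls, d: dict) -> "HillParams":
        return cls(d=float(d["d"]), k=float(d["k"]))


class Side(Enum):
    """Branch of the J-CRC a stimulatory effect level refers to.

    The two concentrations sharing the same stimulatory effect -x% sit on
    the left and right of the curve minimum (EC_-xL and EC_-xR).
    """

    LEFT = "L"
    RIGHT = "R"
    NONE = ""


@dataclass(frozen=True)
class EffectLevel:
    """A signed effect level with its branch tag.

    x is a fraction (0.5 = 50 % inhibition, -0.2 = 20 % stimulation).
    Stimulatory levels on a J-shaped curve are ambiguous without a side.
    The zero-effect level conventionally refers to the right-branch zero
    crossing (the left one collapses onto the origin).
    """

    x: float
    side: Side = Side.NONE

    def __post_init__(self) -> None:
        if self.x > 1:
            raise InvalidInputError("effect fraction cannot exceed 1")
        if self.x < 0 and self.side is Side.NONE:
            raise InvalidInputError(
                "stimulatory levels require a side tag (LEFT or RIGHT)")

    @classmethod
    def parse(cls, text: str) -> "EffectLevel":
        """Parse percent notation such as '80', '0', '-20R', '-10L'."""
        s = str(text).strip().upper().replace("−", "-")
        side = Side.NONE
        if s.endswith(("L", "R")):
            side = Side.LEFT if s[-1] == "L" else Side.RIGHT
            s = s[:-1]
        try:
            x = float(s) / 100.0
        except ValueError as exc:
            raise InvalidInputError(f"cannot parse effect level {text!r}") from exc
        if x >= 0 and side is Side.NONE:
            side = Side.RIGHT
        return cls(x=x, side=side)

    @property
    def label(self) -> str:
        pct = self.x * 100.0
        txt = f"{pct:g}"
        if self.x < 0:
            txt += self.side.value
        return txt


@dataclass(frozen=True)
class HormeticMinimum:
    """Location and depth of the curve minimum (maximum stimulation).

    ec_m : concentration of maximum stimulation (mol/L).
    e_m  : maximum stimulatory effect (signed fraction, <= 0).
    interior : False when the scanned bracket contains no interior
        minimum (monotone curve); values then refer to the bracket edge.
    """

    ec_m: float
    e_m: float
    interior: bool = True


# ---------------------------------------------------------------------------
# forward / inverse model evaluation
# ---------------------------------------------------------------------------


def effect_from_luminescence(treatment_rlu_mean: float,
                             control_rlu_mean: float) -> float:
    """Inhibitory effect from mean relative light units, E = 1 - L/L0."""
    if not control_rlu_mean > 0:
        raise InvalidInputError("control mean RLU must be positive")
    return 1.0 - treatment_rlu_mean / control_rlu_mean


def bp_effect(params: BiphasicParams, c):
    """Biphasic model effect at concentration ``c`` (scalar or array)."""
    c = np.asarray(c, dtype=float)
    left = params.m - params.m / (1.0 + _p10(params.b * (c - params.a)))
    right = (1.0 - params.m) / (1.0 + _p10(params.q * (params.p - c)))
    out = left + right
    return out if out.ndim else float(out)


def bpl_effect(params: BiphasicParams, c):
    """Left-segment sub-model: E = m - m/(1 + 10^(b (C - a)))."""
    c = np.asarray(c, dtype=float)
    out = params.m - params.m / (1.0 + _p10(params.b * (c - params.a)))
    return out if out.ndim else float(out)


def bpl_inverse(params: BiphasicParams, e: float) -> float:
    """Closed-form BPL inverse, C = a + log10(E/(m-E))/b.

    Defined for effects strictly between 0 and the bottom parameter m.
    """
    m = params.m
    lo, hi = min(m, 0.0), max(m, 0.0)
    if not (lo < e < hi):
        raise DomainError(f"effect {e} outside BPL domain ({lo}, {hi})")
    return params.a + math.log10(e / (m - e)) / params.b


def bpr_effect(params: BiphasicParams, c):
    """Right-segment sub-model: E = m + (1-m)/(1 + 10^(q (p - C)))."""
    c = np.asarray(c, dtype=float)
    out = params.m + (1.0 - params.m) / (1.0 + _p10(params.q * (params.p - c)))
    return out if out.ndim else float(out)


def bpr_inverse(params: BiphasicParams, e: float) -> float:
    """Closed-form BPR inverse, C = p - log10((1-E)/(E-m))/q.

    The BPR sub-model reuses m, p and q from the BP fit unchanged: the
    right segment of the BP curve and the BPR curve coincide wherever the
    left sigmoid is saturated.  Defined for m < e < 1.
    """
    m = params.m
    if not (m < e < 1.0):
        raise DomainError(f"effect {e} outside BPR domain ({m}, 1)")
    return params.p - math.log10((1.0 - e) / (e - m)) / params.q


def hill_effect(params: HillParams, c):
    """Hill model effect, E = d C / (k + C)."""
    c = np.asarray(c, dtype=float)
    out = params.d * c / (params.k + c)
    return out if out.ndim else float(out)


def hill_inverse(params: HillParams, e: float) -> float:
    """Hill inverse, C = k E / (d - E); e strictly between 0 and d."""
    d = params.d
    lo, hi = min(d, 0.0), max(d, 0.0)
    if not (lo < e < hi):
        raise DomainError(f"effect {e} outside Hill domain ({lo}, {hi})")
    return params.k * e / (d - e)


# ---------------------------------------------------------------------------
# numerical characterisation of the minimum and left-branch inversion
# ---------------------------------------------------------------------------

#: Fallback bracket (mol/L) when the fitted medians are unusable for
#: bracketing (negative a or p arise for strongly overlapping phases).
_DEFAULT_BRACKET = (1e-8, 1e-2)


def bp_minimum(params: BiphasicParams,
               bracket: Optional[tuple] = None,
               n_grid: int = 512) -> HormeticMinimum:
    """Locate the hormetic minimum of the BP curve.

    A log-spaced grid scan brackets the minimum (guarding against the
    nearly flat plateaus produced by extreme bottom parameters), then a
    bounded scalar minimisation in log-concentration refines it to better
    than 1e-8 relative precision.  A curve that is monotone over the
    bracket yields a flagged (``interior=False``) result at the bracket
    edge rather than an exception.
    """
    if bracket is None:
        if params.a > 0 and params.p > 0:
            bracket = (params.a / 100.0, params.p)
        else:
            bracket = _DEFAULT_BRACKET
    lo, hi = bracket
    if not (0 < lo < hi):
        raise InvalidInputError("bracket must satisfy 0 < lo < hi")
    grid = np.geomspace(lo, hi, n_grid)
    vals = bp_effect(params, grid)
    i = int(np.argmin(vals))
    if i == 0 or i == n_grid - 1:
        return HormeticMinimum(float(grid[i]), float(vals[i]), interior=False)
    res = minimize_scalar(
        lambda u: bp_effect(params, 10.0 ** u),
        bounds=(math.log10(grid[i - 1]), math.log10(grid[i + 1])),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return HormeticMinimum(float(10.0 ** res.x), float(res.fun), interior=True)


def bp_left_inverse(params: BiphasicParams, e: float,
                    minimum: Optional[HormeticMinimum] = None) -> float:
    """Concentration on the left (descending) branch of the BP curve at
    effect ``e``.

    The BP curve itself -- not the BPL sub-model -- describes the left
    segment; its left branch has no closed-form inverse, so the unique
    root of ``bp_effect(c) = e`` on (0, ec_m] is found by Brent's method
    to ~1e-10 relative precision.  Requires e_m < e <= 0.
    """
    if minimum is None:
        minimum = bp_minimum(params)
    if not minimum.interior:
        raise DomainError("curve has no interior hormetic minimum")
    if e <= minimum.e_m:
        raise DomainError(
            f"effect {e} unreachable: below the curve minimum {minimum.e_m:.4f}")
    if e > 0:
        raise DomainError("left-branch inversion is defined for e <= 0")
    lo = minimum.ec_m * 1e-6
    f = lambda c: bp_effect(params, c) - e
    if f(lo) <= 0.0:
        raise DomainError(
            f"effect {e} not bracketed on the left branch above {lo:g} mol/L")
    return float(brentq(f, lo, minimum.ec_m, xtol=minimum.ec_m * 1e-15,
                        rtol=8.9e-16))
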