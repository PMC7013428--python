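"""Mixture interaction diagnosis: co-toxicity coefficients, isoboles,
cross points and toxicity-composition profiles.

The co-toxicity coefficient (CTC) compares the CA-predicted and observed
mixture effect concentrations at one effect level:

    CTC = 100 / (EC_x,mix * sum_i(P_i / EC_x,i))
        = 100 * EC_x,CA / EC_x,mix

CTC = 100 means exact additivity; smaller values mean the mixture needs
more than the additive concentration (antagonism), larger values less
(synergism).  Because CTC is monotone decreasing in EC_x,mix, a 95 % CI
on the observed EC_x,mix maps onto a CTC CI with the bounds swapped, and
an absent EC bound propagates to an absent CTC bound.

The CTC-with-CI (CTCICI) classification cascade:

1. both CI bounds present -- classify by the position of 100 in
   [LL, UL] (inside: additive; interval below 100: antagonistic;
   above: synergistic);
2. one bound present -- form [min(bound, CTC), max(bound, CTC)]; if 100
   falls inside, additive; otherwise fall through to rule 3;
3. no usable CI -- the classical thresholds 80 <= CTC <= 120 additive,
   CTC < 80 antagonistic, CTC > 120 synergistic (bounds inclusive).

An isobole plots, at one effect level, the partial concentrations
P_i * EC_x of equi-effective binary combinations; the CA reference is the
straight line between the two single-component intercepts, and a mixture
ray's observed point (with CI scaled along the ray) is judged against it.
The geometric judgment and the CTCICI judgment are equivalent whenever a
two-sided CI exists.

For J-shaped curves the observed and CA-predicted mixture curves of an
interactive mixture generally intersect at a cross point (CP): the two
curves exchange relative position across it while the interaction type
(from CTCICI/isobole) stays the same on both sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .fitting import ECxEstimate
from .mixtures import PredictedCurve, ca_ecx
from .models import (
    BiphasicParams,
    EffectLevel,
    HormeticMinimum,
    InvalidInputError,
    Side,
    bp_effect,
    bp_minimum,
)

__all__ = [
    "Classification",
    "Rule",
    "InteractionCall",
    "IsobolePoint",
    "CrossPoint",
    "ctc",
    "ctc_ci",
    "ctcici_classify",
    "isobole",
    "cross_point",
    "toxicity_profile",
]


class Classification(Enum):
    ADDITIVE = "ADD"
    ANTAGONISTIC = "ANT"
    SYNERGISTIC = "SYN"


class Rule(Enum):
    CI_BOTH = "CI_BOTH"
    CI_ONE_SIDED = "CI_ONE_SIDED"
    CTC_FALLBACK = "CTC_FALLBACK"


@dataclass(frozen=True)
class InteractionCall:
    """One interaction judgment at one effect level."""

    level: Optional[EffectLevel]
    ctc: float
    ctc_ll: Optional[float]
    ctc_ul: Optional[float]
    classification: Classification
    rule_used: Rule

    def to_dict(self) -> dict:
        return {"level": None if self.level is None else self.level.label,
                "ctc": self.ctc, "ctc_ll": self.ctc_ll,
                "ctc_ul": self.ctc_ul,
                "classification": self.classification.value,
                "rule_used": self.rule_used.value}


@dataclass(frozen=True)
class IsobolePoint:
    """One observed equi-effective point on a binary isobole."""

    level: EffectLevel
    partial_concentrations: tuple
    ci_lower: Optional[tuple]
    ci_upper: Optional[tuple]
    source: str  # "OBSERVED" | "CA_LINE"


@dataclass(frozen=True)
class CrossPoint:
    """Intersection of observed and predicted mixture curves."""

    ec_cp: float
    e_cp: float
    side: Side


def ctc(ecx_mix: float, proportions: Sequence[float],
        component_ecx: Sequence[float]) -> float:
    """Co-toxicity coefficient (full precision; round only for display)."""
    if not (np.isfinite(ecx_mix) and ecx_mix > 0):
        raise InvalidInputError("observed mixture EC_x must be positive")
    return 100.0 * ca_ecx(proportions, component_ecx) / float(ecx_mix)


def round_ctc(value: float) -> int:
    """Display rounding: half away from zero to the nearest integer."""
    return int(math.floor(value + 0.5)) if value >= 0 else -int(
        math.floor(-value + 0.5))


def ctc_ci(ecx_mix_estimate: ECxEstimate, proportions: Sequence[float],
           component_ecx: Sequence[float]) -> tuple:
    """CTC confidence bounds from the observed EC_x,mix CI.

    CTC decreases in EC_x,mix, so the upper CTC bound comes from the
    lower EC bound and vice versa; absent EC bounds propagate.
    """
    ll = ul = None
    if ecx_mix_estimate.ci_lower is not None:
        ul = ctc(ecx_mix_estimate.ci_lower, proportions, component_ecx)
    if ecx_mix_estimate.ci_upper is not None:
        ll = ctc(ecx_mix_estimate.ci_upper, proportions, component_ecx)
    return ll, ul


def _fallback(value: float) -> Classification:
    if 80.0 <= value <= 120.0:
        return Classification.ADDITIVE
    return (Classification.ANTAGONISTIC if value < 80.0
            else Classification.SYNERGISTIC)


def ctcici_classify(ctc_value: float,
                    ctc_ll: Optional[float] = None,
                    ctc_ul: Optional[float] = None,
                    level: Optional[EffectLevel] = None) -> InteractionCall:
    """Apply the CTCICI rule cascade (see module docstring).

    All interval boundaries are inclusive: 100 sitting exactly on a CI
    bound counts as contained, and CTC values of exactly 80 or 120 are
    additive under the fallback rule.
    """
    if ctc_value is None or not np.isfinite(ctc_value):
        raise InvalidInputError("CTC value is required")
    if ctc_ll is not None and ctc_ul is not None:
        if ctc_ll <= 100.0 <= ctc_ul:
            cls = Classification.ADDITIVE
        elif ctc_ul < 100.0:
            cls = Classification.ANTAGONISTIC
        else:
            cls = Classification.SYNERGISTIC
        rule = Rule.CI_BOTH
    elif ctc_ll is not None or ctc_ul is not None:
        bound = ctc_ll if ctc_ll is not None else ctc_ul
        lo, hi = min(bound, ctc_value), max(bound, ctc_value)
        if lo <= 100.0 <= hi:
            cls, rule = Classification.ADDITIVE, Rule.CI_ONE_SIDED
        else:
            cls, rule = _fallback(ctc_value), Rule.CTC_FALLBACK
    else:
        cls, rule = _fallback(ctc_value), Rule.CTC_FALLBACK
    return InteractionCall(level=level, ctc=float(ctc_value),
                           ctc_ll=ctc_ll, ctc_ul=ctc_ul,
                           classification=cls, rule_used=rule)


# ---------------------------------------------------------------------------
# isoboles
# ---------------------------------------------------------------------------


def _ca_line_radial_scale(proportions: np.ndarray,
                          component_ecx: np.ndarray) -> float:
    """Radial distance t at which the ray t*(P1,P2) meets the CA line.

    The CA reference isobole is the straight segment between the axis
    intercepts (EC_x,1, 0) and (0, EC_x,2); the intersection is found by
    solving the 2x2 linear system of ray and line -- an independent
    geometric route to the same quantity the harmonic CA formula gives.
    """
    ec1, ec2 = component_ecx
    a = np.array([[proportions[0], ec1], [proportions[1], -ec2]])
    rhs = np.array([ec1, 0.0])
    t, _s = np.linalg.solve(a, rhs)
    return float(t)


def isobole(level: EffectLevel,
            rays: Sequence[tuple],
            component_ecx: Sequence[float]) -> dict:
    """Binary isobole at one effect level.

    ``rays`` holds (MixtureRay, ECxEstimate) pairs with the observed
    mixture EC_x and its CI.  Returns the CA line endpoints, the observed
    points (partial concentrations P_i * EC_x,mix with CI scaled the same
    way), and a per-ray interaction call judged geometrically against the
    CA line: a ray whose CI segment straddles the line is additive, one
    lying entirely beyond it antagonistic, entirely short of it
    synergistic; one-sided and absent CIs fall back exactly as in the
    CTCICI cascade.
    """
    ec = np.asarray(component_ecx, dtype=float)
    if ec.size != 2:
        raise InvalidInputError("isoboles are defined for binary mixtures")
    if np.any(ec <= 0):
        raise InvalidInputError("component EC_x values must be positive")
    points, calls = [], []
    for ray, est in rays:
        p = ray.proportions
        if p.size != 2:
            raise InvalidInputError("isoboles are defined for binary rays")
        t_ca = _ca_line_radial_scale(p, ec)
        partial = tuple(p * est.value)
        lo = None if est.ci_lower is None else tuple(p * est.ci_lower)
        hi = None if est.ci_upper is None else tuple(p * est.ci_upper)
        points.append(IsobolePoint(level=level, partial_concentrations=partial,
                                   ci_lower=lo, ci_upper=hi,
                                   source="OBSERVED"))
        # geometric judgment along the ray, mirroring the CTCICI cascade
        ctc_val = 100.0 * t_ca / est.value
        if est.ci_lower is not None and est.ci_upper is not None:
            if est.ci_lower <= t_ca <= est.ci_upper:
                cls = Classification.ADDITIVE
            elif est.ci_lower > t_ca:
                cls = Classification.ANTAGONISTIC
            else:
                cls = Classification.SYNERGISTIC
            rule = Rule.CI_BOTH
            ll = 100.0 * t_ca / est.ci_upper
            ul = 100.0 * t_ca / est.ci_lower
        else:
            bound_ec = (est.ci_lower if est.ci_lower is not None
                        else est.ci_upper)
            ll = ul = None
            if est.ci_lower is not None:
                ul = 100.0 * t_ca / est.ci_lower
            if est.ci_upper is not None:
                ll = 100.0 * t_ca / est.ci_upper
            if bound_ec is not None:
                lo_ec = min(bound_ec, est.value)
                hi_ec = max(bound_ec, est.value)
                if lo_ec <= t_ca <= hi_ec:
                    cls, rule = Classification.ADDITIVE, Rule.CI_ONE_SIDED
                else:
                    cls, rule = _fallback(ctc_val), Rule.CTC_FALLBACK
            else:
                cls, rule = _fallback(ctc_val), Rule.CTC_FALLBACK
        calls.append(InteractionCall(level=level, ctc=ctc_val, ctc_ll=ll,
                                     ctc_ul=ul, classification=cls,
                                     rule_used=rule))
    ca_line = ((float(ec[0]), 0.0), (0.0, float(ec[1])))
    return {"level": level, "ca_line": ca_line, "points": points,
            "calls": calls}


# ---------------------------------------------------------------------------
# cross points and toxicity profiles
# ---------------------------------------------------------------------------


def cross_point(observed: BiphasicParams, predicted: PredictedCurve,
                scan_range: Optional[tuple] = None, n_grid: int = 4096,
                minimum: Optional[HormeticMinimum] = None,
                flat_tol: float = 1e-3) -> list:
    """Crossings between the observed BP curve and a predicted curve.

    The predicted curve is interpolated in log-concentration; sign
    changes of (observed - predicted effect) over a dense log-spaced grid
    are refined by Brent's method, and each crossing is labelled LEFT or
    RIGHT of the observed hormetic minimum.  A predicted curve that
    coincides with the observed one (maximum deviation below
    ``flat_tol``) yields no isolated crossing.  The predicted curve
    should be sampled finely enough that its interpolation error stays
    below ``flat_tol``.
    """
    pts = predicted.points()
    if pts.shape[0] < 2:
        raise InvalidInputError("predicted curve has too few points")
    logc_pts = np.log10(pts[:, 0])
    eff_pts = pts[:, 1]

    def pred_effect(c):
        return np.interp(np.log10(c), logc_pts, eff_pts)

    lo = pts[0, 0] if scan_range is None else scan_range[0]
    hi = pts[-1, 0] if scan_range is None else scan_range[1]
    lo = max(lo, pts[0, 0])
    hi = min(hi, pts[-1, 0])
    if not (0 < lo < hi):
        raise InvalidInputError("empty scan range within the predicted curve")
    grid = np.geomspace(lo, hi, n_grid)
    d = bp_effect(observed, grid) - pred_effect(grid)
    if np.max(np.abs(d)) < flat_tol:
        return []
    if minimum is None:
        minimum = bp_minimum(observed)
    out = []
    f = lambda c: bp_effect(observed, c) - pred_effect(c)
    for j in range(n_grid - 1):
        if np.sign(d[j]) != np.sign(d[j + 1]) and d[j] != 0.0:
            root = float(brentq(f, grid[j], grid[j + 1], rtol=1e-12))
            side = Side.LEFT if root < minimum.ec_m else Side.RIGHT
            out.append(CrossPoint(ec_cp=root,
                                  e_cp=float(bp_effect(observed, root)),
                                  side=side))
    return out


def toxicity_profile(levels: Sequence[EffectLevel],
                     subjects: Sequence[tuple]) -> pd.DataFrame:
    """Mixture toxicity (pEC_x = -log10 EC_x,mix) versus composition.

    ``subjects`` holds (label, p_first_component, {level_label: EC_x})
    tuples; single components enter as the boundary points P = 1 and
    P = 0.  Returns a tidy frame (subject, p, level, ec_x, pec_x).
    """
    rows = []
    for label, p_first, ecx_map in subjects:
        for lvl in levels:
            key = lvl.label if isinstance(lvl, EffectLevel) else str(lvl)
            ec = ecx_map.get(key)
            if ec is None:
                continue
            if ec <= 0:
                raise InvalidInputError("EC values must be positive")
            rows.append((label, float(p_first), key, float(ec),
                         -math.log10(ec)))
    return pd.DataFrame(rows, columns=["subject", "p", "level", "ec_x",
                                       "pec_x"])
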