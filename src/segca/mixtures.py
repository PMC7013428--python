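"""Mixture design and additivity prediction (CA and segmented CA).

Concentration addition (CA, Loewe additivity) predicts the concentration
of a mixture eliciting effect x as the harmonic combination of the
component effect concentrations weighted by concentration proportions:

    EC_x,mix = 1 / sum_i(P_i / EC_x,i)

For J-shaped curves plain CA has a predictive blind zone (PBZ): effects
deeper than the shallowest component minimum are unreachable for at least
one component, so its EC_x does not exist and the mixture minimum cannot
be predicted.  Segmented concentration addition (SCA) removes the blind
zone by applying CA separately to monotone descriptions of the two
segments -- the Hill fit of the left (stimulatory) segment and the BPR
sub-model of the right (inhibitory) segment -- and docking the two
predicted branches where they meet.  The docking point directly yields
the predicted mixture minimum (EC_m,SCA, E_m,SCA), which plain CA cannot
provide.

Binary rays follow the direct equipartition-ray (EquRay) design: fixed
molar ratios spread evenly across composition space, converted to molar
concentration proportions P_i = ratio_i / sum(ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .models import (
    BiphasicParams,
    DomainError,
    EffectLevel,
    HillParams,
    HormeticMinimum,
    InvalidInputError,
    Side,
    bp_left_inverse,
    bp_minimum,
    bpr_inverse,
    hill_inverse,
)

__all__ = [
    "MixtureRay",
    "ComponentModels",
    "ComponentModelSet",
    "PredictedCurve",
    "equray_proportions",
    "mixture_stock",
    "ca_ecx",
    "ca_curve_bp",
    "sca_predict",
    "sca_effect_at",
]


def equray_proportions(molar_ratio: Sequence[float]) -> np.ndarray:
    """Molar concentration proportions P_i = ratio_i / sum(ratio)."""
    r = np.asarray(molar_ratio, dtype=float)
    if r.ndim != 1 or r.size == 0 or np.any(r <= 0):
        raise InvalidInputError("molar ratios must be positive")
    return r / r.sum()


def mixture_stock(proportions: Sequence[float],
                  component_stocks: Sequence[float]) -> float:
    """Mixture stock concentration, C_0,mix = sum_i P_i * C_0,i (mol/L)."""
    p = np.asarray(proportions, dtype=float)
    c0 = np.asarray(component_stocks, dtype=float)
    if p.shape != c0.shape:
        raise InvalidInputError("proportions and stocks must align")
    if abs(p.sum() - 1.0) > 1e-12 or np.any(p <= 0):
        raise InvalidInputError("proportions must be positive and sum to 1")
    if np.any(c0 <= 0):
        raise InvalidInputError("stock concentrations must be positive")
    return float(np.dot(p, c0))


def ca_ecx(proportions: Sequence[float],
           component_ecx: Sequence[float]) -> float:
    """Concentration-addition mixture EC_x = 1 / sum_i(P_i / EC_x,i)."""
    p = np.asarray(proportions, dtype=float)
    ec = np.asarray(component_ecx, dtype=float)
    if p.shape != ec.shape:
        raise InvalidInputError("proportions and EC_x values must align")
    if abs(p.sum() - 1.0) > 1e-12 or np.any(p <= 0):
        raise InvalidInputError("proportions must be positive and sum to 1")
    if np.any(~np.isfinite(ec)) or np.any(ec <= 0):
        raise InvalidInputError("component EC_x values must be finite and "
                                "positive")
    return float(1.0 / np.sum(p / ec))


@dataclass(frozen=True)
class MixtureRay:
    """A fixed-ratio binary (or n-ary) mixture ray.

    Components are identified by name; the molar ratio determines the
    concentration proportions.  The stock concentration is optional and,
    when absent, derivable from component stocks via ``mixture_stock``.
    """

    components: tuple
    molar_ratio: tuple
    stock_concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.components) != len(self.molar_ratio):
            raise InvalidInputError("components and molar_ratio must align")
        equray_proportions(self.molar_ratio)  # validates positivity

    @property
    def proportions(self) -> np.ndarray:
        return equray_proportions(self.molar_ratio)


@dataclass(frozen=True)
class ComponentModels:
    """Fitted models of one component: BP (right branch via BPR), Hill
    (left branch) and the hormetic minimum of the BP curve."""

    bp: BiphasicParams
    hill: HillParams
    minimum: HormeticMinimum


@dataclass
class ComponentModelSet:
    """Ordered component models for a mixture prediction."""

    names: tuple
    models: tuple  # of ComponentModels, aligned with names

    @classmethod
    def build(cls, pairs: Sequence[tuple]) -> "ComponentModelSet":
        """From (name, BiphasicParams, HillParams) triples; minima are
        computed from the BP curves."""
        names, models = [], []
        for name, bp, hill in pairs:
            names.append(name)
            models.append(ComponentModels(bp=bp, hill=hill,
                                          minimum=bp_minimum(bp)))
        return cls(names=tuple(names), models=tuple(models))


@dataclass
class PredictedCurve:
    """A predicted mixture J-CRC, split at the (predicted) minimum.

    left / right: arrays of (concentration, effect) rows ordered by
    concentration.  ``docking`` holds (ec_m_sca, e_m_sca) for SCA when the
    two branches meet; ``pbz`` holds the effect interval spanned by the
    component minima where plain CA loses at least one component.
    """

    method: str  # "CA_BP" | "SCA"
    left: np.ndarray
    right: np.ndarray
    docking: Optional[tuple] = None
    pbz: Optional[tuple] = None
    diagnostics: list = field(default_factory=list)

    def points(self) -> np.ndarray:
        pts = [a for a in (self.left, self.right) if a.size]
        if not pts:
            return np.empty((0, 2))
        allpts = np.vstack(pts)
        return allpts[np.argsort(allpts[:, 0])]

    def summary(self) -> dict:
        return {
            "method": self.method,
            "ec_m_sca": None if self.docking is None else self.docking[0],
            "e_m_sca": None if self.docking is None else self.docking[1],
            "pbz": None if self.pbz is None else list(self.pbz),
        }


def ca_curve_bp(component_bp: Sequence[BiphasicParams],
                proportions: Sequence[float],
                levels: Sequence[EffectLevel],
                minima: Optional[Sequence[HormeticMinimum]] = None,
                ) -> PredictedCurve:
    """Plain CA prediction of the mixture curve from the component BP fits.

    Each requested level is inverted per component (numerical BP
    left-branch inverse on the left, closed-form BPR inverse on the
    right) and combined by CA.  Levels deeper than the shallowest
    component minimum fall in the predictive blind zone and are skipped;
    the PBZ interval (spanning the component minima) is reported whenever
    stimulatory levels were requested.
    """
    p = np.asarray(proportions, dtype=float)
    bps = list(component_bp)
    if minima is None:
        minima = [bp_minimum(bp) for bp in bps]
    e_ms = [mn.e_m for mn in minima]
    pbz_lo, pbz_hi = min(e_ms), max(e_ms)

    left_pts, right_pts, diags = [], [], []
    any_stim = False
    for lvl in levels:
        if lvl.x < 0:
            any_stim = True
        try:
            if lvl.x < 0 and lvl.side is Side.LEFT:
                concs = [bp_left_inverse(bp, lvl.x, mn)
                         for bp, mn in zip(bps, minima)]
                left_pts.append((ca_ecx(p, concs), lvl.x))
            else:
                concs = [bpr_inverse(bp, lvl.x) for bp in bps]
                right_pts.append((ca_ecx(p, concs), lvl.x))
        except (DomainError, InvalidInputError) as exc:
            diags.append(f"level {lvl.label}: {exc}")
    if not left_pts and not right_pts:
        raise DomainError("no requested level is reachable by every component")
    left = np.array(sorted(left_pts)) if left_pts else np.empty((0, 2))
    right = np.array(sorted(right_pts)) if right_pts else np.empty((0, 2))
    pbz = (pbz_lo, pbz_hi) if any_stim else None
    return PredictedCurve(method="CA_BP", left=left, right=right,
                          docking=None, pbz=pbz, diagnostics=diags)


def _branch_concentration(models: Sequence[ComponentModels],
                          p: np.ndarray, e: float, left: bool) -> float:
    """CA-combined concentration at effect e on one segment; NaN when any
    component inverse leaves its domain or turns non-positive."""
    try:
        if left:
            concs = [hill_inverse(cm.hill, e) for cm in models]
        else:
            concs = [bpr_inverse(cm.bp, e) for cm in models]
        return ca_ecx(p, concs)
    except (DomainError, InvalidInputError):
        return float("nan")


def sca_predict(models: ComponentModelSet,
                proportions: Sequence[float],
                grid_resolution: int = 512,
                n_scan: int = 2048,
                inhibition_top: float = 0.98) -> PredictedCurve:
    """Segmented-CA prediction of the mixture J-CRC.

    The left predicted branch is CA over the component Hill inverses,
    L(e); the right branch is CA over the component BPR inverses, R(e).
    The docking effect e* is the root of L(e) - R(e) on (e_lo, 0), where
    e_lo = max_i max(d_i, m_i) keeps every component inverse in-domain.
    The root is bracketed by a dense scan and polished by Brent's method;
    if several sign changes exist the shallowest (smallest |e|) is taken
    with a warning.  When no sign change exists the curve is returned with
    ``docking=None`` and a diagnostic (SCA cannot close the curve).

    Returns the predicted curve with the docking point (EC_m,SCA, E_m,SCA)
    and ``grid_resolution`` points per branch.
    """
    p = np.asarray(proportions, dtype=float)
    comps = list(models.models)
    if len(comps) != p.size:
        raise InvalidInputError("proportions must align with components")
    e_lo = max(max(cm.hill.d, cm.bp.m) for cm in comps)
    eps = 1e-6
    if e_lo >= -2 * eps:
        raise DomainError("every component needs a non-vanishing stimulatory "
                          "segment (negative Hill top) for SCA")
    scan = np.linspace(e_lo + eps, -eps, n_scan)
    lvals = np.array([_branch_concentration(comps, p, e, left=True)
                      for e in scan])
    rvals = np.array([_branch_concentration(comps, p, e, left=False)
                      for e in scan])
    diff = lvals - rvals
    valid = np.isfinite(diff)
    diags: list = []

    brackets = []
    idx = np.where(valid)[0]
    for j0, j1 in zip(idx[:-1], idx[1:]):
        if j1 == j0 + 1 and diff[j0] == 0.0:
            brackets.append((scan[j0], scan[j0]))
        elif j1 == j0 + 1 and np.sign(diff[j0]) != np.sign(diff[j1]):
            brackets.append((scan[j0], scan[j1]))
    docking = None
    if brackets:
        if len(brackets) > 1:
            warnings.warn("multiple docking candidates; using the "
                          "shallowest (smallest |e|)", stacklevel=2)
            diags.append(f"{len(brackets)} docking sign changes found")
        e1, e2 = brackets[-1]  # scan runs toward 0, last = shallowest
        if e1 == e2:
            e_star = float(e1)
        else:
            e_star = float(brentq(
                lambda e: _branch_concentration(comps, p, e, True)
                - _branch_concentration(comps, p, e, False),
                e1, e2, xtol=1e-14, rtol=8.9e-16))
        ec_star = _branch_concentration(comps, p, e_star, left=True)
        docking = (float(ec_star), float(e_star))
    else:
        diags.append("no docking: left and right CA branches do not cross")

    e_bottom = docking[1] if docking else float(scan[valid][0])
    e_left = np.linspace(-abs(e_bottom) * 1e-3, e_bottom, grid_resolution)
    left = np.array([( _branch_concentration(comps, p, e, True), e)
                     for e in e_left])
    left = left[np.isfinite(left[:, 0])]
    left = left[np.argsort(left[:, 0])]
    e_right = np.linspace(e_bottom, inhibition_top, grid_resolution)
    right = np.array([( _branch_concentration(comps, p, e, False), e)
                      for e in e_right])
    right = right[np.isfinite(right[:, 0])]
    right = right[right[:, 0] > 0]
    right = right[np.argsort(right[:, 0])]
    return PredictedCurve(method="SCA", left=left, right=right,
                          docking=docking, pbz=None, diagnostics=diags)


def sca_effect_at(models: ComponentModelSet, proportions: Sequence[float],
                  concentrations, docking: Optional[tuple] = None):
    """Effect of the SCA-predicted curve at given concentrations.

    Solves L(e) = c on the left branch (c below EC_m,SCA) or R(e) = c on
    the right branch exactly by root bracketing, rather than
    interpolating curve points.  Used by the synthetic-data generators,
    where the generating curve must satisfy additivity by construction.
    """
    p = np.asarray(proportions, dtype=float)
    comps = list(models.models)
    if docking is None:
        pred = sca_predict(models, p)
        if pred.docking is None:
            raise DomainError("SCA branches do not dock; no closed curve")
        docking = pred.docking
    ec_star, e_star = docking
    c_arr = np.atleast_1d(np.asarray(concentrations, dtype=float))
    out = np.empty_like(c_arr)
    for i, c in enumerate(c_arr):
        if c <= 0:
            raise InvalidInputError("concentrations must be positive")
        if c <= ec_star:
            f = lambda e: _branch_concentration(comps, p, e, True) - c
            hi = -1e-12
            if f(hi) >= 0:  # concentration below the resolvable left tail
                out[i] = 0.0
                continue
            out[i] = brentq(f, e_star, hi, xtol=1e-15, rtol=8.9e-16)
        else:
            f = lambda e: _branch_concentration(comps, p, e, False) - c
            hi = 1.0 - 1e-12
            if f(hi) <= 0:
                out[i] = 1.0
                continue
            out[i] = brentq(f, e_star, hi, xtol=1e-15, rtol=8.9e-16)
    return out if np.asarray(concentrations).ndim else float(out[0])
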