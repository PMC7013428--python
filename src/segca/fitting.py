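"""Estimation of biphasic and Hill models from replicate plate data.

Fits the five-parameter biphasic (BP) model to pooled replicate
concentration-effect observations by deterministic multi-start nonlinear
least squares, fits the Hill model to the left (stimulatory) segment,
computes R^2/RMSE, builds the observation-based pointwise 95 % confidence
band of the mean effect, and extracts effect concentrations EC_x with
band-derived confidence intervals.

The BP least-squares surface is multi-modal: very different parameter
regimes (e.g. a bottom parameter of -0.4 versus -80 with negative phase
medians) can describe the same J-curve almost equally well.  A fixed
multi-start grid over the bottom parameter, with medians and slopes seeded
from the observed minimum and the observed 50 %-inhibition crossing, makes
the fit deterministic for a given dataset (no RNG is involved).

Confidence intervals for EC_x follow the replicate-band construction:
pointwise mean +/- t(0.975, n-1) * SE at each tested concentration, the
band offsets carried along the fitted curve and the resulting envelopes
monotonised within each branch of the J-curve and intersected with the
requested effect level.  An
envelope that never attains the level on its branch yields an absent
(None) bound -- the "NA" pattern seen with steep or noisy segments.  This
band construction is one documented interpretation of an
"observation-based 95 % CI"; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .models import (
    BiphasicParams,
    DomainError,
    EffectLevel,
    HillParams,
    HormeticMinimum,
    InvalidInputError,
    Side,
    bp_effect,
    bp_left_inverse,
    bp_minimum,
    bpr_inverse,
    hill_effect,
)

__all__ = [
    "ControlVariabilityError",
    "FitConvergenceError",
    "DoseResponseDataset",
    "FitResult",
    "ECxEstimate",
    "read_datasets",
    "fit_biphasic",
    "fit_hill_left",
    "goodness_of_fit",
    "effect_confidence_band",
    "ecx_with_ci",
]

#: Maximum tolerated coefficient of variation of the blank controls.
CONTROL_CV_LIMIT = 0.15

#: Fixed multi-start grid over the bottom parameter m.
M_STARTS = (-0.2, -0.5, -1.0, -5.0, -50.0)
#: Slope-scale multipliers applied to the finite-difference slope seeds.
SLOPE_SCALES = (1.0, 0.25)


class ControlVariabilityError(InvalidInputError):
    """Blank-control scatter exceeds the assay acceptance limit."""


class FitConvergenceError(RuntimeError):
    """No start converged; carries best-so-far diagnostics."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class DoseResponseDataset:
    """Replicate concentration-effect observations for one subject.

    Long-form pooled arrays: ``concentration[i]`` (mol/L, positive) pairs
    with one replicate ``effect[i]`` (signed fraction).  ``controls``
    optionally holds raw control responses (RLU) when effects were derived
    from luminescence.
    """

    subject_id: str
    concentration: np.ndarray
    effect: np.ndarray
    controls: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        e = np.asarray(self.effect, dtype=float)
        if c.shape != e.shape or c.ndim != 1 or c.size == 0:
            raise InvalidInputError("concentration and effect must be equal-"
                                    "length 1-D arrays")
        if np.any(c <= 0):
            raise InvalidInputError("treatment concentrations must be positive")
        order = np.argsort(c, kind="stable")
        self.concentration = c[order]
        self.effect = e[order]
        if self.controls is not None:
            self.controls = np.asarray(self.controls, dtype=float)

    @property
    def n_obs(self) -> int:
        return self.concentration.size

    def unique_concentrations(self) -> np.ndarray:
        return np.unique(self.concentration)

    def mean_effects(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique concentrations and per-concentration mean effects."""
        uc = self.unique_concentrations()
        means = np.array([self.effect[self.concentration == c].mean()
                          for c in uc])
        return uc, means

    def observed_minimum(self) -> tuple[float, float]:
        """Tested concentration with the lowest mean effect, and that mean."""
        uc, me = self.mean_effects()
        i = int(np.argmin(me))
        return float(uc[i]), float(me[i])

    def to_frame(self) -> pd.DataFrame:
        reps: dict = {}
        rows = []
        for c, e in zip(self.concentration, self.effect):
            reps[c] = reps.get(c, 0) + 1
            rows.append((self.subject_id, c, reps[c], e, "effect"))
        if self.controls is not None:
            for j, r in enumerate(self.controls, start=1):
                rows.append((self.subject_id, 0.0, j, r, "rlu"))
        return pd.DataFrame(rows, columns=["subject_id",
                                           "concentration_mol_per_L",
                                           "replicate", "response",
                                           "response_type"])


def read_datasets(source: Union[str, pd.DataFrame],
                  control_cv_limit: float = CONTROL_CV_LIMIT,
                  ) -> dict[str, DoseResponseDataset]:
    """Read long-format CSV (or DataFrame) into per-subject datasets.

    Expected columns: subject_id, concentration_mol_per_L, replicate,
    response, response_type in {rlu, effect}.  Control rows are flagged by
    concentration 0; for RLU data the effect is 1 - L/L0 with L0 the mean
    control RLU.  Datasets whose control CV exceeds ``control_cv_limit``
    are rejected (assay acceptance gate on blank variability).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
        if df.empty:
            raise InvalidInputError(f"no data rows in {source}")
    required = {"subject_id", "concentration_mol_per_L", "replicate",
                "response", "response_type"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    df["concentration_mol_per_L"] = df["concentration_mol_per_L"].astype(float)
    df["response"] = df["response"].astype(float)

    out: dict[str, DoseResponseDataset] = {}
    for subject, g in df.groupby("subject_id", sort=False):
        ctrl = g[g["concentration_mol_per_L"] == 0.0]
        trt = g[g["concentration_mol_per_L"] > 0.0]
        if trt.empty:
            raise InvalidInputError(f"subject {subject!r} has no treatment rows")
        rtype = trt["response_type"].iloc[0]
        controls = None
        if rtype == "rlu":
            if ctrl.empty:
                raise InvalidInputError(
                    f"subject {subject!r}: RLU data require control rows")
            controls = ctrl["response"].to_numpy(dtype=float)
            l0 = controls.mean()
            if l0 <= 0:
                raise InvalidInputError(
                    f"subject {subject!r}: non-positive control mean")
            cv = controls.std(ddof=1) / l0 if controls.size > 1 else 0.0
            if cv > control_cv_limit:
                raise ControlVariabilityError(
                    f"subject {subject!r}: control CV {cv:.3f} exceeds the "
                    f"{control_cv_limit:.0%} acceptance limit")
            eff = 1.0 - trt["response"].to_numpy(dtype=float) / l0
        elif rtype == "effect":
            eff = trt["response"].to_numpy(dtype=float)
            if not ctrl.empty:
                controls = ctrl["response"].to_numpy(dtype=float)
        else:
            raise InvalidInputError(
                f"subject {subject!r}: unknown response_type {rtype!r}")
        out[str(subject)] = DoseResponseDataset(
            subject_id=str(subject),
            concentration=trt["concentration_mol_per_L"].to_numpy(dtype=float),
            effect=eff,
            controls=controls,
        )
    return out


@dataclass
class FitResult:
    """A fitted model with goodness-of-fit diagnostics."""

    params: Union[BiphasicParams, HillParams]
    r_squared: Optional[float]
    rmse: float
    n_obs: int
    converged: bool

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(),
                "r_squared": self.r_squared, "rmse": self.rmse,
                "n_obs": self.n_obs, "converged": self.converged}


@dataclass
class ECxEstimate:
    """Effect concentration with band-derived confidence bounds.

    Absent bounds (``None``) arise when the corresponding band envelope
    never attains the level on the requested branch.
    """

    level: EffectLevel
    value: float
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.ci_lower is not None and self.ci_upper is not None
                and not (self.ci_lower <= self.value <= self.ci_upper)):
            raise InvalidInputError(
                "CI bounds must bracket the point estimate")

    def to_dict(self) -> dict:
        return {"level": self.level.label, "value": self.value,
                "ci_lower": self.ci_lower, "ci_upper": self.ci_upper}


def goodness_of_fit(observed: Sequence[float],
                    predicted: Sequence[float]) -> tuple[Optional[float], float]:
    """R^2 about the observed mean, and RMSE.

    R^2 is None (undefined) when the observed values have zero variance.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise InvalidInputError("need equal-length vectors of size >= 2")
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return None, rmse
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return r2, rmse


# ---------------------------------------------------------------------------
# BP and Hill fitting
# ---------------------------------------------------------------------------


def _bp_start_points(uc: np.ndarray, me: np.ndarray) -> list[np.ndarray]:
    """Deterministic start grid seeded from the observed curve shape."""
    i_min = int(np.argmin(me))
    c_min = uc[i_min]
    a0 = c_min / 3.0
    b0 = 2.0 / max(c_min - a0, 0.1 * c_min)
    # right-branch 50 % crossing (log-interpolated), fallback: geometric mean
    rc, re = uc[i_min:], me[i_min:]
    p0 = math.sqrt(c_min * uc[-1])
    for j in range(1, rc.size):
        if re[j - 1] < 0.5 <= re[j]:
            w = (0.5 - re[j - 1]) / (re[j] - re[j - 1])
            p0 = 10 ** ((1 - w) * math.log10(rc[j - 1]) + w * math.log10(rc[j]))
            break
    q0 = 2.0 / max(p0 - c_min, 0.2 * p0)
    starts = []
    for m0 in M_STARTS:
        for s in SLOPE_SCALES:
            starts.append(np.array([m0, a0, b0 * s, p0, q0 * s]))
    return starts


def fit_biphasic(dataset: DoseResponseDataset) -> FitResult:
    """Fit the five-parameter BP model by multi-start least squares.

    Requires at least 5 distinct concentrations (one per parameter).
    Pooled replicates are fitted unweighted; the best of the fixed start
    grid is kept, so the result is deterministic for a given dataset.
    """
    uc, me = dataset.mean_effects()
    if uc.size < 5:
        raise InvalidInputError(
            f"BP fitting needs >= 5 distinct concentrations, got {uc.size}")
    c, e = dataset.concentration, dataset.effect

    def resid(x):
        pr = BiphasicParams(m=x[0], a=x[1], b=x[2], p=x[3], q=x[4])
        return bp_effect(pr, c) - e

    lb = np.array([-1e4, -1.0, 1e-3, -1.0, 1e-3])
    ub = np.array([1.0, 1.0, 1e12, 1.0, 1e12])
    best = None
    for x0 in _bp_start_points(uc, me):
        x0 = np.clip(x0, lb, ub)
        try:
            res = least_squares(resid, x0, bounds=(lb, ub), x_scale="jac",
                                method="trf", max_nfev=400)
        except Exception:  # a pathological start must not kill the fit
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitConvergenceError("all BP starts failed", best=best)
    params = BiphasicParams(m=float(best.x[0]), a=float(best.x[1]),
                            b=float(best.x[2]), p=float(best.x[3]),
                            q=float(best.x[4]))
    r2, rmse = goodness_of_fit(e, bp_effect(params, c))
    return FitResult(params=params, r_squared=r2, rmse=rmse,
                     n_obs=dataset.n_obs, converged=bool(best.success))


def fit_hill_left(dataset: DoseResponseDataset,
                  minimum: Optional[HormeticMinimum] = None) -> FitResult:
    """Fit the Hill model to the left (stimulatory) segment.

    Observations at concentrations up to and *including* the observed
    lowest point enter the fit -- sharing that point between the left
    (Hill) and right (BPR) descriptions is what lets the two CA-predicted
    branches dock later.  Needs >= 3 usable distinct concentrations.
    """
    c_min_obs, e_min_obs = dataset.observed_minimum()
    mask = dataset.concentration <= c_min_obs
    c = dataset.concentration[mask]
    e = dataset.effect[mask]
    if np.unique(c).size < 3:
        raise InvalidInputError(
            "Hill left-segment fit needs >= 3 distinct concentrations at or "
            "below the observed lowest point")

    def resid(x):
        d, k = x
        return d * c / (k + c) - e

    d0 = 2.0 * e_min_obs if e_min_obs < 0 else -0.1
    best = None
    for dscale in (1.0, 0.6, 2.0):
        for kscale in (1.0, 0.3, 3.0):
            x0 = np.array([d0 * dscale, c_min_obs * kscale])
            res = least_squares(resid, x0,
                                bounds=([-1e3, 1e-12], [1e3, 1.0]),
                                x_scale="jac", method="trf", max_nfev=200)
            if best is None or res.cost < best.cost:
                best = res
    d_fit, k_fit = float(best.x[0]), float(best.x[1])
    if d_fit == 0.0:
        d_fit = -1e-12  # flat segment: keep the container constructible
    params = HillParams(d=d_fit, k=k_fit)
    r2, rmse = goodness_of_fit(e, hill_effect(params, c))
    return FitResult(params=params, r_squared=r2, rmse=rmse,
                     n_obs=int(mask.sum()), converged=bool(best.success))


# ---------------------------------------------------------------------------
# confidence band and EC_x extraction
# ---------------------------------------------------------------------------


def effect_confidence_band(dataset: DoseResponseDataset,
                           ci_level: float = 0.95) -> pd.DataFrame:
    """Pointwise t-based CI of the mean effect at each tested concentration.

    Returns a DataFrame with columns concentration, n, mean, lo, hi.
    Single-replicate concentrations get NaN bounds (band absent there).
    """
    if not 0 < ci_level < 1:
        raise InvalidInputError("ci_level must be in (0, 1)")
    rows = []
    for c in dataset.unique_concentrations():
        vals = dataset.effect[dataset.concentration == c]
        n = vals.size
        mean = float(vals.mean())
        if n >= 2:
            se = float(vals.std(ddof=1)) / math.sqrt(n)
            t = float(stats.t.ppf(0.5 + ci_level / 2.0, n - 1))
            lo, hi = mean - t * se, mean + t * se
        else:
            lo = hi = float("nan")
        rows.append((float(c), n, mean, lo, hi))
    return pd.DataFrame(rows, columns=["concentration", "n", "mean",
                                       "lo", "hi"])


def _invert_envelope(conc: np.ndarray, env: np.ndarray, level: float,
                     effect_increasing: bool) -> Optional[float]:
    """Concentration where a monotonised band envelope attains ``level``.

    The envelope is forced monotone along the branch (non-decreasing in
    concentration for the rising branch, non-increasing for the falling
    one) before inversion by log-linear interpolation.  None when the
    level is never attained.
    """
    if conc.size < 2 or np.any(~np.isfinite(env)):
        return None
    logc = np.log10(conc)
    if effect_increasing:
        mono = np.maximum.accumulate(env)
        x, y = mono, logc
    else:
        mono = np.minimum.accumulate(env)
        x, y = mono[::-1], logc[::-1]
    if not (x[0] <= level <= x[-1]):
        return None
    return float(10.0 ** np.interp(level, x, y))


def ecx_with_ci(fit: FitResult, band: Optional[pd.DataFrame],
                level: EffectLevel,
                minimum: Optional[HormeticMinimum] = None) -> ECxEstimate:
    """EC_x point estimate from the fitted BP curve, CI from the band.

    The point estimate inverts the fitted curve: the closed-form BPR
    inverse on the right branch (all inhibition levels and right-side
    stimulation levels), the numerical BP left-branch inverse on the left.
    Each CI bound comes from intersecting one band envelope with the
    level; a bound is absent (None) when that envelope never reaches the
    level on the branch.
    """
    params = fit.params
    if not isinstance(params, BiphasicParams):
        raise InvalidInputError("EC_x extraction requires a BP fit")
    if minimum is None:
        minimum = bp_minimum(params)
    if level.x < 0 and level.side is Side.LEFT:
        value = bp_left_inverse(params, level.x, minimum)
        branch_left = True
    else:
        value = bpr_inverse(params, level.x)
        branch_left = False
        if value <= 0:
            raise DomainError(
                f"level {level.label} maps to a non-positive concentration")

    lo_b = hi_b = None
    if band is not None and len(band) >= 2:
        conc = band["concentration"].to_numpy()
        means = band["mean"].to_numpy()
        i_min = int(np.argmin(means))
        if branch_left:
            sel = slice(0, i_min + 1)
            inc = False
        else:
            sel = slice(i_min, len(band))
            inc = True
        c_br = conc[sel]
        if c_br.size >= 2:
            # envelopes follow the fitted curve's shape, offset by the
            # replicate-band half-widths interpolated across the branch;
            # chord interpolation between tested points would bias both
            # bounds on coarse dilution grids
            logc_br = np.log10(c_br)
            d_hi = band["hi"].to_numpy()[sel] - means[sel]
            d_lo = means[sel] - band["lo"].to_numpy()[sel]
            grid = np.geomspace(c_br[0], c_br[-1], 512)
            lg = np.log10(grid)
            f = bp_effect(params, grid)
            env_hi = f + np.interp(lg, logc_br, d_hi)
            env_lo = f - np.interp(lg, logc_br, d_lo)
            c_from_hi = _invert_envelope(grid, env_hi, level.x, inc)
            c_from_lo = _invert_envelope(grid, env_lo, level.x, inc)
            if inc:
                lo_b, hi_b = c_from_hi, c_from_lo  # rising branch
            else:
                lo_b, hi_b = c_from_lo, c_from_hi  # falling branch
            # numerical envelope crossings can land marginally across
            # the point estimate; widen to preserve the CI ordering
            if lo_b is not None:
                lo_b = min(lo_b, value)
            if hi_b is not None:
                hi_b = max(hi_b, value)
    return ECxEstimate(level=level, value=float(value),
                       ci_lower=lo_b, ci_upper=hi_b)
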