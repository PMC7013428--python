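"""Seeded synthetic plate-data generators.

Emulates the microplate bioluminescence-inhibition assay the pipeline is
built for: a geometric dilution series (16 concentrations by default,
factor-2 dilution from the stock), at least 4 replicate wells per
concentration and 24 blank controls whose variability stays within the
+/-15 % acceptance gate.  Observation noise is additive Gaussian on the
effect scale (sigma 0.02 by default, which lands fits comfortably inside
an R^2 > 0.91 / RMSE < 0.12 envelope); an optional RLU mode emits raw
relative light units L = L0 (1 - E) with multiplicative lognormal control
scatter at the stated CV.

Mixture generators build their noiseless truth from the segmented-CA
prediction of the component models, so additivity holds by construction
and a fitted mixture should recover CTC = 100 on average; an interactive
mixture scales the concentration axis by a deviation factor (> 1:
antagonism with CTC ~ 100/deviation; < 1: synergism).

All randomness flows from the design seed through one
``numpy.random.default_rng`` instance; identical seeds give identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import CONTROL_CV_LIMIT, DoseResponseDataset
from .mixtures import ComponentModelSet, MixtureRay, sca_effect_at, sca_predict
from .models import BiphasicParams, DomainError, InvalidInputError, bp_effect

__all__ = [
    "PlateDesign",
    "generate_single",
    "generate_additive_mixture",
    "generate_interactive_mixture",
]


@dataclass(frozen=True)
class PlateDesign:
    """Microplate layout and noise model for one simulated assay."""

    n_concentrations: int = 16
    dilution: float = 2.0
    top_concentration: float = 1.28e-3
    n_replicates: int = 4
    n_controls: int = 24
    noise_sd: float = 0.02
    control_cv: float = 0.10
    seed: int = 0
    mode: str = "effect"  # "effect" | "rlu"
    control_rlu: float = 1e6

    def __post_init__(self) -> None:
        if self.n_concentrations < 5:
            raise InvalidInputError("need >= 5 concentrations")
        if self.n_replicates < 2:
            raise InvalidInputError("need >= 2 replicates")
        if self.dilution <= 1:
            raise InvalidInputError("dilution factor must exceed 1")
        if self.top_concentration <= 0:
            raise InvalidInputError("top concentration must be positive")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        if not 0 <= self.control_cv <= CONTROL_CV_LIMIT:
            raise InvalidInputError(
                f"control CV must stay within the {CONTROL_CV_LIMIT:.0%} "
                "assay acceptance gate")
        if self.mode not in ("effect", "rlu"):
            raise InvalidInputError("mode must be 'effect' or 'rlu'")

    def concentrations(self) -> np.ndarray:
        powers = np.arange(self.n_concentrations - 1, -1, -1, dtype=float)
        return self.top_concentration / self.dilution ** powers


def _assemble(subject_id: str, design: PlateDesign, conc: np.ndarray,
              true_effect: np.ndarray, rng: np.random.Generator,
              ) -> DoseResponseDataset:
    noisy = true_effect[:, None] + rng.normal(
        0.0, design.noise_sd, size=(conc.size, design.n_replicates))
    noisy = np.minimum(noisy, 1.0)  # full light loss is the ceiling
    long_c = np.repeat(conc, design.n_replicates)
    controls = None
    if design.mode == "rlu":
        s = np.sqrt(np.log1p(design.control_cv ** 2))
        controls = design.control_rlu * rng.lognormal(
            -s * s / 2.0, s, size=design.n_controls)
        l0 = controls.mean()
        rlu = design.control_rlu * (1.0 - noisy.ravel())
        effects = 1.0 - rlu / l0
    else:
        effects = noisy.ravel()
    return DoseResponseDataset(
        subject_id=subject_id, concentration=long_c, effect=effects,
        controls=controls,
        meta={"seed": design.seed, "noise_sd": design.noise_sd,
              "mode": design.mode})


def generate_single(truth: BiphasicParams, design: PlateDesign,
                    subject_id: str = "sim") -> DoseResponseDataset:
    """Simulate one plate from a known biphasic truth curve."""
    rng = np.random.default_rng(design.seed)
    conc = design.concentrations()
    return _assemble(subject_id, design, conc, bp_effect(truth, conc), rng)


def generate_additive_mixture(models: ComponentModelSet, ray: MixtureRay,
                              design: PlateDesign,
                              subject_id: str = "sim_mix",
                              ) -> DoseResponseDataset:
    """Simulate a mixture plate whose truth is the SCA prediction.

    By construction the noiseless curve satisfies concentration addition
    branch-wise, so downstream CTC estimates should centre on 100.
    Raises when the component branches do not dock (no closed truth).
    """
    p = ray.proportions
    pred = sca_predict(models, p)
    if pred.docking is None:
        raise DomainError("SCA branches do not dock; cannot build an "
                          "additive truth curve")
    rng = np.random.default_rng(design.seed)
    conc = design.concentrations()
    truth = sca_effect_at(models, p, conc, docking=pred.docking)
    return _assemble(subject_id, design, conc, np.asarray(truth), rng)


def generate_interactive_mixture(models: ComponentModelSet, ray: MixtureRay,
                                 design: PlateDesign, deviation: float,
                                 subject_id: str = "sim_mix",
                                 ) -> DoseResponseDataset:
    """Simulate an interactive mixture plate.

    The truth curve is the SCA prediction with its concentration axis
    scaled by ``deviation``: a mixture needing ``deviation`` times the
    additive concentration for the same effect (deviation > 1 gives
    antagonism with CTC ~ 100/deviation, < 1 synergism).
    """
    if not deviation > 0:
        raise InvalidInputError("deviation factor must be positive")
    p = ray.proportions
    pred = sca_predict(models, p)
    if pred.docking is None:
        raise DomainError("SCA branches do not dock; cannot build a "
                          "truth curve")
    rng = np.random.default_rng(design.seed)
    conc = design.concentrations()
    truth = sca_effect_at(models, p, conc / deviation, docking=pred.docking)
    ds = _assemble(subject_id, design, conc, np.asarray(truth), rng)
    ds.meta["deviation"] = deviation
    return ds
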