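"""Published reference values for the CTCC/OTCC bioluminescence study.

Chlortetracycline hydrochloride (CTCC) and oxytetracycline hydrochloride
(OTCC) both produce J-shaped concentration-response curves on the
luminescence of *Aliivibrio fischeri*, as do their seven binary fixed-ratio
mixtures M1..M7 (molar ratios 12:1, 10:3, 8:5, 1:1, 5:8, 3:10 and 1:12 on
an equipartition-ray design).  The raw plate data of that study were never
deposited; what is available are the printed fitted parameters, effect
concentrations, and interaction statistics.  This module ships those
printed values verbatim as fixtures: they are *inputs* for the downstream
algebra (segmented concentration-addition prediction, co-toxicity
coefficients, isoboles) and for regression tests -- nothing here is
computed by this package.

Units: concentrations mol/L; effects in the tables are percent (converted
to fractions only where stated); CTC values are dimensionless with 100 =
additivity.  ``None`` marks a confidence bound printed as not available.
"""

from __future__ import annotations

from .models import BiphasicParams, HillParams

SUBJECTS = ["CTCC", "OTCC", "M1", "M2", "M3", "M4", "M5", "M6", "M7"]
MIXTURES = ["M1", "M2", "M3", "M4", "M5", "M6", "M7"]
COMPONENTS = ["CTCC", "OTCC"]

#: CTCC:OTCC molar ratios of the equipartition-ray design.
MOLAR_RATIOS = {
    "M1": (12, 1), "M2": (10, 3), "M3": (8, 5), "M4": (1, 1),
    "M5": (5, 8), "M6": (3, 10), "M7": (1, 12),
}

#: Stock concentrations C_0 (mol/L).
STOCKS = {
    "CTCC": 1.28e-3, "OTCC": 1.22e-3,
    "M1": 1.28e-3, "M2": 1.27e-3, "M3": 1.26e-3, "M4": 1.25e-3,
    "M5": 1.25e-3, "M6": 1.24e-3, "M7": 1.23e-3,
}

#: Molecular weights (g/mol) of the hydrochloride salts.
MOLECULAR_WEIGHTS = {"CTCC": 515.34, "OTCC": 496.89}

#: Fitted five-parameter biphasic models (whole J-CRC) for every subject.
BP_PARAMS = {
    "CTCC": BiphasicParams(m=-0.4371, a=1.683e-6, b=531630, p=5.156e-5, q=28869),
    "OTCC": BiphasicParams(m=-80.26, a=-1.791e-5, b=120853, p=-1.042e-3, q=1669),
    "M1": BiphasicParams(m=-0.4783, a=2.085e-6, b=553767, p=5.649e-5, q=25904),
    "M2": BiphasicParams(m=-0.3467, a=2.240e-6, b=852676, p=6.923e-5, q=29086),
    "M3": BiphasicParams(m=-0.3678, a=2.658e-6, b=1064074, p=8.129e-5, q=28456),
    "M4": BiphasicParams(m=-0.3967, a=2.633e-6, b=1326084, p=9.964e-5, q=15435),
    "M5": BiphasicParams(m=-0.5370, a=5.823e-6, b=196214, p=1.241e-4, q=8527),
    "M6": BiphasicParams(m=-1.196, a=-8.300e-7, b=182580, p=8.442e-5, q=2411),
    "M7": BiphasicParams(m=-76.32, a=-4.627e-5, b=43150, p=-1.064e-3, q=1576),
}

#: Goodness of fit of the BP fits (R^2, RMSE).
BP_GOF = {
    "CTCC": (0.999, 0.022), "OTCC": (0.985, 0.049), "M1": (0.997, 0.034),
    "M2": (0.992, 0.058), "M3": (0.994, 0.048), "M4": (0.998, 0.028),
    "M5": (0.996, 0.033), "M6": (0.975, 0.062), "M7": (0.914, 0.112),
}

#: Hill fits of the left (stimulatory) segment -- single components only
#: (the mixtures' left segments were not Hill-fitted).
HILL_PARAMS = {
    "CTCC": HillParams(d=-0.8941, k=6.634e-6),
    "OTCC": HillParams(d=-0.8026, k=8.775e-6),
}
HILL_GOF = {"CTCC": (0.966, 0.031), "OTCC": (0.954, 0.035)}

#: Observed hormetic minimum: EC_m (mol/L) and E_m (percent).
EC_M = {
    "CTCC": 5.75e-6, "OTCC": 1.24e-5, "M1": 6.00e-6, "M2": 6.00e-6,
    "M3": 5.50e-6, "M4": 4.75e-6, "M5": 1.55e-5, "M6": 1.15e-5, "M7": 2.70e-5,
}
E_M_PCT = {
    "CTCC": -36.9, "OTCC": -37.1, "M1": -40.6, "M2": -32.7, "M3": -35.8,
    "M4": -35.0, "M5": -36.8, "M6": -31.0, "M7": -39.6,
}

#: Segmented-CA predicted docking point for the mixtures:
#: EC_m,SCA (mol/L) and E_m,SCA (percent).
EC_M_SCA = {
    "M1": 4.94e-6, "M2": 5.28e-6, "M3": 5.68e-6, "M4": 6.02e-6,
    "M5": 6.40e-6, "M6": 6.97e-6, "M7": 7.72e-6,
}
E_M_SCA_PCT = {
    "M1": -37.5, "M2": -37.6, "M3": -37.8, "M4": -37.9,
    "M5": -38.0, "M6": -38.2, "M7": -38.5,
}

#: Cross point between observed and CA-predicted mixture curves:
#: EC_CP (mol/L) and E_CP (percent with branch tag).
EC_CP = {
    "M1": 3.01e-6, "M2": 1.97e-5, "M3": 1.18e-5, "M4": 1.82e-5,
    "M5": 1.32e-5, "M6": 3.40e-5, "M7": 2.05e-5,
}
E_CP_PCT = {
    "M1": "-30.1L", "M2": "-29.8R", "M3": "-35.3R", "M4": "-32.3R",
    "M5": "-35.5L", "M6": "-25.0R", "M7": "-33.8L",
}

#: The standard effect-level panel (percent notation with branch suffix).
LEVELS = ["80", "50", "20", "0", "-20R", "-30R", "-30L", "-20L", "-10L"]

#: Effect concentrations EC_x (mol/L) per subject, by level label.
EC_TABLE = {
    "CTCC": {"80": 7.93e-5, "50": 6.11e-5, "20": 4.81e-5, "0": 3.89e-5,
             "-20R": 2.70e-5, "-30R": 1.77e-5, "-30L": 2.88e-6,
             "-20L": 1.93e-6, "-10L": 1.14e-6},
    "OTCC": {"80": 5.20e-4, "50": 2.81e-4, "20": 1.58e-4, "0": 9.90e-5,
             "-20R": 5.09e-5, "-30R": 2.97e-5, "-30L": 5.28e-6,
             "-20L": 2.98e-6, "-10L": 1.64e-6},
    "M1": {"80": 8.83e-5, "50": 7.13e-5, "20": 5.35e-5, "0": 4.41e-5,
           "-20R": 3.16e-5, "-30R": 2.30e-5, "-30L": 2.95e-6,
           "-20L": 2.18e-6, "-10L": 1.49e-6},
    "M2": {"80": 9.73e-5, "50": 7.72e-5, "20": 6.29e-5, "0": 5.31e-5,
           "-20R": 3.72e-5, "-30R": 1.93e-5, "-30L": 3.52e-6,
           "-20L": 2.50e-6, "-10L": 1.87e-6},
    "M3": {"80": 1.10e-4, "50": 9.02e-5, "20": 7.52e-5, "0": 6.55e-5,
           "-20R": 5.04e-5, "-30R": 3.58e-5, "-30L": 3.42e-6,
           "-20L": 2.76e-6, "-10L": 2.27e-6},
    "M4": {"80": 1.52e-4, "50": 1.16e-4, "20": 9.07e-5, "0": 7.27e-5,
           "-20R": 4.81e-5, "-30R": 2.64e-5, "-30L": 3.38e-6,
           "-20L": 2.78e-6, "-10L": 2.43e-6},
    "M5": {"80": 2.24e-4, "50": 1.61e-4, "20": 1.19e-4, "0": 9.16e-5,
           "-20R": 5.88e-5, "-30R": 3.71e-5, "-30L": 9.44e-6,
           "-20L": 7.03e-6, "-10L": 5.24e-6},
    "M6": {"80": 4.99e-4, "50": 3.04e-4, "20": 1.84e-4, "0": 1.16e-4,
           "-20R": 5.06e-5, "-30R": 1.71e-5, "-30L": 8.28e-6,
           "-20L": 4.00e-6, "-10L": 2.41e-6},
    "M7": {"80": 5.80e-4, "50": 3.24e-4, "20": 1.93e-4, "0": 1.30e-4,
           "-20R": 7.93e-5, "-30R": 5.63e-5, "-30L": 1.24e-5,
           "-20L": 7.89e-6, "-10L": 4.98e-6},
}

#: Printed co-toxicity coefficients with 95% CI bounds and the published
#: interaction call, per mixture and level: (CTC, CTC_LL, CTC_UL, label).
#: ``None`` bounds were printed as NA.  Labels: ADD additive, ANT
#: antagonistic (no synergism was observed in the study).
CTC_TABLE = {
    "M1": {
        "80": (96, 81, 100, "ADD"), "50": (91, 84, 100, "ADD"),
        "20": (95, 90, 104, "ADD"), "0": (93, 85, 103, "ADD"),
        "-20R": (89, 73, 115, "ADD"), "-30R": (79, 61, 178, "ADD"),
        "-30L": (101, 61, 131, "ADD"), "-20L": (91, 68, 123, "ADD"),
        "-10L": (78, 55, 173, "ADD"),
    },
    "M2": {
        "80": (101, 72, 114, "ADD"), "50": (97, 85, 105, "ADD"),
        "20": (91, 78, 105, "ADD"), "0": (85, 72, 110, "ADD"),
        "-20R": (81, 62, None, "ADD"), "-30R": (101, 47, None, "ADD"),
        "-30L": (91, None, 155, "ADD"), "-20L": (84, None, 149, "ADD"),
        "-10L": (66, 41, None, "ANT"),
    },
    "M3": {
        "80": (107, 84, 113, "ADD"), "50": (97, 86, 106, "ADD"),
        "20": (87, 83, 91, "ANT"), "0": (78, 71, 91, "ANT"),
        "-20R": (65, 54, 108, "ADD"), "-30R": (59, 39, None, "ANT"),
        "-30L": (102, None, 135, "ADD"), "-20L": (81, 50, 113, "ADD"),
        "-10L": (57, 43, None, "ANT"),
    },
    "M4": {
        "80": (90, 75, 97, "ANT"), "50": (86, 78, 89, "ANT"),
        "20": (81, 75, 88, "ANT"), "0": (77, 71, 87, "ANT"),
        "-20R": (73, 60, 100, "ADD"), "-30R": (84, 53, None, "ADD"),
        "-30L": (110, None, 128, "ADD"), "-20L": (84, 74, 92, "ANT"),
        "-10L": (55, 48, 70, "ANT"),
    },
    "M5": {
        "80": (74, 60, 79, "ANT"), "50": (73, 64, 80, "ANT"),
        "20": (71, 64, 78, "ANT"), "0": (68, 59, 80, "ANT"),
        "-20R": (65, 52, 99, "ANT"), "-30R": (64, 42, None, "ANT"),
        "-30L": (42, None, 55, "ANT"), "-20L": (35, 26, 45, "ANT"),
        "-10L": (27, 20, 39, "ANT"),
    },
    "M6": {
        "80": (46, 33, 61, "ANT"), "50": (50, 38, 65, "ANT"),
        "20": (56, 42, 79, "ANT"), "0": (63, 42, 113, "ADD"),
        "-20R": (83, 41, None, "ADD"), "-30R": (150, 37, None, "ADD"),
        "-30L": (53, None, 147, "ADD"), "-20L": (66, None, 144, "ADD"),
        "-10L": (62, 26, 179, "ADD"),
    },
    "M7": {
        "80": (63, 39, 109, "ADD"), "50": (68, 36, 111, "ADD"),
        "20": (70, 41, 122, "ADD"), "0": (68, 39, 151, "ADD"),
        "-20R": (60, 30, None, "ANT"), "-30R": (50, 22, None, "ANT"),
        "-30L": (40, None, 141, "ADD"), "-20L": (36, None, 177, "ADD"),
        "-10L": (32, None, None, "ANT"),
    },
}
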