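"""Shared fixtures: reference parameter sets and synthetic plates."""

import pytest

import segca
from segca import reference as ref


@pytest.fixture(scope="session")
def ctcc_bp():
    return ref.BP_PARAMS["CTCC"]


@pytest.fixture(scope="session")
def otcc_bp():
    return ref.BP_PARAMS["OTCC"]


@pytest.fixture(scope="session")
def component_models():
    """CTCC + OTCC component model set (BP + Hill + minimum)."""
    return segca.ComponentModelSet.build(
        [(n, ref.BP_PARAMS[n], ref.HILL_PARAMS[n]) for n in ("CTCC", "OTCC")])


@pytest.fixture(scope="session")
def component_ec50():
    """Component EC50 values recomputed from the BPR inverses."""
    return [segca.bpr_inverse(ref.BP_PARAMS[n], 0.5) for n in ("CTCC", "OTCC")]


@pytest.fixture
def plate(ctcc_bp):
    """One noisy synthetic plate from the CTCC reference truth."""
    design = segca.PlateDesign(seed=42, noise_sd=0.02)
    return segca.generate_single(ctcc_bp, design, subject_id="CTCC_sim")
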