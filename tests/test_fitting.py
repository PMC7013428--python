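"""BP/Hill fitting, goodness of fit, confidence bands and EC_x CIs."""

import numpy as np
import pandas as pd
import pytest

import segca
from segca import reference as ref
from segca.fitting import (
    ControlVariabilityError,
    DoseResponseDataset,
    ecx_with_ci,
    effect_confidence_band,
    fit_biphasic,
    fit_hill_left,
    goodness_of_fit,
    read_datasets,
)
from segca.models import (
    DomainError,
    EffectLevel,
    InvalidInputError,
    bp_effect,
    bp_minimum,
    bpr_inverse,
)


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        r2, rmse = goodness_of_fit([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert (r2, rmse) == (1.0, 0.0)

    def test_hand_computed_constant_prediction(self):
        # SS_res = SS_tot = 0.5 about the observed mean, so R^2 = 0
        r2, rmse = goodness_of_fit([0.0, 1.0], [0.5, 0.5])
        assert r2 == pytest.approx(0.0)
        assert rmse == pytest.approx(0.5)

    def test_constant_observed_undefined_r2(self):
        r2, rmse = goodness_of_fit([0.3, 0.3, 0.3], [0.2, 0.3, 0.4])
        assert r2 is None
        assert np.isfinite(rmse)


class TestDatasetIngestion:
    def test_sorts_and_validates(self):
        ds = DoseResponseDataset("x", [3e-6, 1e-6, 2e-6], [0.3, 0.1, 0.2])
        assert list(ds.concentration) == [1e-6, 2e-6, 3e-6]
        with pytest.raises(InvalidInputError):
            DoseResponseDataset("x", [0.0, 1e-6], [0.1, 0.2])

    def test_rlu_roundtrip_with_controls(self):
        rows = [("s", 0.0, j, 1000.0, "rlu") for j in range(1, 5)]
        rows += [("s", 1e-6, 1, 500.0, "rlu"), ("s", 2e-6, 1, 1100.0, "rlu")]
        df = pd.DataFrame(rows, columns=["subject_id",
                                         "concentration_mol_per_L",
                                         "replicate", "response",
                                         "response_type"])
        ds = read_datasets(df)["s"]
        assert ds.effect == pytest.approx([0.5, -0.1])

    def test_control_cv_gate(self):
        rows = [("s", 0.0, 1, 500.0, "rlu"), ("s", 0.0, 2, 1500.0, "rlu"),
                ("s", 1e-6, 1, 900.0, "rlu")]
        df = pd.DataFrame(rows, columns=["subject_id",
                                         "concentration_mol_per_L",
                                         "replicate", "response",
                                         "response_type"])
        with pytest.raises(ControlVariabilityError):
            read_datasets(df)


class TestBiphasicFit:
    def test_noiseless_identifiability(self, ctcc_bp):
        ds = segca.generate_single(ctcc_bp,
                                   segca.PlateDesign(seed=0, noise_sd=0.0))
        res = fit_biphasic(ds)
        assert res.r_squared > 0.9999
        for attr in ("m", "a", "b", "p", "q"):
            assert getattr(res.params, attr) == pytest.approx(
                getattr(ctcc_bp, attr), rel=1e-4), attr

    def test_noisy_recovery_of_ec50(self, ctcc_bp, plate):
        res = fit_biphasic(plate)
        truth = bpr_inverse(ctcc_bp, 0.5)
        assert bpr_inverse(res.params, 0.5) == pytest.approx(truth, rel=0.05)
        assert res.r_squared > 0.91 and res.rmse < 0.12

    def test_deterministic(self, plate):
        p1 = fit_biphasic(plate).params
        p2 = fit_biphasic(plate).params
        assert p1 == p2

    def test_needs_five_concentrations(self, ctcc_bp):
        c = np.repeat([1e-6, 2e-6, 4e-6, 8e-6], 2)
        ds = DoseResponseDataset("x", c, bp_effect(ctcc_bp, c))
        with pytest.raises(InvalidInputError):
            fit_biphasic(ds)

    def test_ecx_monotone_in_level_on_right_branch(self, plate):
        res = fit_biphasic(plate)
        ecs = [bpr_inverse(res.params, x) for x in (0.0, 0.2, 0.5, 0.8)]
        assert np.all(np.diff(ecs) > 0)


class TestHillLeftFit:
    def test_recovers_segmented_truth(self, component_models):
        # a self-mixture plate's left segment is generated by the Hill
        # model itself, so the left fit must recover (d, k)
        ms = segca.ComponentModelSet.build(
            [("CTCC", ref.BP_PARAMS["CTCC"], ref.HILL_PARAMS["CTCC"])] * 2)
        ray = segca.MixtureRay(("CTCC", "CTCC"), (1, 1))
        ds = segca.generate_additive_mixture(
            ms, ray, segca.PlateDesign(seed=7, noise_sd=0.0,
                                       top_concentration=1.28e-3))
        res = fit_hill_left(ds)
        assert res.params.d == pytest.approx(ref.HILL_PARAMS["CTCC"].d,
                                             rel=0.10)
        assert res.params.k == pytest.approx(ref.HILL_PARAMS["CTCC"].k,
                                             rel=0.15)

    def test_flat_left_segment_gives_near_zero_top(self):
        # no stimulatory dip: the left-segment fit must not invent one,
        # and the downstream segmented prediction refuses such a ray
        uc = np.geomspace(1e-7, 1e-4, 8)
        ue = np.where(uc > 3e-5, 0.8,
                      -1e-8 * np.arange(1, 9))  # sub-noise "dip"
        ds = DoseResponseDataset("flat", np.repeat(uc, 2), np.repeat(ue, 2))
        res = fit_hill_left(ds)
        assert abs(res.params.d) < 1e-3
        ms = segca.ComponentModelSet.build(
            [("flat", ref.BP_PARAMS["CTCC"], res.params)] * 2)
        with pytest.raises(DomainError):
            segca.sca_predict(ms, [0.5, 0.5])

    def test_needs_three_left_concentrations(self, ctcc_bp):
        c = np.array([4e-6, 8e-6, 1.6e-5, 3.2e-5, 6.4e-5])
        ds = DoseResponseDataset("x", c, bp_effect(ctcc_bp, c))
        with pytest.raises(InvalidInputError):
            fit_hill_left(ds)


class TestConfidenceBand:
    def test_t_distribution_width_two_replicates(self):
        ds = DoseResponseDataset("x", [1e-6, 1e-6], [0.4, 0.6])
        band = effect_confidence_band(ds)
        row = band.iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["hi"] - row["mean"] == pytest.approx(12.706 * 0.1,
                                                        rel=1e-3)

    def test_identical_replicates_zero_width(self):
        ds = DoseResponseDataset("x", [1e-6] * 3, [0.5] * 3)
        band = effect_confidence_band(ds)
        assert band.iloc[0]["lo"] == band.iloc[0]["hi"] == 0.5

    def test_single_replicate_band_absent(self):
        ds = DoseResponseDataset("x", [1e-6, 2e-6, 2e-6],
                                 [0.1, 0.2, 0.3])
        band = effect_confidence_band(ds)
        assert np.isnan(band.iloc[0]["lo"])
        assert np.isfinite(band.iloc[1]["lo"])

    def test_average_halfwidth_matches_theory(self, ctcc_bp):
        # 4 replicates at sigma 0.02: E[halfwidth] = t(0.975,3) c4 sigma/2
        # with c4 = E[s]/sigma = 0.9213 for n = 4; concentrations whose
        # true effect sits against the ceiling clip are excluded
        widths = []
        for seed in range(20):
            ds = segca.generate_single(ctcc_bp, segca.PlateDesign(seed=seed))
            band = effect_confidence_band(ds)
            keep = bp_effect(ctcc_bp,
                             band["concentration"].to_numpy()) < 0.9
            widths.append(np.mean((band["hi"] - band["mean"])[keep]))
        assert np.mean(widths) == pytest.approx(3.182 * 0.9213 * 0.01,
                                                rel=0.08)


class TestECxWithCI:
    def test_point_estimates_against_reference(self):
        res = segca.FitResult(params=ref.BP_PARAMS["CTCC"], r_squared=1.0,
                              rmse=0.0, n_obs=64, converged=True)
        est = ecx_with_ci(res, None, EffectLevel.parse("80"))
        assert est.value == pytest.approx(7.93e-5, rel=0.01)
        est = ecx_with_ci(res, None, EffectLevel.parse("-20L"))
        assert est.value == pytest.approx(1.93e-6, rel=0.01)

    def test_ci_brackets_point_estimate(self, ctcc_bp, plate):
        res = fit_biphasic(plate)
        band = effect_confidence_band(plate)
        for label in ("80", "50", "0", "-20R", "-20L"):
            est = ecx_with_ci(res, band, EffectLevel.parse(label))
            if est.ci_lower is not None and est.ci_upper is not None:
                assert est.ci_lower <= est.value <= est.ci_upper

    def test_unattained_level_gives_absent_bound(self, ctcc_bp):
        # truncate the plate so the band never reaches 80 % inhibition
        design = segca.PlateDesign(seed=3, top_concentration=6.5e-5,
                                   n_concentrations=12)
        ds = segca.generate_single(ctcc_bp, design)
        res = segca.FitResult(params=ctcc_bp, r_squared=1.0, rmse=0.0,
                              n_obs=ds.n_obs, converged=True)
        band = effect_confidence_band(ds)
        est = ecx_with_ci(res, band, EffectLevel.parse("80"))
        assert est.ci_upper is None  # lower envelope never attains 0.8

    def test_unreachable_point_level_is_error(self, ctcc_bp):
        res = segca.FitResult(params=ctcc_bp, r_squared=1.0, rmse=0.0,
                              n_obs=10, converged=True)
        mn = bp_minimum(ctcc_bp)
        with pytest.raises(DomainError):
            ecx_with_ci(res, None, EffectLevel(x=mn.e_m - 0.05,
                                               side=segca.Side.LEFT), mn)


def test_parameter_recovery_median_error():
    """Median EC50 error over seeded synthetic plates stays below 5 %."""
    truth = ref.BP_PARAMS["CTCC"]
    ec50_truth = bpr_inverse(truth, 0.5)
    errs = []
    for seed in range(12):
        ds = segca.generate_single(truth, segca.PlateDesign(seed=seed))
        res = fit_biphasic(ds)
        errs.append(abs(bpr_inverse(res.params, 0.5) / ec50_truth - 1.0))
    assert np.median(errs) < 0.05
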