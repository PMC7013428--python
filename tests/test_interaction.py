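"""Co-toxicity coefficients, CTCICI classification, isoboles, cross
points and toxicity-composition profiles."""

import numpy as np
import pytest

import segca
from segca import reference as ref
from segca.fitting import ECxEstimate
from segca.interaction import (
    Classification,
    Rule,
    cross_point,
    ctc,
    ctc_ci,
    ctcici_classify,
    isobole,
    round_ctc,
    toxicity_profile,
)
from segca.mixtures import MixtureRay, ca_curve_bp, ca_ecx, equray_proportions
from segca.models import EffectLevel, InvalidInputError, Side, bp_effect


class TestCTC:
    def test_m1_ec50(self):
        val = ctc(7.13e-5, equray_proportions((12, 1)), [6.11e-5, 2.81e-4])
        assert round_ctc(val) == 91

    def test_m5_ec50(self):
        val = ctc(1.61e-4, equray_proportions((5, 8)), [6.11e-5, 2.81e-4])
        assert round_ctc(val) == 73

    def test_additive_mixture_is_100(self):
        p = equray_proportions((3, 4))
        ec = [2e-5, 9e-5]
        assert ctc(ca_ecx(p, ec), p, ec) == pytest.approx(100.0, rel=1e-12)

    def test_ctc_of_ca_prediction_is_definitionally_100(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            ec = 10 ** rng.uniform(-6, -3, 2)
            r = rng.uniform(0.05, 0.95)
            p = np.array([r, 1 - r])
            assert ctc(ca_ecx(p, ec), p, ec) == pytest.approx(100.0,
                                                              rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            ctc(-1e-5, [0.5, 0.5], [1e-5, 1e-5])


class TestCTCCI:
    def test_monotone_map_swaps_bounds(self):
        est = ECxEstimate(EffectLevel.parse("50"), 1e-4,
                          ci_lower=8e-5, ci_upper=1.3e-4)
        p = equray_proportions((1, 1))
        comp = [6e-5, 3e-4]
        ll, ul = ctc_ci(est, p, comp)
        assert ll < ctc(est.value, p, comp) < ul
        assert ul == pytest.approx(ctc(8e-5, p, comp))

    def test_absent_ec_bound_propagates(self):
        est = ECxEstimate(EffectLevel.parse("50"), 1e-4, ci_lower=8e-5,
                          ci_upper=None)
        ll, ul = ctc_ci(est, [0.5, 0.5], [6e-5, 3e-4])
        assert ll is None and ul is not None

    def test_zero_width_ci_collapses(self):
        est = ECxEstimate(EffectLevel.parse("50"), 1e-4, ci_lower=1e-4,
                          ci_upper=1e-4)
        p, comp = equray_proportions((1, 1)), [6e-5, 3e-4]
        ll, ul = ctc_ci(est, p, comp)
        assert ll == ul == pytest.approx(ctc(1e-4, p, comp))


class TestCTCICIRules:
    @pytest.mark.parametrize("triple, expected, rule", [
        ((91, 84, 100), Classification.ADDITIVE, Rule.CI_BOTH),
        ((74, 60, 79), Classification.ANTAGONISTIC, Rule.CI_BOTH),
        ((130, 121, 150), Classification.SYNERGISTIC, Rule.CI_BOTH),
        # one-sided interval [62, 81] excludes 100 -> fallback: additive
        ((81, 62, None), Classification.ADDITIVE, Rule.CTC_FALLBACK),
        # one-sided interval [47, 101] contains 100
        ((101, 47, None), Classification.ADDITIVE, Rule.CI_ONE_SIDED),
        ((32, None, None), Classification.ANTAGONISTIC, Rule.CTC_FALLBACK),
        ((125, None, None), Classification.SYNERGISTIC, Rule.CTC_FALLBACK),
        # inclusive boundaries: 100 on a bound, and CTC exactly 80/120
        ((73, 60, 100), Classification.ADDITIVE, Rule.CI_BOTH),
        ((80, None, None), Classification.ADDITIVE, Rule.CTC_FALLBACK),
        ((120, None, None), Classification.ADDITIVE, Rule.CTC_FALLBACK),
    ])
    def test_rule_cascade(self, triple, expected, rule):
        call = ctcici_classify(*triple)
        assert call.classification is expected
        assert call.rule_used is rule

    def test_reproduces_all_printed_judgments(self):
        mismatches = []
        for mix, cells in ref.CTC_TABLE.items():
            for lvl, (c, ll, ul, label) in cells.items():
                got = ctcici_classify(c, ll, ul).classification.value
                if got != label:
                    mismatches.append((mix, lvl, got, label))
        assert mismatches == []

    def test_missing_ctc_rejected(self):
        with pytest.raises(InvalidInputError):
            ctcici_classify(float("nan"))


class TestIsobole:
    def _ray(self, ratio):
        return MixtureRay(("CTCC", "OTCC"), ratio)

    def test_near_additive_point_lies_on_ca_line(self):
        # M1 at -30L printed CTC 101: the observed point sits on the line
        level = EffectLevel.parse("-30L")
        comp = [ref.EC_TABLE["CTCC"]["-30L"], ref.EC_TABLE["OTCC"]["-30L"]]
        est = ECxEstimate(level, ref.EC_TABLE["M1"]["-30L"])
        out = isobole(level, [(self._ray((12, 1)), est)], comp)
        pt = out["points"][0].partial_concentrations
        # on the CA line, x/ec1 + y/ec2 = 1 (printed 3-digit EC values
        # leave ~1 % rounding slack)
        assert pt[0] / comp[0] + pt[1] / comp[1] == pytest.approx(1.0,
                                                                 abs=0.02)

    def test_antagonistic_ray_beyond_line(self):
        level = EffectLevel.parse("50")
        comp = [6e-5, 3e-4]
        p = equray_proportions((1, 1))
        ca = ca_ecx(p, comp)
        est = ECxEstimate(level, 2 * ca, ci_lower=1.9 * ca, ci_upper=2.1 * ca)
        out = isobole(level, [(self._ray((1, 1)), est)], comp)
        call = out["calls"][0]
        assert call.classification is Classification.ANTAGONISTIC
        assert call.ctc == pytest.approx(50.0, rel=1e-9)

    def test_matches_ctcici_for_two_sided_cis(self, component_ec50):
        # the geometric judgment and the CTC-with-CI judgment agree
        rng = np.random.default_rng(21)
        level = EffectLevel.parse("50")
        for _ in range(40):
            ratio = tuple(rng.integers(1, 13, 2))
            p = equray_proportions(ratio)
            ca = ca_ecx(p, component_ec50)
            obs = ca * 10 ** rng.uniform(-0.4, 0.4)
            est = ECxEstimate(level, obs, ci_lower=obs * 0.85,
                              ci_upper=obs * 1.2)
            out = isobole(level, [(self._ray(ratio), est)], component_ec50)
            geo = out["calls"][0].classification
            val = ctc(obs, p, component_ec50)
            ll, ul = ctc_ci(est, p, component_ec50)
            assert geo is ctcici_classify(val, ll, ul).classification

    def test_single_component_ray_sits_on_axis(self):
        level = EffectLevel.parse("50")
        comp = [6e-5, 3e-4]
        est = ECxEstimate(level, 6e-5)
        ray = MixtureRay(("CTCC", "OTCC"), (1, 1e-9))
        out = isobole(level, [(ray, est)], comp)
        pt = out["points"][0].partial_concentrations
        assert pt[0] == pytest.approx(6e-5, rel=1e-6)
        assert pt[1] == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def m5_ca_curve():
    levels = [EffectLevel.parse(f"{x}") for x in range(0, 96, 5)]
    levels += [EffectLevel(x=-x / 100, side=Side.RIGHT)
               for x in range(2, 37, 2)]
    levels += [EffectLevel(x=-x / 100, side=Side.LEFT)
               for x in range(2, 37, 2)]
    p = equray_proportions(ref.MOLAR_RATIOS["M5"])
    return ca_curve_bp([ref.BP_PARAMS["CTCC"], ref.BP_PARAMS["OTCC"]],
                       p, levels)


class TestCrossPoint:
    def test_m5_cross_point_location(self, m5_ca_curve):
        cps = cross_point(ref.BP_PARAMS["M5"], m5_ca_curve)
        near = [cp for cp in cps
                if cp.ec_cp == pytest.approx(1.32e-5, rel=0.05)]
        assert near, [c.ec_cp for c in cps]
        cp = near[0]
        assert cp.e_cp * 100 == pytest.approx(-35.5, abs=1.0)
        assert cp.side is Side.LEFT

    def test_m5_positions_exchange_across_cp(self, m5_ca_curve):
        # observed minus predicted changes sign across the cross point
        cps = cross_point(ref.BP_PARAMS["M5"], m5_ca_curve)
        cp = cps[0]
        pts = m5_ca_curve.points()
        logc, eff = np.log10(pts[:, 0]), pts[:, 1]
        pred = lambda c: np.interp(np.log10(c), logc, eff)
        d_lo = bp_effect(ref.BP_PARAMS["M5"], cp.ec_cp * 0.8) - pred(
            cp.ec_cp * 0.8)
        d_hi = bp_effect(ref.BP_PARAMS["M5"], cp.ec_cp * 1.2) - pred(
            cp.ec_cp * 1.2)
        assert np.sign(d_lo) != np.sign(d_hi)

    def test_identical_curves_no_crossing(self, ctcc_bp):
        levels = [EffectLevel(x=x / 100, side=Side.RIGHT)
                  for x in range(1, 99)]
        curve = ca_curve_bp([ctcc_bp, ctcc_bp], [0.5, 0.5], levels)
        assert cross_point(ctcc_bp, curve) == []

    def test_uniform_offset_no_crossing(self, ctcc_bp):
        levels = [EffectLevel.parse(f"{x}") for x in range(5, 96, 5)]
        shifted = segca.BiphasicParams(m=ctcc_bp.m, a=ctcc_bp.a * 3,
                                       b=ctcc_bp.b / 3, p=ctcc_bp.p * 3,
                                       q=ctcc_bp.q / 3)
        curve = ca_curve_bp([shifted, shifted], [0.5, 0.5], levels)
        cps = cross_point(ctcc_bp, curve)
        assert cps == []


class TestToxicityProfile:
    def test_pec_arithmetic(self):
        df = toxicity_profile([EffectLevel.parse("50")],
                              [("CTCC", 1.0, {"50": 6.11e-5})])
        assert df["pec_x"].iloc[0] == pytest.approx(4.214, abs=1e-3)

    def test_boundaries_and_monotonicity_at_ec50(self):
        subjects = [("CTCC", 1.0, ref.EC_TABLE["CTCC"])]
        for mix in ref.MIXTURES:
            p = equray_proportions(ref.MOLAR_RATIOS[mix])[0]
            subjects.append((mix, p, ref.EC_TABLE[mix]))
        subjects.append(("OTCC", 0.0, ref.EC_TABLE["OTCC"]))
        df = toxicity_profile([EffectLevel.parse("50")], subjects)
        df = df.sort_values("p")
        # boundary rows are the single components
        assert df.iloc[0]["subject"] == "OTCC"
        assert df.iloc[-1]["subject"] == "CTCC"
        # across the mixture rays, toxicity rises with the CTCC share
        mixes = df[df["subject"].isin(ref.MIXTURES)]
        assert np.all(np.diff(mixes["pec_x"].to_numpy()) > 0)
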