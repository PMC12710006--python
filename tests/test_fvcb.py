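"""FvCB forward model, temperature scaling and A-Ci fitting."""

from dataclasses import replace

import numpy as np
import pytest

from canopyphot import fvcb, synth

CONST = fvcb.FvCBParameters()


class TestArrhenius:
    def test_reference_temperature_identity(self):
        assert fvcb.arrhenius_scale(404.9, 79430.0, 25.0) == pytest.approx(404.9)

    def test_zero_activation_energy(self):
        for t in (-5.0, 10.0, 40.0):
            assert fvcb.arrhenius_scale(100.0, 0.0, t) == pytest.approx(100.0)

    def test_kc_at_35C_matches_direct_evaluation(self):
        # independent one-line evaluation of the Arrhenius expression
        t_k = 35.0 + 273.15
        expected = 404.9 * np.exp(79430.0 * (t_k - 298.15) / (298.15 * 8.314 * t_k))
        assert fvcb.arrhenius_scale(404.9, 79430.0, 35.0) == pytest.approx(expected, rel=1e-12)

    def test_scale_then_normalize_is_identity(self):
        for t in (5.0, 18.0, 33.0):
            k_t = fvcb.arrhenius_scale(60.0, 65330.0, t)
            assert fvcb.arrhenius_to_25(k_t, 65330.0, t) == pytest.approx(60.0, rel=1e-14)

    def test_absolute_zero_rejected(self):
        with pytest.raises(ValueError):
            fvcb.arrhenius_scale(1.0, 1000.0, -274.0)
        with pytest.raises(ValueError):
            fvcb.arrhenius_scale(-1.0, 1000.0, 25.0)


class TestForwardModel:
    def test_compensation_point_gives_minus_rd(self):
        p = replace(CONST, vcmax25=60.0, jmax25=120.0, rd25=1.0)
        a = fvcb.forward_assimilation(p, p.gammastar25, q=1500.0, tleaf=25.0)
        assert a == pytest.approx(-1.0, abs=1e-10)

    def test_saturating_ci_approaches_j_over_4_minus_rd(self):
        p = replace(CONST, vcmax25=200.0, jmax25=100.0, rd25=1.0)
        j = fvcb.electron_transport_rate(100.0, 1500.0, p.theta, p.alpha)
        a = fvcb.forward_assimilation(p, 1e7, q=1500.0, tleaf=25.0)
        assert a == pytest.approx(j / 4.0 - 1.0, rel=1e-4)

    def test_hand_evaluated_minimum_of_ac_and_aj(self):
        # independent evaluation of both limitation expressions at 25 °C
        vc, jm, rd, ci, q = 60.0, 120.0, 1.0, 300.0, 1500.0
        gstar, kc, ko, o = 42.75, 404.9, 278.4, 210.0
        ac = vc * (ci - gstar) / (ci + kc * (1 + o / ko))
        aq = 0.24 * q
        j = (aq + jm - np.sqrt((aq + jm) ** 2 - 4 * 0.85 * aq * jm)) / (2 * 0.85)
        aj = j * (ci - gstar) / (4 * ci + 8 * gstar)
        expected = min(ac, aj) - rd
        p = replace(CONST, vcmax25=vc, jmax25=jm, rd25=rd)
        assert fvcb.forward_assimilation(p, ci, q=q, tleaf=25.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_monotone_nondecreasing_in_ci(self):
        p = replace(CONST, vcmax25=80.0, jmax25=150.0, rd25=1.0)
        ci = np.linspace(CONST.gammastar25, 2000.0, 500)
        a = fvcb.forward_assimilation(p, ci)
        assert np.all(np.diff(a) >= -1e-10)

    def test_continuous_across_limitation_transition(self):
        p = replace(CONST, vcmax25=80.0, jmax25=150.0, rd25=1.0)
        ci = np.linspace(50.0, 1500.0, 20001)
        a = fvcb.forward_assimilation(p, ci)
        # largest jump between adjacent fine-grid points stays O(grid step)
        assert np.max(np.abs(np.diff(a))) < 0.05

    def test_negative_ci_rejected(self):
        with pytest.raises(ValueError):
            fvcb.forward_assimilation(CONST, -5.0)


class TestFitACi:
    def test_noise_free_round_trip(self):
        gen = replace(CONST, vcmax25=80.0, jmax25=160.0, rd25=1.2)
        curve = synth.simulate_aci(gen, noise_sd=0.0)
        fit = fvcb.fit_aci(curve, constants=CONST)
        assert fit.converged
        assert fit.params.vcmax25 == pytest.approx(80.0, rel=1e-3)
        assert fit.params.jmax25 == pytest.approx(160.0, rel=1e-3)
        assert fit.params.rd25 == pytest.approx(1.2, rel=1e-3)
        assert fit.rmse_fit < 1e-6

    def test_temperature_round_trip_recovers_25C_values(self):
        gen = replace(CONST, vcmax25=70.0, jmax25=140.0, rd25=1.0)
        protocol = synth.RampProtocol(tleaf=30.0)
        curve = synth.simulate_aci(gen, protocol=protocol, noise_sd=0.0)
        fit = fvcb.fit_aci(curve, constants=CONST)
        assert fit.params.vcmax25 == pytest.approx(70.0, rel=1e-3)
        assert fit.params.jmax25 == pytest.approx(140.0, rel=1e-3)

    def test_limitation_labels_cover_curve_and_switch(self):
        gen = replace(CONST, vcmax25=60.0, jmax25=114.0, rd25=1.0)
        curve = synth.simulate_aci(gen, noise_sd=0.0)
        fit = fvcb.fit_aci(curve, constants=CONST)
        assert fit.limitation.shape == curve.ci.shape
        assert set(np.unique(fit.limitation)) == {"rubisco", "rubp"}
        # Rubisco limits at low Ci, RuBP regeneration at high Ci
        assert fit.limitation[0] == "rubisco"
        assert fit.limitation[-1] == "rubp"

    def test_identical_ci_rejected(self):
        curve = fvcb.ACiCurve(ci=np.full(10, 400.0), a=np.linspace(1, 5, 10))
        with pytest.raises(ValueError):
            fvcb.fit_aci(curve)

    def test_nan_inputs_rejected(self):
        a = np.linspace(0, 20, 10)
        a[3] = np.nan
        with pytest.raises(ValueError):
            fvcb.ACiCurve(ci=np.linspace(50, 1500, 10), a=a)

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            fvcb.ACiCurve(ci=np.linspace(50, 1500, 5), a=np.zeros(5))


class TestTraitSummary:
    def _fit(self, vc, jm, plant, converged=True):
        p = replace(CONST, vcmax25=vc, jmax25=jm, rd25=1.0)
        return fvcb.FitResult(
            params=p, rmse_fit=0.1, limitation=np.array(["rubisco"]), converged=converged,
            plant_id=plant,
        )

    def test_single_leaf_passthrough(self):
        out = fvcb.trait_summary([self._fit(60.0, 120.0, "A")])
        assert out.loc[0, "vcmax25"] == pytest.approx(60.0)
        assert out.loc[0, "n_leaves"] == 1

    def test_two_leaves_arithmetic_mean(self):
        out = fvcb.trait_summary([self._fit(60.0, 120.0, "A"), self._fit(80.0, 150.0, "A")])
        assert out.loc[0, "vcmax25"] == pytest.approx(70.0)
        assert out.loc[0, "jmax25"] == pytest.approx(135.0)

    def test_unconverged_fits_excluded_and_flagged(self):
        fits = [
            self._fit(60.0, 120.0, "A"),
            self._fit(999.0, 1000.0, "A", converged=False),
            self._fit(50.0, 100.0, "B", converged=False),
        ]
        out = fvcb.trait_summary(fits).set_index("plant_id")
        assert out.loc["A", "vcmax25"] == pytest.approx(60.0)
        assert not out.loc["A", "all_converged"]
        assert np.isnan(out.loc["B", "vcmax25"])
        assert out.loc["B", "n_converged"] == 0

    def test_grouping_maps_leaves_to_plants(self):
        fits = [self._fit(60.0, 120.0, "leaf1"), self._fit(70.0, 140.0, "leaf2")]
        out = fvcb.trait_summary(fits, grouping={"leaf1": "P", "leaf2": "P"})
        assert len(out) == 1
        assert out.loc[0, "vcmax25"] == pytest.approx(65.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fvcb.trait_summary([])


def test_curves_csv_round_trip(tmp_path):
    gen = replace(CONST, vcmax25=55.0, jmax25=110.0, rd25=0.8)
    curves = [
        synth.simulate_aci(gen, noise_sd=0.5, seed=s, plant_id=f"p{s}") for s in (1, 2)
    ]
    path = tmp_path / "curves.csv"
    fvcb.write_curves_csv(curves, path)
    back = fvcb.read_curves_csv(path)
    assert len(back) == 2
    np.testing.assert_allclose(back[0].ci, curves[0].ci)
    np.testing.assert_allclose(back[0].a, curves[0].a)
    assert back[0].q == curves[0].q
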