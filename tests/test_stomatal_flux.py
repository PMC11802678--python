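"""Multiplicative conductance model, flux partition and POD accumulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxstab.errors import ValidationError
from oxstab.stomatal_flux import (SpeciesFluxParams, accumulate_pod,
                                  boundary_layer_resistance,
                                  conductance_mmol_to_ms, f_light, f_phen,
                                  f_temp, f_vpd, pod_from_series,
                                  ppb_to_nmol_m3, project_cl_oxs,
                                  read_params_file, species_preset,
                                  stomatal_conductance, stomatal_flux,
                                  tolerance_utilisation)

P = SpeciesFluxParams()


class TestResponseFunctions:
    def test_temperature_optimum_and_bounds(self):
        assert f_temp(P.t_opt, P) == pytest.approx(1.0)
        assert f_temp(P.t_min, P) == 0.0
        assert f_temp(P.t_max, P) == 0.0
        assert f_temp(P.t_min - 5, P) == 0.0 and f_temp(P.t_max + 5, P) == 0.0

    def test_temperature_hand_evaluation(self):
        p = SpeciesFluxParams(t_min=0, t_opt=20, t_max=35)
        expected = 0.5 * (25 / 15) ** 0.75
        assert f_temp(10.0, p) == pytest.approx(expected, rel=1e-9)

    def test_light_saturation(self):
        assert f_light(0.0, P) == 0.0
        assert f_light(1e7, P) == pytest.approx(1.0)
        p = SpeciesFluxParams(light_a=0.006)
        assert f_light(500.0, p) == pytest.approx(1 - np.exp(-3), rel=1e-9)
        with pytest.raises(ValidationError):
            f_light(-1.0, P)

    def test_vpd_piecewise_linear(self):
        assert f_vpd(P.vpd_min, P) == pytest.approx(1.0)
        assert f_vpd(P.vpd_max, P) == pytest.approx(P.fmin)
        mid = 0.5 * (P.vpd_min + P.vpd_max)
        assert f_vpd(mid, P) == pytest.approx((1 + P.fmin) / 2)
        assert f_vpd(0.0, P) == 1.0 and f_vpd(10.0, P) == P.fmin

    def test_phenology_trapezoid(self, alpine_gs):
        p = SpeciesFluxParams(phen_ramp_days=10)
        assert f_phen("2023-07-15", alpine_gs, p) == 1.0
        assert f_phen("2023-05-31", alpine_gs, p) == 0.0
        assert f_phen("2023-10-01", alpine_gs, p) == 0.0
        assert f_phen("2023-06-06", alpine_gs, p) == pytest.approx(0.5)

    @given(st.floats(-20, 50), st.floats(0, 3000), st.floats(0, 6))
    def test_all_factors_bounded(self, t, ppfd, vpd):
        assert 0.0 <= f_temp(t, P) <= 1.0
        assert 0.0 <= f_light(ppfd, P) < 1.0
        assert P.fmin <= f_vpd(vpd, P) <= 1.0


class TestConductance:
    def test_all_factors_one_gives_gmax(self, alpine_gs):
        g = stomatal_conductance(P.t_opt, 1e7, 0.0, "2023-07-15", alpine_gs, P)
        assert g == pytest.approx(P.gmax, rel=1e-6)

    def test_darkness_closes_stomata(self, alpine_gs):
        assert stomatal_conductance(P.t_opt, 0.0, 0.0, "2023-07-15",
                                    alpine_gs, P) == 0.0

    def test_fmin_floor_rule(self, alpine_gs):
        # extreme VPD and cold push f_temp*f_vpd below fmin; the floor holds
        g = stomatal_conductance(1.0, 1e7, 10.0, "2023-07-15", alpine_gs, P)
        assert g == pytest.approx(P.gmax * P.fmin, rel=1e-6)

    @given(st.floats(-10, 45), st.floats(0, 3000), st.floats(0, 6))
    def test_bounded_by_gmax(self, alpine_gs, t, ppfd, vpd):
        g = stomatal_conductance(t, ppfd, vpd, "2023-07-15", alpine_gs, P)
        assert 0.0 <= g <= P.gmax


class TestFluxChain:
    def test_gas_state_conversion(self):
        # 1 ppb at 20 degC, standard pressure: P/(RT) = 41.6 mol m-3
        assert ppb_to_nmol_m3(1.0, 20.0) == pytest.approx(41.57, abs=0.05)
        assert ppb_to_nmol_m3(0.0, 20.0) == 0.0

    def test_closed_stomata_no_external_path_gives_zero(self, alpine_gs):
        p = SpeciesFluxParams(gext=0.0)
        fst = stomatal_flux(50.0, P.t_opt, 0.0, 0.0, "2023-07-15",
                            alpine_gs, p)
        assert fst == 0.0

    def test_no_boundary_layer_limit_reduces_to_c_times_gsto(self, alpine_gs):
        p = SpeciesFluxParams(gext=0.0, leaf_dimension=1e-12, wind_speed=50.0)
        fst = stomatal_flux(50.0, P.t_opt, 1e7, 0.0, "2023-07-15",
                            alpine_gs, p)
        gsto_ms = conductance_mmol_to_ms(p.gmax, P.t_opt)
        assert fst == pytest.approx(ppb_to_nmol_m3(50.0, P.t_opt) * gsto_ms,
                                    rel=1e-3)

    def test_resistance_chain_hand_oracle(self, alpine_gs):
        """One fixed record evaluated as a single independent expression."""
        p = SpeciesFluxParams()
        t, ppfd, vpd, o3 = 14.0, 500.0, 0.5, 60.0
        fst = stomatal_flux(o3, t, ppfd, vpd, "2023-07-15", alpine_gs, p)
        molar = 101325.0 / (8.31446 * 287.15)
        gsto_mmol = p.gmax * (1 - np.exp(-0.006 * 500.0))  # ft=fv=1 at optimum
        gsto_ms = gsto_mmol * 1e-3 / molar
        rb = 1.3 * 150.0 * np.sqrt(0.008 / 2.0)
        rc = 1.0 / (gsto_ms + 1 / 2500.0)
        oracle = (o3 * molar * 1e-9 * 1e9) * gsto_ms * rc / (rb + rc)
        assert fst == pytest.approx(oracle, rel=1e-9)

    def test_nonpositive_wind_rejected(self):
        with pytest.raises(ValidationError):
            boundary_layer_resistance(P, wind_speed=0.0)


class TestPodAccumulation:
    def test_unit_arithmetic(self):
        fst = np.ones(1000)
        rad = np.full(1000, 100.0)
        assert accumulate_pod(fst, rad, y=0.0) == pytest.approx(3.6)
        assert accumulate_pod(fst, rad, y=2.0) == 0.0

    def test_night_hours_excluded(self):
        fst = np.ones(100)
        rad = np.zeros(100)
        assert accumulate_pod(fst, rad, y=0.0) == 0.0

    def test_monotone_in_threshold(self, alpine_env, alpine_gs):
        p = species_preset("Pinus mugo")
        pods = [pod_from_series(alpine_env, alpine_gs, p, y=y)["pod"]
                for y in (0.0, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(pods, pods[1:]))
        assert pods[0] > 0

    def test_pod_nondecreasing_in_time(self, alpine_env, alpine_gs):
        p = species_preset("Pinus mugo")
        res = pod_from_series(alpine_env, alpine_gs, p)
        assert np.all(np.asarray(res["fst"]) >= 0.0)


class TestCriticalLevelProjection:
    def test_flat_profile_linearity(self, alpine_env, alpine_gs):
        p = species_preset("Pinus mugo")
        lo = project_cl_oxs(52.7, alpine_env, alpine_gs, p)
        hi = project_cl_oxs(158.5, alpine_env, alpine_gs, p)
        dbl = project_cl_oxs(105.4, alpine_env, alpine_gs, p)
        assert hi / lo == pytest.approx(158.5 / 52.7, rel=1e-9)
        assert dbl == pytest.approx(2 * lo, rel=1e-9)
        assert project_cl_oxs(0.0, alpine_env, alpine_gs, p) == 0.0

    def test_diurnal_peak_beats_flat_profile_at_equal_mean(
            self, foothill_env, foothill_gs):
        """Daytime-peaking O₃ coincides with open stomata, so the ambient
        profile accumulates at least the flat same-mean POD0."""
        p = species_preset("Pinus mugo")
        ambient = pod_from_series(foothill_env, foothill_gs, p)["pod"]
        mean_o3 = float(foothill_env.loc[
            foothill_gs.mask(foothill_env["timestamp"]), "o3_ppb"].mean())
        flat = project_cl_oxs(mean_o3, foothill_env, foothill_gs, p)
        assert ambient >= flat

    @pytest.mark.parametrize("amb,cl,expected", [
        (8.2, 32.2, 25.5), (15.0, 83.2, 18.0), (10.0, 10.0, 100.0)])
    def test_tolerance_utilisation(self, amb, cl, expected):
        assert round(tolerance_utilisation(amb, cl), 1) == expected
        with pytest.raises(ValidationError):
            tolerance_utilisation(1.0, 0.0)


class TestParameters:
    def test_preset_aliases_follow_related_species(self):
        assert species_preset("Pinus sylvestris").gmax == \
            species_preset("Pinus cembra").gmax
        assert species_preset("Abies alba").gmax == \
            species_preset("Picea abies").gmax
        assert species_preset("Abies alba").name == "Abies alba"

    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            SpeciesFluxParams(t_min=20, t_opt=10, t_max=35)
        with pytest.raises(ValidationError):
            SpeciesFluxParams(fmin=0.0)
        with pytest.raises(ValidationError):
            SpeciesFluxParams(vpd_min=3.0, vpd_max=1.0)

    def test_params_file_round_trip(self, tmp_path):
        path = tmp_path / "species.params"
        path.write_text("# dwarf pine\nname = Pinus mugo\ngmax = 104\n"
                        "t_opt = 16\nfmin = 0.1\n")
        p = read_params_file(path)
        assert (p.name, p.gmax, p.t_opt) == ("Pinus mugo", 104.0, 16.0)
        bad = tmp_path / "bad.params"
        bad.write_text("gmax 104\n")
        with pytest.raises(ValidationError, match="key = value"):
            read_params_file(bad)
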