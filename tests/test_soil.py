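"""Soil mass, stock, base-saturation and classification accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punastocks import (DomainError, base_saturation, classify_profile,
                        fine_earth_bulk_density, layer_weathered_mass,
                        profile_base_saturation, profile_carbon_stock,
                        profile_fine_earth_mass, root_stock,
                        summarize_profiles, weathered_bulk_density)
from punastocks.soil import rock_volume_fraction

from conftest import cation_columns, make_layers


class TestLayerArithmetic:
    @pytest.mark.parametrize("wfe,wr,v,expected", [
        (800.0, 200.0, 1000.0, 1.0),
        (1000.0, 0.0, 1000.0, 1.0),       # rock-free, W_fe = V
        (800.0, 200.0, 600.0, 1000.0 / 600.0),
    ])
    def test_weathered_bulk_density(self, wfe, wr, v, expected):
        assert weathered_bulk_density(wfe, wr, v) == pytest.approx(expected)

    def test_zero_volume_rejected(self):
        with pytest.raises(DomainError):
            weathered_bulk_density(800.0, 200.0, 0.0)

    @pytest.mark.parametrize("rho,h,expected", [
        (1.0, 100.0, 100.0),   # g cm^-3 x mm = kg m^-2, factor exactly 1
        (1.0, 0.0, 0.0),
        (1.5, 50.0, 75.0),
    ])
    def test_layer_weathered_mass(self, rho, h, expected):
        assert layer_weathered_mass(rho, h) == pytest.approx(expected)

    def test_fine_earth_bulk_density(self):
        # 800 / (600 - 200/2.65)
        assert fine_earth_bulk_density(800.0, 200.0, 600.0) == pytest.approx(
            800.0 / (600.0 - 200.0 / 2.65))

    def test_fine_earth_density_rock_free_equals_weathered(self):
        assert fine_earth_bulk_density(900.0, 0.0, 1000.0) == pytest.approx(
            weathered_bulk_density(900.0, 0.0, 1000.0))

    def test_rock_volume_exceeding_sample_rejected(self):
        with pytest.raises(DomainError):
            fine_earth_bulk_density(10.0, 2.65 * 600.0, 600.0)


class TestProfileMass:
    def test_single_layer_printed_form(self):
        # M_w = 1.0 g cm^-3 * 100 mm = 100 kg m^-2; 80% fine earth -> 80
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 10.0,
                               "fine_earth_g": 800.0, "rock_g": 200.0,
                               "volume_cm3": 1000.0}])
        assert profile_fine_earth_mass(layers, form="printed") == pytest.approx(80.0)
        assert profile_fine_earth_mass(layers, form="algebraic") == pytest.approx(80.0)

    def test_rock_free_profile_equals_weathered_mass(self):
        layers = make_layers([
            {"top_cm": 0.0, "bottom_cm": 10.0, "fine_earth_g": 900.0, "rock_g": 0.0},
            {"top_cm": 10.0, "bottom_cm": 30.0, "fine_earth_g": 1100.0, "rock_g": 0.0},
        ])
        mw = 0.9 * 100.0 + 1.1 * 200.0
        assert profile_fine_earth_mass(layers) == pytest.approx(mw)

    def test_two_identical_layers_double_single(self):
        one = make_layers([{"top_cm": 0.0, "bottom_cm": 10.0}])
        two = make_layers([{"top_cm": 0.0, "bottom_cm": 10.0},
                           {"top_cm": 10.0, "bottom_cm": 20.0}])
        assert profile_fine_earth_mass(two) == pytest.approx(
            2.0 * profile_fine_earth_mass(one))

    def test_fine_earth_free_layer_contributes_zero(self):
        layers = make_layers([
            {"top_cm": 0.0, "bottom_cm": 10.0},
            {"top_cm": 10.0, "bottom_cm": 20.0, "fine_earth_g": 0.0, "rock_g": 500.0},
        ])
        only_first = make_layers([{"top_cm": 0.0, "bottom_cm": 10.0}])
        assert profile_fine_earth_mass(layers) == pytest.approx(
            profile_fine_earth_mass(only_first))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(
        st.tuples(st.floats(1.0, 5000.0), st.floats(0.0, 5000.0),
                  st.floats(100.0, 5000.0), st.floats(0.1, 60.0)),
        min_size=1, max_size=6))
    def test_printed_and_algebraic_forms_agree(self, layer_params):
        specs, top = [], 0.0
        for wfe, wr, v, thickness in layer_params:
            specs.append({"top_cm": top, "bottom_cm": top + thickness,
                          "fine_earth_g": wfe, "rock_g": wr, "volume_cm3": v})
            top += thickness
        layers = make_layers(specs)
        printed = profile_fine_earth_mass(layers, form="printed")
        algebraic = profile_fine_earth_mass(layers, form="algebraic")
        assert algebraic == pytest.approx(printed, rel=1e-9)


class TestStocks:
    def test_carbon_stock_arithmetic(self):
        # 80 kg m^-2 fine earth at 5% C -> 4 kg C m^-2
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 10.0, "carbon_pct": 5.0}])
        soc, _ = profile_carbon_stock(layers)
        assert soc == pytest.approx(4.0)

    def test_zero_concentration_zero_stock(self):
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 10.0, "carbon_pct": 0.0},
                              {"top_cm": 10.0, "bottom_cm": 40.0, "carbon_pct": 0.0}])
        assert profile_carbon_stock(layers)[0] == 0.0

    def test_missing_concentration_names_layer(self):
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 10.0,
                               "carbon_pct": np.nan}])
        with pytest.raises(DomainError, match="carbon_pct"):
            profile_carbon_stock(layers)

    def test_stock_equals_per_layer_loop(self, rng):
        specs, top = [], 0.0
        for _ in range(5):
            thickness = rng.uniform(3, 30)
            specs.append({"top_cm": top, "bottom_cm": top + thickness,
                          "fine_earth_g": rng.uniform(400, 1200),
                          "rock_g": rng.uniform(0, 400),
                          "volume_cm3": rng.uniform(700, 1300),
                          "carbon_pct": rng.uniform(0.5, 8)})
            top += thickness
        layers = make_layers(specs)
        expected = 0.0
        for s in specs:  # brute-force oracle, one layer at a time
            rho_w = (s["fine_earth_g"] + s["rock_g"]) / s["volume_cm3"]
            mw = rho_w * (s["bottom_cm"] - s["top_cm"]) * 10.0
            mfe = mw * s["fine_earth_g"] / (s["fine_earth_g"] + s["rock_g"])
            expected += s["carbon_pct"] / 100.0 * mfe
        assert profile_carbon_stock(layers)[0] == pytest.approx(expected, rel=1e-12)

    def test_reslicing_homogeneous_layer_preserves_stocks(self):
        whole = make_layers([{"top_cm": 0.0, "bottom_cm": 30.0}])
        sliced = make_layers([
            {"top_cm": 0.0, "bottom_cm": 7.0},
            {"top_cm": 7.0, "bottom_cm": 18.0},
            {"top_cm": 18.0, "bottom_cm": 30.0},
        ])
        assert profile_fine_earth_mass(sliced) == pytest.approx(
            profile_fine_earth_mass(whole))
        assert profile_carbon_stock(sliced)[0] == pytest.approx(
            profile_carbon_stock(whole)[0])
        assert root_stock(sliced)[0] == pytest.approx(root_stock(whole)[0])

    def test_root_stock_subsample_scaling(self):
        # 0.2 g roots in a 20 g subsample over 80 kg m^-2 fine earth -> 0.8
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 10.0}])
        biomass, carbon = root_stock(layers, carbon_fraction=0.5)
        assert biomass == pytest.approx(0.8)
        assert carbon == pytest.approx(0.4)

    def test_root_free_profile(self):
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 10.0,
                               "root_subsample_root_g": 0.0}])
        assert root_stock(layers) == (0.0, 0.0)

    def test_root_carbon_fraction(self):
        # a 1.8 kg m^-2 root mass at 50% carbon is 0.9 kg C m^-2
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 10.0,
                               "root_subsample_root_g": 20.0 * 1.8 / 80.0}])
        biomass, carbon = root_stock(layers, carbon_fraction=0.5)
        assert biomass == pytest.approx(1.8)
        assert carbon == pytest.approx(0.9)


class TestBaseSaturation:
    def test_no_acidity_is_full_saturation(self):
        assert base_saturation(
            {**cation_columns(100.0)}) == pytest.approx(100.0)

    def test_bases_equal_acidity_is_half(self):
        assert base_saturation({**cation_columns(50.0)}) == pytest.approx(50.0)

    def test_worked_example(self):
        exch = {"exch_ca": 4.0, "exch_mg": 2.0, "exch_k": 1.0, "exch_na": 1.0,
                "exch_al": 2.0, "exch_fe": 0.0, "exch_mn": 0.0, "exch_h": 0.0}
        assert base_saturation(exch) == pytest.approx(80.0)

    def test_zero_ecec_flagged_missing(self):
        exch = dict.fromkeys(
            ["exch_ca", "exch_mg", "exch_k", "exch_na",
             "exch_al", "exch_fe", "exch_mn", "exch_h"], 0.0)
        assert np.isnan(base_saturation(exch))

    def test_profile_mean_is_mass_weighted(self):
        layers = make_layers([
            {"top_cm": 0.0, "bottom_cm": 10.0, **cation_columns(80.0)},
            {"top_cm": 10.0, "bottom_cm": 40.0, **cation_columns(20.0)},
        ])
        # second layer has 3x the fine-earth mass of the first
        assert profile_base_saturation(layers) == pytest.approx(
            (80.0 * 1 + 20.0 * 3) / 4)


class TestClassification:
    def test_shallow_base_rich_dark_profile_is_mollic_leptosol(self):
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 15.0,
                               "carbon_pct": 5.0, "munsell_value": 2,
                               "munsell_chroma": 2, **cation_columns(60.0)}])
        assert classify_profile(layers) == "Mollic Leptosol"

    def test_deep_base_rich_is_phaeozem(self):
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 50.0,
                               **cation_columns(70.0)}])
        assert classify_profile(layers) == "Phaeozem"

    def test_deep_acidic_is_umbrisol(self):
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 50.0,
                               **cation_columns(30.0)}])
        assert classify_profile(layers) == "Umbrisol"

    def test_rocky_profile_takes_leptosol_branch(self):
        # 85% rock by volume at 30 cm depth: rule (1) despite the depth
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 30.0,
                               "volume_cm3": 1000.0,
                               "rock_g": 0.85 * 2.65 * 1000.0,
                               "fine_earth_g": 100.0,
                               **cation_columns(30.0)}])
        assert rock_volume_fraction(layers) == pytest.approx(0.85)
        assert classify_profile(layers) == "Leptosol"

    def test_shallow_acidic_profile_is_plain_leptosol(self):
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 20.0,
                               **cation_columns(30.0)}])
        assert classify_profile(layers) == "Leptosol"

    def test_missing_input_undetermined(self):
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 50.0,
                               "munsell_value": np.nan}])
        out = classify_profile(layers)
        assert out.startswith("undetermined") and "munsell_value" in out


class TestSummaries:
    def test_summarize_profiles_roundtrip(self):
        layers = pd.concat([
            make_layers([{"top_cm": 0.0, "bottom_cm": 10.0},
                         {"top_cm": 10.0, "bottom_cm": 40.0}], profile_id="A"),
            make_layers([{"top_cm": 0.0, "bottom_cm": 15.0}], profile_id="B",
                        vegetation="grassland"),
        ])
        out = summarize_profiles(layers).set_index("profile_id")
        assert out.loc["A", "total_depth_cm"] == 40.0
        assert out.loc["A", "n_layers"] == 2
        assert out.loc["B", "classification"] == "Mollic Leptosol"
        assert out.loc["A", "soc_stock_kg_m2"] == pytest.approx(
            profile_carbon_stock(layers[layers.profile_id == "A"])[0])

    def test_non_contiguous_layers_rejected(self):
        layers = make_layers([{"top_cm": 0.0, "bottom_cm": 10.0},
                              {"top_cm": 15.0, "bottom_cm": 30.0}])
        with pytest.raises(DomainError, match="contiguous"):
            summarize_profiles(layers)
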