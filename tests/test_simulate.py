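"""Generator unit and property tests: growth law, well simulation, tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hccscreen as h
from hccscreen.models import FourPLKill
from hccscreen.simulate import (
    FieldTooCrowdedError,
    IncubationConfig,
    OpticsConfig,
    _place_cells,
    default_dose_ladder,
    selective_compounds,
    simulate_organelle_image,
)


class TestGrowthLaw:
    @pytest.mark.parametrize("n0,td,t,expected,rtol", [
        (100, 24, 24, 200, 1e-12),      # one doubling
        (100, 24, 0, 100, 1e-12),       # identity at t=0
        (800, 23.8, 72, 6511, 1e-3),    # pilot-density Huh7 over 3 days
    ])
    def test_expected_counts(self, n0, td, t, expected, rtol):
        assert h.grow_population(n0, td, t) == pytest.approx(expected, rel=rtol)

    def test_nonpositive_doubling_time_rejected(self):
        with pytest.raises(ValueError):
            h.grow_population(100, 0, 24)
        with pytest.raises(ValueError):
            h.grow_population(100, -5, 24)

    @settings(max_examples=50, derandomize=True)
    @given(n0=st.floats(0, 1e5), td=st.floats(1, 100), t=st.floats(0, 200))
    def test_doubling_identity(self, n0, td, t):
        a = h.grow_population(n0, td, t + td)
        b = 2 * h.grow_population(n0, td, t)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_poisson_variant_is_seeded(self):
        r1 = h.grow_population(500, 24, 48, rng=np.random.default_rng(7))
        r2 = h.grow_population(500, 24, 48, rng=np.random.default_rng(7))
        assert r1 == r2


class TestFourPLKill:
    def test_zero_dose_gives_top(self):
        k = FourPLKill(top=100, bottom=0, ic50_m=1e-6, hill=1)
        assert k.viability_pct(0.0) == pytest.approx(100)

    def test_midpoint(self):
        k = FourPLKill(top=100, bottom=0, ic50_m=2.5e-6, hill=1.7)
        assert k.viability_pct(2.5e-6) == pytest.approx(50)

    @settings(max_examples=50, derandomize=True)
    @given(top=st.floats(50, 100), delta=st.floats(0, 50),
           hill=st.floats(0.1, 5), lg=st.floats(-9, -4))
    def test_monotone_nonincreasing_in_dose(self, top, delta, hill, lg):
        k = FourPLKill(top=top, bottom=top - delta, ic50_m=10**lg, hill=hill)
        doses = np.logspace(-12, -3, 40)
        v = k.viability_pct(doses)
        assert (np.diff(v) <= 1e-9).all()

    def test_top_below_bottom_rejected(self):
        with pytest.raises(ValueError):
            FourPLKill(top=10, bottom=50, ic50_m=1e-6)


def _entry(layout, role=None, compound=None):
    sub = layout
    if role:
        sub = sub[sub["role"] == role]
    if compound:
        sub = sub[sub["compound"] == compound]
    return next(sub.itertuples(index=False))


SMALL_OPTICS = OpticsConfig(field_size_px=256, n_fields=2, capture_fraction=0.01)


@pytest.fixture(scope="module")
def layout(library):
    tests = [c for c in library if c not in ("DMSO", "sorafenib")]
    return h.pilot_plate_layout(tests)


class TestSimulateWell:
    def test_dmso_survival_is_one_minus_baseline_death(self, layout,
                                                       populations, library):
        rec = h.simulate_well(_entry(layout, role="negative_control"),
                              populations, library, seed=5,
                              optics=SMALL_OPTICS, render=False)
        for name, pop in populations.items():
            expected = rec.truth.n_grown[name] * (1 - pop.baseline_death_frac)
            sd = np.sqrt(expected)
            assert abs(rec.truth.n_survive[name] - expected) < 5 * sd

    def test_dose_at_ic50_halves_population(self, populations):
        drug = h.DrugEffectModel(
            compound_id="x",
            effects={"Huh7": FourPLKill(top=100, bottom=0, ic50_m=1e-6, hill=2)})
        entry = pd.DataFrame([("P1", "A03", "test", "x", 1e-6, 1)],
                             columns=["plate", "well", "role", "compound",
                                      "dose_M", "replicate"])
        rec = h.simulate_well(next(entry.itertuples(index=False)), populations,
                              {"x": drug}, seed=6, optics=SMALL_OPTICS,
                              render=False)
        pop = populations["Huh7"]
        expected = rec.truth.n_grown["Huh7"] * 0.5 * (1 - pop.baseline_death_frac)
        assert abs(rec.truth.n_survive["Huh7"] - expected) < 5 * np.sqrt(expected)

    def test_selective_compound_spares_hepatocytes(self, layout, populations,
                                                   library):
        rec = h.simulate_well(
            _entry(layout, compound="pyrimethamine-like"), populations,
            library, seed=7, render=False)
        surv_hcc = rec.truth.n_survive["Huh7"] / rec.truth.n_grown["Huh7"]
        surv_hep = rec.truth.n_survive["Fa2N-4"] / rec.truth.n_grown["Fa2N-4"]
        assert surv_hcc < 0.35
        assert surv_hep > 0.9

    def test_seeded_determinism_bit_identical(self, layout, populations,
                                              library):
        e = _entry(layout, role="negative_control")
        a = h.simulate_well(e, populations, library, seed=42, optics=SMALL_OPTICS)
        b = h.simulate_well(e, populations, library, seed=42, optics=SMALL_OPTICS)
        assert a.images.keys() == b.images.keys()
        for key in a.images:
            assert np.array_equal(a.images[key], b.images[key])
        pd.testing.assert_frame_equal(a.truth.cells, b.truth.cells)

    def test_truth_rows_match_rendered_fields(self, layout, populations,
                                              library):
        rec = h.simulate_well(_entry(layout, role="negative_control"),
                              populations, library, seed=9, optics=SMALL_OPTICS)
        assert rec.n_fields == SMALL_OPTICS.n_fields
        per_field = rec.truth.cells.groupby("field").size()
        for f in range(SMALL_OPTICS.n_fields):
            assert (f, "hoechst") in rec.images
            assert rec.images[(f, "hoechst")].dtype == np.uint16
        assert per_field.sum() == len(rec.truth.cells)
        for name in populations:
            assert rec.truth.n_survive[name] <= rec.truth.n_grown[name] * 1.2

    def test_overcrowded_field_raises_named_error(self):
        with pytest.raises(FieldTooCrowdedError, match="min separation"):
            _place_cells(500, 64, min_sep=14.4, margin=12,
                         rng=np.random.default_rng(0))


class TestDoseResponseTable:
    def test_zero_dose_returns_top_noise_free(self):
        k = FourPLKill(top=87, bottom=5, ic50_m=1e-7, hill=1.3)
        tab = h.simulate_dose_response_table(k, default_dose_ladder())
        assert (tab.loc[tab["dose_M"] == 0, "viability_pct"] == 87).all()

    def test_asymptote_at_high_dose(self):
        k = FourPLKill(top=100, bottom=12, ic50_m=1e-9, hill=1)
        doses = np.concatenate([[0.0], np.logspace(-9, -3, 7)])
        tab = h.simulate_dose_response_table(k, doses)
        high = tab.loc[tab["dose_M"] == 1e-3, "viability_pct"].iloc[0]
        assert high == pytest.approx(12, abs=1e-4)

    def test_value_at_one_micromolar_matches_hand_formula(self):
        k = FourPLKill(top=100, bottom=0, ic50_m=2.764e-6, hill=1)
        tab = h.simulate_dose_response_table(k, default_dose_ladder())
        got = tab.loc[np.isclose(tab["dose_M"], 1e-6), "viability_pct"].iloc[0]
        assert got == pytest.approx(100 / (1 + 1 / 2.764), rel=1e-9)

    def test_too_few_nonzero_doses_rejected(self):
        k = FourPLKill(top=100, bottom=0, ic50_m=1e-6)
        with pytest.raises(ValueError, match="nonzero doses"):
            h.simulate_dose_response_table(k, [0.0, 1e-9, 1e-8, 1e-7])

    def test_noise_is_seeded(self):
        k = FourPLKill(top=100, bottom=0, ic50_m=1e-6)
        a = h.simulate_dose_response_table(k, default_dose_ladder(),
                                           noise_sd=5, seed=3)
        b = h.simulate_dose_response_table(k, default_dose_ladder(),
                                           noise_sd=5, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestResazurin:
    def test_background_only_at_zero_cells(self):
        assert h.simulate_resazurin(0, gain=0.02, background=7) == 7

    def test_linearity(self):
        lo = h.simulate_resazurin(1000, 0.01, 5)
        hi = h.simulate_resazurin(2000, 0.01, 5)
        assert hi - lo == pytest.approx(0.01 * 1000)
        assert lo == pytest.approx(15)

    def test_bad_gain_rejected(self):
        with pytest.raises(ValueError):
            h.simulate_resazurin(10, gain=0, background=1)


class TestOrganelleAndSpheroid:
    def test_zero_vesicle_rate_gives_zero_puncta(self):
        sim = simulate_organelle_image(n_cells=30, vesicle_rate=0, seed=1)
        assert (sim.truth["puncta_count"] == 0).all()

    def test_poisson_rate_ratio_recovered_in_truth(self):
        a = simulate_organelle_image(n_cells=220, vesicle_rate=4, size=768,
                                     seed=21)
        b = simulate_organelle_image(n_cells=220, vesicle_rate=12, size=768,
                                     seed=22)
        ratio = b.truth["puncta_count"].mean() / a.truth["puncta_count"].mean()
        assert ratio == pytest.approx(3.0, abs=0.3)

    def test_fully_lysosomal_ctsb_concentrated_in_puncta(self):
        sim = simulate_organelle_image(n_cells=20, vesicle_rate=5,
                                       translocated_frac=0.0,
                                       background=0.0, read_noise_sd=0.0,
                                       seed=2)
        inside_cells = sim.ctsb[sim.cell_labels > 0].astype(float)
        # all signal sits in puncta: the median footprint pixel is empty
        assert np.median(inside_cells) == 0

    def test_spheroid_midplane_index_and_bounds(self):
        st_ = h.simulate_spheroid_stack(n_slices=50, apoptotic_frac=0.5, seed=3,
                                        size=256, radius_px=80,
                                        cells_per_midplane=40)
        assert st_.midplane_index == 25
        assert st_.n_slices == 50
        assert 0 <= st_.true_midplane_apoptotic_frac <= 1
        with pytest.raises(ValueError):
            h.simulate_spheroid_stack(n_slices=2)


class TestLibraryAndLayout:
    def test_library_has_43_compounds_plus_controls(self, library):
        assert len(library) == 45
        assert {"DMSO", "sorafenib"} <= set(library)
        assert set(selective_compounds()) <= set(library)

    def test_layout_controls_and_duplicates(self, library):
        tests = [c for c in library if c not in ("DMSO", "sorafenib")]
        lay = h.pilot_plate_layout(tests)
        assert (lay["role"] == "negative_control").sum() == 8
        assert (lay["role"] == "positive_control").sum() == 8
        per_comp = lay[lay["role"] == "test"].groupby("compound").size()
        assert (per_comp == 2).all()
        assert len(lay) == 8 + 8 + 2 * 43

    def test_hcc_marker_contrast_enforced(self, populations):
        from hccscreen.models import check_marker_contrast

        with pytest.raises(ValueError, match="must exceed"):
            check_marker_contrast(populations["Fa2N-4"], populations["Huh7"])
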