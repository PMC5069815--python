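"""Inhibition, Z'-factor and hit-calling logic (count-level, no imaging)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hccscreen as h
from hccscreen.models import FourPLKill, WellRecord
from hccscreen.screening import (
    AssayWindowError,
    call_hits,
    compute_zprime,
    percent_inhibition,
    run_pilot_screen,
)
from hccscreen.simulate import OpticsConfig


class TestPercentInhibition:
    def test_control_level_count_is_zero_inhibition(self):
        assert percent_inhibition(100, [95, 105, 100]) == pytest.approx(0)

    def test_empty_well_is_full_inhibition(self):
        assert percent_inhibition(0, [95, 105, 100]) == pytest.approx(100)

    def test_hand_computed_example(self):
        assert percent_inhibition(40, [95, 105, 100]) == pytest.approx(60)

    def test_stimulation_reports_negative(self):
        assert percent_inhibition(150, [100, 100, 100]) == pytest.approx(-50)

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            percent_inhibition(40, [100, 100])

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_inhibition(40, [0, 0, 0])

    def test_pooled_control_wells_center_on_zero(self, populations, library):
        # simulate 48 DMSO control wells; inhibition of each half-B well
        # against the half-A mean should average out near 0
        optics = OpticsConfig(n_fields=1, capture_fraction=0.01)
        counts = []
        for i in range(48):
            entry = pd.DataFrame(
                [("P1", f"A{i:02d}", "negative_control", "DMSO", 0.0, 1)],
                columns=["plate", "well", "role", "compound", "dose_M",
                         "replicate"])
            rec = h.simulate_well(next(entry.itertuples(index=False)),
                                  populations, library, seed=1000 + i,
                                  optics=optics, render=False)
            counts.append((rec.truth.cells["population"] == "Huh7").sum())
        ref, probe = counts[:24], counts[24:]
        inhib = [percent_inhibition(c, ref) for c in probe]
        assert abs(np.mean(inhib)) < 3.0


class TestZPrime:
    def test_perfect_separation_gives_one(self):
        assert compute_zprime([90, 90, 90], [10, 10, 10]) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # means 90 / 10, sample SDs 2 / 2 -> 1 - 3*4/80 = 0.85
        assert compute_zprime([88, 90, 92], [8, 10, 12]) == pytest.approx(0.85)

    def test_no_window_raises(self):
        with pytest.raises(AssayWindowError, match="no assay window"):
            compute_zprime([50, 50], [50, 50])
        with pytest.raises(AssayWindowError, match="no assay window"):
            compute_zprime([50], [10, 12])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1000), min_size=2, max_size=10),
           st.lists(st.floats(0, 1000), min_size=2, max_size=10))
    def test_bounded_above_by_one(self, pos, neg):
        try:
            z = compute_zprime(pos, neg)
        except AssayWindowError:
            return
        assert z <= 1.0

    def test_wide_variability_gives_nonpositive_zprime(self):
        # sd_p + sd_n >= window/3  ->  Z' <= 0
        z = compute_zprime([60, 100, 140], [0, 30, 60])  # sds 40/30, window 70
        assert z <= 0

    def test_zprime_improves_with_more_counted_cells(self, populations,
                                                     library):
        # counting statistics: capturing more cells tightens both control
        # arms and raises Z' (3 capture levels, fixed seeds)
        zs = []
        for frac in (0.006, 0.02, 0.06):
            optics = OpticsConfig(n_fields=4, capture_fraction=frac)
            arm = {"negative_control": [], "positive_control": []}
            for role, compound, dose in (
                    ("negative_control", "DMSO", 0.0),
                    ("positive_control", "sorafenib", 10e-6)):
                for i in range(8):
                    entry = pd.DataFrame(
                        [("P1", f"B{i:02d}", role, compound, dose, 1)],
                        columns=["plate", "well", "role", "compound",
                                 "dose_M", "replicate"])
                    rec = h.simulate_well(next(entry.itertuples(index=False)),
                                          populations, library,
                                          seed=7000 + i, optics=optics,
                                          render=False)
                    arm[role].append(
                        (rec.truth.cells["population"] == "Huh7").sum())
            zs.append(compute_zprime(arm["positive_control"],
                                     arm["negative_control"]))
        assert zs[0] < zs[1] < zs[2]


class TestCallHits:
    def _table(self, hcc, hep):
        return pd.DataFrame({"compound": ["x"], "hcc_inhibition_pct": [hcc],
                             "hep_inhibition_pct": [hep]})

    @pytest.mark.parametrize("hcc,hep,expected", [
        (60, 10, True),    # satisfies both thresholds
        (50, 10, False),   # strict boundary on HCC inhibition
        (90, 20, False),   # strict boundary on hepatocyte inhibition
        (49.9, 0, False),
        (100, 19.9, True),
    ])
    def test_strict_dual_threshold(self, hcc, hep, expected):
        out = call_hits(self._table(hcc, hep))
        assert bool(out["hit"].iloc[0]) is expected

    def test_monotone_in_hcc_inhibition(self):
        base = call_hits(self._table(55, 10))["hit"].iloc[0]
        stronger = call_hits(self._table(80, 10))["hit"].iloc[0]
        assert base and stronger

    def test_monotone_kill_lowers_survival_same_seed(self, populations):
        # raising a compound's true HCC kill (same seed) never raises the
        # surviving HCC count, the quantity hit calling thresholds
        entry = pd.DataFrame([("P1", "C03", "test", "x", 10e-6, 1)],
                             columns=["plate", "well", "role", "compound",
                                      "dose_M", "replicate"])
        survivors = []
        for bottom in (60.0, 30.0, 0.0):
            drug = h.DrugEffectModel(compound_id="x", effects={
                "Huh7": FourPLKill(top=100, bottom=bottom, ic50_m=1e-6)})
            rec = h.simulate_well(next(entry.itertuples(index=False)),
                                  populations, {"x": drug}, seed=99,
                                  render=False)
            survivors.append(rec.truth.n_survive["Huh7"])
        assert survivors[0] >= survivors[1] >= survivors[2]


def _mock_record(plate, well, role, compound, dose, rep, n_hcc, n_hep,
                 seed=0):
    """WellRecord with a pre-computed cell table (skips imaging)."""
    rng = np.random.default_rng(seed)
    n = n_hcc + n_hep
    chalv1 = np.r_[np.exp(rng.normal(np.log(1300), 0.3, n_hcc)),
                   np.exp(rng.normal(np.log(220), 0.3, n_hep))]
    afp = np.r_[np.exp(rng.normal(np.log(1300), 0.3, n_hcc)),
                np.exp(rng.normal(np.log(220), 0.3, n_hep))]
    cells = pd.DataFrame({
        "field": np.zeros(n, int), "cell_id": np.arange(1, n + 1),
        "centroid_row": rng.uniform(0, 512, n),
        "centroid_col": rng.uniform(0, 512, n),
        "nucleus_area_px": np.full(n, 113),
        "chalv1_ring": chalv1, "afp_ring": afp,
        "chalv1_nucleus": chalv1, "afp_nucleus": afp,
    })
    return WellRecord(plate=plate, well=well, role=role, compound=compound,
                      dose_m=dose, replicate=rep, cells=cells)


def _mock_plate(test_specs, n_ctrl_cells=(350, 230), pos_hcc=40, seed=0):
    """Build records+layout from {compound: (n_hcc, n_hep)} per duplicate."""
    rows, records = [], {}
    k = 0
    for i in range(8):
        w = f"A{i+1:02d}"
        rows.append(("P1", w, "negative_control", "DMSO", 0.0, i + 1))
        records[w] = _mock_record("P1", w, "negative_control", "DMSO", 0.0,
                                  i + 1, *n_ctrl_cells, seed=seed + k)
        k += 1
    for i in range(8):
        w = f"B{i+1:02d}"
        rows.append(("P1", w, "positive_control", "sorafenib", 10e-6, i + 1))
        records[w] = _mock_record("P1", w, "positive_control", "sorafenib",
                                  10e-6, i + 1, pos_hcc, 180, seed=seed + k)
        k += 1
    col = 3
    for comp, (n_hcc, n_hep) in test_specs.items():
        for rep in (1, 2):
            w = f"C{col:02d}"
            rows.append(("P1", w, "test", comp, 10e-6, rep))
            records[w] = _mock_record("P1", w, "test", comp, 10e-6, rep,
                                      n_hcc, n_hep, seed=seed + k)
            col += 1
            k += 1
    layout = pd.DataFrame(rows, columns=["plate", "well", "role", "compound",
                                         "dose_M", "replicate"])
    return records, layout


class TestRunPilotScreen:
    def test_selective_compound_called_pan_toxic_not(self):
        records, layout = _mock_plate({
            "selective": (60, 225),     # ~83% HCC, ~2% hep inhibition
            "pan-toxic": (60, 90),      # both inhibited
            "inactive": (345, 230),
        })
        res = run_pilot_screen(records, layout)
        assert not res.aborted
        assert res.zprime > 0.5
        assert res.hits == ["selective"]
        assert "Z'" in res.report

    def test_all_dmso_plate_has_zero_hits(self):
        records, layout = _mock_plate({})
        res = run_pilot_screen(records, layout)
        assert res.hits == []

    def test_no_positive_controls_aborts_with_window_error(self):
        records, layout = _mock_plate({})
        drop = [w for w in records if records[w].role == "positive_control"]
        for w in drop:
            del records[w]
        layout = layout[layout["role"] != "positive_control"]
        with pytest.raises(AssayWindowError, match="no assay window"):
            run_pilot_screen(records, layout)

    def test_low_zprime_aborts_but_reports(self):
        # noisy controls: negative arm count spread makes Z' collapse
        records, layout = _mock_plate({"selective": (60, 225)})
        for i, w in enumerate(w for w in records
                              if records[w].role == "negative_control"):
            rec = records[w]
            # strided subsampling keeps the class mix but spreads the counts
            rec.cells = rec.cells.iloc[::(1 + i % 4)].copy()
        res = run_pilot_screen(records, layout, zprime_gate=0.5)
        assert res.aborted
        assert res.hits == []
        assert "ABORTED" in res.report

    def test_qc_failing_wells_are_excluded(self):
        records, layout = _mock_plate({"selective": (60, 225)})
        # one replicate well decimated below the 100-cell QC floor
        records["C03"].cells = records["C03"].cells.iloc[:40].copy()
        res = run_pilot_screen(records, layout)
        assert any("C03" in e for e in res.qc_excluded)
        comp = res.compounds.set_index("compound")
        assert comp.loc["selective", "n_wells"] == 1
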