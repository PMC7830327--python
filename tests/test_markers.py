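import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_dataset
from ramanmcr import synth
from ramanmcr.errors import (
    InvalidModelError,
    MissingLabelError,
    ParameterError,
)
from ramanmcr.markers import (
    Band,
    CalibrationModel,
    annotate_components,
    band_intensity,
    biomolecular_ratios,
    fit_unsaturation_calibration,
    integrate_band,
    marker_ratio_report,
    predict_double_bonds,
)


class TestIntegrateBand:
    def test_triangle_area(self):
        axis = np.arange(0.0, 2001.0)
        y = np.maximum(0.0, 1.0 - np.abs(axis - 1000.0) / 10.0)  # base 20, height 1
        area = integrate_band((axis, y), Band("t", 1000.0, 10.0), "linear")
        assert area == pytest.approx(10.0, rel=1e-12)

    def test_straight_line_cancels_under_linear_baseline(self):
        axis = np.arange(900.0, 1100.0)
        y = 0.3 * axis + 7.0
        area = integrate_band((axis, y), Band("t", 1000.0, 15.0), "linear")
        assert area == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_closed_form(self):
        axis = np.arange(800.0, 1200.0, 0.5)
        amp, sigma = 5.0, 3.0
        y = amp * np.exp(-((axis - 1000.0) ** 2) / (2 * sigma**2))
        area = integrate_band((axis, y), Band("t", 1000.0, 15.0), "none")
        assert area == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=0.01)

    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
    )
    def test_linearity_without_baseline(self, a, b):
        axis = np.arange(900.0, 1100.0)
        rng = np.random.default_rng(0)
        s1 = rng.uniform(size=axis.size)
        s2 = rng.uniform(size=axis.size)
        band = Band("t", 1000.0, 20.0)
        lhs = integrate_band((axis, a * s1 + b * s2), band, "none")
        rhs = a * integrate_band((axis, s1), band, "none") + b * integrate_band(
            (axis, s2), band, "none"
        )
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_window_outside_axis_rejected(self):
        axis = np.arange(900.0, 1000.0)
        with pytest.raises(ParameterError):
            integrate_band((axis, np.ones(axis.size)), Band("t", 995.0, 15.0))

    def test_band_validation(self):
        with pytest.raises(Exception):
            Band("bad", 5000.0, 10.0)
        with pytest.raises(Exception):
            Band("bad", 1000.0, 0.0)

    def test_peak_height_mode(self):
        axis = np.arange(900.0, 1100.0)
        y = np.zeros(axis.size)
        y[axis == 1000.0] = 4.0
        assert band_intensity((axis, y), Band("t", 1000.0, 10.0), "none") == 4.0


class TestBiomolecularRatios:
    def _cells(self, nucleic_scale_b=1.0, n=10, noise=0.0, seed=0):
        W = synth.make_pure_components(synth.GeneratorConfig())
        axis = W.index.to_numpy()
        lip = W["Lipid 2"].to_numpy()
        npc = W["N+P"].to_numpy()
        rng = np.random.default_rng(seed)
        cols, cells, groups = [], [], []
        for g, scale in (("A", 1.0), ("B", nucleic_scale_b)):
            for i in range(n):
                jitter = 1.0 + noise * rng.normal()
                cols.append(jitter * (lip + scale * npc))
                cells.append(f"{g}{i}")
                groups.append(g)
        return make_dataset(np.column_stack(cols), groups=groups, cells=cells, axis=axis)

    def test_identical_groups_are_null(self):
        per_cell, summary = biomolecular_ratios(self._cells(1.0, noise=0.05))
        for _, row in summary.iterrows():
            assert row["mean_A"] == pytest.approx(row["mean_B"], rel=0.1)

    def test_doubled_nucleic_band_doubles_ratio(self):
        _, summary = biomolecular_ratios(self._cells(2.0))
        row = summary[summary["ratio"] == "nucleic/lipid"].iloc[0]
        assert row["mean_B"] / row["mean_A"] == pytest.approx(2.0, rel=0.05)
        assert row["p_welch"] < 1e-6

    def test_single_cell_has_no_sd(self):
        ds = self._cells(1.0, n=1)
        _, summary = biomolecular_ratios(ds)
        assert np.isnan(summary["sd_A"]).all()


class TestAnnotation:
    def test_ground_truth_components_labelled(self):
        W = synth.make_pure_components(synth.GeneratorConfig())
        ann = annotate_components(W.to_numpy(), W.index.to_numpy())
        assert [a.label for a in ann] == list(W.columns)
        by = {a.label: a for a in ann}
        assert by["Lipid 1"].ester and not by["Lipid 2"].ester and not by["Lipid 3"].ester

    def test_flat_spectrum_is_autofluorescence(self):
        axis = np.arange(739.0, 1801.0)
        ann = annotate_components(np.ones((axis.size, 1)), axis)
        assert ann[0].label == "AF"

    def test_scale_invariance(self):
        W = synth.make_pure_components(synth.GeneratorConfig())
        axis = W.index.to_numpy()
        l1 = annotate_components(W.to_numpy(), axis)
        l2 = annotate_components(123.0 * W.to_numpy(), axis)
        assert [a.label for a in l1] == [a.label for a in l2]


class TestMarkerRatioReport:
    def _annotations(self):
        W = synth.make_pure_components(synth.GeneratorConfig())
        return annotate_components(W.to_numpy(), W.index.to_numpy()), list(W.columns)

    def test_nine_ratios_and_group_stats(self):
        ann, names = self._annotations()
        rng = np.random.default_rng(0)
        H = np.abs(rng.normal(1.0, 0.1, size=(7, 20))) + 0.5
        groups = np.array(["A"] * 10 + ["B"] * 10)
        H[names.index("Lipid 1"), groups == "B"] *= 0.2
        rep = marker_ratio_report(H, ann, groups)
        assert len(rep["ratios"]) == 9
        e = rep["ratios"]["Lipid 1/N+P"]
        assert e["per_group"]["A"]["mean"] > e["per_group"]["B"]["mean"]
        assert e["p_welch"] < 0.01

    def test_zero_denominator_cell_excluded_and_counted(self):
        ann, names = self._annotations()
        H = np.ones((7, 6))
        H[names.index("P"), 2] = 0.0
        rep = marker_ratio_report(H, ann, ["A", "A", "A", "B", "B", "B"])
        assert rep["ratios"]["Lipid 1/P"]["n_excluded"] == 1
        assert rep["ratios"]["Lipid 1/N+P"]["n_excluded"] == 0

    def test_missing_label_is_explicit(self):
        ann, _ = self._annotations()
        ann = [a for a in ann if a.label != "P"]
        with pytest.raises(MissingLabelError, match="P"):
            marker_ratio_report(np.ones((7, 4)), ann, ["A", "A", "B", "B"])


class TestCalibration:
    def test_generator_standards_recover_construction_line(self):
        stds = [
            (s.name, s.spectrum, s.ndb)
            for s in synth.simulate_standards()
            if s.name != "TLA"
        ]
        model = fit_unsaturation_calibration(stds)
        assert model.r_squared > 0.9999
        assert model.slope == pytest.approx(synth.CC_AMPLITUDE_PER_NDB, rel=0.01)
        # inverse prediction returns each training standard's own NDB
        for name, spec, ndb in stds:
            pred = predict_double_bonds(model, spec)
            assert pred.ndb == pytest.approx(ndb, abs=0.1)
            assert not pred.ester

    def test_two_point_fit_interpolates(self):
        stds = {s.name: s for s in synth.simulate_standards()}
        model = fit_unsaturation_calibration(
            [("PMA", stds["PMA"].spectrum, 1), ("DHA", stds["DHA"].spectrum, 6)]
        )
        assert model.r_squared == pytest.approx(1.0)

    def test_equal_ndb_rejected(self):
        stds = {s.name: s for s in synth.simulate_standards()}
        with pytest.raises(InvalidModelError):
            fit_unsaturation_calibration(
                [("PMA", stds["PMA"].spectrum, 1), ("OA", stds["OA"].spectrum, 1)]
            )

    def test_unsaturation_increases_with_ndb(self):
        from ramanmcr.markers import _standard_ratio

        stds = {s.name: s for s in synth.simulate_standards()}
        assert _standard_ratio(stds["DHA"].spectrum) > _standard_ratio(stds["PMA"].spectrum)

    def test_tla_differs_from_la_only_at_ester_band(self):
        stds = {s.name: s for s in synth.simulate_standards()}
        la, tla = stds["LA"].spectrum, stds["TLA"].spectrum
        diff = np.abs(tla.intensities - la.intensities)
        outside = (la.wavenumbers < 1680) | (la.wavenumbers > 1800)
        assert diff[~outside].max() > 0.1
        # only Lorentzian tails of the ester band leak outside the window
        assert diff[outside].max() < 0.02 * la.intensities.max()

    def test_invalid_slope_rejected(self):
        import pandas as pd

        model = CalibrationModel(-1.0, 0.0, 1.0, np.zeros(2), pd.DataFrame())
        stds = {s.name: s for s in synth.simulate_standards()}
        with pytest.raises(InvalidModelError):
            predict_double_bonds(model, stds["LA"].spectrum)
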