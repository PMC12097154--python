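import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pupitome.preprocess import (classify_missingness, filter_peptides,
                                 impute_missing, transform_and_center)
from .conftest import make_peptide_table


def samples_of(design):
    return design.samples


class TestFilterPeptides:
    def test_empty_table_passes_through(self, small_design):
        t = make_peptide_table(small_design, [])
        assert len(filter_peptides(t, small_design)) == 0

    def test_hand_enumerated_example(self, small_design):
        """Six peptides: decoy, contaminant, single-sample, sole-ion
        protein, and two clean rows -> exactly the two clean survive."""
        s = samples_of(small_design)
        full = {x: 10.0 for x in s}
        rows = [
            ("pepD", "PD", True, False, 3, full),
            ("pepC", "PC", False, True, 3, full),
            ("pepS", "PS", False, False, 3, {s[0]: 10.0}),
            ("pepI", "PI", False, False, 1, full),
            ("pepA", "PA", False, False, 3, full),
            ("pepB", "PB", False, False, 3, full),
        ]
        out = filter_peptides(make_peptide_table(small_design, rows),
                              small_design)
        assert list(out["peptide"]) == ["pepA", "pepB"]

    def test_clean_table_is_noop_and_idempotent(self, small_design):
        s = samples_of(small_design)
        rows = [(f"p{i}", f"P{i}", False, False, 2,
                 {x: 5.0 + i for x in s}) for i in range(4)]
        t = make_peptide_table(small_design, rows)
        once = filter_peptides(t, small_design)
        pd.testing.assert_frame_equal(once, t)
        pd.testing.assert_frame_equal(filter_peptides(once, small_design),
                                      once)

    def test_single_sample_cells_blanked_per_run(self, study_design):
        """A peptide seen once in one run but fully in another keeps only
        the complete run's cells."""
        runs = study_design.runs
        r1 = study_design.run_samples(runs[0])
        r2 = study_design.run_samples(runs[1])
        cells = {r1[0]: 9.0}
        cells.update({x: 8.0 for x in r2})
        t = make_peptide_table(study_design,
                               [("p1", "P1", False, False, 4, cells)])
        out = filter_peptides(t, study_design)
        assert len(out) == 1
        assert np.isnan(out.iloc[0][r1[0]])
        assert (out.iloc[0][r2] == 8.0).all()

    def test_unknown_sample_column_rejected(self, small_design):
        t = make_peptide_table(small_design, [])
        t["mystery_sample"] = []
        with pytest.raises(ValueError, match="not in design"):
            filter_peptides(t, small_design)


class TestTransformAndCenter:
    def test_known_centering(self, small_design):
        s = samples_of(small_design)
        cells = dict(zip(s[:3], [4.0, 16.0, 64.0]))
        rows = [("p1", "P1", False, False, 2, {s[0]: 4.0}),
                ("p2", "P1", False, False, 2, {s[0]: 16.0}),
                ("p3", "P1", False, False, 2, {s[0]: 64.0})]
        del cells
        tm = transform_and_center(make_peptide_table(small_design, rows),
                                  small_design)
        np.testing.assert_allclose(tm.values[s[0]], [-2.0, 0.0, 2.0])

    def test_constant_sample_centers_to_zero(self, small_design):
        s = samples_of(small_design)
        rows = [(f"p{i}", "P1", False, False, 2, {s[0]: 8.0})
                for i in range(3)]
        tm = transform_and_center(make_peptide_table(small_design, rows),
                                  small_design)
        np.testing.assert_allclose(tm.values[s[0]], 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=3,
                    max_size=12))
    def test_observed_median_is_zero(self, small_design, values):
        s = samples_of(small_design)
        rows = [(f"p{i}", "P1", False, False, 2, {s[0]: v})
                for i, v in enumerate(values)]
        tm = transform_and_center(make_peptide_table(small_design, rows),
                                  small_design)
        assert abs(np.median(tm.values[s[0]])) < 1e-9

    def test_centering_invariant_to_sample_scaling(self, small_design):
        """Multiplying one sample's raw intensities by a constant (an
        additive shift on the log2 scale) leaves the centered matrix
        unchanged."""
        s = samples_of(small_design)
        rng = np.random.default_rng(0)
        base = {x: rng.uniform(4, 4000) for x in s}
        rows = [(f"p{i}", "P1", False, False, 2,
                 {x: base[x] * rng.uniform(0.5, 2) for x in s})
                for i in range(6)]
        t1 = make_peptide_table(small_design, rows)
        t2 = t1.copy()
        t2[s[0]] = t2[s[0]] * 37.0
        m1 = transform_and_center(t1, small_design)
        m2 = transform_and_center(t2, small_design)
        np.testing.assert_allclose(m1.values.to_numpy(),
                                   m2.values.to_numpy(), atol=1e-9)

    def test_nonpositive_intensity_names_cell(self, small_design):
        s = samples_of(small_design)
        rows = [("pX", "P1", False, False, 2, {s[0]: -3.0})]
        with pytest.raises(ValueError, match="pX"):
            transform_and_center(make_peptide_table(small_design, rows),
                                 small_design)


class TestMissingness:
    def _mask_for(self, design, present):
        s = samples_of(design)
        trip = design.triplicates()[0][1]
        cells = {c: v for c, v in zip(trip, present) if v is not None}
        cells.update({c: 5.0 for c in s if c not in trip})
        t = make_peptide_table(design, [("p1", "P1", False, False, 2, cells)])
        tm = transform_and_center(t, design)
        return classify_missingness(tm, design), trip

    def test_one_missing_is_mar(self, small_design):
        mask, trip = self._mask_for(small_design, [5.0, 5.2, None])
        assert pd.isna(mask.iloc[0][trip[0]])
        assert pd.isna(mask.iloc[0][trip[1]])
        assert mask.iloc[0][trip[2]] == "MAR"

    def test_two_missing_are_mnar(self, small_design):
        mask, trip = self._mask_for(small_design, [5.0, None, None])
        assert pd.isna(mask.iloc[0][trip[0]])
        assert mask.iloc[0][trip[1]] == "MNAR"
        assert mask.iloc[0][trip[2]] == "MNAR"

    def test_all_missing_are_mnar(self, small_design):
        mask, trip = self._mask_for(small_design, [None, None, None])
        assert [mask.iloc[0][c] for c in trip] == ["MNAR"] * 3

    def test_at_most_one_mar_per_triplicate(self, small_design, study_data):
        table, _ = study_data
        from pupitome.preprocess import filter_peptides
        import pupitome
        design = pupitome.torc_study_design()
        tm = transform_and_center(filter_peptides(table, design), design)
        mask = classify_missingness(tm, design)
        for _, trip in design.triplicates():
            n_mar = (mask[trip] == "MAR").sum(axis=1)
            assert (n_mar <= 1).all()


class TestImputation:
    def _impute(self, design, present, **kw):
        """Build a centered-scale matrix directly (values may be negative)."""
        from pupitome.preprocess import TransformedMatrix
        s = samples_of(design)
        trip = design.triplicates()[0][1]
        cells = {c: v for c, v in zip(trip, present) if v is not None}
        cells.update({c: 2.0 for c in s if c not in trip})
        data = pd.DataFrame([{"peptide": "p1", "protein": "P1",
                              "is_decoy": False, "is_contaminant": False,
                              "n_ions": 2,
                              **{c: cells.get(c, np.nan) for c in s}}])
        tm = TransformedMatrix(data, s,
                               {r: -5.0 for r in design.runs})
        mask = classify_missingness(tm, design)
        return impute_missing(tm, mask, design, **kw), trip

    def test_mar_is_95_percent_of_triplicate_minimum(self, small_design):
        out, trip = self._impute(small_design, [10.0, 12.0, None], seed=1)
        assert out.data.iloc[0][trip[2]] == pytest.approx(0.95 * 10.0)

    def test_mar_on_negative_centered_scale(self, small_design):
        out, trip = self._impute(small_design, [-2.0, -1.0, None], seed=1)
        assert out.data.iloc[0][trip[2]] == pytest.approx(0.95 * -2.0)

    def test_mar_raw_scale_alternative(self, small_design):
        out, trip = self._impute(small_design, [-2.0, -1.0, None], seed=1,
                                 mar_scale="raw")
        assert out.data.iloc[0][trip[2]] == pytest.approx(
            -2.0 + np.log2(0.95))

    def test_observed_values_unchanged_and_complete(self, study_design,
                                                    study_data):
        table, _ = study_data
        filtered = filter_peptides(table, study_design)
        tm = transform_and_center(filtered, study_design)
        mask = classify_missingness(tm, study_design)
        observed = tm.values.notna()
        out = impute_missing(tm, mask, study_design, seed=5)
        assert not out.values.isna().any().any()
        a = tm.values.to_numpy()
        b = out.values.to_numpy()
        np.testing.assert_array_equal(a[observed.to_numpy()],
                                      b[observed.to_numpy()])

    def test_mnar_draw_mean_matches_run_quantile(self, small_design):
        """10,000 MinProb draws have a sample mean within the 3-SE CLT
        band of the run's 0.5% observed quantile."""
        s = samples_of(small_design)
        trip = small_design.triplicates()[0][1]
        rng = np.random.default_rng(3)
        rows = []
        for i in range(10000):
            cells = {c: float(rng.uniform(4, 4096)) for c in s}
            cells.pop(trip[1])
            cells.pop(trip[2])          # two missing -> MNAR
            rows.append((f"p{i}", f"P{i}", False, False, 2, cells))
        t = make_peptide_table(small_design, rows)
        tm = transform_and_center(t, small_design)
        mask = classify_missingness(tm, small_design)
        out = impute_missing(tm, mask, small_design, sd_mnar=0.05, seed=8)
        run = small_design.runs[0]
        draws = out.values[trip[1]].to_numpy()
        se = 0.05 / np.sqrt(len(draws))
        assert abs(draws.mean() - tm.run_quantiles[run]) < 3 * se

    def test_mnar_determinism(self, small_design):
        a, trip = self._impute(small_design, [5.0, None, None], seed=42)
        b, _ = self._impute(small_design, [5.0, None, None], seed=42)
        assert a.data.iloc[0][trip[1]] == b.data.iloc[0][trip[1]]
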