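"""Preprocessing: max aggregation, detection filter, normalization, imputation."""

import numpy as np
import pandas as pd
import pytest

from cecselect.datamodel import ContaminantPanel, TEMPERATURE_RESPONSE
from cecselect.errors import ValidationError
from cecselect.preprocess import (aggregate_max_by_site, build_response_block,
                                  drop_undetected, impute_missing,
                                  median_normalize)

from conftest import make_matrix

COLS = ["site", "event", "analyte", "contaminant_class", "concentration",
        "censored", "detection_limit"]


def panel_from(rows, temps):
    return ContaminantPanel(records=pd.DataFrame(rows, columns=COLS),
                            site_temperature=temps)


class TestAggregateMaxBySite:
    def test_censored_contribute_zero_and_max_over_events(self):
        rows = [("P", "e1", "a", "ppcp", np.nan, True, 0.1),
                ("P", "e2", "a", "ppcp", 0.3, False, 0.1),
                ("P", "e3", "a", "ppcp", 0.5, False, 0.1)]
        agg = aggregate_max_by_site(panel_from(rows, {"P": [20.0]}))
        assert agg.max_concentration.loc["P", "a"] == 0.5
        assert agg.n_observations.loc["P", "a"] == 3

    def test_all_censored_aggregates_to_exactly_zero(self):
        rows = [("P", e, "a", "ppcp", np.nan, True, 0.1) for e in "123"]
        agg = aggregate_max_by_site(panel_from(rows, {"P": [20.0]}))
        assert agg.max_concentration.loc["P", "a"] == 0.0

    def test_temperature_is_site_maximum(self):
        rows = [("P", "e1", "a", "ppcp", 0.1, False, 0.1)]
        agg = aggregate_max_by_site(panel_from(rows, {"P": [19.5, 22.0, 21.0]}))
        assert agg.max_temperature["P"] == 22.0

    def test_site_without_temperature_rejected(self):
        rows = [("P", "e1", "a", "ppcp", 0.1, False, 0.1)]
        with pytest.raises(ValidationError, match="temperature"):
            aggregate_max_by_site(panel_from(rows, {}))

    def test_matches_bruteforce_nested_loops(self, small_study):
        panel, _, _ = small_study
        agg = aggregate_max_by_site(panel)
        df = panel.records
        for site in agg.sites:
            for analyte in agg.analytes:
                sub = df[(df["site"] == site) & (df["analyte"] == analyte)]
                expect = max((0.0 if c else v for v, c in
                              zip(sub["concentration"], sub["censored"])),
                             default=0.0)
                expect = max(expect, 0.0)
                assert agg.max_concentration.loc[site, analyte] == pytest.approx(
                    0.0 if np.isnan(expect) else expect, abs=0)
                assert agg.n_observations.loc[site, analyte] == len(sub)

    def test_idempotent_on_own_output(self, small_study):
        """Re-aggregating the aggregate (viewed as a 1-event panel) is a
        no-op."""
        panel, _, _ = small_study
        agg = aggregate_max_by_site(panel)
        rows = []
        for site in agg.sites:
            for analyte in agg.analytes:
                v = agg.max_concentration.loc[site, analyte]
                rows.append((site, "e1", analyte, "ppcp",
                             np.nan if v == 0 else v, v == 0, 0.001))
        again = aggregate_max_by_site(panel_from(
            rows, {s: [agg.max_temperature[s]] for s in agg.sites}))
        assert np.array_equal(again.max_concentration.to_numpy(),
                              agg.max_concentration.to_numpy())


class TestDropUndetected:
    def test_counts_on_study_shaped_panel(self):
        rows = []
        for i in range(220):
            detected = i < 69
            for site in ("P", "F"):
                rows.append((site, "e1", f"a{i:03d}", "ppcp",
                             0.5 if detected and site == "P" else np.nan,
                             not (detected and site == "P"), 0.1))
        filt = drop_undetected(aggregate_max_by_site(
            panel_from(rows, {"P": [20.0], "F": [19.0]})))
        assert len(filt.retained) == 69
        assert len(filt.dropped) == 151

    def test_identity_when_all_detected(self):
        rows = [("P", "e1", "a", "ppcp", 0.2, False, 0.1),
                ("P", "e1", "b", "ppcp", 0.4, False, 0.1)]
        agg = aggregate_max_by_site(panel_from(rows, {"P": [20.0]}))
        filt = drop_undetected(agg)
        assert filt.dropped == []
        assert filt.aggregate.analytes == agg.analytes

    def test_matches_bruteforce_scan(self, small_study):
        panel, _, _ = small_study
        agg = aggregate_max_by_site(panel)
        filt = drop_undetected(agg)
        expect = {a for a in agg.analytes
                  if any(agg.max_concentration[a] > 0)}
        assert set(filt.retained) == expect


class TestMedianNormalize:
    def test_simple_column(self):
        m = median_normalize(make_matrix([[2.0], [4.0], [8.0]], "PPF"))
        assert m.values["M1"].tolist() == [0.5, 1.0, 2.0]
        assert m.normalized

    def test_double_normalization_refused(self):
        m = median_normalize(make_matrix([[2.0], [4.0], [8.0]], "PPF"))
        with pytest.raises(ValidationError, match="already"):
            median_normalize(m)

    def test_random_matrix_medians_unit(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.lognormal(size=(32, 50)), "PFBG" * 8)
        out = median_normalize(m)
        med = np.median(out.values.to_numpy(), axis=0)
        assert np.abs(med - 1).max() < 1e-12

    def test_blockwise_removes_block_effect(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(size=(20, 10))
        vals = base.copy()
        vals[10:] *= 5.0   # strong run-day intensity shift
        m = make_matrix(vals, "PF" * 10, blocks=["d1"] * 10 + ["d2"] * 10)
        out = median_normalize(m)
        arr = out.values.to_numpy()
        for rows in (slice(0, 10), slice(10, 20)):
            assert np.abs(np.median(arr[rows], axis=0) - 1).max() < 1e-12
        # the x5 factor is gone: block medians coincide
        assert np.abs(np.median(arr[:10], axis=0)
                      - np.median(arr[10:], axis=0)).max() < 1e-12

    def test_all_missing_metabolite_named(self):
        vals = [[1.0, np.nan], [2.0, np.nan], [3.0, np.nan]]
        with pytest.raises(ValidationError, match="M2"):
            median_normalize(make_matrix(vals, "PPF"))


class TestImputeMissing:
    def test_minimum_mode(self):
        vals = [[0.5], [1.0], [np.nan], [2.0]]
        res = impute_missing(make_matrix(vals, "PPFF", normalized=False))
        assert res.n_imputed == 1
        assert res.matrix.values["M1"].iloc[2] == 0.5

    def test_half_minimum_mode(self):
        vals = [[0.5], [1.0], [np.nan], [2.0]]
        res = impute_missing(make_matrix(vals, "PPFF"), "half-minimum")
        assert res.matrix.values["M1"].iloc[2] == 0.25

    def test_identity_without_missing(self):
        vals = [[0.5], [1.0], [2.0]]
        m = make_matrix(vals, "PPF")
        res = impute_missing(m)
        assert res.n_imputed == 0
        assert np.array_equal(res.matrix.values.to_numpy(), m.values.to_numpy())

    def test_fail_on_missing_mode(self):
        vals = [[0.5], [np.nan], [2.0]]
        with pytest.raises(ValidationError, match="missing"):
            impute_missing(make_matrix(vals, "PPF"), "fail-on-missing")

    def test_random_missingness_filled_with_column_minimum(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(size=(20, 15))
        mask = rng.random(vals.shape) < 0.1
        mask[0] = False          # keep every column partially observed
        vals_m = vals.copy()
        vals_m[mask] = np.nan
        res = impute_missing(make_matrix(vals_m, "PF" * 10))
        col_min = np.nanmin(vals_m, axis=0)
        out = res.matrix.values.to_numpy()
        assert res.n_imputed == int(mask.sum())
        assert np.array_equal(out[mask], col_min[np.where(mask)[1]])


class TestBuildResponseBlock:
    def test_rows_repeat_site_aggregate(self):
        rows = [("P", "e1", "a", "ppcp", 0.2, False, 0.1),
                ("F", "e1", "a", "ppcp", 0.7, False, 0.1)]
        agg = drop_undetected(aggregate_max_by_site(
            panel_from(rows, {"P": [20.0], "F": [18.0]}))).aggregate
        m = make_matrix([[1.0]] * 4, "PPFF", normalized=True)
        block = build_response_block(agg, m)
        assert block.values.shape == (4, 2)
        assert block.response_names == ["a", TEMPERATURE_RESPONSE]
        assert block.values.iloc[0].tolist() == [0.2, 20.0]
        assert block.values.iloc[2].tolist() == [0.7, 18.0]

    def test_unknown_site_rejected(self):
        rows = [("P", "e1", "a", "ppcp", 0.2, False, 0.1)]
        agg = aggregate_max_by_site(panel_from(rows, {"P": [20.0]}))
        m = make_matrix([[1.0], [1.0], [1.0]], "PPX", normalized=True)
        with pytest.raises(ValidationError, match="X"):
            build_response_block(agg, m)

    def test_all_zero_column_rejected(self):
        rows = [("P", "e1", "a", "ppcp", np.nan, True, 0.1),
                ("F", "e1", "a", "ppcp", np.nan, True, 0.1)]
        agg = aggregate_max_by_site(panel_from(rows, {"P": [20.0], "F": [19.0]}))
        m = make_matrix([[1.0], [1.0]], "PF", normalized=True)
        with pytest.raises(ValidationError, match="drop_undetected"):
            build_response_block(agg, m)

    def test_equality_scan_on_synthetic_study(self, small_study):
        panel, matrix, _ = small_study
        filt = drop_undetected(aggregate_max_by_site(panel))
        imp = impute_missing(median_normalize(matrix))
        block = build_response_block(filt.aggregate, imp.matrix)
        wide = filt.aggregate.max_concentration.copy()
        wide[TEMPERATURE_RESPONSE] = filt.aggregate.max_temperature
        for sample in block.values.index:
            site = matrix.site_of[sample]
            assert np.array_equal(block.values.loc[sample].to_numpy(),
                                  wide.loc[site].to_numpy())
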