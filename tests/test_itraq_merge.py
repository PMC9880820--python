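"""Ratio assembly, replicate merging, median polish, and the variability filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import cortexatlas as ca
from cortexatlas.itraq_merge import RatioMatrix


def _batch(batch_id, rep, data, regions, reference="REF"):
    df = pd.DataFrame(data, index=[f"P{i}" for i in range(len(data))], columns=regions)
    return ca.BatchTable(batch_id, rep, df, reference)


class TestComputeReferenceRatios:
    design = {"ch1": "A", "ch2": "B", "ch3": "REF"}

    def test_ratio_arithmetic_and_reference_identity(self):
        intens = pd.DataFrame(
            {"ch1": [200.0, 50.0], "ch2": [400.0, 100.0], "ch3": [100.0, 100.0]},
            index=["P0", "P1"],
        )
        bt = ca.compute_reference_ratios(intens, self.design, "REF")
        assert bt.values.loc["P0", "A"] == 2.0
        assert bt.values.loc["P1", "B"] == 1.0
        assert (bt.values["REF"] == 1.0).all()

    def test_zero_reference_marks_row_missing(self):
        intens = pd.DataFrame(
            {"ch1": [200.0, 50.0], "ch2": [400.0, 100.0], "ch3": [0.0, 100.0]},
            index=["P0", "P1"],
        )
        bt = ca.compute_reference_ratios(intens, self.design, "REF")
        assert bt.values.loc["P0"].isna().all()
        assert not bt.values.loc["P1"].isna().any()

    def test_missing_reference_channel_is_design_error(self):
        intens = pd.DataFrame({"ch1": [1.0], "ch2": [1.0]}, index=["P0"])
        with pytest.raises(ValueError, match="reference"):
            ca.compute_reference_ratios(intens, {"ch1": "A", "ch2": "B"}, "REF")


class TestMergeBatches:
    def test_replicate_averaging_is_linear_then_log2(self):
        """Replicate ratios 1.0 and 4.0 merge to log2(2.5)."""
        t1 = _batch("B1", "r1", [[1.0, 1.0]], ["A", "REF"])
        t2 = _batch("B1", "r2", [[4.0, 1.0]], ["A", "REF"])
        merged = ca.merge_batches([t1, t2])
        assert merged.values.loc["P0", "A"] == pytest.approx(np.log2(2.5))
        assert merged.values.loc["P0", "REF"] == 0.0
        log_merged = ca.merge_batches([t1, t2], avg_scale="log")
        assert log_merged.values.loc["P0", "A"] == pytest.approx(1.0)  # mean of log2(1), log2(4)

    def test_protein_missing_in_one_replicate_dropped(self):
        t1 = _batch("B1", "r1", [[2.0, 1.0], [3.0, 1.0]], ["A", "REF"])
        t2 = _batch("B1", "r2", [[2.0, 1.0], [np.nan, np.nan]], ["A", "REF"])
        t3 = _batch("B2", "r1", [[2.0, 1.0], [3.0, 1.0]], ["B", "REF"])
        t4 = _batch("B2", "r2", [[2.0, 1.0], [3.0, 1.0]], ["B", "REF"])
        merged = ca.merge_batches([t1, t2, t3, t4])
        assert list(merged.values.index) == ["P0"]
        assert merged.values.isna().sum().sum() == 0

    def test_duplicate_region_across_batches_rejected(self):
        t1 = _batch("B1", "r1", [[2.0, 1.0]], ["A", "REF"])
        t2 = _batch("B2", "r1", [[2.0, 1.0]], ["A", "REF"])
        with pytest.raises(ValueError, match="appears in batches"):
            ca.merge_batches([t1, t2])

    def test_reference_column_zero_before_normalization(self, merged):
        assert (merged.values[merged.provenance["reference_region"]] == 0.0).all()


# hand-polished oracles: (input, expected fixed point)
_POLISH_CASES = [
    ([[1.0, 2.0], [3.0, 4.0]], [[0.0, 0.0], [0.0, 0.0]]),
    # col medians [4,6,8] then row medians [-4,0,14], both zero afterwards
    ([[1.0, 2.0, 3.0], [4.0, 6.0, 8.0], [10.0, 20.0, 30.0]],
     [[1.0, 0.0, -1.0], [0.0, 0.0, 0.0], [-8.0, 0.0, 8.0]]),
]


class TestMedianNormalize:
    @pytest.mark.parametrize("data,expected", _POLISH_CASES)
    def test_hand_polish_oracle(self, data, expected):
        out = ca.median_normalize(RatioMatrix(pd.DataFrame(data)))
        np.testing.assert_allclose(out.values.to_numpy(), expected, atol=1e-9)

    def test_fixed_point_unchanged(self):
        data = pd.DataFrame([[1.0, 0.0, -1.0], [0.0, 0.0, 0.0], [-8.0, 0.0, 8.0]])
        out = ca.median_normalize(RatioMatrix(data))
        np.testing.assert_allclose(out.values.to_numpy(), data.to_numpy(), atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ca.median_normalize(RatioMatrix(pd.DataFrame([[1.0, np.inf]])))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            st.tuples(st.integers(2, 8), st.integers(2, 8)),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    def test_postcondition_and_idempotence(self, vals):
        """After polishing, all row and column medians are ~0 and a second
        polish is a no-op."""
        out = ca.median_normalize(RatioMatrix(pd.DataFrame(vals)))
        v = out.values.to_numpy()
        assert np.abs(np.median(v, axis=0)).max() <= 1e-9
        assert np.abs(np.median(v, axis=1)).max() <= 1e-9
        again = ca.median_normalize(out)
        np.testing.assert_allclose(again.values.to_numpy(), v, atol=1e-9)


class TestVariabilityFilter:
    def test_constant_row_excluded_and_range_rule(self):
        df = pd.DataFrame(
            {
                "A": [0.0, -0.6, 0.0],
                "B": [0.0, 0.6, 0.4],
                "C": [0.0, 0.0, -0.4],
            },
            index=["flat", "wide", "narrow"],
        )
        res = ca.variability_filter(RatioMatrix(df, normalized=True), min_log2_range=1.0)
        assert res.retained_ids == ["wide"]  # range 1.2 >= 1; others 0 and 0.8

    def test_invariant_to_row_and_column_shifts(self, normalized):
        res = ca.variability_filter(normalized)
        shifted = normalized.values.copy()
        shifted.iloc[0] += 3.0  # full-row shift: range unchanged
        res2 = ca.variability_filter(RatioMatrix(shifted, normalized=True))
        assert res.retained_ids == res2.retained_ids
        shifted_col = normalized.values.add(
            pd.Series(2.0, index=normalized.values.columns), axis=1
        )
        res3 = ca.variability_filter(RatioMatrix(shifted_col, normalized=True))
        assert res.retained_ids == res3.retained_ids

    def test_planted_signatures_pass(self, default_atlas, merged, variable):
        """>= 95% of planted signature proteins that survive the merge pass
        the FC>2 filter at the default effect size and noise."""
        _, _, truth = default_atlas
        planted = (truth.all_cluster_signatures | truth.all_ba_signatures) & set(
            merged.protein_ids
        )
        passed = planted & set(variable.retained_ids)
        assert len(passed) / len(planted) >= 0.95

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ca.variability_filter(RatioMatrix(pd.DataFrame()))


class TestBatchCv:
    def test_identical_replicates_zero_cv(self):
        t1 = _batch("B1", "r1", [[2.0, 1.0], [3.0, 1.0]], ["A", "REF"])
        t2 = _batch("B1", "r2", [[2.0, 1.0], [3.0, 1.0]], ["A", "REF"])
        assert ca.batch_cv([t1, t2]) == {"B1": 0.0}

    def test_hand_cv(self):
        """Replicates 90 and 110 give CV = sample sd / mean ~ 0.1414."""
        t1 = _batch("B1", "r1", [[90.0, 1.0]], ["A", "REF"])
        t2 = _batch("B1", "r2", [[110.0, 1.0]], ["A", "REF"])
        assert ca.batch_cv([t1, t2])["B1"] == pytest.approx(np.sqrt(2) * 10 / 100)

    def test_single_replicate_rejected(self):
        t1 = _batch("B1", "r1", [[2.0, 1.0]], ["A", "REF"])
        with pytest.raises(ValueError, match="single replicate"):
            ca.batch_cv([t1])

    def test_lognormal_noise_gives_expected_median_cv(self):
        """log2 noise of 0.09 per channel corresponds to a median replicate
        CV in the 4-9% range."""
        cfg = ca.AtlasConfig(noise_sd=0.09, missing_rate=0.0, n_proteins=1000, seed=8)
        tables, _ = ca.generate_proteome(cfg)
        bts = [
            ca.compute_reference_ratios(
                t.intensities, t.channel_design, t.reference_region, t.batch_id, t.replicate_id
            )
            for t in tables
        ]
        cvs = ca.batch_cv(bts)
        assert all(0.04 <= v <= 0.09 for v in cvs.values())
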