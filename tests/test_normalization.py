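"""Normalization chains: log-CPM, quantile normalization, protein rollup."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromalink.normalization import (
    average_replicates,
    gene_body_rpkm,
    log_cpm,
    normalize_atac,
    quantile_normalize,
    rollup_protein,
    transform_rna,
)


def _single_column(counts):
    return pd.DataFrame({"s1": counts}, index=[f"f{i}" for i in range(len(counts))])


class TestLogCpm:
    def test_hand_computed_values(self):
        # library 1e6 -> scaled prior 5; zero count and c=995
        counts = _single_column([0, 995, 1_000_000 - 995])
        out = log_cpm(counts)
        assert out.iloc[0, 0] == pytest.approx(np.log2(5 / 1_000_010 * 1e6), abs=1e-9)
        assert out.iloc[0, 0] == pytest.approx(2.3219, abs=1e-3)
        assert out.iloc[1, 0] == pytest.approx(np.log2(1000 / 1_000_010 * 1e6), abs=1e-9)
        assert out.iloc[1, 0] == pytest.approx(9.9657, abs=1e-3)

    def test_scale_invariance_in_prior_limit(self):
        counts = _single_column([10, 90, 900])
        a = log_cpm(counts, prior=1e-9)
        b = log_cpm(2 * counts, prior=1e-9)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)

    @given(st.lists(st.integers(0, 10_000), min_size=3, max_size=12))
    def test_strictly_monotone_within_column(self, counts):
        if sum(counts) == 0:
            counts[0] = 1
        out = log_cpm(_single_column(counts)).iloc[:, 0].to_numpy()
        order = np.argsort(counts, kind="mergesort")
        diffs = np.diff(np.array(counts)[order])
        vals = np.diff(out[order])
        assert np.all(vals[diffs > 0] > 0)
        assert np.allclose(vals[diffs == 0], 0)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            log_cpm(_single_column([0, 0, 0]))


class TestQuantileNormalize:
    def test_two_column_sort_average_oracle(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [4.0, 2.0]}, index=["r1", "r2"])
        out = quantile_normalize(m)
        # reference distribution: mean of sorted columns = [1.5, 3.5]
        assert out["a"].tolist() == [1.5, 3.5]
        assert out["b"].tolist() == [3.5, 1.5]

    def test_identical_columns_are_a_fixed_point(self):
        m = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        assert np.allclose(quantile_normalize(m).to_numpy(), m.to_numpy())

    def test_ties_get_mean_of_tied_reference_quantiles(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 10.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].tolist() == [
            pytest.approx((ref[0] + ref[1]) / 2),
            pytest.approx((ref[0] + ref[1]) / 2),
            pytest.approx(ref[2]),
        ]

    @given(
        st.lists(
            st.lists(
                st.floats(-50, 50, allow_nan=False), min_size=5, max_size=5,
                unique=True,
            ),
            min_size=2,
            max_size=5,
        )
    )
    def test_columns_share_sorted_multiset(self, cols):
        # tie-free columns: tie-averaging intentionally departs from the
        # shared multiset for tied values (see the dedicated tie test)
        m = pd.DataFrame({f"c{i}": v for i, v in enumerate(cols)})
        out = quantile_normalize(m).to_numpy()
        first = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            assert np.allclose(np.sort(out[:, j]), first)
        assert np.allclose(out.mean(axis=0), out.mean(axis=0)[0])


class TestReplicateAveraging:
    def test_mean_of_replicates(self):
        m = pd.DataFrame({"x_r1": [2.0], "x_r2": [4.0], "y_r1": [1.0], "y_r2": [2.0], "y_r3": [6.0]})
        out = average_replicates(m, {"x": ["x_r1", "x_r2"], "y": ["y_r1", "y_r2", "y_r3"]})
        assert out.loc[0, "x"] == 3.0
        assert out.loc[0, "y"] == 3.0

    def test_single_replicate_identity(self):
        m = pd.DataFrame({"x_r1": [2.5, 7.0]})
        out = average_replicates(m, {"x": ["x_r1"]})
        assert out["x"].tolist() == [2.5, 7.0]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            average_replicates(pd.DataFrame({"a": [1.0]}), {"x": []})

    def test_atac_chain_duplicate_replicates_equal_deduplicated(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(
            rng.poisson(50, size=(40, 3)).astype(float), columns=["a", "b", "c"]
        )
        dup = pd.concat(
            [base.rename(columns={c: f"{c}_r1" for c in base})],
            axis=1,
        )
        dup = pd.concat(
            [dup, base.rename(columns={c: f"{c}_r2" for c in base})], axis=1
        )
        chained = normalize_atac(
            dup, {c: [f"{c}_r1", f"{c}_r2"] for c in base.columns}
        )
        single = normalize_atac(base, {c: [c] for c in base.columns})
        assert np.allclose(chained[base.columns].to_numpy(), single.to_numpy())


def _pep(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "peptide_id", "gene_id", "run_id", "channel_id", "sample_id",
            "is_reference", "intensity",
        ],
    )


class TestProteinRollup:
    def test_hand_computed_ratio(self):
        # channel totals equal (500 vs 500) so rescaling is a no-op;
        # gene G: (100+300)/(50+150) = 2 -> log2 = 1
        table = _pep(
            [
                ("p1", "G", "run1", "ch1", "s1", False, 100.0),
                ("p2", "G", "run1", "ch1", "s1", False, 300.0),
                ("p1", "G", "run1", "ref", "", True, 50.0),
                ("p2", "G", "run1", "ref", "", True, 150.0),
                ("p3", "H", "run1", "ch1", "s1", False, 100.0),
                ("p3", "H", "run1", "ref", "", True, 300.0),
            ]
        )
        out = rollup_protein(table)
        assert out.loc["G", "s1"] == pytest.approx(1.0)
        assert out.loc["H", "s1"] == pytest.approx(np.log2(100 / 300))

    def test_channel_rescaled_to_reference_total(self):
        # sample-channel total 500 vs reference total 1000 -> factor 2
        table = _pep(
            [
                ("p1", "G", "run1", "ch1", "s1", False, 500.0),
                ("p1", "G", "run1", "ref", "", True, 1000.0),
            ]
        )
        out = rollup_protein(table)
        assert out.loc["G", "s1"] == pytest.approx(0.0)  # 500*2 / 1000

    def test_missing_peptide_filled_with_run_minimum(self):
        table = _pep(
            [
                ("p1", "G", "run1", "ch1", "s1", False, np.nan),
                ("p2", "G", "run1", "ch1", "s1", False, 40.0),
                ("p1", "G", "run1", "ref", "", True, 10.0),
                ("p2", "G", "run1", "ref", "", True, 40.0),
            ]
        )
        out = rollup_protein(table)
        # run minimum is 10 -> sample sums 50, ref sums 50, after rescale
        assert out.loc["G", "s1"] == pytest.approx(0.0)

    def test_gene_absent_from_run_is_nan_not_zero(self):
        table = _pep(
            [
                ("p1", "G", "run1", "ch1", "s1", False, 100.0),
                ("p1", "G", "run1", "ref", "", True, 100.0),
                ("p2", "H", "run2", "ch2", "s2", False, 100.0),
                ("p2", "H", "run2", "ref", "", True, 100.0),
            ]
        )
        out = rollup_protein(table)
        assert np.isnan(out.loc["G", "s2"])
        assert np.isnan(out.loc["H", "s1"])

    def test_replicates_averaged_after_log2(self):
        # channel totals balanced by gene H so rescaling is a no-op in
        # both runs; G measures log2(4) in run1 and log2(1) in run2
        table = _pep(
            [
                ("p1", "G", "run1", "ch1", "s1", False, 400.0),
                ("p1", "G", "run1", "ref", "", True, 100.0),
                ("p2", "H", "run1", "ch1", "s1", False, 100.0),
                ("p2", "H", "run1", "ref", "", True, 400.0),
                ("p1", "G", "run2", "ch1", "s1", False, 100.0),
                ("p1", "G", "run2", "ref", "", True, 100.0),
                ("p2", "H", "run2", "ch1", "s1", False, 100.0),
                ("p2", "H", "run2", "ref", "", True, 100.0),
            ]
        )
        out = rollup_protein(table)
        assert out.loc["G", "s1"] == pytest.approx((np.log2(4) + 0.0) / 2)
        assert out.loc["H", "s1"] == pytest.approx((np.log2(0.25) + 0.0) / 2)

    def test_row_order_and_peptide_split_invariance(self):
        rng = np.random.default_rng(1)
        rows = []
        for g in ("G", "H"):
            for pj in range(3):
                rows.append((f"{g}{pj}", g, "run1", "ch1", "s1", False, float(rng.integers(10, 500))))
                rows.append((f"{g}{pj}", g, "run1", "ref", "", True, float(rng.integers(10, 500))))
        table = _pep(rows)
        shuffled = table.sample(frac=1.0, random_state=2)
        # split one peptide row into two summing to the same intensity
        extra = table.iloc[[0]].assign(intensity=table.iloc[0]["intensity"] / 2)
        split = pd.concat(
            [table.assign(
                intensity=np.where(
                    np.arange(len(table)) == 0, table["intensity"] / 2, table["intensity"]
                )
            ), extra],
            ignore_index=True,
        )
        base = rollup_protein(table)
        pd.testing.assert_frame_equal(base, rollup_protein(shuffled))
        pd.testing.assert_frame_equal(base, rollup_protein(split))

    def test_run_without_reference_rejected(self):
        with pytest.raises(ValueError):
            rollup_protein(_pep([("p1", "G", "run1", "ch1", "s1", False, 1.0)]))


class TestGeneBodyRpkm:
    def test_hand_computed_rpkm(self):
        counts = pd.DataFrame({"s1": [100]}, index=["g1"])
        out = gene_body_rpkm(counts, {"g1": 2_000}, {"s1": 1e7}, quantile=False)
        assert out.loc["g1", "s1"] == pytest.approx(5.0)

    def test_depth_invariance(self):
        counts = pd.DataFrame({"s1": [100]}, index=["g1"])
        a = gene_body_rpkm(counts, {"g1": 2_000}, {"s1": 1e7}, quantile=False)
        b = gene_body_rpkm(2 * counts, {"g1": 2_000}, {"s1": 2e7}, quantile=False)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_length_normalization_ratio(self):
        counts = pd.DataFrame({"s1": [100, 100]}, index=["g1", "g2"])
        out = gene_body_rpkm(
            counts, {"g1": 1_000, "g2": 2_000}, {"s1": 1e6}, quantile=False
        )
        assert out.loc["g1", "s1"] == pytest.approx(2 * out.loc["g2", "s1"])

    def test_zero_length_gene_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            gene_body_rpkm(counts, {"g1": 0}, {"s1": 1e6})


def test_transform_rna_delegates_to_log_cpm():
    counts = _single_column([0, 10, 100])
    pd.testing.assert_frame_equal(transform_rna(counts), log_cpm(counts))
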