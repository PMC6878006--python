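"""Reporter normalization, PSM-to-protein aggregation, replicate merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfmap import aggregate_protein, build_profiles, merge_replicates, normalize_spectrum
from sfmap.errors import PipelineError, SpectrumRejected
from sfmap.ingest import (
    CHANNEL_COLS,
    PROFILE_COLS,
    REPORTER_COLS,
    profile_matrix,
    read_merged_profiles,
    read_psm_table,
    write_profile_table,
)


class TestNormalizeSpectrum:
    @pytest.mark.parametrize(
        "reporters, expected",
        [
            (np.full(10, 500.0), np.full(10, 0.1)),
            (np.eye(10)[0], np.eye(10)[0]),
            (
                np.array([1, 2, 3, 4, 0, 0, 0, 0, 0, 0], dtype=float),
                np.array([0.1, 0.2, 0.3, 0.4, 0, 0, 0, 0, 0, 0]),
            ),
        ],
        ids=["uniform", "indicator", "ratio-to-sum"],
    )
    def test_ratio_to_sum(self, reporters, expected):
        np.testing.assert_allclose(normalize_spectrum(reporters), expected)

    @pytest.mark.parametrize(
        "reporters",
        [np.zeros(10), np.append(np.ones(9), -1.0), np.append(np.ones(9), np.nan), np.ones(8)],
        ids=["all-zero", "negative", "nan", "short"],
    )
    def test_unquantifiable_spectra_rejected(self, reporters):
        with pytest.raises(SpectrumRejected):
            normalize_spectrum(reporters)

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=10, max_size=10)
    )
    @settings(max_examples=50, derandomize=True)
    def test_output_is_composition(self, values):
        out = normalize_spectrum(np.array(values))
        assert abs(out.sum() - 1.0) < 1e-9
        assert (out >= 0).all()


class TestAggregateProtein:
    def test_single_psm_passes_through(self):
        psm = np.array([[1, 2, 3, 4, 0, 0, 0, 0, 0, 0]], dtype=float)
        np.testing.assert_allclose(
            aggregate_protein(psm), normalize_spectrum(psm[0])
        )

    def test_channelwise_median(self):
        # channel-1 normalized values {0.1, 0.2, 0.9} -> median 0.2
        rows = []
        for v in (0.1, 0.2, 0.9):
            row = np.full(10, (1 - v) / 9)
            row[0] = v
            rows.append(row)
        medians = np.median(np.stack(rows), axis=0)
        expected = medians / medians.sum()
        np.testing.assert_allclose(aggregate_protein(np.stack(rows)), expected)
        assert abs(medians[0] - 0.2) < 1e-12

    def test_median_then_renormalize(self):
        # hand-computed: medians of {(.5,.5,0,...), (.5,.5,0,...), (0,0,1,0,...)}
        psms = np.zeros((3, 10))
        psms[0, :2] = psms[1, :2] = 0.5
        psms[2, 2] = 1.0
        out = aggregate_protein(psms)
        expected = np.zeros(10)
        expected[:2] = 0.5
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_psm_order_invariance(self):
        rng = np.random.default_rng(0)
        psms = rng.uniform(0.1, 10, size=(7, 10))
        base = aggregate_protein(psms)
        for _ in range(5):
            perm = rng.permutation(7)
            np.testing.assert_array_equal(aggregate_protein(psms[perm]), base)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            aggregate_protein(np.empty((0, 10)))


class TestMergeReplicates:
    @staticmethod
    def frame(ids):
        rng = np.random.default_rng(1)
        vals = rng.dirichlet(np.ones(10), size=len(ids))
        df = pd.DataFrame(vals, index=pd.Index(ids, name="protein_id"),
                          columns=CHANNEL_COLS)
        df["n_psms"] = 1
        return df

    def test_intersection_and_dropped(self):
        merged, dropped = merge_replicates(self.frame(["a", "b"]), self.frame(["b", "c"]))
        assert list(merged.index) == ["b"]
        assert dropped == ["a", "c"]

    def test_identical_inputs_keep_everything(self):
        f = self.frame(["a", "b", "c"])
        merged, dropped = merge_replicates(f, f)
        assert len(merged) == 3 and dropped == []

    def test_disjoint_inputs_fail(self):
        with pytest.raises(PipelineError):
            merge_replicates(self.frame(["a"]), self.frame(["b"]))

    def test_combined_is_concatenation(self):
        f1, f2 = self.frame(["a", "b"]), self.frame(["a", "b"])
        merged, _ = merge_replicates(f1, f2)
        np.testing.assert_array_equal(
            profile_matrix(merged)[:, :10], f1[CHANNEL_COLS].to_numpy()
        )
        np.testing.assert_array_equal(
            profile_matrix(merged)[:, 10:], f2[CHANNEL_COLS].to_numpy()
        )


class TestEndToEndIngest:
    def test_profile_blocks_sum_to_one(self, small_dataset):
        profiles, _ = build_profiles(small_dataset.psm_table)
        X = profile_matrix(profiles)
        assert X.shape[1] == 20
        np.testing.assert_allclose(X[:, :10].sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(X[:, 10:].sum(axis=1), 1.0, atol=1e-9)

    def test_unquantifiable_psms_dropped_not_fatal(self, small_dataset):
        psms = small_dataset.psm_table.copy()
        psms.loc[psms.index[0], REPORTER_COLS] = 0.0  # all-zero spectrum
        psms.loc[psms.index[1], REPORTER_COLS[3]] = np.nan
        profiles, _ = build_profiles(psms)
        assert len(profiles) > 0

    def test_round_trip_precision(self, small_dataset, tmp_path):
        profiles, _ = build_profiles(small_dataset.psm_table)
        path = tmp_path / "profiles.csv"
        write_profile_table(profiles, path)
        back = read_merged_profiles(path)
        np.testing.assert_allclose(
            profile_matrix(back), profile_matrix(profiles), atol=1e-12
        )

    def test_unknown_replicate_label_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"protein_group_id": ["p1"], "replicate": ["rep3"],
             **{c: [1.0] for c in REPORTER_COLS}}
        )
        path = tmp_path / "psms.csv"
        df.to_csv(path, index=False)
        with pytest.raises(PipelineError, match="replicate"):
            read_psm_table(path)
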