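import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from channelpat import (
    DatasetManifest,
    EegSegment,
    build_feature_matrix,
    extract_features,
    pair_code,
    save_segment,
)
from channelpat.features import feature_names
from channelpat.transform import RankSequence


def brute_force_counts(values: np.ndarray, c: int) -> np.ndarray:
    """Count each ordered pair (a, b) by scanning the sequence."""
    counts = np.zeros(c * c, dtype=int)
    for a in range(1, c + 1):
        for b in range(1, c + 1):
            hits = sum(
                1
                for i in range(len(values) - 1)
                if values[i] == a and values[i + 1] == b
            )
            counts[c * (a - 1) + (b - 1)] = hits
    return counts


class TestPairCode:
    @pytest.mark.parametrize(
        "a, b, c, code", [(1, 1, 14, 0), (14, 14, 14, 195), (2, 1, 14, 14), (5, 6, 14, 61)]
    )
    def test_known_codes(self, a, b, c, code):
        assert pair_code(a, b, c) == code

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            pair_code(0, 1, 14)
        with pytest.raises(ValueError):
            pair_code(1, 15, 14)

    def test_bijective_over_all_pairs(self):
        codes = {pair_code(a, b, 14) for a in range(1, 15) for b in range(1, 15)}
        assert codes == set(range(196))


class TestExtract:
    def test_hand_coded_pairs(self):
        fv = extract_features([2, 1, 1, 2], n_channels=14)
        nonzero = {i + 1: int(c) for i, c in enumerate(fv.counts) if c}
        assert nonzero == {15: 1, 1: 1, 2: 1}

    def test_vector_length_and_sum(self, rng):
        n = 10
        blocks = np.stack([rng.permutation(14) + 1 for _ in range(n)])
        ranks = RankSequence(values=blocks.ravel(), n_channels=14)
        fv = extract_features(ranks)
        assert fv.counts.shape == (196,)
        assert fv.counts.sum() == 14 * n - 1

    def test_too_short(self):
        with pytest.raises(ValueError):
            extract_features([1], n_channels=3)

    @settings(max_examples=200, deadline=None)
    @given(
        st.integers(2, 6).flatmap(
            lambda c: st.tuples(
                st.just(c), st.lists(st.integers(1, c), min_size=2, max_size=40)
            )
        )
    )
    def test_conservation_and_oracle(self, c_and_values):
        c, values = c_and_values
        fv = extract_features(values, n_channels=c)
        assert fv.counts.sum() == len(values) - 1
        np.testing.assert_array_equal(fv.counts, brute_force_counts(np.array(values), c))

    @settings(max_examples=100, deadline=None)
    @given(
        st.integers(2, 5).flatmap(
            lambda c: st.tuples(
                st.just(c), st.lists(st.integers(1, c), min_size=2, max_size=30)
            )
        )
    )
    def test_reversal_transposes_pair_table(self, c_and_values):
        c, values = c_and_values
        fwd = extract_features(values, n_channels=c).as_table()
        rev = extract_features(values[::-1], n_channels=c).as_table()
        np.testing.assert_array_equal(rev, fwd.T)


class TestFeatureMatrix:
    def _segments(self, rng, n, c=14):
        return [
            EegSegment(rng.normal(size=(c, 8)), [f"ch{i}" for i in range(c)], f"s{i}")
            for i in range(n)
        ]

    def test_shape(self, rng):
        segs = self._segments(rng, 4)
        fm = build_feature_matrix(segments=segs, labels=["A", "B", "A", "B"])
        assert fm.X.shape == (4, 196)
        assert len(feature_names(14)) == 196

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_feature_matrix(segments=[], labels=[])

    def test_identical_segments_identical_rows(self, rng):
        data = rng.normal(size=(14, 8))
        segs = [EegSegment(data.copy(), [f"ch{i}" for i in range(14)], f"s{i}") for i in range(2)]
        fm = build_feature_matrix(segments=segs, labels=["A", "A"])
        np.testing.assert_array_equal(fm.X[0], fm.X[1])

    def test_mixed_channel_counts_rejected(self, rng):
        segs = [
            EegSegment(rng.normal(size=(3, 5)), ["a", "b", "c"]),
            EegSegment(rng.normal(size=(4, 5)), ["a", "b", "c", "d"]),
        ]
        with pytest.raises(ValueError, match="channels"):
            build_feature_matrix(segments=segs, labels=["A", "B"])

    def test_manifest_order_preserved(self, tmp_path, rng):
        entries = []
        for i, lab in enumerate(["B", "A", "B"]):
            p = tmp_path / f"seg{i}.csv"
            save_segment(
                EegSegment(rng.normal(size=(3, 6)), ["x", "y", "z"], f"seg{i}"), p
            )
            entries.append((p, lab))
        fm = build_feature_matrix(DatasetManifest(entries=entries))
        assert fm.labels == ["B", "A", "B"]
        assert fm.segment_ids == ["seg0", "seg1", "seg2"]

    def test_frame_round_trip(self, rng):
        from channelpat.features import FeatureMatrix

        segs = self._segments(rng, 3)
        fm = build_feature_matrix(segments=segs, labels=["A", "B", "A"])
        back = FeatureMatrix.from_frame(fm.to_frame())
        np.testing.assert_array_equal(back.X, fm.X)
        assert back.labels == fm.labels
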