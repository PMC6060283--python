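"""Ordinal-pattern and permutation-entropy unit and property tests.

The reference implementation is checked against an independent
brute-force oracle that enumerates embedding windows with plain Python
sorting, and against hand-computed values for the classic worked
example series (4, 7, 9, 10, 6, 11, 3).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pesp.errors import ConfigurationError, ValidationError
from pesp.ordinal_entropy import (
    EntropyConfig,
    PatternDistribution,
    entropy_variant,
    n_windows,
    ordinal_pattern,
    pattern_distribution,
    permutation_entropy,
    read_feature_series,
    sliding_feature_matrix,
    write_feature_series,
)
from pesp.signal_io import Recording


def brute_force_pe(series, m, lam):
    """Independent oracle: explicit window loop, stable sort by (value, index)."""
    series = list(series)
    n_vec = len(series) - (m - 1) * lam
    counts = {}
    for i in range(n_vec):
        window = [series[i + j * lam] for j in range(m)]
        pattern = tuple(sorted(range(1, m + 1), key=lambda j: (window[j - 1], j)))
        counts[pattern] = counts.get(pattern, 0) + 1
    probs = [c / n_vec for c in counts.values()]
    h = -sum(p * math.log(p) for p in probs)
    return counts, h / math.log(math.factorial(m))


class TestOrdinalPattern:
    @pytest.mark.parametrize(
        "vector, expected",
        [
            ((1, 2, 3, 4), (1, 2, 3, 4)),
            ((5, 5, 5), (1, 2, 3)),  # ties keep ascending index order
            ((9, 10, 6), (3, 1, 2)),
            ((3, 1, 2), (2, 3, 1)),
            ((2, 1, 1), (2, 3, 1)),
        ],
    )
    def test_known_patterns(self, vector, expected):
        assert ordinal_pattern(np.array(vector, dtype=float)) == expected

    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            ordinal_pattern(np.array([1.0, np.nan, 2.0]))


class TestPatternDistribution:
    def test_worked_example_counts(self):
        dist = pattern_distribution(np.array([4, 7, 9, 10, 6, 11, 3]), EntropyConfig(m=3))
        assert dist.n_vectors == 5
        assert dist.counts == {(1, 2, 3): 2, (3, 1, 2): 2, (2, 1, 3): 1}

    def test_monotone_series_single_pattern(self):
        for m in (2, 3, 4, 5):
            dist = pattern_distribution(np.arange(30.0), EntropyConfig(m=m))
            assert dist.counts == {tuple(range(1, m + 1)): 30 - (m - 1)}

    def test_boundary_single_vector(self):
        dist = pattern_distribution(np.array([3.0, 1.0, 2.0, 5.0]), EntropyConfig(m=2, lam=3))
        assert dist.n_vectors == 1

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            pattern_distribution(np.array([1.0, 2.0]), EntropyConfig(m=4))


class TestPermutationEntropy:
    def test_worked_example_value(self):
        dist = pattern_distribution(np.array([4, 7, 9, 10, 6, 11, 3]), EntropyConfig(m=3))
        expected = -(2 * 0.4 * math.log(0.4) + 0.2 * math.log(0.2)) / math.log(6)
        assert permutation_entropy(dist, 3) == pytest.approx(expected, abs=1e-12)
        assert permutation_entropy(dist, 3) == pytest.approx(0.589, abs=5e-4)

    def test_monotone_gives_zero(self):
        dist = pattern_distribution(np.arange(50.0), EntropyConfig(m=4))
        assert permutation_entropy(dist, 4) == 0.0

    def test_uniform_distribution_gives_one(self):
        m = 3
        counts = {}
        import itertools

        for perm in itertools.permutations(range(1, m + 1)):
            counts[perm] = 7
        dist = PatternDistribution(counts=counts, n_vectors=7 * 6)
        assert permutation_entropy(dist, m) == pytest.approx(1.0, abs=1e-12)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValidationError):
            permutation_entropy(PatternDistribution(counts={}, n_vectors=0), 3)

    def test_brute_force_equivalence_random_series(self):
        """Pipeline PE equals independent enumeration to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(15, 51))
            series = rng.normal(size=n)
            m = int(rng.integers(2, 6))
            lam = int(rng.integers(1, 4))
            if n < (m - 1) * lam + 1:
                continue
            dist = pattern_distribution(series, EntropyConfig(m=m, lam=lam))
            oracle_counts, oracle_pe = brute_force_pe(series, m, lam)
            assert dist.counts == oracle_counts
            assert permutation_entropy(dist, m) == pytest.approx(oracle_pe, abs=1e-12)

    def test_iid_noise_is_nearly_maximal(self):
        rng = np.random.default_rng(7)
        series = rng.uniform(size=100_000)
        dist = pattern_distribution(series, EntropyConfig(m=4, lam=1))
        assert permutation_entropy(dist, 4) > 0.99

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        data=st.lists(st.integers(-1000, 1000), min_size=10, max_size=40),
        scale=st.floats(0.1, 100.0),
        shift=st.floats(-50.0, 50.0),
    )
    def test_invariance_under_monotone_affine_maps(self, data, scale, shift):
        """PE is rank-based: positive scaling and shifts change nothing.

        Integer-valued series keep the tie structure exact under the
        affine map, so the pattern counts must match exactly.
        """
        series = np.asarray(data, dtype=float)
        cfg = EntropyConfig(m=3)
        base = pattern_distribution(series, cfg)
        mapped = pattern_distribution(scale * series + shift, cfg)
        assert base.counts == mapped.counts

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        dist = pattern_distribution(rng.normal(size=500), EntropyConfig(m=4))
        assert dist.probabilities().sum() == pytest.approx(1.0, abs=1e-12)


class TestEntropyVariants:
    def _uniform(self, m):
        import itertools

        return PatternDistribution(
            counts={p: 3 for p in itertools.permutations(range(1, m + 1))},
            n_vectors=3 * math.factorial(m),
        )

    def _single(self, m):
        return PatternDistribution(counts={tuple(range(1, m + 1)): 9}, n_vectors=9)

    @pytest.mark.parametrize("measure", ["TPE", "RPE", "MPE"])
    def test_degenerate_distribution_gives_zero(self, measure):
        assert entropy_variant(self._single(4), 4, measure, q=2.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("measure", ["TPE", "RPE", "MPE"])
    def test_uniform_distribution_gives_one(self, measure):
        assert entropy_variant(self._uniform(3), 3, measure, q=2.0) == pytest.approx(1.0, abs=1e-12)

    def test_renyi_limit_recovers_shannon(self):
        """RPE -> PE as q -> 1 on the worked-example distribution."""
        dist = pattern_distribution(np.array([4, 7, 9, 10, 6, 11, 3]), EntropyConfig(m=3))
        pe = permutation_entropy(dist, 3)
        for q in (1 + 1e-6, 1 - 1e-6):
            assert entropy_variant(dist, 3, "RPE", q=q) == pytest.approx(pe, abs=1e-5)

    def test_q_equal_one_rejected(self):
        with pytest.raises(ConfigurationError):
            entropy_variant(self._uniform(3), 3, "TPE", q=1.0)

    def test_variants_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            dist = pattern_distribution(rng.normal(size=60), EntropyConfig(m=3))
            for measure, q in (("TPE", 2.0), ("RPE", 2.0), ("RPE", 0.5), ("MPE", 2.0)):
                v = entropy_variant(dist, 3, measure, q=q)
                assert 0.0 <= v <= 1.0 + 1e-12


class TestSlidingFeatures:
    def test_window_count_formula(self):
        assert n_windows(921_600, 256, 5.0) == 720
        assert n_windows(1280, 256, 5.0) == 1
        assert n_windows(1279, 256, 5.0) == 0
        assert n_windows(2 * 3600 * 256, 256, 5.0) == 1440

    def test_feature_matrix_shape_and_range(self):
        rng = np.random.default_rng(11)
        rec = Recording(rng.normal(size=(6, 13 * 1280 + 100)), 256.0, [f"c{i}" for i in range(6)])
        fs = sliding_feature_matrix(rec, EntropyConfig())
        assert fs.values.shape == (6, 13)  # trailing partial window dropped
        assert np.all((fs.values >= 0) & (fs.values <= 1))
        assert np.all(np.diff(fs.window_starts) == 5.0)

    def test_window_values_match_direct_computation(self):
        rng = np.random.default_rng(2)
        sig = rng.normal(size=(2, 3 * 1280))
        rec = Recording(sig, 256.0, ["a", "b"])
        fs = sliding_feature_matrix(rec, EntropyConfig())
        for c in range(2):
            for w in range(3):
                chunk = sig[c, w * 1280 : (w + 1) * 1280]
                dist = pattern_distribution(chunk, EntropyConfig())
                assert fs.values[c, w] == pytest.approx(permutation_entropy(dist, 4), abs=1e-12)

    def test_exactly_one_window(self):
        rec = Recording(np.random.default_rng(0).normal(size=(1, 1280)), 256.0, ["a"])
        assert sliding_feature_matrix(rec, EntropyConfig()).n_windows == 1

    def test_too_short_recording_rejected(self):
        rec = Recording(np.zeros((1, 100)), 256.0, ["a"])
        with pytest.raises(ValidationError):
            sliding_feature_matrix(rec, EntropyConfig())

    def test_roundtrip_io(self, tmp_path):
        rng = np.random.default_rng(4)
        rec = Recording(rng.normal(size=(3, 4 * 1280)), 256.0, ["x", "y", "z"])
        fs = sliding_feature_matrix(rec, EntropyConfig(m=3, lam=2))
        path = tmp_path / "features.tsv"
        write_feature_series(fs, path)
        back = read_feature_series(path)
        np.testing.assert_allclose(back.values, fs.values, atol=1e-9)
        assert back.config == fs.config
        assert back.channel_ids == ["x", "y", "z"]
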