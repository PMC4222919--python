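import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from divlink import (
    AbundanceTable,
    hill_number,
    locus_diversity,
    mean_locus_diversity,
    species_profile,
)

import pandas as pd


def _distributions(min_size=2, max_size=12):
    return (
        st.lists(
            st.floats(min_value=0.01, max_value=10.0),
            min_size=min_size,
            max_size=max_size,
        )
        .map(lambda w: np.array(w) / np.sum(w))
    )


class TestHillNumber:
    @pytest.mark.parametrize("a", [0.0, 0.5, 1.0, 2.0, 7.3, math.inf])
    def test_uniform_gives_variant_count(self, a):
        assert hill_number([0.25] * 4, a) == pytest.approx(4.0)

    @pytest.mark.parametrize("a", [0.0, 1.0, 2.0, math.inf])
    def test_single_variant_gives_one(self, a):
        assert hill_number([1.0], a) == pytest.approx(1.0)

    def test_two_variant_profile(self):
        assert hill_number([0.7, 0.3], 2.0) == pytest.approx(1.7241, abs=1e-4)
        assert hill_number([0.7, 0.3], math.inf) == pytest.approx(1.4286, abs=1e-4)

    def test_order_one_is_entropy_limit(self):
        p = np.array([0.6, 0.3, 0.1])
        expected = math.exp(-sum(x * math.log(x) for x in p))
        assert hill_number(p, 1.0) == pytest.approx(expected, rel=1e-12)
        # approaching from nearby orders converges to the same value
        assert hill_number(p, 1.0 + 1e-7) == pytest.approx(expected, rel=1e-5)

    def test_zero_frequencies_dropped(self):
        assert hill_number([0.5, 0.5, 0.0], 0.0) == 2.0
        assert hill_number([0.5, 0.5, 0.0], 2.0) == pytest.approx(2.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hill_number([0.5, 0.6], 2.0)
        with pytest.raises(ValueError):
            hill_number([1.2, -0.2], 2.0)
        with pytest.raises(ValueError):
            hill_number([1.0], -1.0)

    @given(p=_distributions())
    def test_monotone_nonincreasing_in_order(self, p):
        orders = [0.0, 0.5, 1.0, 2.0, 5.0, math.inf]
        values = [hill_number(p, a) for a in orders]
        for lo, hi in zip(values[1:], values[:-1]):
            assert lo <= hi + 1e-9
        assert values[-1] >= 1.0

    @given(p=_distributions())
    def test_replication_invariance(self, p):
        # duplicating every variant's share (renormalised) leaves nu_a fixed
        doubled = np.concatenate([p, p]) / 2.0
        for a in (0.0, 1.0, 2.0, math.inf):
            assert hill_number(doubled, a) == pytest.approx(
                2 * hill_number(p, a), rel=1e-9
            )


class TestSpeciesProfile:
    @staticmethod
    def _table(counts, plot="P1"):
        frame = pd.DataFrame(
            [counts], index=[plot], columns=[f"S{i}" for i in range(len(counts))]
        )
        return AbundanceTable(frame)

    def test_uniform_counts(self):
        prof = species_profile(self._table([10, 10, 10]), "P1")
        assert list(prof.values()) == pytest.approx([3.0, 3.0, 3.0])

    def test_skewed_counts(self):
        prof = species_profile(self._table([70, 20, 10]), "P1")
        assert prof[0.0] == 3.0
        assert prof[2.0] == pytest.approx(1.8519, abs=1e-4)
        assert prof[math.inf] == pytest.approx(1.4286, abs=1e-4)

    def test_matches_hill_number_of_frequencies(self):
        table = self._table([5, 3, 2, 7])
        prof = species_profile(table, "P1", orders=(2.0,))
        assert prof[2.0] == pytest.approx(hill_number(table.frequencies("P1"), 2.0))


class TestLocusDiversity:
    def test_even_frequencies_maximal(self):
        assert locus_diversity(0.5, correction="none") == pytest.approx(2.0)

    def test_monomorphic_is_one(self):
        assert locus_diversity(1.0, correction="none") == pytest.approx(1.0)

    def test_correction_modes(self):
        assert locus_diversity(0.7, 10) == pytest.approx(1.9157, abs=1e-4)
        assert locus_diversity(0.7, 10, correction="unbiased_simpson") == pytest.approx(
            1.8750, abs=1e-4
        )

    def test_agrees_with_hill_number_before_correction(self):
        for f in (0.1, 0.35, 0.5, 0.8):
            assert locus_diversity(f, correction="none") == pytest.approx(
                hill_number([f, 1 - f], 2.0)
            )

    def test_correction_needs_sample_size(self):
        with pytest.raises(ValueError, match="n required"):
            locus_diversity(0.5)
        with pytest.raises(ValueError, match="n >= 2"):
            locus_diversity(0.5, 1)

    def test_vectorised(self):
        out = locus_diversity(np.array([0.5, 0.7]), np.array([10, 10]))
        assert out.shape == (2,)
        assert out[1] == pytest.approx(1.9157, abs=1e-4)


class TestMeanLocusDiversity:
    def test_hand_means(self):
        assert mean_locus_diversity([1.0, 2.0]) == pytest.approx(1.5)
        assert mean_locus_diversity([1.2, 1.5, 1.8]) == pytest.approx(1.5)

    def test_constant_identity(self):
        assert mean_locus_diversity([1.37] * 5) == pytest.approx(1.37)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_locus_diversity([])


class TestAgainstIndependentImplementation:
    def test_matches_scikit_bio_alpha_diversity(self):
        """Richness and inverse-Simpson cross-checked against scikit-bio."""
        from skbio.diversity.alpha import enspie, observed_features

        rng = np.random.default_rng(42)
        for _ in range(25):
            counts = rng.integers(0, 40, size=8)
            if counts.sum() == 0:
                continue
            p = counts / counts.sum()
            assert hill_number(p, 0.0) == pytest.approx(observed_features(counts))
            assert hill_number(p, 2.0) == pytest.approx(enspie(counts), rel=1e-9)
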