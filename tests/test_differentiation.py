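import itertools

import numpy as np
import pandas as pd
import pytest

from divlink import (
    BinaryMarkerMatrix,
    delta_from_counts,
    delta_multilocus,
    delta_statistic,
    perm_test_delta,
    perm_test_delta_multilocus,
)


def brute_force_delta(counts):
    """Independent direct implementation of the complement-distance definition."""
    counts = np.asarray(counts, dtype=float)
    J, V = counts.shape
    sizes = counts.sum(axis=1)
    total = counts.sum()
    delta = 0.0
    for j in range(J):
        fj = counts[j] / sizes[j]
        comp = counts.sum(axis=0) - counts[j]
        fc = comp / comp.sum()
        Dj = 0.5 * sum(abs(fj[v] - fc[v]) for v in range(V))
        delta += (sizes[j] / total) * Dj
    return delta


class TestDeltaStatistic:
    def test_complete_differentiation(self):
        delta, c, D = delta_from_counts([[5, 0], [0, 5]])
        assert delta == pytest.approx(1.0)
        assert D.tolist() == [1.0, 1.0]

    def test_identical_plots_zero(self):
        delta, _, _ = delta_from_counts([[6, 4], [6, 4], [6, 4]])
        assert delta == pytest.approx(0.0)

    def test_hand_l1_example(self):
        # two equal plots with frequencies (0.8, 0.2) vs (0.4, 0.6)
        delta, c, D = delta_from_counts([[8, 2], [4, 6]])
        assert D.tolist() == pytest.approx([0.4, 0.4])
        assert delta == pytest.approx(0.4)

    def test_from_individual_labels(self):
        variants = ["A"] * 8 + ["B"] * 2 + ["A"] * 4 + ["B"] * 6
        plots = ["P1"] * 10 + ["P2"] * 10
        res = delta_statistic(variants, plots)
        assert res.delta == pytest.approx(0.4)
        assert sum(res.c_j.values()) == pytest.approx(1.0)

    def test_matches_bruteforce_on_tiny_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            J = rng.integers(2, 4)
            V = rng.integers(2, 4)
            counts = rng.integers(0, 5, size=(J, V))
            counts[:, 0] += 1  # keep plots non-empty
            delta, _, _ = delta_from_counts(counts)
            assert delta == pytest.approx(brute_force_delta(counts), rel=1e-12)
            assert 0.0 <= delta <= 1.0

    def test_invariant_under_relabeling(self):
        counts = np.array([[3, 1, 2], [0, 4, 1], [2, 2, 2]])
        base = delta_from_counts(counts)[0]
        for perm in itertools.permutations(range(3)):
            assert delta_from_counts(counts[:, perm])[0] == pytest.approx(base)
            assert delta_from_counts(counts[list(perm)])[0] == pytest.approx(base)

    def test_merging_identical_plots_keeps_zero_at_zero(self):
        # with complement distances, merging identical plots can RAISE delta
        # (the twin no longer dilutes the complement), so the only safe
        # invariant is at the boundary: homogeneous communities stay at 0
        counts = np.array([[6, 2], [6, 2], [6, 2]])
        merged = np.array([[12, 4], [6, 2]])
        assert delta_from_counts(counts)[0] == pytest.approx(0.0)
        assert delta_from_counts(merged)[0] == pytest.approx(0.0)

    def test_duplicating_every_plot_preserves_delta_direction(self):
        counts = np.array([[6, 2], [1, 7]])
        doubled = np.array([[6, 2], [1, 7], [6, 2], [1, 7]])
        d1 = delta_from_counts(counts)[0]
        d2 = delta_from_counts(doubled)[0]
        assert 0.0 <= d2 <= d1 + 1e-12

    def test_empty_plot_rejected(self):
        with pytest.raises(ValueError):
            delta_from_counts([[0, 0], [1, 2]])


class TestPermTestDelta:
    def test_identical_plots_p_near_one(self):
        variants = (["A"] * 5 + ["B"] * 5) * 2
        plots = ["P1"] * 10 + ["P2"] * 10
        res = perm_test_delta(variants, plots, n_perm=499, seed=0)
        assert res.delta == pytest.approx(0.0)
        assert res.p_value > 0.9

    def test_strong_structure_detected(self):
        variants = ["A"] * 12 + ["B"] * 12
        plots = ["P1"] * 12 + ["P2"] * 12
        res = perm_test_delta(variants, plots, n_perm=4999, seed=0)
        assert res.delta == pytest.approx(1.0)
        assert res.p_value < res.two_sided_level
        assert res.significant

    def test_two_sided_criterion_level(self):
        res = perm_test_delta(["A", "B"] * 4, ["P1"] * 4 + ["P2"] * 4,
                              n_perm=4999, seed=1, alpha=0.05, m=6)
        assert res.two_sided_level == pytest.approx(0.05 / 12)

    def test_low_resolution_warns(self):
        with pytest.warns(UserWarning, match="resolve"):
            perm_test_delta(["A", "B"] * 4, ["P1"] * 4 + ["P2"] * 4,
                            n_perm=20, seed=1)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for seed in range(60):
            variants = rng.choice(["A", "B", "C"], size=30)
            plots = np.repeat(["P1", "P2", "P3"], 10)
            res = perm_test_delta(variants, plots, n_perm=99, seed=seed)
            pvals.append(res.p_value)
        # under exchangeability the upper-tail p is not concentrated at 0
        assert np.mean(np.array(pvals) <= 0.10) < 0.25
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.15)


class TestMultilocusDelta:
    @staticmethod
    def _matrix():
        meta = pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(12)],
                "species": ["S"] * 12,
                "plot": np.repeat(["P1", "P2", "P3"], 4),
            }
        )
        rng = np.random.default_rng(8)
        calls = pd.DataFrame(
            rng.integers(0, 2, size=(12, 4)).astype(float),
            columns=["L1", "L2", "L3", "L4"],
        )
        return BinaryMarkerMatrix(meta, calls)

    def test_mean_over_per_locus_deltas(self):
        m = self._matrix()
        per_locus = []
        for locus in m.locus_ids:
            col = m.calls[locus]
            counts = np.zeros((3, 2))
            for j, plot in enumerate(["P1", "P2", "P3"]):
                vals = col[m.meta["plot"] == plot]
                counts[j, 0] = (vals == 1.0).sum()
                counts[j, 1] = (vals == 0.0).sum()
            per_locus.append(delta_from_counts(counts)[0])
        assert delta_multilocus(m) == pytest.approx(np.mean(per_locus))

    def test_permutation_test_runs_and_bounds(self):
        out = perm_test_delta_multilocus(self._matrix(), n_perm=49, seed=0, m=6)
        assert 0.0 <= out["delta"] <= 1.0
        assert 0.0 < out["p_value"] <= 1.0
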