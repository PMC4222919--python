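import numpy as np
import pandas as pd
import pytest

from divlink import ScanConfig, q_values, scan_counts, verdict


def _results(post_probs, alphas=None):
    alphas = alphas if alphas is not None else [1.0] * len(post_probs)
    return pd.DataFrame(
        {"alpha": alphas, "post_prob": post_probs},
        index=pd.Index([f"L{i}" for i in range(len(post_probs))], name="locus_id"),
    )


class TestQValues:
    def test_certain_loci_have_zero_q(self):
        out = q_values(_results([1.0, 1.0, 1.0]))
        assert out["fdr"].tolist() == pytest.approx([0.0, 0.0, 0.0])

    def test_cumulative_mean_of_complements(self):
        out = q_values(_results([0.99, 0.98]))
        assert out["fdr"].tolist() == pytest.approx([0.01, 0.015])

    def test_zero_probability_locus_gets_mean_complement(self):
        out = q_values(_results([0.9, 0.5, 0.0]))
        assert out.loc["L2", "fdr"] == pytest.approx(np.mean([0.1, 0.5, 1.0]))

    def test_flooring_by_sample_count(self):
        out = q_values(_results([1.0, 1.0]), n_samples=500)
        assert out["fdr"].tolist() == pytest.approx([1 / 500, 1 / 500])

    def test_monotone_down_the_ranking(self):
        rng = np.random.default_rng(0)
        pp = rng.random(30)
        out = q_values(_results(pp.tolist()))
        ranked = out.sort_values("post_prob", ascending=False)["fdr"].to_numpy()
        assert (np.diff(ranked) >= -1e-12).all()


class TestVerdict:
    @pytest.mark.parametrize(
        "alpha,pp,expected",
        [
            (1.2, 0.99, "diversifying"),
            (-0.8, 0.99, "balancing"),
            (1.2, 0.80, "neutral"),
            (-0.8, 0.90, "neutral"),
            (0.0, 0.99, "neutral"),
        ],
    )
    def test_mapping(self, alpha, pp, expected):
        assert verdict(alpha, pp) == expected


class TestScanConfig:
    def test_fast_profile_is_ten_times_shorter(self):
        full, fast = ScanConfig(), ScanConfig.fast()
        assert fast.out_iterations == full.out_iterations // 10
        assert fast.pilot_length == full.pilot_length // 10
        assert fast.burn_in == full.burn_in // 10
        assert fast.pilot_runs == full.pilot_runs
        assert fast.thinning == full.thinning

    def test_validation(self):
        with pytest.raises(ValueError):
            ScanConfig(out_iterations=0)
        with pytest.raises(ValueError):
            ScanConfig(fis_bounds=(0.5, 0.2))
        with pytest.raises(ValueError):
            ScanConfig(prior_odds_neutral=0.0)


class TestScanCounts:
    @staticmethod
    def _mini_config(seed=0):
        return ScanConfig(
            out_iterations=200,
            thinning=5,
            pilot_runs=5,
            pilot_length=200,
            burn_in=1000,
            seed=seed,
        )

    @staticmethod
    def _dominant_counts(q, n_per_pop, fis, rng):
        phi = q**2 + fis * q * (1 - q)
        return rng.binomial(n_per_pop, phi), np.full(phi.shape, n_per_pop)

    def test_planted_gradient_locus_stands_out(self):
        rng = np.random.default_rng(12)
        J, n = 8, 40
        theta = 0.95 / 0.05
        q = np.clip(
            rng.beta(0.5 * theta, 0.5 * theta, size=(15, J)), 1e-3, 1 - 1e-3
        )
        q[0] = np.linspace(0.05, 0.95, J)  # the planted diversifying locus
        absent, nmat = self._dominant_counts(q, n, 0.1, rng)
        res, diag = scan_counts(absent, nmat, self._mini_config(seed=3))
        assert res.iloc[0]["post_prob"] > 0.9
        assert res.iloc[0]["alpha"] > 0
        assert res.iloc[0]["post_prob"] == res["post_prob"].max()
        assert diag["n_samples"] == 200

    def test_neutral_counts_stay_quiet(self):
        rng = np.random.default_rng(5)
        theta = 0.95 / 0.05
        p = rng.uniform(0.2, 0.8, size=20)
        q = np.clip(
            rng.beta(p[:, None] * theta, (1 - p[:, None]) * theta, size=(20, 10)),
            1e-3,
            1 - 1e-3,
        )
        absent, nmat = self._dominant_counts(q, 35, 0.1, rng)
        res, _ = scan_counts(absent, nmat, self._mini_config(seed=4))
        assert (res["post_prob"] > 0.95).sum() <= 1
        assert (res["fdr"] < 0.05).sum() <= 1

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(9)
        q = rng.uniform(0.2, 0.8, size=(6, 4))
        absent, nmat = self._dominant_counts(q, 25, 0.1, rng)
        r1, _ = scan_counts(absent, nmat, self._mini_config(seed=7))
        r2, _ = scan_counts(absent, nmat, self._mini_config(seed=7))
        pd.testing.assert_frame_equal(r1, r2)

    def test_chain_length_robustness(self):
        """Full vs half chain length: decisive posterior probabilities and
        the called set agree; mean drift stays below the MC tolerance."""
        from divlink import SimDesign, filter_loci, locus_frequencies, simulate_dataset
        from divlink.outlier import scan

        design = SimDesign(
            seed=7, n_loci=60, outlier_loci=((10, 0.05, 0.95), (40, 0.05, 0.95))
        )
        bundle = simulate_dataset(design)
        m = bundle["markers"]["Picea"]
        retained, _ = filter_loci(locus_frequencies(m))
        full = ScanConfig.fast(seed=1)
        half = ScanConfig.fast(
            seed=2, pilot_length=250, burn_in=2500, out_iterations=250
        )
        r_full, _ = scan(m, full, retained=retained)
        r_half, _ = scan(m, half, retained=retained)
        diff = (r_full["post_prob"] - r_half["post_prob"]).abs()
        planted = [
            l for l in bundle["truth"]["Picea"]["outlier_loci"] if l in diff.index
        ]
        assert (diff.loc[planted] < 0.05).all()
        assert diff.mean() < 0.05
        assert set(r_full[r_full["fdr"] < 0.05].index) == set(
            r_half[r_half["fdr"] < 0.05].index
        )

    def test_input_validation(self):
        with pytest.raises(ValueError, match="two populations"):
            scan_counts(np.zeros((3, 1)), np.ones((3, 1)), self._mini_config())
        with pytest.raises(ValueError, match="lie in"):
            scan_counts(np.full((2, 3), 5.0), np.full((2, 3), 4.0), self._mini_config())
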