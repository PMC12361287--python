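"""Cross-validated ΔLogLik, fold p-values, Fisher combination, scaling regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import surpread as sp
from surpread.evaluation import make_folds


class TestLrtP:
    def test_zero_improvement_gives_one(self):
        assert sp.lrt_p(0.0) == 1.0

    def test_chi2_quantile(self):
        # 2·ΔLL = 5.991 at df 2 sits at the 5% upper tail
        assert sp.lrt_p(5.991 / 2, df=2) == pytest.approx(0.05, abs=1e-4)
        assert sp.lrt_p(5.991 / 2, df=2) == pytest.approx(
            stats.chi2.sf(5.991, 2), abs=1e-12
        )

    def test_negative_clamps_to_one(self):
        assert sp.lrt_p(-3.0) == 1.0

    def test_df_validation(self):
        with pytest.raises(ValueError):
            sp.lrt_p(1.0, df=0)


class TestFisher:
    def test_single_p_identity(self):
        for p in (0.001, 0.05, 0.3, 1.0):
            assert sp.fisher_combine([p]) == pytest.approx(p, abs=1e-12)

    def test_all_ones(self):
        assert sp.fisher_combine([1.0] * 10) == pytest.approx(1.0)

    def test_two_p05(self):
        # X = −2(ln .05 + ln .05) ≈ 11.98, df 4
        expected = stats.chi2.sf(-2 * 2 * np.log(0.05), 4)
        assert sp.fisher_combine([0.05, 0.05]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0175, abs=5e-4)

    @pytest.mark.parametrize("bad", [[], [0.0, 0.5], [0.5, 1.1], [-0.1]])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            sp.fisher_combine(bad)


class TestFolds:
    def test_equal_partition(self):
        folds = make_folds(100, 10, seed=0)
        assert [len(f) for f in folds] == [10] * 10
        assert sorted(np.concatenate(folds)) == list(range(100))

    def test_k_validation(self):
        with pytest.raises(ValueError):
            make_folds(100, 1, seed=0)
        with pytest.raises(ValueError):
            make_folds(5, 10, seed=0)


class TestCvDeltaLoglik:
    def test_real_effect_detected(self, analysis_table):
        res = sp.cv_delta_loglik(analysis_table, k=10, seed=3)
        assert res.mean_delta_ll_per_word > 0
        assert sum(f.delta_ll_per_word > 0 for f in res.folds) >= 8
        assert res.fisher_p < 0.01

    def test_aggregation_identities(self, analysis_table):
        res = sp.cv_delta_loglik(analysis_table, k=10, seed=3)
        per_word = np.array([f.delta_ll_per_word for f in res.folds])
        assert res.mean_delta_ll_per_word == pytest.approx(per_word.mean())
        assert res.per_1000 == pytest.approx(1000 * res.mean_delta_ll_per_word)
        assert res.se == pytest.approx(per_word.std(ddof=1) / np.sqrt(10))
        for f in res.folds:
            assert f.delta_ll_per_word == pytest.approx(f.delta_ll_total / f.n_test)

    def test_null_effect_penalized_on_heldout(self):
        """With no true surprisal effect, the two extra parameters cost
        held-out likelihood: mean ΔLL/word ≤ 0 averaged over seeds."""
        rng = np.random.default_rng(5)
        means = []
        for rep in range(30):
            n = 300
            df = pd.DataFrame(
                {
                    "length_chars": rng.integers(1, 12, n),
                    "zipf_freq": rng.uniform(2, 7, n),
                    "word_pos": rng.integers(2, 20, n),
                    "prev_length": rng.integers(1, 12, n),
                    "prev_zipf": rng.uniform(2, 7, n),
                    "surprisal": rng.uniform(0, 12, n),
                    "prev_surprisal": rng.uniform(0, 12, n),
                }
            )
            df["gd_ms"] = (
                200 + 5 * df.length_chars - 6 * df.zipf_freq + rng.normal(0, 25, n)
            )
            res = sp.cv_delta_loglik(df, k=5, seed=rep)
            means.append(res.mean_delta_ll_per_word)
        assert np.mean(means) <= 0

    def test_p_source_options(self, analysis_table):
        ps = {
            src: sp.cv_delta_loglik(analysis_table, k=5, seed=1, p_source=src).fisher_p
            for src in ("fold_exact", "heldout", "train")
        }
        assert all(0 < p <= 1 for p in ps.values())
        with pytest.raises(ValueError, match="p_source"):
            sp.cv_delta_loglik(analysis_table, k=5, seed=1, p_source="bogus")

    def test_k_validation(self, analysis_table):
        with pytest.raises(ValueError):
            sp.cv_delta_loglik(analysis_table, k=1, seed=0)

    def test_noise_monotonicity(self, small_corpus):
        """Extra response noise weakly decreases mean ΔLL/word (over seeds)."""
        rng = np.random.default_rng(9)
        analysis = sp.attach_spillover(small_corpus["records"], small_corpus["truth"])
        table, _ = sp.apply_exclusions(analysis)
        gains = []
        for sd in (0.0, 60.0, 200.0):
            vals = []
            for rep in range(5):
                noisy = table.copy()
                noisy["gd_ms"] = noisy["gd_ms"] + rng.normal(0, sd, len(noisy))
                vals.append(sp.cv_delta_loglik(noisy, k=5, seed=rep).mean_delta_ll_per_word)
            gains.append(np.mean(vals))
        assert gains[0] >= gains[1] >= gains[2]


def _fake_result(gain, corpus, measure, family, n_params):
    return sp.EvalResult(
        mean_delta_ll_per_word=gain / 1000.0,
        se=0.0,
        fisher_p=0.5,
        folds=[],
        metadata={"corpus": corpus, "measure": measure, "family": family,
                  "n_params": n_params},
    )


class TestScalingRegression:
    sizes = np.array([1e8, 5e8, 1e9, 5e9])

    def _grid(self, slope):
        out = []
        for corpus in ("c1", "c2"):
            for measure in ("ffd", "gd"):
                for s in self.sizes:
                    out.append(
                        _fake_result(2.0 + slope * s / 1e8, corpus, measure, "fam", s)
                    )
        return out

    def test_exact_slope_recovery(self):
        res = sp.scaling_regression(self._grid(-0.023))
        assert res.slope_per_100M == pytest.approx(-0.023, abs=1e-10)

    def test_constant_gains_zero_slope(self):
        res = sp.scaling_regression(self._grid(0.0))
        assert res.slope_per_100M == pytest.approx(0.0, abs=1e-10)

    def test_inverse_scaling_sign(self):
        """Gains decreasing in model size give a negative slope."""
        res = sp.scaling_regression(self._grid(-0.5))
        assert res.slope_per_100M < 0

    def test_single_size_errors(self):
        results = [_fake_result(1.0, "c", "gd", "f", 1e8) for _ in range(4)]
        with pytest.raises(ValueError, match="distinct model sizes"):
            sp.scaling_regression(results)
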