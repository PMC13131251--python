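"""RNA-seq re-analysis checks: count filter, TMM oracle equivalence,
log-CPM arithmetic, precision weights, moderated fit, congruence."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sdmeta import rnaseq_validate as rv


def naive_tmm(counts):
    """Unoptimized TMM oracle: direct formulas, explicit sorting."""
    x = np.asarray(counts, float)
    lib = x.sum(axis=0)
    f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for j in range(x.shape[1]):
        m_list, a_list, w_list = [], [], []
        for g in range(x.shape[0]):
            o, r = x[g, j], x[g, ref]
            if o > 0 and r > 0:
                m_list.append(np.log2((o / lib[j]) / (r / lib[ref])))
                a_list.append(0.5 * np.log2((o / lib[j]) * (r / lib[ref])))
                w_list.append(
                    (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
                )
        m = np.array(m_list)
        a = np.array(a_list)
        w = np.array(w_list)
        if np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m)
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = np.ones(n, bool)
        keep &= (rank_m >= np.floor(n * 0.3) + 1) & (rank_m <= n - np.floor(n * 0.3))
        keep &= (rank_a >= np.floor(n * 0.05) + 1) & (rank_a <= n - np.floor(n * 0.05))
        factors.append(2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def _counts_df(arr, prefix="S"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"G{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestFilterLowCounts:
    def test_mean_below_ten_removed_and_exactly_ten_retained(self):
        counts = _counts_df([[9, 9, 9], [10, 10, 10], [100, 3, 5]])
        out = rv.filter_low_counts(counts)
        assert list(out.index) == ["G1", "G2"]

    def test_engineered_low_rows_all_removed(self, rng):
        high = rng.poisson(100, size=(400, 6))
        low = rng.integers(0, 4, size=(100, 6))
        counts = _counts_df(np.vstack([high, low]))
        out = rv.filter_low_counts(counts)
        assert len(out) == 400

    def test_empty_result_is_error(self):
        with pytest.raises(ValueError, match="no genes"):
            rv.filter_low_counts(_counts_df([[1, 1], [2, 2]]))


class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.poisson(50, size=300)
        counts = _counts_df(np.column_stack([col, col]))
        np.testing.assert_allclose(rv.tmm_factors(counts), [1.0, 1.0])

    def test_pure_depth_difference_gives_unit_factors(self, rng):
        col = rng.poisson(50, size=300) + 1
        counts = _counts_df(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(rv.tmm_factors(counts), [1.0, 1.0], atol=1e-12)

    def test_matches_naive_oracle(self, rng):
        counts = _counts_df(rng.poisson(rng.uniform(5, 500, size=(200, 1)),
                                        size=(200, 4)))
        np.testing.assert_allclose(
            rv.tmm_factors(counts), naive_tmm(counts), atol=1e-10
        )

    def test_geometric_mean_is_one(self, rng):
        counts = _counts_df(rng.poisson(rng.uniform(5, 500, size=(300, 1)) *
                                        rng.uniform(0.5, 2, size=6), size=(300, 6)))
        f = rv.tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_edger_calcnormfactors(self, rng):
        """Independent oracle: edgeR's calcNormFactors on a small matrix."""
        counts = _counts_df(
            rng.poisson(rng.uniform(5, 300, size=(150, 1)) *
                        rng.uniform(0.5, 2, size=5), size=(150, 5))
        )
        rows = ";".join(
            "c(" + ",".join(str(int(v)) for v in counts.iloc[i]) + ")"
            for i in range(len(counts))
        )
        script = (
            "suppressMessages(library(edgeR));"
            f"x <- matrix(c({','.join(str(int(v)) for v in counts.to_numpy().ravel(order='F'))}),"
            f" nrow={len(counts)}, ncol={counts.shape[1]});"
            "f <- calcNormFactors(x, method='TMM');"
            "cat(f, sep='\\n')"
        )
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=180, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.fail(f"edgeR oracle unavailable: {exc}")
        expected = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(rv.tmm_factors(counts), expected, atol=1e-6)

    def test_disjoint_support_is_error(self):
        counts = _counts_df([[5, 0], [8, 0], [0, 9]])
        with pytest.raises(ValueError, match="no expressed genes"):
            rv.tmm_factors(counts)


class TestLogCpm:
    def test_direct_arithmetic(self):
        counts = _counts_df([[100], [999_900 - 100]])
        counts.iloc[1, 0] = 1_000_000 - 100  # library exactly 1e6
        out = rv.log_cpm(counts, np.array([1.0]))
        assert out.iloc[0, 0] == pytest.approx(np.log2(100.5 / (1e6 + 1) * 1e6), abs=1e-9)
        assert out.iloc[0, 0] == pytest.approx(6.651, abs=1e-3)

    def test_all_zero_gene_constant_across_equal_libraries(self):
        counts = _counts_df([[0, 0], [500, 500], [500, 500]])
        out = rv.log_cpm(counts, np.array([1.0, 1.0]))
        assert out.iloc[0, 0] == out.iloc[0, 1]

    def test_scaling_invariance_up_to_prior(self, rng):
        base = rng.poisson(300, size=(200, 3)) + 100
        a = rv.log_cpm(_counts_df(base))
        b = rv.log_cpm(_counts_df(2 * base))
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 0.01


class TestVoomWeights:
    def _design(self, n):
        return np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])

    def test_flat_mean_variance_trend_gives_flat_weights(self, rng):
        # equal-mean Poisson counts: no mean-variance gradient across genes
        counts = _counts_df(rng.poisson(500, size=(300, 8)))
        w = rv.voom_weights(counts, np.ones(8), self._design(8))
        cv = w.to_numpy().std() / w.to_numpy().mean()
        assert cv < 0.10

    def test_weights_track_precision_at_low_counts(self, rng):
        means = rng.uniform(2, 2000, size=400)
        disp = 0.2
        lam = means[:, None] * rng.gamma(1 / disp, disp, size=(400, 8))
        counts = _counts_df(rng.poisson(lam))
        counts = counts[counts.mean(axis=1) > 0.5]
        w = rv.voom_weights(counts, np.ones(8), self._design(8))
        mean_counts = counts.mean(axis=1)
        low = mean_counts < 50
        rho = stats.spearmanr(mean_counts[low], w.mean(axis=1)[low]).statistic
        # counting noise dominates at low abundance: precision grows with mean
        assert rho > 0

    def test_deterministic(self, rng):
        counts = _counts_df(rng.poisson(100, size=(100, 6)))
        d = self._design(6)
        a = rv.voom_weights(counts, np.ones(6), d)
        b = rv.voom_weights(counts, np.ones(6), d)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_residual_df(self, rng):
        counts = _counts_df(rng.poisson(100, size=(50, 2)))
        with pytest.raises(ValueError, match="residual"):
            rv.voom_weights(counts, np.ones(2), self._design(2))


class TestFitDe:
    def test_shrinkage_off_limit_matches_classical_t(self, rng):
        # identical true variances, generous df: moderation ~ no-op
        n = 400
        y = pd.DataFrame(rng.normal(5.0, 1.0, size=(300, n)),
                         index=[f"G{i}" for i in range(300)])
        cond = np.repeat(["CTRL", "SD"], n // 2)
        out = rv.fit_de(y, None, cond).set_index("gene")
        t_classic = np.array([
            stats.ttest_ind(row[n // 2:], row[: n // 2]).statistic
            for row in y.to_numpy()
        ])
        rel = np.abs(out["t_mod"].to_numpy() - t_classic) / np.abs(t_classic)
        assert np.median(rel) < 0.05

    def test_parameter_recovery_of_unit_shift(self, rng):
        from sdmeta import synthdata

        # balanced up/down shifts keep the library composition neutral,
        # so TMM does not re-absorb part of the generated effect
        genes = [f"G{i}" for i in range(500)]
        truth = pd.DataFrame({
            "gene": genes,
            "mu_true": [1.0] * 50 + [-1.0] * 50 + [0.0] * 400,
            "tau2_true": 0.0, "rs_effect_true": 0.0,
            "is_de": [True] * 100 + [False] * 400,
        })
        counts, samples = synthdata.simulate_validation_counts(
            truth, 20, seed=8, dispersion=0.02
        )
        de = rv.run_validation_de(counts, samples).set_index("gene")
        up = de.loc[de.index.intersection(genes[:50]), "log2fc"]
        down = de.loc[de.index.intersection(genes[50:100]), "log2fc"]
        assert 0.9 < up.mean() < 1.1
        assert -1.1 < down.mean() < -0.9

    def test_sign_consistency_between_effect_and_t(self, rng):
        y = pd.DataFrame(rng.normal(0, 1, size=(200, 10)))
        cond = np.repeat(["CTRL", "SD"], 5)
        out = rv.fit_de(y, None, cond)
        nz = out["log2fc"] != 0
        assert (np.sign(out.loc[nz, "log2fc"]) == np.sign(out.loc[nz, "t_mod"])).all()
        assert (out["fdr"] >= out["p"] - 1e-15).all()


class TestCongruence:
    def _meta(self, fc, fdr):
        return pd.DataFrame({
            "gene": [f"G{i}" for i in range(len(fc))],
            "log2fc": fc, "fdr": fdr,
        })

    def test_self_comparison_is_perfect(self, rng):
        fc = rng.normal(0, 0.5, size=30)
        meta = self._meta(fc, np.full(30, 0.01))
        de = meta.rename(columns={})[["gene", "log2fc", "fdr"]]
        s = rv.congruence(meta, de)
        assert s.n_same_direction == s.n_represented == s.n_degs == 30
        assert s.n_fully_validated == 30
        assert s.ols_slope == pytest.approx(1.0)
        assert s.spearman_rho == pytest.approx(1.0)

    def test_constructed_sign_flips_counted(self, rng):
        fc = np.abs(rng.normal(1, 0.2, size=10))
        meta = self._meta(fc, np.full(10, 0.01))
        de_fc = fc.copy()
        de_fc[:3] *= -1  # exactly 3 of 10 flipped
        de = pd.DataFrame({"gene": meta["gene"], "log2fc": de_fc,
                           "fdr": np.full(10, 0.5)})
        s = rv.congruence(meta, de)
        assert s.n_same_direction == 7
        assert s.n_fully_validated == 0

    def test_chain_inequality_holds(self, rng):
        fc = rng.normal(0, 0.5, size=50)
        meta = self._meta(fc, rng.uniform(0, 0.2, size=50))
        de = pd.DataFrame({
            "gene": [f"G{i}" for i in range(0, 50, 2)],
            "log2fc": rng.normal(0, 0.5, size=25),
            "fdr": rng.uniform(0, 0.3, size=25),
        })
        s = rv.congruence(meta, de, q=0.1)
        assert (s.n_fully_validated <= s.n_same_direction
                <= s.n_represented <= s.n_degs)

    def test_zero_represented_is_error(self):
        meta = self._meta([0.5], [0.01])
        de = pd.DataFrame({"gene": ["OTHER"], "log2fc": [0.5], "fdr": [0.01]})
        with pytest.raises(ValueError, match="represented"):
            rv.congruence(meta, de)

    def test_orientation_flips_regression(self, rng):
        fc = rng.normal(0, 0.5, size=40)
        meta = self._meta(fc, np.full(40, 0.01))
        de = pd.DataFrame({"gene": meta["gene"],
                           "log2fc": 2.0 * fc + rng.normal(0, 0.01, 40),
                           "fdr": np.full(40, 0.5)})
        fwd = rv.congruence(meta, de, orientation="validation_on_meta")
        rev = rv.congruence(meta, de, orientation="meta_on_validation")
        assert fwd.ols_slope == pytest.approx(2.0, rel=0.05)
        assert rev.ols_slope == pytest.approx(0.5, rel=0.05)
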