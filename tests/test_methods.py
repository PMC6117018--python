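"""Per-gene fitters: OLS, batch fixed effects, random-intercept ML, EB.

The mixed model is checked against a brute-force profile-likelihood grid
(full covariance matrices, slogdet) and against statsmodels MixedLM; the
empirical-Bayes adjuster against a straight-line loop implementation of the
published parametric location/scale equations and against the reference R
implementation (sva::ComBat) run through Rscript.
"""

import subprocess

import numpy as np
import pytest
from scipy import stats as sps

from batchbench import (SimulationScenario, calibrate, eb_batch_adjust,
                        denoise_matrix, fit_gene_lm, fit_gene_lm_batch,
                        fit_gene_lmm, fit_lm, fit_lm_batch, fit_lmm,
                        inject_effects)
from batchbench.evaluate import bh_adjust


class TestLM:
    def test_exact_linear_relationship(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_gene_lm(2 * t, t)
        assert fit.slope == pytest.approx(2.0)
        assert fit.p_value < 1e-12

    def test_closed_form_four_points(self):
        fit = fit_gene_lm(np.array([1.0, 3.0, 5.0, 7.0]),
                          np.array([0.0, 1.0, 2.0, 3.0]))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(9)
        t = rng.normal(0, 1, 50)
        Y = rng.normal(0, 1, (1000, 50))
        p = fit_lm(Y, t).p_value
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_gene_lm(np.arange(4.0), np.ones(4))


class TestLMBatch:
    def test_single_batch_equals_plain_lm(self):
        rng = np.random.default_rng(1)
        t = rng.normal(0, 1, 20)
        y = 0.5 * t + rng.normal(0, 1, 20)
        a = fit_gene_lm(y, t)
        b = fit_gene_lm_batch(y, t, np.array(["x"] * 20))
        assert a.slope == pytest.approx(b.slope, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_pure_batch_signal_removed(self):
        """y equal to the batch effect: slope ~ 0 and p roughly uniform."""
        rng = np.random.default_rng(2)
        batch = np.repeat(list("abcdef"), 10)
        t = rng.normal(0, 1, 60)
        pvals, slopes = [], []
        for _ in range(200):
            r = rng.normal(0, 2.72, 6)
            y = r[np.searchsorted(list("abcdef"), batch)] + rng.normal(0, 0.05, 60)
            f = fit_gene_lm_batch(y, rng.permutation(t), batch)
            pvals.append(f.p_value)
            slopes.append(f.slope)
        assert abs(np.mean(slopes)) < 0.01
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_orthogonal_covariate_matches_plain_lm(self):
        """With batch orthogonal to the covariate, partialling out batch
        leaves the slope (FWL) but shrinks the residual variance."""
        rng = np.random.default_rng(3)
        batch = np.repeat(list("abcd"), 12)
        t = np.tile(rng.normal(0, 1, 12), 4)
        t = t - np.mean(t)
        r = np.array([3.0, -1.0, 2.0, -4.0])
        y = 1.2 * t + r[np.searchsorted(list("abcd"), batch)] + rng.normal(0, 0.3, 48)
        plain = fit_gene_lm(y, t)
        adj = fit_gene_lm_batch(y, t, batch)
        assert adj.slope == pytest.approx(plain.slope, abs=1e-9)
        assert adj.residual_variance < plain.residual_variance


class TestLMM:
    def test_zero_between_batch_variance_reduces_to_ols(self):
        """Batch means forced exactly equal: the variance ratio hits the zero
        boundary and (slope, p) match plain OLS."""
        rng = np.random.default_rng(4)
        batch = np.repeat(list("abc"), 8)
        t = rng.normal(0, 1, 24)
        y = 0.8 * t + rng.normal(0, 0.5, 24)
        for g in "abc":  # remove all between-batch mean differences
            y[batch == g] -= (y[batch == g] - 0.8 * t[batch == g]).mean()
        lmm = fit_gene_lmm(y, t, batch)
        ols = fit_gene_lm(y, t)
        assert lmm.batch_variance < 1e-6
        assert lmm.slope == pytest.approx(ols.slope, abs=1e-6)
        assert lmm.p_value == pytest.approx(ols.p_value, rel=1e-4)

    def test_profile_matches_brute_force_grid(self):
        """Tiny instance: the profiled deviance optimum matches an exhaustive
        grid search over the ML criterion (full V, slogdet) to 1e-4."""
        rng = np.random.default_rng(5)
        m, batch = 6, np.array(["a", "a", "a", "b", "b", "b"])
        t = rng.normal(0, 1, m)
        y = t + rng.normal(0, 1.5, 2)[[0, 0, 0, 1, 1, 1]] + rng.normal(0, 0.4, m)

        def deviance(lam):
            V = np.eye(m)
            for g in "ab":
                idx = np.flatnonzero(batch == g)
                V[np.ix_(idx, idx)] += lam
            Vi = np.linalg.inv(V)
            X = np.column_stack([np.ones(m), t])
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            resid = y - X @ beta
            s2 = resid @ Vi @ resid / m
            return m * np.log(s2) + np.linalg.slogdet(V)[1]

        grid = np.linspace(0.0, 200.0, 400001)
        brute = min(deviance(l) for l in grid)
        fit = fit_gene_lmm(y, t, batch)
        lam_hat = fit.batch_variance / fit.residual_variance
        assert deviance(lam_hat) <= brute + 1e-4

    def test_matches_statsmodels_ml(self):
        """Slope and variance components agree with MixedLM(reml=False)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        m, b = 60, 6
        batch = np.repeat(np.arange(b), m // b)
        t = rng.normal(0, 1, m)
        for _ in range(3):
            y = 1.0 * t + rng.normal(0, 2.0, b)[batch] + rng.normal(0, 0.5, m)
            mine = fit_gene_lmm(y, t, batch)
            ref = sm.MixedLM(y, sm.add_constant(t), groups=batch).fit(reml=False)
            assert mine.slope == pytest.approx(ref.params[1], abs=1e-5)
            assert mine.batch_variance == pytest.approx(
                np.asarray(ref.cov_re)[0, 0], rel=1e-3, abs=1e-5)
            assert mine.residual_variance == pytest.approx(ref.scale, rel=1e-3)

    def test_slope_recovery_at_scale(self):
        """beta1 = 1, sigma_u = 2.72, sigma = 0.3, m = 251: mean slope within
        0.02 of 1 over 100 genes."""
        rng = np.random.default_rng(7)
        m, b = 251, 14
        batch = np.repeat(np.arange(b), [18] * 13 + [17])
        t = rng.normal(0, 1, m)
        Y = (t[None, :] + rng.normal(0, 2.72, (100, b))[:, batch]
             + rng.normal(0, 0.3, (100, m)))
        table = fit_lmm(Y, t, batch)
        assert abs(table.slope.mean() - 1.0) < 0.02


def eb_oracle(Y, batch, tol=1e-4, max_iter=100):
    """Straight-line loop implementation of the parametric EB equations
    (standardize, per-batch moments, normal / inverse-gamma shrinkage)."""
    Y = np.asarray(Y, float)
    labels = sorted(set(batch), key=list(batch).index)
    w, m = Y.shape
    nj = {g: sum(b == g for b in batch) for g in labels}
    # pooled mean and variance from the batch-means fit
    grand = np.zeros(w)
    fitted = np.zeros_like(Y)
    for g in labels:
        cols = [k for k, b in enumerate(batch) if b == g]
        bm = Y[:, cols].mean(axis=1)
        grand += bm * (nj[g] / m)
        fitted[:, cols] = bm[:, None]
    var_pooled = ((Y - fitted) ** 2).sum(axis=1) / m
    s = (Y - grand[:, None]) / np.sqrt(var_pooled)[:, None]

    out = np.empty_like(Y)
    for g in labels:
        cols = [k for k, b in enumerate(batch) if b == g]
        block = s[:, cols]
        n = len(cols)
        g_hat = block.mean(axis=1)
        d_hat = block.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        dm, dv = d_hat.mean(), d_hat.var(ddof=1)
        a = (2 * dv + dm ** 2) / dv
        bpr = (dm * dv + dm ** 3) / dv
        g_old, d_old = g_hat.copy(), d_hat.copy()
        change, it = np.inf, 0
        while change > tol and it < max_iter:
            g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
            sum2 = ((block - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + bpr) / (n / 2.0 + a - 1.0)
            change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                         np.max(np.abs(d_new - d_old) / np.abs(d_old)))
            g_old, d_old = g_new, d_new
            it += 1
        out[:, cols] = (block - g_old[:, None]) / np.sqrt(d_old)[:, None]
    return out * np.sqrt(var_pooled)[:, None] + grand[:, None]


class TestEB:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(7, 1, (5, 12))
        adj, _ = eb_batch_adjust(Y, np.array(["a"] * 12))
        assert np.abs(adj - Y).max() < 1e-9

    def test_location_shift_removed(self):
        """Two equal batches, batch 2 shifted by +c: post-adjustment batch
        means agree within 0.02 c."""
        rng = np.random.default_rng(9)
        c = 2.0
        w, half = 400, 100
        Y = rng.normal(7, 0.1, (w, 2 * half))
        Y[:, half:] += c
        batch = np.array(["a"] * half + ["b"] * half)
        adj, _ = eb_batch_adjust(Y, batch)
        gap = adj[:, half:].mean(axis=1) - adj[:, :half].mean(axis=1)
        assert np.abs(gap).max() < 0.02 * c

    def test_matches_straight_line_oracle(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(6, 1.3, (10, 10))
        Y[:, 5:] += rng.normal(0, 1, (10, 1))
        batch = np.array(["a"] * 5 + ["b"] * 5)
        adj, _ = eb_batch_adjust(Y, batch)
        assert np.abs(adj - eb_oracle(Y, batch)).max() < 1e-6

    def test_matches_reference_r_implementation(self, tmp_path):
        """The adjusted matrix agrees with sva::ComBat (parametric priors)."""
        rng = np.random.default_rng(11)
        nj = [6, 5, 7]
        batch = np.repeat(["a", "b", "c"], nj)
        Y = rng.normal(7, 1.5, (20, sum(nj)))
        Y += np.repeat(rng.normal(0, 1.2, 3), nj)[None, :]
        np.savetxt(tmp_path / "Y.tsv", Y, delimiter="\t")
        (tmp_path / "batch.txt").write_text("\n".join(batch) + "\n")
        script = (
            "suppressMessages(library(sva));"
            f"Y <- as.matrix(read.table('{tmp_path}/Y.tsv'));"
            f"b <- scan('{tmp_path}/batch.txt', what='character', quiet=TRUE);"
            "adj <- ComBat(dat=Y, batch=b, par.prior=TRUE);"
            f"write.table(adj, '{tmp_path}/adj.tsv', sep='\\t',"
            "row.names=FALSE, col.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        ref = np.loadtxt(tmp_path / "adj.tsv")
        adj, _ = eb_batch_adjust(Y, batch)
        assert np.abs(adj - ref).max() < 1e-4

    def test_pooled_mean_approximately_preserved(self):
        """De-standardization restores each gene's pooled mean up to the
        (small) distortion that location shrinkage and scale division
        introduce — exact preservation is not a property of the parametric
        EB equations, but the drift is far below the removed batch shifts."""
        rng = np.random.default_rng(12)
        shifts = np.repeat(rng.normal(0, 1, 3), 10)
        Y = rng.normal(5, 1, (50, 30)) + shifts
        adj, _ = eb_batch_adjust(Y, np.repeat(["a", "b", "c"], 10))
        drift = np.abs(adj.mean(axis=1) - Y.mean(axis=1))
        assert drift.max() < 0.05 * np.ptp(shifts)

    def test_zero_variance_gene_flagged(self):
        rng = np.random.default_rng(13)
        Y = rng.normal(0, 1, (6, 12))
        Y[0] = np.where(np.arange(12) < 6, 1.0, 2.0)  # constant within batch
        adj, eb = eb_batch_adjust(Y, np.array(["a"] * 6 + ["b"] * 6))
        assert np.all(np.isfinite(adj))
        assert eb.floored_genes[0]

    def test_tiny_batch_rejected(self):
        with pytest.raises(ValueError, match="<= 1 sample"):
            eb_batch_adjust(np.zeros((3, 5)), np.array(["a"] * 4 + ["b"]))


class TestAdjustedRegression:
    def test_no_batch_limit_matches_raw_regression(self):
        """No batch structure anywhere (gamma = 0, latent offsets 0):
        p-values from regression on EB-adjusted data track the raw OLS
        p-values (Spearman > 0.99)."""
        from batchbench import CohortConfig, generate_base_cohort
        # large batches so batch means are well estimated: the limit statement
        # concerns the adjustment's bias, not its small-sample noise
        cohort = generate_base_cohort(CohortConfig(
            n_genes=120, batch_sizes=[60] * 4, latent_batch_sd=0.0, seed=30))
        stats = calibrate(cohort)
        sc = SimulationScenario(effect_sd=0.5, gamma=0.0, n_effect_genes=30,
                                seed=20)
        sim = inject_effects(cohort, sc, stats)
        Y = sim.matrix.study().values.to_numpy()
        t = sim.treatment.to_numpy()
        raw_p = fit_lm(Y, t).p_value
        adj, _ = eb_batch_adjust(Y, sim.study_batch.to_numpy())
        adj_p = fit_lm(adj, t).p_value
        assert sps.spearmanr(raw_p, adj_p).statistic > 0.99

    def test_saturated_effect_all_detected(self, tiny_cohort):
        """SD = 3 with batch effects: every effect gene survives BH 5%."""
        stats = calibrate(tiny_cohort)
        sc = SimulationScenario(effect_sd=3.0, gamma=2.72, n_effect_genes=30,
                                seed=21)
        sim = inject_effects(tiny_cohort, sc, stats)
        Y = sim.matrix.study().values.to_numpy()
        adj, _ = eb_batch_adjust(Y, sim.study_batch.to_numpy())
        p = fit_lm(adj, sim.treatment.to_numpy()).p_value
        assert np.all(bh_adjust(p)[:30] < 0.05)


class TestMethodAgreement:
    def test_batch_aware_slopes_concordant(self, full_cohort, full_stats):
        """Balanced design, SD = 0.5: slope estimates from the three
        batch-aware methods correlate > 0.99 across genes."""
        sc = SimulationScenario(effect_sd=0.5, gamma=2.72, n_effect_genes=150,
                                seed=22)
        sim = inject_effects(full_cohort, sc, full_stats)
        Y = sim.matrix.study().values.to_numpy()
        t = sim.treatment.to_numpy()
        batch = sim.study_batch.to_numpy()
        s_lmm = fit_lmm(Y, t, batch).slope
        s_lmb = fit_lm_batch(Y, t, batch).slope
        adj, _ = eb_batch_adjust(Y, batch)
        s_eb = fit_lm(adj, t).slope
        assert np.corrcoef(s_lmm, s_lmb)[0, 1] > 0.99
        assert np.corrcoef(s_lmm, s_eb)[0, 1] > 0.99
        assert np.corrcoef(s_lmb, s_eb)[0, 1] > 0.99


class TestDenoise:
    @pytest.mark.parametrize("method", ["lmm", "lm_batch", "eb"])
    def test_injected_batch_effects_recovered(self, tiny_cohort, method):
        stats = calibrate(tiny_cohort)
        sc = SimulationScenario(effect_sd=0.0, gamma=2.0, n_effect_genes=0,
                                seed=23)
        sim = inject_effects(tiny_cohort, sc, stats)
        out = denoise_matrix(sim.matrix, method)
        removed = sim.matrix.values.to_numpy() - out.values.to_numpy()
        batch = sim.matrix.samples["batch"].to_numpy()
        per_batch = np.array([removed[:, batch == b].mean()
                              for b in sim.matrix.batches])
        r = sim.batch_effects.to_numpy()
        assert np.corrcoef(per_batch, r)[0, 1] > 0.99

    @pytest.mark.parametrize("method", ["lmm", "lm_batch", "eb"])
    def test_no_batch_effect_input_roughly_unchanged(self, tiny_cohort, method):
        stats = calibrate(tiny_cohort)
        sc = SimulationScenario(effect_sd=0.0, gamma=0.0, n_effect_genes=0,
                                seed=24)
        sim = inject_effects(tiny_cohort, sc, stats)
        out = denoise_matrix(sim.matrix, method)
        diff = np.abs(out.values.to_numpy() - sim.matrix.values.to_numpy())
        # at most the batch-mean sampling noise gets removed
        resid_scale = np.median(calibrate(tiny_cohort).residual_sd)
        assert np.median(diff) < 3 * resid_scale / np.sqrt(6)
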