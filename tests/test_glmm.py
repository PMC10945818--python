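"""Binomial mixed model: kinship expansion, designs, fits, FDR.

The fit is cross-checked against two independent oracles: a hand-coded
IRLS binomial regression (no random effects) and a brute-force grid search
over an independently coded Laplace-approximated likelihood.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize
from scipy.special import expit

from bioembed.glmm import (
    BinomialMixedModel,
    KinshipMatrix,
    ModelSpec,
    bh_fdr,
    build_design,
    expand_kinship,
    fit_site,
    scan,
    standardized_effect,
)
from bioembed.qc import MethylationCounts
from bioembed.simulate import simulate_pedigree


# ---------------------------------------------------------------------------
# oracles


def irls_binomial_oracle(m, r, X, maxiter=200):
    """Independently coded IRLS for the plain binomial GLM."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        pi = expit(eta)
        W = np.clip(r * pi * (1 - pi), 1e-12, None)
        z = eta + (m - r * pi) / W
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta


def laplace_loglik_oracle(m, r, X, K, sg2, se2):
    """Independent Laplace-approximate marginal loglik at fixed variances."""
    n = len(m)
    p = X.shape[1]
    Sigma = sg2 * K + se2 * np.eye(n)
    Sigma_inv = np.linalg.inv(Sigma)

    def neg_pen(params):
        beta, b = params[:p], params[p:]
        eta = X @ beta + b
        return -(
            m @ eta - r @ np.logaddexp(0.0, eta) - 0.5 * b @ Sigma_inv @ b
        )

    res = optimize.minimize(
        neg_pen, np.zeros(p + n), method="BFGS",
        options={"gtol": 1e-9, "maxiter": 500},
    )
    beta, b = res.x[:p], res.x[p:]
    eta = X @ beta + b
    pi = expit(eta)
    W = r * pi * (1 - pi)
    H = Sigma_inv + np.diag(W)
    ll = (
        -res.fun
        - 0.5 * np.linalg.slogdet(Sigma)[1]
        - 0.5 * np.linalg.slogdet(H)[1]
    )
    return ll, beta


def bh_oracle(p):
    """Step-up q-values: q_(i) = min_{j >= i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


# ---------------------------------------------------------------------------


class TestExpandKinship:
    def test_repeated_samples_share_block(self):
        kin = KinshipMatrix(["a", "b"], np.eye(2))
        K = expand_kinship(kin, ["a", "a", "b"])
        assert K.shape == (3, 3)
        assert np.allclose(K[:2, :2], 1.0)
        assert np.allclose(K[2, :2], 0.0)

    def test_parent_offspring_entries_preserved(self, trio_kinship):
        K = expand_kinship(trio_kinship, ["fa", "c1"])
        assert K[0, 1] == 0.5

    def test_unmapped_sample_raises(self, trio_kinship):
        with pytest.raises(KeyError):
            expand_kinship(trio_kinship, ["fa", "nobody"])

    @pytest.mark.parametrize("seed", range(10))
    def test_expanded_matrix_psd_random_pedigrees(self, seed):
        _, kin = simulate_pedigree(n_founders=8, n_generations=3, seed=seed)
        rng = np.random.default_rng(seed)
        samples = list(
            rng.choice(kin.individual_ids, size=len(kin.individual_ids) + 5)
        )
        K = expand_kinship(kin, samples)
        assert np.linalg.eigvalsh(K)[0] >= -1e-8


class TestBuildDesign:
    def _covariates(self):
        rng = np.random.default_rng(13)
        n = 12
        base = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "individual_id": [f"i{i}" for i in range(n)],
                "habitat_low_quality_at_birth": [1, 1, 1, 0, 0, 0] * 2,
                "cumulative": [3, 1, 0, 2, 4, 0, 1, 2, 3, 0, 5, 2],
                "drought": [1, 0, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1],
                "maternal_loss": [0, 1, 0, 0, 1, 0, 1, 0, 0, 1, 1, 0],
                "close_sibling": [0, 0, 0, 1, 0, 0, 1, 1, 0, 0, 1, 0],
                "low_maternal_rank": [1, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 1],
                "large_group": [1, 0, 0, 0, 0, 0, 1, 0, 1, 0, 1, 1],
                "age_at_sampling": list(rng.uniform(4, 20, n).round(1)),
                "rank_at_sampling": [2, 4, None, 1, 3, 5, 7, 2, 9, 4, 6, 8],
                "sex": ["male", "female"] * 6,
                "batch": ["b0", "b0", "b1", "b1", "b0", "b1"] * 2,
                "conversion_rate": list(rng.uniform(0.985, 0.999, n).round(4)),
                "mean_depth": list(rng.uniform(20, 40, n).round(1)),
            }
        )
        base.loc[4, "age_at_sampling"] = 7.0
        return base

    def test_model2_nesting_hand_coded(self):
        cov = self._covariates()
        design = build_design(ModelSpec(2), cov)
        X = design.X
        # low-habitat individual with cumulative 3: nested terms split
        assert X.loc["s0", "adversity_low"] == 3.0
        assert X.loc["s0", "adversity_high"] == 0.0
        assert X.loc["s3", "adversity_low"] == 0.0
        assert X.loc["s3", "adversity_high"] == 2.0
        # sex-nested rank, no sex main effect
        assert X.loc["s0", "male_rank"] == 2.0
        assert X.loc["s0", "female_rank"] == 0.0
        assert X.loc["s1", "female_rank"] == 4.0
        assert "sex" not in X.columns
        # hand-enumerated row: s4 is a high-habitat male, cumulative 4,
        # rank 3, batch b0
        expected_s4 = {
            "intercept": 1.0, "habitat_low": 0.0, "adversity_low": 0.0,
            "adversity_high": 4.0, "age": 7.0, "female_rank": 0.0,
            "male_rank": 3.0, "batch_b1": 0.0,
            "conversion_rate": float(cov.loc[4, "conversion_rate"]),
            "mean_depth": float(cov.loc[4, "mean_depth"]),
        }
        for col, val in expected_s4.items():
            assert X.loc["s4", col] == pytest.approx(val)

    def test_model1_drops_missing_rank_model2_keeps(self):
        cov = self._covariates()
        d1 = build_design(ModelSpec(1), cov)
        d2 = build_design(ModelSpec(2), cov)
        assert "s2" in d1.dropped_samples and "s2" not in d1.sample_ids
        assert "s2" in d2.sample_ids
        # mean imputation within sex for the retained missing-rank male
        assert d2.X.loc["s2", "male_rank"] == pytest.approx(
            np.mean([2, 3, 7, 9, 6])
        )

    def test_all_female_cohort_drops_male_rank_with_warning(self):
        cov = self._covariates()
        cov["sex"] = "female"
        with pytest.warns(UserWarning, match="male_rank"):
            design = build_design(ModelSpec(2), cov)
        assert "male_rank" not in design.X.columns
        assert "male_rank" in design.dropped_columns

    def test_model3_uses_component_flags(self):
        design = build_design(ModelSpec(3), self._covariates())
        assert design.X.loc["s0", "drought_low"] == 1.0
        assert design.X.loc["s3", "drought_high"] == 1.0
        assert design.X.loc["s3", "drought_low"] == 0.0


class TestFitSite:
    def test_constant_fraction_gives_null_effect(self):
        n = 24
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {"intercept": np.ones(n), "x": rng.normal(size=n)}
        )
        r = np.full(n, 20)
        m = np.full(n, 10)
        res = fit_site(m, r, X, None)
        assert abs(res.params["x"]) < 1e-8
        assert res.sigma2_g < 1e-3

    def test_glm_oracle_equivalence(self):
        """Fixed zero variances reproduce a hand-coded IRLS fit to 1e-6."""
        rng = np.random.default_rng(4)
        n = 50
        Xmat = np.column_stack([np.ones(n), rng.normal(size=n)])
        r = rng.integers(10, 40, size=n)
        m = rng.binomial(r, expit(-0.5 + 0.8 * Xmat[:, 1]))
        res = fit_site(
            m, r, pd.DataFrame(Xmat, columns=["intercept", "x"]),
            np.eye(n), fix_sigma_g=0.0, fix_sigma_e=0.0,
        )
        beta_oracle = irls_binomial_oracle(m, r, Xmat)
        assert np.allclose(res.params.to_numpy(), beta_oracle, atol=1e-6)

    def test_grid_oracle_small_pedigree(self):
        """Laplace fit beats/matches a brute-force variance grid (n = 8)."""
        # parent-offspring pairs: expected kinship entry 0.5
        K = np.eye(8)
        for i in range(0, 8, 2):
            K[i, i + 1] = K[i + 1, i] = 0.5
        rng = np.random.default_rng(9)
        x = rng.normal(size=8)
        X = np.column_stack([np.ones(8), x])
        L = np.linalg.cholesky(K + 1e-9 * np.eye(8))
        eta = 0.3 + 1.0 * x + np.sqrt(0.5) * (L @ rng.normal(size=8))
        r = np.full(8, 60)
        m = rng.binomial(r, expit(eta))
        res = fit_site(m, r, pd.DataFrame(X, columns=["intercept", "x"]), K)

        grid = np.geomspace(1e-3, 3.0, 10)
        best_ll, best_beta, best_sg2 = -np.inf, None, None
        for sg2 in grid:
            for se2 in grid:
                ll, beta = laplace_loglik_oracle(
                    m.astype(float), r.astype(float), X, K, sg2, se2
                )
                if ll > best_ll:
                    best_ll, best_beta, best_sg2 = ll, beta, sg2
        ll_fit, _ = laplace_loglik_oracle(
            m.astype(float), r.astype(float), X, K,
            max(res.sigma2_g, 1e-12), max(res.sigma2_e, 1e-12),
        )
        # the continuous optimiser must do at least as well as the grid
        assert ll_fit >= best_ll - 1e-3
        assert abs(res.params["x"] - best_beta[1]) < 0.05
        # variance agreement to grid resolution (grid step ~2.4x)
        assert (
            best_sg2 / 3 <= max(res.sigma2_g, 1e-3) <= best_sg2 * 3
            or abs(res.sigma2_g - best_sg2) < 0.05
        )

    def test_zero_coverage_samples_dropped(self):
        n = 20
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        r = np.full(n, 20)
        r[:3] = 0
        m = rng.binomial(r, 0.4)
        res = fit_site(m, r, X, None)
        assert res.model.nobs == n - 3

    def test_non_psd_kinship_rejected(self):
        n = 6
        K = -np.eye(n)
        X = pd.DataFrame({"intercept": np.ones(n)})
        with pytest.raises(ValueError, match="PSD"):
            fit_site(np.full(n, 5), np.full(n, 10), X, K)

    def test_summary_lists_terms(self):
        rng = np.random.default_rng(1)
        n = 20
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        r = np.full(n, 25)
        m = rng.binomial(r, 0.5)
        text = fit_site(m, r, X, None).summary()
        assert "sigma2_g" in text and "x" in text


class TestScan:
    def _setup(self, n_sites, n_samples=40, beta_habitat=0.0, seed=0):
        rng = np.random.default_rng(seed)
        cov = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n_samples)],
                "individual_id": [f"i{i}" for i in range(n_samples)],
                "habitat_low_quality_at_birth": (
                    np.arange(n_samples) < n_samples // 4
                ).astype(int),
                "cumulative": rng.integers(0, 6, n_samples),
                "drought": rng.integers(0, 2, n_samples),
                "maternal_loss": rng.integers(0, 2, n_samples),
                "close_sibling": rng.integers(0, 2, n_samples),
                "low_maternal_rank": rng.integers(0, 2, n_samples),
                "large_group": rng.integers(0, 2, n_samples),
                "age_at_sampling": rng.uniform(4, 20, n_samples),
                "rank_at_sampling": rng.integers(1, 20, n_samples),
                "sex": np.where(rng.random(n_samples) < 0.5, "male", "female"),
                "batch": "b0",
                "conversion_rate": 0.99,
                "mean_depth": 30.0,
            }
        )
        kin = KinshipMatrix(
            individual_ids=list(cov["individual_id"]), K=np.eye(n_samples)
        )
        low = cov["habitat_low_quality_at_birth"].to_numpy(float)
        eta = rng.normal(0, 1, size=(n_sites, 1)) + beta_habitat * low
        total = rng.integers(15, 45, size=(n_sites, n_samples))
        meth = rng.binomial(total, expit(eta))
        counts = MethylationCounts(
            site_ids=[f"chr1_{100 + i}" for i in range(n_sites)],
            sample_ids=list(cov["sample_id"]),
            meth=meth,
            total=total,
        )
        return counts, cov, kin

    def test_null_sites_have_moderate_z(self):
        counts, cov, kin = self._setup(60, seed=5)
        res = scan(counts, ModelSpec(2), cov, kin)
        assert (res["z"].abs() < 6).all()
        assert res["converged"].all()

    def test_sample_permutation_leaves_z_unchanged(self):
        counts, cov, kin = self._setup(5, seed=6)
        res1 = scan(counts, ModelSpec(2), cov, kin)
        order = list(np.random.default_rng(0).permutation(counts.n_samples))
        counts_p = counts.reorder_samples(order)
        cov_p = cov.iloc[order].reset_index(drop=True)
        res2 = scan(counts_p, ModelSpec(2), cov_p, kin)
        merged = res1.merge(res2, on=["site_id", "term"], suffixes=("_a", "_b"))
        assert np.allclose(merged["z_a"], merged["z_b"], atol=1e-6)

    def test_qvalues_present_per_term(self):
        counts, cov, kin = self._setup(10, seed=7)
        res = scan(counts, ModelSpec(1), cov, kin)
        for _, grp in res.groupby("term"):
            assert grp["q"].notna().all()
            assert (grp["q"] >= grp["p"] - 1e-12).all()


class TestBhFdr:
    def test_hand_worked_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr(np.array([1.0]))[0] == 1.0

    def test_nan_excluded(self):
        q = bh_fdr(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1])
        assert not np.isnan(q[0])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40)
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_step_up_oracle(self, pvals):
        p = np.array(pvals)
        assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([1.5]))


class TestStandardizedEffect:
    @pytest.mark.parametrize("beta,se,z", [(1.0, 0.5, 2.0), (0.0, 1.0, 0.0)])
    def test_values(self, beta, se, z):
        assert standardized_effect(beta, se) == z

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            standardized_effect(1.0, 0.0)

    def test_z_squared_is_wald_chisq(self):
        rng = np.random.default_rng(3)
        n = 30
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        r = np.full(n, 30)
        m = rng.binomial(r, expit(0.4 * X["x"].to_numpy()))
        res = fit_site(m, r, X, None)
        z = standardized_effect(float(res.params["x"]), float(res.bse["x"]))
        assert z**2 == pytest.approx(float(res.zvalues["x"]) ** 2, abs=1e-8)
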