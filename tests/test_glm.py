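import numpy as np
import pandas as pd
import pytest

from somnet.design import make_design_manifest
from somnet.glm import (
    FULL_COLUMNS,
    FULL_GROUPS,
    GlmPriors,
    _fit_model,
    _log_posterior_and_grad,
    bh_adjust,
    build_design,
    classify_and_intersect,
    fit_gene,
    lrt,
    mean_log_expression_gen0,
)
from somnet.normalize import size_factors, split_counts


@pytest.fixture(scope="module")
def design_f(one_rep_manifest_module, factors_module):
    mani, factors = one_rep_manifest_module, factors_module
    return build_design(mani, factors)


@pytest.fixture(scope="module")
def one_rep_manifest_module():
    m = make_design_manifest(rna_replicates=(1,))
    return m[m.sex == "F"]


@pytest.fixture(scope="module")
def factors_module(one_rep_manifest_module):
    return pd.Series(1.0, index=one_rep_manifest_module["sample_id"])


class TestBuildDesign:
    def test_control_rep1_gen0_row(self, design_f, one_rep_manifest_module):
        mani = one_rep_manifest_module.reset_index(drop=True)
        i = mani.index[
            (mani.scheme == "control") & (mani.population_replicate == 1) & (mani.generation == 0)
        ][0]
        assert list(design_f.X[i]) == [1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]

    def test_short_rep1_gen13_row(self, design_f, one_rep_manifest_module):
        mani = one_rep_manifest_module.reset_index(drop=True)
        i = mani.index[
            (mani.scheme == "short") & (mani.population_replicate == 1) & (mani.generation == 13)
        ][0]
        row = dict(zip(FULL_COLUMNS, design_f.X[i]))
        assert row == {
            "b1": 1, "b2": 0, "b_short1": 1, "b_short2": 0, "b_long1": 0, "b_long2": 0,
            "b_gen": 13, "b_short_gen1": 13, "b_short_gen2": 0,
            "b_long_gen1": 0, "b_long_gen2": 0,
        }

    def test_every_sample_activates_one_intercept(self, design_f):
        assert np.all(design_f.X[:, 0] + design_f.X[:, 1] == 1)

    def test_empty_manifest_gives_empty_matrix(self):
        empty = pd.DataFrame(
            columns=["scheme", "population_replicate", "generation", "sex", "sample_id"]
        )
        d = build_design(empty, pd.Series(dtype=float))
        assert d.X.shape == (0, 11)

    def test_unknown_scheme_rejected(self, factors_module, one_rep_manifest_module):
        bad = one_rep_manifest_module.copy()
        bad.loc[bad.index[0], "scheme"] = "medium"
        with pytest.raises(ValueError, match="scheme"):
            build_design(bad, factors_module)

    def test_mixed_sexes_rejected(self, factors_module):
        m = make_design_manifest(rna_replicates=(1,))
        with pytest.raises(ValueError, match="sex"):
            build_design(m, factors_module)


class TestLrt:
    def test_equal_likelihoods_give_p_one(self):
        stat, p = lrt(-100.0, -100.0)
        assert stat == 0.0
        assert p == 1.0

    def test_chi_square_quantile(self):
        """statistic 9.488 at df 4 sits at the 5% tail."""
        _, p = lrt(-100.0, -100.0 - 9.488 / 2, df=4)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_chi_square_cdf_value(self):
        _, p = lrt(-100.0, -100.25, df=4)
        assert p == pytest.approx(0.9735, abs=5e-4)

    def test_negative_statistic_is_an_error(self):
        with pytest.raises(RuntimeError):
            lrt(-110.0, -100.0)


class TestBhAdjust:
    def test_step_up_by_hand(self):
        q, _ = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_pvalues_unchanged(self):
        q, _ = bh_adjust([0.3, 0.3, 0.3])
        assert np.allclose(q, 0.3)

    def test_single_pvalue(self):
        q, _ = bh_adjust([0.123])
        assert q[0] == pytest.approx(0.123)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=50)
        q, _ = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFitGene:
    def test_constant_counts_shrink_interactions(self, design_f, one_rep_manifest_module):
        y = np.full(design_f.X.shape[0], 50)
        priors = GlmPriors(y0bar=np.log(51.0))
        fit = fit_gene(y, design_f, priors, n_restarts=2)
        for name in ("b_short_gen1", "b_short_gen2", "b_long_gen1", "b_long_gen2"):
            assert abs(fit.params[name]) < 0.1
        assert fit.p > 0.5

    def test_map_beats_random_draws(self, design_f, one_rep_manifest_module, rng):
        mani = one_rep_manifest_module
        y = rng.poisson(
            np.exp(4.0 + 0.03 * mani["generation"].to_numpy())
        )
        priors = GlmPriors(y0bar=4.0)
        fit = fit_gene(y, design_f, priors, n_restarts=3)
        res = _fit_model(y, design_f.X, design_f.offsets, priors, FULL_GROUPS,
                         n_restarts=3, seed=0)
        best = res["log_posterior"]
        for _ in range(100):
            theta = res["theta"] + rng.normal(0, 0.2, res["theta"].shape)
            lp, _ = _log_posterior_and_grad(
                theta, y.astype(float), design_f.X, design_f.offsets, priors, FULL_GROUPS
            )
            assert lp <= best + 1e-6

    def test_flat_priors_single_replicate_match_ml_oracle(self):
        """Wide priors + one replicate: MAP equals the NB-GLM MLE."""
        sm = pytest.importorskip("statsmodels.api")
        manifest = make_design_manifest(pop_replicates=(1,), rna_replicates=(1,), sexes=("F",))
        rng = np.random.default_rng(8)
        gen = manifest["generation"].to_numpy(float)
        short = (manifest["scheme"] == "short").to_numpy(float)
        long_ = (manifest["scheme"] == "long").to_numpy(float)
        eta = 4.0 + 0.02 * gen - 0.3 * short + 0.25 * long_ - 0.05 * short * gen
        y = rng.poisson(rng.gamma(8.0, np.exp(eta) / 8.0))
        factors = pd.Series(1.0, index=manifest["sample_id"])
        design = build_design(manifest, factors)
        priors = GlmPriors(y0bar=4.0, hyper_mu_sd=1e4, hyper_sigma_scale=1e4,
                           gen_slope_sd=1e4)
        fit = fit_gene(y, design, priors, n_restarts=4)
        # oracle: statsmodels NB2 with the same (collapsed) design
        X = np.column_stack([np.ones_like(gen), short, long_, gen, short * gen, long_ * gen])
        ml = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
        betas = [
            fit.params["b1"],
            fit.params["b_short1"],
            fit.params["b_long1"],
            fit.params["b_gen"],
            fit.params["b_short_gen1"],
            fit.params["b_long_gen1"],
        ]
        assert np.allclose(betas, ml.params[:6], atol=2e-3)
        assert fit.alpha == pytest.approx(1.0 / ml.params[-1], rel=0.02)

    def test_tightening_hyper_scale_pools_replicates(self, design_f, one_rep_manifest_module, rng):
        """Smaller half-Cauchy scale pulls replicate slopes together."""
        mani = one_rep_manifest_module
        gen = mani["generation"].to_numpy(float)
        short = (mani["scheme"] == "short").to_numpy(float)
        rep2 = (mani["population_replicate"] == 2).to_numpy(float)
        eta = 4.0 - (0.04 + 0.06 * rep2) * short * gen
        y = rng.poisson(rng.gamma(10.0, np.exp(eta) / 10.0))
        gaps = []
        for scale in (1.0, 0.05, 0.005):
            priors = GlmPriors(y0bar=4.0, hyper_sigma_scale=scale)
            fit = fit_gene(y, design_f, priors, n_restarts=2)
            gaps.append(abs(fit.params["b_short_gen1"] - fit.params["b_short_gen2"]))
        assert gaps[2] <= gaps[1] <= gaps[0] + 1e-6


def test_classify_and_intersect_sign_logic():
    f = pd.DataFrame(
        {
            "q": [1e-5, 1e-5, 0.5, 1e-5],
            "mu_short_gen": [-0.02, 0.01, -0.05, -0.03],
            "mu_long_gen": [0.03, 0.02, 0.06, 0.04],
        },
        index=["a", "b", "c", "d"],
    )
    m = pd.DataFrame(
        {
            "q": [1e-5, 1e-5, 1e-5, 0.9],
            "mu_short_gen": [-0.01, -0.02, -0.05, -0.03],
            "mu_long_gen": [0.02, -0.01, 0.06, 0.04],
        },
        index=["a", "b", "c", "d"],
    )
    out = classify_and_intersect(f, m)
    assert out["F"] == {"a", "d"}
    assert out["M"] == {"a", "c"}
    assert out["both"] == {"a"}
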