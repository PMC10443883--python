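import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somnet.spearman import (
    compare_all_pairs,
    fisher_ci,
    fisher_difference_test,
    intervals_overlap,
    spearman_rho,
)


class TestSpearmanRho:
    def test_monotone_increasing_gives_one(self, rng):
        x = rng.normal(size=20)
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_monotone_decreasing_gives_minus_one(self, rng):
        x = rng.normal(size=20)
        assert spearman_rho(x, -(x ** 3)) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 7.0, 7.0, 9.0])
        rx, ry = stats.rankdata(x), stats.rankdata(y)  # mid-ranks
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 2.0], [2.0, 1.0])


class TestFisherCi:
    def test_zero_rho_closed_form(self):
        lo, hi = fisher_ci(0.0, 26)
        half = np.tanh(stats.norm.ppf(0.975) / np.sqrt(23))
        assert lo == pytest.approx(-half)
        assert hi == pytest.approx(half)

    def test_degenerate_level_collapses(self):
        lo, hi = fisher_ci(0.4, 30, level=1e-12)
        assert lo == pytest.approx(0.4, abs=1e-6)
        assert hi == pytest.approx(0.4, abs=1e-6)

    def test_interval_stays_inside_unit_range(self):
        lo, hi = fisher_ci(0.5, 26)
        assert -1 < lo < 0.5 < hi < 1

    @pytest.mark.parametrize("rho,n", [(1.0, 26), (0.5, 3)])
    def test_invalid_inputs_rejected(self, rho, n):
        with pytest.raises(ValueError):
            fisher_ci(rho, n)


def test_overlap_is_symmetric():
    a, b = (0.1, 0.5), (0.4, 0.9)
    assert intervals_overlap(a, b) == intervals_overlap(b, a) is True
    c = (0.6, 0.9)
    assert intervals_overlap(a, c) == intervals_overlap(c, a) is False


def make_expr(rng, genes, n_samples, rho=0.0):
    cov = np.full((len(genes), len(genes)), rho) + (1 - rho) * np.eye(len(genes))
    vals = rng.multivariate_normal(np.zeros(len(genes)), cov, size=n_samples).T
    return pd.DataFrame(vals, index=genes, columns=[f"s{j}" for j in range(n_samples)])


class TestCompareAllPairs:
    def test_pair_enumeration_count(self, rng):
        genes = [f"g{i}" for i in range(10)]
        expr = {s: make_expr(rng, genes, 26) for s in ("short", "control", "long")}
        out = compare_all_pairs(expr, genes)
        assert len(out) == 45 * 3  # C(10,2) pairs x schemes

    def test_two_genes_one_pair(self, rng):
        genes = ["a", "b"]
        expr = {s: make_expr(rng, genes, 26) for s in ("control", "long")}
        out = compare_all_pairs(expr, genes)
        assert len(out) == 2
        assert {c.scheme for c in out} == {"control", "long"}

    def test_planted_long_only_correlation_is_flagged(self):
        """rho=0.8 in 'long' only: overlap with control mostly rejected."""
        hits, null_hits = 0, 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            expr = {
                "control": make_expr(rng, ["a", "b"], 26, rho=0.0),
                "long": make_expr(rng, ["a", "b"], 26, rho=0.8),
                "short": make_expr(rng, ["a", "b"], 26, rho=0.0),
            }
            out = {c.scheme: c for c in compare_all_pairs(expr, ["a", "b"])}
            hits += not out["long"].overlaps_control
            null_hits += not out["short"].overlaps_control
        assert hits >= 0.5 * n_seeds
        assert null_hits <= 0.1 * n_seeds

    def test_nonoverlap_calls_subset_of_difference_test(self):
        """CI non-overlap is conservative against the z-difference test."""
        for seed in range(60):
            rng = np.random.default_rng(seed)
            expr = {
                "control": make_expr(rng, ["a", "b"], 26, rho=0.0),
                "long": make_expr(rng, ["a", "b"], 26, rho=rng.uniform(0, 0.9)),
            }
            out = {c.scheme: c for c in compare_all_pairs(expr, ["a", "b"])}
            long_c = out["long"]
            ctl = out["control"]
            if not long_c.overlaps_control:
                p_diff = fisher_difference_test(long_c.rho, long_c.n, ctl.rho, ctl.n)
                assert p_diff < 0.05
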