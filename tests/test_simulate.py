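import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somnet.design import make_design_manifest
from somnet.simulate import (
    InteractingPair,
    PopulationConfig,
    SimulationConfig,
    simulate_counts,
    simulate_phenotypes_with_selection,
)
from somnet.qgen import realized_heritability, selection_stats


@pytest.fixture(scope="module")
def flat_manifest():
    return make_design_manifest(rna_replicates=(1,))


def test_counts_are_deterministic_given_seed(flat_manifest):
    cfg = SimulationConfig(n_genes=5, n_intergenic=2, seed=7)
    a = simulate_counts(flat_manifest, cfg)
    b = simulate_counts(flat_manifest, cfg)
    pd.testing.assert_frame_equal(a, b)


def test_no_signal_counts_have_stable_mean(flat_manifest):
    """With zero slopes the generation-13 mean matches generation 0."""
    cfg = SimulationConfig(n_genes=30, n_intergenic=5, dispersion=1e4,
                           replicate_sd=0.0, seed=3)
    counts = simulate_counts(flat_manifest, cfg).drop(columns="region")
    m = flat_manifest
    s0 = m[m.generation == 0]["sample_id"]
    s13 = m[m.generation == 13]["sample_id"]
    mean0 = counts.loc[:, s0].to_numpy()[:30].mean()
    mean13 = counts.loc[:, s13].to_numpy()[:30].mean()
    n = 30 * len(s0)
    se = np.sqrt(np.exp(5.0) / n * 2)  # near-Poisson at huge dispersion
    assert abs(mean13 - mean0) < 3 * se


def test_log_linear_slope_gives_expected_count_ratio(flat_manifest):
    """slope 0.1/generation over 13 generations => mean ratio e^1.3."""
    slopes = np.zeros(20)
    slopes[0] = 0.1
    cfg = SimulationConfig(n_genes=20, n_intergenic=2, slope_long=slopes,
                           dispersion=1e5, replicate_sd=0.0, seed=5)
    counts = simulate_counts(flat_manifest, cfg).drop(columns="region")
    m = flat_manifest[flat_manifest.scheme == "long"]
    g0 = counts.loc["gene_0000", m[m.generation == 0]["sample_id"]].mean()
    g13 = counts.loc["gene_0000", m[m.generation == 13]["sample_id"]].mean()
    assert g13 / g0 == pytest.approx(np.exp(1.3), rel=0.2)


def test_null_pair_latent_correlation_centered_on_zero():
    """sigma12^2 = 0: cross-gene trajectory correlations average to ~0."""
    manifest = make_design_manifest(rna_replicates=(1,), sexes=("F",))
    corrs = []
    for seed in range(60):
        cfg = SimulationConfig(
            n_genes=2, n_intergenic=1, dispersion=1e4, replicate_sd=0.0, seed=seed,
            interacting_pairs=[InteractingPair(0, 1, "long", 1.0, 1.0, 0.0, 3.0)],
        )
        counts = simulate_counts(manifest, cfg).drop(columns="region")
        m = manifest[manifest.scheme == "long"].sort_values(["generation", "population_replicate"])
        a = np.log(counts.loc["gene_0000", m.sample_id].to_numpy(float) + 1)
        b = np.log(counts.loc["gene_0001", m.sample_id].to_numpy(float) + 1)
        corrs.append(np.corrcoef(a, b)[0, 1])
    se = np.std(corrs, ddof=1) / np.sqrt(len(corrs))
    assert abs(np.mean(corrs)) < 2.5 * se + 0.05


def test_planted_pair_induces_positive_correlation():
    manifest = make_design_manifest(rna_replicates=(1,), sexes=("F",))
    corrs = []
    for seed in range(30):
        cfg = SimulationConfig(
            n_genes=2, n_intergenic=1, dispersion=1e4, replicate_sd=0.0, seed=seed,
            interacting_pairs=[InteractingPair(0, 1, "long", 1.5, 1.5, 0.95 * 1.5, 2.0)],
        )
        counts = simulate_counts(manifest, cfg).drop(columns="region")
        m = manifest[manifest.scheme == "long"].sort_values(["generation", "population_replicate"])
        a = np.log(counts.loc["gene_0000", m.sample_id].to_numpy(float) + 1)
        b = np.log(counts.loc["gene_0001", m.sample_id].to_numpy(float) + 1)
        corrs.append(np.corrcoef(a, b)[0, 1])
    assert np.mean(corrs) > 0.5


def test_unknown_gene_in_pair_rejected():
    with pytest.raises(ValueError, match="unknown gene"):
        SimulationConfig(
            n_genes=3, interacting_pairs=[InteractingPair(0, 7, "long", 1, 1, 0.5, 3)]
        )


def test_invalid_signal_covariance_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(
            n_genes=3, interacting_pairs=[InteractingPair(0, 1, "long", 1, 1, 2.0, 3)]
        )


def test_nb_dispersion_matches_configuration(flat_manifest):
    """Constant-mean genes show the configured mean-variance relation."""
    cfg = SimulationConfig(n_genes=200, n_intergenic=2, dispersion=5.0,
                           replicate_sd=0.0, seed=21)
    counts = simulate_counts(flat_manifest, cfg).drop(columns="region").to_numpy()[:200]
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    # regression of (var - mean) on mean^2 recovers 1/alpha
    slope = np.sum((var - mean) * mean ** 2) / np.sum(mean ** 4)
    assert slope == pytest.approx(1 / 5.0, rel=0.25)


# ---------------------------------------------------------- phenotypes


def test_phenotypes_respect_sleep_bounds():
    ph = simulate_phenotypes_with_selection(
        PopulationConfig(scheme="long", mean0=650.0), 0.3, 10, seed=2
    )
    assert ph["night_sleep_minutes"].between(0.0, 720.0).all()


def test_selected_counts_per_generation():
    cfg = PopulationConfig(scheme="short", n_measured=50, n_selected=10)
    ph = simulate_phenotypes_with_selection(cfg, 0.2, 5, seed=3)
    counts = ph[ph.selected_parent].groupby(["generation", "sex"]).size()
    assert (counts == 10).all()


def test_zero_heritability_gives_no_response():
    """h2 = 0: regression of cumulated R on cumulated S is ~0."""
    slopes = []
    for seed in range(25):
        ph = simulate_phenotypes_with_selection(
            PopulationConfig(scheme="short"), 0.0, 10, seed=seed
        )
        traj = selection_stats(ph, "short", 1)
        slopes.append(realized_heritability(traj).h2)
    t = np.mean(slopes) / (np.std(slopes, ddof=1) / np.sqrt(len(slopes)))
    assert abs(t) < 3.0


def test_invalid_heritability_rejected():
    with pytest.raises(ValueError):
        simulate_phenotypes_with_selection(PopulationConfig(), 1.5, 3, seed=0)


def test_selection_asymmetry_near_upper_bound():
    """Baseline near the 720-minute ceiling: downward selection responds more."""
    short_resp, long_resp = [], []
    for seed in range(12):
        ps = simulate_phenotypes_with_selection(PopulationConfig(scheme="short"), 0.15, 13, seed)
        pl = simulate_phenotypes_with_selection(PopulationConfig(scheme="long"), 0.15, 13, seed)
        gs = ps.groupby("generation")["night_sleep_minutes"].mean()
        gl = pl.groupby("generation")["night_sleep_minutes"].mean()
        short_resp.append(gs.iloc[0] - gs.iloc[-1])
        long_resp.append(gl.iloc[-1] - gl.iloc[0])
    assert np.mean(short_resp) > np.mean(long_resp)


def test_phenotypes_deterministic_given_seed():
    a = simulate_phenotypes_with_selection(PopulationConfig(), 0.15, 4, seed=9)
    b = simulate_phenotypes_with_selection(PopulationConfig(), 0.15, 4, seed=9)
    pd.testing.assert_frame_equal(a, b)
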