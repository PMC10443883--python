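"""Synthetic phenotypes and counts emulating the selection experiment.

Two generators live here:

* :func:`simulate_counts` draws a genes+intergenic x samples matrix of
  negative-binomial read counts whose log-mean follows scheme-specific
  linear generation trends with replicate offsets; designated gene pairs
  additionally receive correlated latent trajectories drawn from the
  same two-channel squared-exponential GP prior that the inference
  modules fit, so recovery tests are well-posed.

* :func:`simulate_phenotypes_with_selection` runs truncation selection
  on night sleep (minutes per 12-h night, bounded [0, 720]) under an
  infinitesimal additive model: phenotype = breeding value + normal
  environment, offspring breeding value = mid-parent + Mendelian
  segregation noise.  The best (or worst) ``n_selected`` of
  ``n_measured`` flies per sex are parents each generation; controls
  pick parents at random.

All randomness flows from a single integer seed; per-gene substreams
are derived deterministically from (seed, gene index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import PairKernelParams, assemble_pair_covariance, robust_cholesky, se_kernel_matrix

PHENOTYPE_COLUMNS = [
    "fly_id",
    "scheme",
    "population_replicate",
    "generation",
    "sex",
    "night_sleep_minutes",
    "selected_parent",
]

SLEEP_MIN, SLEEP_MAX = 0.0, 720.0


@dataclass
class InteractingPair:
    """A planted gene-gene interaction active in one selection scheme."""

    gene_i: int
    gene_j: int
    scheme: str
    sigma2_i: float
    sigma2_j: float
    sigma2_12: float
    ell: float

    def kernel_params(self) -> PairKernelParams:
        return PairKernelParams(
            sigma2_1=self.sigma2_i,
            sigma2_2=self.sigma2_j,
            sigma2_12=self.sigma2_12,
            ell1=self.ell,
            ell2=self.ell,
        )


@dataclass
class SimulationConfig:
    """Generative settings for the synthetic count matrix.

    ``baseline_log_mean`` is the log expected count of each gene at
    generation 0 in controls; ``slope_short``/``slope_long`` are
    per-generation log-scale trends applied in the respective scheme
    (controls always follow ``slope_control``).  ``replicate_sd`` is the
    SD of population-replicate log offsets.  ``dispersion`` is the NB
    concentration alpha (variance mu + mu^2/alpha).
    """

    n_genes: int = 50
    n_intergenic: int = 20
    baseline_log_mean: float | np.ndarray = 5.0
    slope_short: float | np.ndarray = 0.0
    slope_long: float | np.ndarray = 0.0
    slope_control: float | np.ndarray = 0.0
    replicate_sd: float = 0.05
    dispersion: float = 10.0
    intergenic_log_mean: float = 1.0
    interacting_pairs: list[InteractingPair] = field(default_factory=list)
    #: SD of per-gene latent GP wiggle for non-interacting genes (0 = none)
    background_gp_sd: float = 0.0
    background_gp_ell: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")
        for pair in self.interacting_pairs:
            for g in (pair.gene_i, pair.gene_j):
                if not (0 <= g < self.n_genes):
                    raise ValueError(f"interacting pair references unknown gene index {g}")
            pair.kernel_params()  # validates |sigma12^2| <= sigma_i sigma_j

    def _per_gene(self, value: float | np.ndarray) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_genes,))
        return np.array(arr)


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, gene_index]))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 counts via gamma-Poisson mixture: var = mean + mean^2/alpha."""
    lam = rng.gamma(shape=alpha, scale=np.asarray(mean) / alpha)
    return rng.poisson(lam)


def simulate_counts(manifest: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Draw the synthetic count matrix for ``manifest``.

    Returns a DataFrame indexed by feature id with a leading ``region``
    column (genic/intergenic) and one integer column per sample_id.
    """
    slopes = {
        "short": config._per_gene(config.slope_short),
        "long": config._per_gene(config.slope_long),
        "control": config._per_gene(config.slope_control),
    }
    baseline = config._per_gene(config.baseline_log_mean)
    unknown = set(manifest["scheme"]) - set(slopes)
    if unknown:
        raise ValueError(f"unknown scheme labels in manifest: {sorted(unknown)}")

    gens = np.sort(manifest["generation"].unique())
    sexes = list(manifest["sex"].unique())
    scheme_reps = sorted(
        set(zip(manifest["scheme"], manifest["population_replicate"])), key=str
    )

    # latent GP deviations per (gene, sex, scheme) over the generation grid
    deviations: dict[tuple[int, str, str], np.ndarray] = {}
    for k, pair in enumerate(config.interacting_pairs):
        rng = _gene_rng(config.seed, config.n_genes + config.n_intergenic + k)
        kmat = assemble_pair_covariance(pair.kernel_params(), gens, gens, jitter=1e-8)
        chol = robust_cholesky(kmat, jitter=1e-8)
        for sex in sexes:
            draw = chol @ rng.standard_normal(2 * len(gens))
            deviations[(pair.gene_i, sex, pair.scheme)] = draw[: len(gens)]
            deviations[(pair.gene_j, sex, pair.scheme)] = draw[len(gens):]

    paired_genes = {
        (p.gene_i, p.scheme) for p in config.interacting_pairs
    } | {(p.gene_j, p.scheme) for p in config.interacting_pairs}

    manifest = manifest.reset_index(drop=True)
    sample_ids = manifest["sample_id"].to_numpy()
    gen_idx = np.searchsorted(gens, manifest["generation"].to_numpy())
    n_samples = len(manifest)

    rows = np.empty((config.n_genes + config.n_intergenic, n_samples), dtype=np.int64)
    feature_ids, regions = [], []

    for g in range(config.n_genes):
        rng = _gene_rng(config.seed, g)
        rep_offsets = {
            sr: rng.normal(0.0, config.replicate_sd) for sr in scheme_reps
        }
        if config.background_gp_sd > 0:
            kmat = se_kernel_matrix(gens, config.background_gp_sd ** 2, config.background_gp_ell)
            chol = robust_cholesky(kmat, jitter=1e-8)
            wiggle = {sex: chol @ rng.standard_normal(len(gens)) for sex in sexes}
        else:
            wiggle = {sex: np.zeros(len(gens)) for sex in sexes}

        eta = np.full(n_samples, baseline[g])
        for i, row in enumerate(manifest.itertuples(index=False)):
            scheme = row.scheme
            eta[i] += rep_offsets[(scheme, row.population_replicate)]
            eta[i] += slopes[scheme][g] * row.generation
            if (g, scheme) in paired_genes:
                eta[i] += deviations[(g, row.sex, scheme)][gen_idx[i]]
            elif config.background_gp_sd > 0:
                eta[i] += wiggle[row.sex][gen_idx[i]]
        rows[g] = _nb_draw(rng, np.exp(eta), config.dispersion)
        feature_ids.append(f"gene_{g:04d}")
        regions.append("genic")

    for k in range(config.n_intergenic):
        rng = _gene_rng(config.seed, config.n_genes + k)
        mean = np.full(n_samples, np.exp(config.intergenic_log_mean))
        rows[config.n_genes + k] = _nb_draw(rng, mean, config.dispersion)
        feature_ids.append(f"intergenic_{k:04d}")
        regions.append("intergenic")

    out = pd.DataFrame(rows, index=pd.Index(feature_ids, name="feature_id"), columns=sample_ids)
    out.insert(0, "region", regions)
    return out


@dataclass
class PopulationConfig:
    """One replicate population under a selection scheme."""

    scheme: str = "control"
    n_measured: int = 100  # flies measured per sex per generation
    n_selected: int = 25  # parents chosen per sex
    mean0: float = 515.0  # founding mean night sleep, minutes
    phenotypic_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.scheme not in ("short", "control", "long"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.n_selected > self.n_measured:
            raise ValueError("n_selected cannot exceed n_measured")


def simulate_phenotypes_with_selection(
    pop_config: PopulationConfig,
    h2_true: float,
    n_generations: int,
    seed: int,
    population_replicate: int = 1,
) -> pd.DataFrame:
    """Simulate ``n_generations`` rounds of truncation selection.

    Returns a phenotype table with one row per measured fly; the
    ``selected_parent`` flag marks the flies used to breed the next
    generation (chosen at random under the control scheme).
    """
    if not 0.0 <= h2_true <= 1.0:
        raise ValueError(f"h2_true must be in [0, 1], got {h2_true}")
    cfg = pop_config
    scheme_code = {"short": 0, "control": 1, "long": 2}[cfg.scheme]
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, scheme_code, population_replicate])
    )
    vp = cfg.phenotypic_sd ** 2
    va = h2_true * vp
    ve = vp - va

    n = cfg.n_measured
    # founding breeding values, one cohort per sex
    bv = {sex: rng.normal(0.0, np.sqrt(va), n) if va > 0 else np.zeros(n) for sex in "FM"}

    records = []
    for gen in range(n_generations + 1):
        pheno, selected = {}, {}
        for sex in "FM":
            p = np.clip(cfg.mean0 + bv[sex] + rng.normal(0.0, np.sqrt(ve), n), SLEEP_MIN, SLEEP_MAX)
            pheno[sex] = p
            if cfg.scheme == "control":
                idx = rng.choice(n, size=cfg.n_selected, replace=False)
            elif cfg.scheme == "short":
                idx = np.argsort(p)[: cfg.n_selected]
            else:  # long
                idx = np.argsort(p)[-cfg.n_selected:]
            selected[sex] = idx
            flag = np.zeros(n, dtype=bool)
            flag[idx] = True
            for i in range(n):
                records.append(
                    (
                        f"{cfg.scheme}{population_replicate}_g{gen:02d}_{sex}_{i:03d}",
                        cfg.scheme,
                        population_replicate,
                        gen,
                        sex,
                        p[i],
                        bool(flag[i]),
                    )
                )
        if gen == n_generations:
            break
        # breed next generation: each offspring from a random sire x dam pair
        dam_bv = bv["F"][selected["F"]]
        sire_bv = bv["M"][selected["M"]]
        seg_sd = np.sqrt(va / 2.0) if va > 0 else 0.0
        for sex in "FM":
            dams = rng.integers(0, len(dam_bv), n)
            sires = rng.integers(0, len(sire_bv), n)
            mid = 0.5 * (dam_bv[dams] + sire_bv[sires])
            bv[sex] = mid + rng.normal(0.0, seg_sd, n) if seg_sd > 0 else mid

    return pd.DataFrame(records, columns=PHENOTYPE_COLUMNS)
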