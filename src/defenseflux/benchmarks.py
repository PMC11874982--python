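"""Canonical study configurations and experiment runners.

These are the simulation conditions under which the package's headline
behaviours are demonstrated end to end: parameter recovery of the gain/loss
model, calibration and power of the Poisson PGLMM, recovery of the defense
effect from sister-clade flux ratios, branch-level linkage statistics, and
the depth-stratified skewness pattern.  The same conditions back both the
test suite and the reproduction script, so every reported number is
recomputed from scratch.  The rationale for each condition (and what it does
and does not emulate about real strain data) is laid out in the methods
note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cladeflux import sister_pair_table
from .gainloss import TwoStateGainLoss
from .pglmm import PoissonPGLMM, brownian_covariance
from .pipeline import family_masks
from .simulate import SimulationConfig, generate_dataset, simulate_tree

__all__ = [
    "effect_recovery_config",
    "timescale_config",
    "linkage_config",
    "run_pair_study",
    "run_pglmm_calibration",
    "run_linkage_study",
]


def effect_recovery_config(seed: int,
                           defense_effect: float = 0.5) -> SimulationConfig:
    """Sister-clade flux recovery: 200-genome trees, 1000 accessory
    families, slow defense turnover (few, deep defense gains and losses)
    so DEF+/DEF- clades are pure in residence time and the flux ratio
    isolates the defense effect phi."""
    return SimulationConfig(
        n_genomes=200,
        mge_gain_rate=15.0, mge_loss_rate=30.0, n_mge_families=30,
        defense_linkage=0.5, defense_loss_linkage=0.3,
        defense_independent_gain_rate=0.5,
        clonal_fraction=0.0,
        n_families={"prophage": 0, "plasmid": 0, "transposon": 0,
                    "neutral": 1000},
        base_gain_rate={"prophage": 30.0, "plasmid": 30.0,
                        "transposon": 30.0, "neutral": 30.0},
        base_loss_rate={"prophage": 60.0, "plasmid": 60.0,
                        "transposon": 60.0, "neutral": 60.0},
        defense_effect=defense_effect, seed=seed,
    )


def timescale_config(seed: int) -> SimulationConfig:
    """Depth-stratification study: strain trees with large near-clonal
    complexes, fast element turnover with bursty cargo co-transfer,
    heritable mobility variation across lineages, strong linkage
    (p_link = 0.9) and suppressive defense (phi = 0.5)."""
    return SimulationConfig(
        n_genomes=300,
        mge_gain_rate=300.0, mge_loss_rate=600.0, n_mge_families=40,
        defense_independent_gain_rate=10.0,
        defense_linkage=0.9, defense_loss_linkage=0.8,
        clonal_fraction=0.5, clonal_mean_size=15.0, clonal_height=8e-6,
        n_families={"prophage": 100, "plasmid": 100, "transposon": 100,
                    "neutral": 700},
        base_gain_rate={"prophage": 500.0, "plasmid": 500.0,
                        "transposon": 500.0, "neutral": 400.0},
        base_loss_rate={"prophage": 1000.0, "plasmid": 1000.0,
                        "transposon": 1000.0, "neutral": 800.0},
        defense_effect=0.5, seed=seed,
    )


def linkage_config(seed: int, p_link: float = 0.9,
                   q_link: float = 0.5) -> SimulationConfig:
    """Branch-level co-occurrence study (ground-truth events)."""
    return SimulationConfig(
        n_genomes=200,
        mge_gain_rate=30.0, mge_loss_rate=60.0, n_mge_families=20,
        defense_independent_gain_rate=5.0,
        defense_linkage=p_link, defense_loss_linkage=q_link,
        n_families={"prophage": 10, "plasmid": 10, "transposon": 10,
                    "neutral": 30},
        seed=seed,
    )


def run_pair_study(config_fn, seeds, include_stem: bool = True,
                   fit_subsample: int | None = 300) -> pd.DataFrame:
    """Simulate per-seed species, fit the gain/loss model, compute
    sister-pair flux rates over all non-singleton non-defense families and
    pool the pair tables."""
    parts = []
    for seed in seeds:
        ds = generate_dataset(config_fn(seed))
        est = TwoStateGainLoss(n_categories=4, n_starts=1,
                               fit_subsample=fit_subsample).fit(
            ds.matrix, tree=ds.tree)
        events = est.expected_events(ds.matrix, tree=ds.tree)
        masks = family_masks(ds.annotation, events.family_ids)
        table = sister_pair_table(
            ds.tree, ds.traits.df.iloc[:, 0],
            {"total": events.aggregate(masks["total"])},
            include_stem=include_stem)
        if len(table):
            table.insert(0, "seed", seed)
            parts.append(table)
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


def run_pglmm_calibration(n_reps: int = 400, n: int = 100,
                          sigma2: float = 0.3, beta1: float = 0.0,
                          beta0: float = np.log(50), seed: int = 0):
    """Wald rejection rate and coefficient estimates for the Poisson PGLMM
    under a phylogenetic null or alternative; one shared tree per study."""
    cfg = SimulationConfig(n_genomes=n, clonal_fraction=0.0, seed=seed)
    tree = simulate_tree(cfg, seed=seed)
    cov = brownian_covariance(tree, rescale=True)
    L = np.linalg.cholesky(cov.matrix + 1e-10 * np.eye(n))
    rejections = 0
    estimates = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        x = rng.integers(0, 2, n).astype(float)
        eps = L @ rng.normal(0, np.sqrt(sigma2), n)
        y = rng.poisson(np.exp(beta0 + beta1 * x + eps))
        fit = PoissonPGLMM().fit(x[:, None], y, cov=cov)
        rejections += fit.beta_pvalues_[0] < 0.05
        estimates.append(fit.coef_[0])
    return rejections / n_reps, np.asarray(estimates)


def run_linkage_study(seeds, p_link: float = 0.9, q_link: float = 0.5):
    """Pooled ground-truth branch event table over seeds."""
    from .linkage import branch_table_from_history
    from .simulate import simulate_defense_history, simulate_mge_history

    tables = []
    for seed in seeds:
        cfg = linkage_config(seed, p_link=p_link, q_link=q_link)
        tree = simulate_tree(cfg, seed=seed)
        mge, _ = simulate_mge_history(tree, cfg, seed=seed + 10_000)
        dh, _ = simulate_defense_history(tree, mge, cfg, seed=seed + 20_000)
        tables.append(branch_table_from_history(tree, dh, mge))
    return pd.concat(tables, ignore_index=True)
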