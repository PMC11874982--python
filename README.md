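# defenseflux

Phylogeny-aware analysis of how prokaryotic defense systems (restriction–
modification, DNA-modification systems, abortive infection, CRISPR-Cas,
Gabija, DRT, CBASS) relate to mobile-genetic-element (MGE) abundance and to
rates of horizontal gene transfer (HGT) within bacterial and archaeal
species.

Defense systems are expected to block invading MGEs and so reduce gene
exchange — but defense systems themselves travel on MGEs, so over short
evolutionary timescales their presence can be *positively* associated with
gene flux. `defenseflux` implements the statistical machinery needed to
dissect this tension on strain-level data:

- **Poisson phylogenetic GLMM** per species:
  `Y_i ~ Poisson(mu_i)`, `log mu_i = beta0 + sum_j beta_j X_ij + eps_i`,
  `eps ~ N(0, sigma2_phy C)` with `C` the Brownian-motion covariance from
  the strain tree; Laplace estimation, Wald tests, identity-covariance
  counterpart and conditional-AIC comparison. Effect sizes
  `ES = exp(beta) − 1` are classified both by `P < 0.05` and by the
  smallest-significant-effect-size (SSES) threshold.
- **Two-state gene gain/loss model** over Roary-style presence/absence
  matrices: gamma rate mixture (K = 4, shared shape), stationary root,
  pruning likelihood, and exact per-branch posterior expected numbers of
  gains and losses via uniformization.
- **Sister-clade flux comparison**: DEF+ clades (≥ 80% of leaves carry the
  system) vs their DEF− sisters, per-clade gain/loss rates (expected events
  per unit branch length, singletons excluded), log-ratio Wilcoxon tests,
  and depth stratification (recent < 1e-5, old > 1e-3 substitutions/site)
  with d'Agostino skewness tests.
- **Branch-level linkage statistics**: co-gain/co-loss percentages with
  exact binomial CIs, length-proportional random expectations, conditional
  probabilities, risk ratios, Fisher exact tests, terminal/internal splits.
- **Synthetic data generator** with event-level ground truth: birth–death
  strain trees with clonal complexes, MGE driver families with heritable
  mobility, branch-linked defense gains/losses, burst cargo co-transfer and
  a tunable defense effect `phi` on gene-gain rates.

The two core estimators follow scikit-learn conventions
(`TwoStateGainLoss`, `PoissonPGLMM`: constructor hyper-parameters,
`fit`, trailing-underscore attributes, `get_params`/`set_params`).

## Worked example

Simulate a 200-genome species in which CRISPR presence halves the gene-gain
rate (`defense_effect = 0.5`) while defense gains ride MGE gains with
probability 0.9, then run the full pipeline:

```python
from defenseflux import (SimulationConfig, generate_dataset,
                         TwoStateGainLoss, branch_table_from_history,
                         linkage_report)
from defenseflux.pipeline import family_masks
from defenseflux.cladeflux import sister_pair_table, test_logratios

cfg = SimulationConfig(n_genomes=200, defense_effect=0.5, seed=1)
ds = generate_dataset(cfg)

# gain/loss inference and per-branch expected events
est = TwoStateGainLoss(n_categories=4).fit(ds.matrix, tree=ds.tree)
events = est.expected_events(ds.matrix, tree=ds.tree)
print(f"g={est.gain_rate_:.1f} l={est.loss_rate_:.1f} "
      f"alpha={est.gamma_shape_:.2f}")

# DEF+/DEF- sister-clade gain-rate ratio
masks = family_masks(ds.annotation, events.family_ids)
pairs = sister_pair_table(ds.tree, ds.traits.df["CRISPR"],
                          {"total": events.aggregate(masks["total"])})
median_ratio, p = test_logratios(pairs["log_gain_ratio"])
print(f"pairs={len(pairs)} median DEF+/DEF- gain ratio={median_ratio:.2f} "
      f"(Wilcoxon p={p:.3g})")

# branch-level defense/MGE co-occurrence (ground-truth events)
table = branch_table_from_history(ds.tree, ds.defense_history,
                                  ds.mge_history)
print(linkage_report(table)[["event", "co_percent", "expected_percent",
                             "rr"]].round(2))
```

Output:

```
g=33.8 l=84.9 alpha=0.80
pairs=6 median DEF+/DEF- gain ratio=6.32 (Wilcoxon p=0.156)
  event  co_percent  expected_percent   rr
0  gain       100.0             71.69  inf
1  loss       100.0             85.99  inf
```

The fitted rates are per substitution/site of core divergence; the gamma
shape < 1 reflects the across-family rate heterogeneity in the generator.
Every defense gain in this species sits on a branch that also gained an
MGE, against a random expectation of 71.7% under length-proportional
placement (the risk ratio is infinite because no defense gain occurred off
an MGE-gain branch). Note the median sister-clade gain ratio is far *above*
one even though the simulated defense effect halves the gain rate: the
handful of DEF+/DEF− pairs in a single species is dominated by recent
co-acquisitions, which is precisely the masking effect the timescale
analysis untangles. The pooled studies in `docs/methods.md` (slow-turnover
conditions, ten species) recover the simulated `phi = 0.5` as a median
ratio of ~0.6, and the depth-stratified analysis separates the positive
recent signal from the negative long-term one.

The same pipeline is available from the shell:

```sh
defenseflux run-all --seed 1 --out-dir out/
```

writes `presence.Rtab`, `branch_events.tsv`, `pglmm.tsv`,
`associations.tsv`, `clade_pairs.tsv`, `timescale.tsv` and `linkage.tsv`.

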