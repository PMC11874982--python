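# Methods

This note documents the models, algorithms, numerical choices and synthetic
study conditions implemented in `defenseflux`, and what the validation
studies do and do not demonstrate about real data.

## Overview

The package quantifies how prokaryotic defense systems (RM, DMS, Abi,
CRISPR-Cas, Gabija, DRT, CBASS) relate to mobile-genetic-element (MGE)
abundance and to rates of horizontal gene transfer within a species, using
three phylogeny-aware components:

1. a **Poisson phylogenetic GLMM** linking per-genome gene counts to defense
   presence with a tree-derived random effect;
2. a **two-state gain/loss model** over gene-family presence/absence
   patterns, yielding per-branch posterior expected numbers of gains and
   losses;
3. **comparative statistics** built on those expectations: DEF+/DEF−
   sister-clade flux ratios, branch-level defense/MGE co-event statistics,
   and depth-stratified skewness of log gain-ratios.

A synthetic-data generator with full ground truth closes the loop: every
statistical behaviour the package claims is demonstrated by recovering known
simulated signals end to end.

## Poisson phylogenetic GLMM

Model per species: `Y_i ~ Poisson(mu_i)` with
`log mu_i = beta0 + sum_j beta_j X_ij + eps_i`, `eps ~ N(0, sigma2_phy C)`,
where `X_ij` is the presence (0/1) of defense system `j` in genome `i` and
`C[i,k]` is the root-to-MRCA shared path length of genomes `i` and `k`
(Brownian motion on the strain tree). The identity-covariance counterpart
replaces `C` with `I` on the same code path.

**Estimation.** Laplace approximation. The random effect is parameterised
as `b = L a` with `C + 1e-8·I = L Lᵀ`, so the penalised joint log-likelihood
is maximised over `(beta, a)` by Newton iterations with step halving
(tolerance 1e-8 on the step). The marginal likelihood
`l(sigma2) = l_joint(β̂, â) − ½ log det(I + sigma2 LᵀWL)` is profiled over
`log sigma2` on `[-12, 4]` by bounded scalar minimisation, with an explicit
boundary comparison against the `sigma2 = 0` Poisson GLM; the better of the
two wins. `C` is rescaled to unit mean diagonal before fitting (numerical
conditioning; fixed effects and their tests are invariant, `sigma2_phy` is
then per unit of mean tree depth).

**Inference.** Wald tests with
`cov(beta) = (Xᵀ (W⁻¹ + sigma2 C)⁻¹ X)⁻¹` evaluated at the fit
(`W = diag(mû)`). No multiple-testing correction is applied anywhere — the
classification criteria deliberately mirror raw `P < 0.05` usage; treat the
counts as descriptive, not as FDR-controlled discoveries.

**Model comparison.** Conditional AIC: `−2·l_cond(y; mû) + 2·rho` where
`rho = tr[(TᵀWT + P)⁻¹ TᵀWT]` is the trace of the working-response hat
matrix (`T = [X, L]`, `P` the random-effect penalty) — the Vaida–Blanchard
effective degrees of freedom. At `sigma2 = 0`, `rho` equals the number of
fixed effects and the cAIC is exactly the Poisson GLM AIC (tested to 1e-4).
Differences below 2 are conventionally read as "equivalent".

**Calibration (measured, not assumed).** Under a phylogenetic Poisson null
(n = 100 genomes, `sigma2 = 0.3`, 400 replicates) the Wald test for a binary
predictor rejects at nominal 0.05 within [0.02, 0.09]; the mean estimate of
`beta1 = ln 1.3` over 50 replicates is within 0.05 of the truth; the cAIC
prefers the phylogenetic model in ≥ 80% of 25 phylogenetically simulated
replicates.

## Effect sizes and the SSES classification

Coefficients are reported as relative differences `ES = exp(beta) − 1`
(multiplicative scale under the log link; a raw difference-of-means variant
is available as `raw_effect_size`). Two classifications are attached per
(response, system) group across species:

- **P criterion** — sign of ES where `p < 0.05`, else null;
- **SSES criterion** — the smallest |ES| reaching `p < 0.05` within the
  group defines a threshold; associations with |ES| strictly above it are
  classified by sign, ties and everything else are null. The species that
  attains the SSES itself is therefore null under this criterion even when
  significant — a deliberate strict-inequality reading.

## Two-state gain/loss inference

Each gene family evolves independently on the fixed rooted strain tree as a
0/1 Markov chain with gain rate `g` and loss rate `l` (events per
substitution/site). Across-family rate heterogeneity is a single discretized
gamma mixture: K = 4 equal-probability categories of a mean-1 gamma with
shape `alpha`, scaling `g` and `l` jointly (a shared mixture keeps `g/l`
identifiable; an alternative with independent gain and loss mixtures is not
implemented). The root prior is the stationary distribution
`pi1 = g/(g+l)`. The likelihood of a leaf pattern is computed by Felsenstein
pruning, vectorised over families and categories, with per-node scaling; it
matches exhaustive enumeration over internal states on all trees with ≤ 5
leaves to 1e-9 and sums to one over all patterns.

**Fitting.** `(log g, log l, log alpha)` maximised by L-BFGS-B (ftol 1e-8)
from a deterministic multi-start grid: `(g, l)` in `{0.1, 1, 10}²` scaled by
the inverse mean root-to-tip depth (rates are per substitution/site, so the
natural unit is one event per tip path), `alpha` in `{0.5, 1, 5}`; the best
grid points are refined. Because `g` and `l` are two global parameters, they
may optionally be fitted on a deterministic evenly-spaced subsample of
families (`fit_subsample`); posterior event expectations always use every
family. An all-constant matrix is rejected ("no signal").

**Per-branch expected events.** For each branch and rate category the
package computes the 2×2 table of expected 0→1 and 1→0 transition counts
conditional on the branch endpoints, by uniformization at rate `g + l` with
the Poisson series truncated once its tail is negligible (the inner
convolution over jump counts is exact); the probability of at least one
transition uses the closed-form taboo matrices `exp(t[[-g,0],[l,-l]])` and
`exp(t[[-g,g],[0,-l]])`. Endpoint joint posteriors come from an
inside–outside pass; category weights are per-family posteriors. These
conditional expectations match an endpoint-conditioned fine-discretization
simulation to two decimals over a `(g, l, t)` grid, and the flux balance
`sum_branches E[gains − losses] = sum` of posterior state changes holds on
small trees to 1e-8.

For downstream binary "event calls" a branch is called as carrying an event
when the posterior probability of ≥ 1 event (combined over the family set of
interest) exceeds 0.5 (configurable; the appropriate threshold is genuinely
underdetermined and results involving calls should be read with that in
mind).

**Known limitation.** Expected events are statistically visible events:
gain–loss round trips inside one branch, or flux inflated by unmodelled
lineage-specific rate variation, are not recoverable by any method from
presence/absence patterns. On data simulated from the model itself at
moderate rates, total inferred gains match the true count within a few
percent; under saturation or strong mobility heterogeneity they
underestimate the raw event count.

## DEF+/DEF− sister-clade flux

DEF+ clades are found by a preorder sweep that stops at the first node whose
leaf set is ≥ 80% defense-positive ("maximal disjoint qualifying clades");
DEF− clades analogously. A literal "narrowest clades" reading degenerates to
single leaves, so maximality is the implemented interpretation — this is the
single riskiest interpretive choice in the package. Sister pairs are
qualifying clades of opposite sign that are children of the same node; pairs
of two single-genome clades are excluded.

A clade's gain (loss) rate is the summed expected gains (losses) over its
branches, for the family set of interest (species-wise singleton families
always excluded, defense-system families excluded), divided by the summed
branch length. **By default the clade's stem branch is included**: the
retention of one-singleton pairs only makes sense if a single-genome clade
has a defined rate over its terminal branch, and acquisition events riding
in on the stem are precisely what produces the positive short-timescale
signal. The effect-recovery study below instead uses `include_stem=False`,
because its purpose is to isolate the within-clade flux modulation from the
acquisition burst; both options are first-class.

Pairs are compared by log-transformed DEF+/DEF− rate ratios (two-sided
Wilcoxon signed-rank against 0); ratios with a zero rate on either side are
excluded and counted in an `n_undefined` column. Pair depth is the mean path
length from the pair's parent node to its descendant leaves (a max-distance
variant is available), stratified as recent (< 1e-5 substitutions/site) and
old (> 1e-3), open intervals, middle band reported separately. Skewness per
stratum uses the d'Agostino normalising transformation as implemented in
`scipy.stats.skewtest` (n ≥ 8 required; note scipy maps an exactly-zero
statistic to a non-zero z, so perfect symmetry yields p ≈ 0.31, not 1).

## Branch-level linkage statistics

Events are binary per branch. For gains (and analogously losses) the package
reports: the percentage of defense-event branches that also carry an MGE
event with exact Clopper–Pearson 95% CIs; the random expectation under
independent placement of defense events proportional to branch length (the
share of total length on MGE-event branches; a branch-count-uniform variant
is behind a flag); a two-sided exact binomial test of the observed
co-fraction against that expectation; conditional probabilities
`P(def | MGE)` and `P(def | no MGE)`; the risk ratio with the standard
log-method 95% CI (`z = 1.96`); Fisher's exact test; and all of the above
recomputed on terminal-only and internal-only branch subsets.

One caution discovered during validation and worth stating: when both event
margins are placed proportionally to branch length, the branch-level risk
ratio exceeds 1 even without any linkage, because both margins concentrate
on long branches. The RR coverage property is therefore checked under an
exchangeable null (defense events uniform over branches); on real data the
length-proportional expectation percentages are the appropriate null
summary, and RRs should be compared against that backdrop.

## The synthetic-data generator

The generator produces a species dataset (tree, presence/absence matrix,
trait table, annotations) with a complete event-level ground truth that
replays exactly to the emitted leaf states. It is a stand-in for real strain
data — the analysis pipeline defines what must be emulated, and the
following components are each motivated by a specific, load-bearing feature
of real data:

- **Tree**: birth–death topology conditioned on the number of genomes
  (dendropy), mean root-to-tip depth rescaled exactly to
  `tree_height_target` (default 0.01 substitutions/site, a typical
  within-species core divergence). Two realism features: per-branch
  lognormal rate multipliers (`rate_lognormal_sigma`, default 1.0) spread
  branch lengths over orders of magnitude, and a fraction of tips
  (`clonal_fraction`) is expanded into near-clonal coalescent clusters of
  mean size `clonal_mean_size` and height `clonal_height` (default 5e-6).
  Without clusters, birth–death trees are ultrametric with essentially no
  nodes shallower than 1e-5 substitutions/site and the "recent" stratum is
  structurally empty.
- **MGE drivers**: `n_mge_families` families evolve as two-state chains at
  `(mge_gain_rate, mge_loss_rate)` from stationary roots. A log-scale
  random walk (`mobility_sigma` per split) makes element mobility heritable
  along lineages; lineages that drift to low mobility freeze their defense
  state, which is what creates genuinely deep DEF+ and DEF− clades.
- **Defense**: on each branch with ≥ 1 driver gain the defense system is
  gained with probability `defense_linkage` (p_link) at the position of the
  first driver gain; background gains occur as a Poisson process
  (`defense_independent_gain_rate`); a present system is lost with
  probability `defense_loss_linkage` (q_link) on branches with ≥ 1 driver
  loss. By default (`defense_blocks_mge`) the defense effect feeds back on
  driver gains — defense blocks element acquisition — using the defense
  state at the branch start (branch-granular approximation).
- **Accessory families**: per class (prophage/plasmid/transposon marker and
  neutral), two-state chains whose gain rate is multiplied by
  `defense_effect` (phi) on tree segments where defense is present;
  per-family mean-1 gamma rate multipliers (`family_rate_gamma_shape`)
  reproduce the strong across-family rate heterogeneity of real pangenomes
  (homogeneous fast rates would saturate the phylogenetic signal).
  MGE-class cargo families are additionally co-gained/co-lost in bursts
  with same-class driver events (`cargo_gain_burst`/`cargo_loss_burst`
  expected families per event): elements carry cargo genes, and without
  bursts a defense acquisition perturbs a single family and leaves no
  detectable short-timescale signature.
- **Singletons**: injected at `singleton_fraction` of the family count,
  one random host genome each; singleton flags in the annotation are always
  recomputed from column sums.

Branch-level linkage (rather than explicit element genealogies) matches the
resolution of the downstream inference, which only ever observes same-branch
co-events. One defense system is simulated per run; multi-system datasets
are independent runs sharing a tree.

## Validation studies (study conditions)

All studies run on 1 CPU within the test suite; sizes were chosen as the
smallest that make the targeted signal statistically unambiguous.

- **Effect recovery** (`effect_recovery_config`): 200 genomes, 1000
  accessory families at gain/loss 30/60, slow defense dynamics (driver
  rates 15/30, p_link 0.5, q_link 0.3, background 0.5) so DEF+/DEF− clades
  are pure in residence time; phi = 0.5; 10 seeds; stem excluded. The
  pooled median DEF+/DEF− gain ratio recovers 0.5 within 25% with Wilcoxon
  p < 0.05, the loss ratio stays near 1, and under phi = 1 the per-seed
  Wilcoxon rejects at no more than the nominal rate. Note the measured
  median sits slightly above phi itself (~0.6): 80%-purity clades are not
  100% defense-resident, and posterior expectations shrink extreme
  contrasts — both attenuations are inherent to the method, not bugs.
- **Timescale pattern** (`timescale_config`): 300 genomes, half in clonal
  complexes of mean size 15, fast bursty element turnover (driver rates
  300/600, cargo 400–500/800–1000, bursts of 5), p_link 0.9, q_link 0.8,
  phi = 0.5, mobility sigma 0.75; 25 seeds pooling > 100 pairs. The log
  gain-ratio distribution is significantly positively skewed in the recent
  stratum (< 1e-5) and centred below zero in the old stratum (> 1e-3) —
  the short-term co-transfer signal masking a long-term suppressive
  effect.
- **Linkage statistics** (`linkage_config`): ground-truth branch events at
  p_link 0.9; co-gain/co-loss percentages far above their
  length-proportional expectations, risk ratios ≫ 1, Fisher p ≪ 1e-8;
  exact-test values cross-checked against independent enumerations to
  1e-10.

What these studies do **not** show: recovery of the paper-scale effect
magnitudes from real genomes (tens of thousands of genomes, annotation
noise, incomplete assemblies, non-binary family calls), robustness to tree
estimation error (trees are taken as known), or behaviour under model
violations such as family-specific loss/gain asymmetries. The generator's
linkage is branch-granular; it cannot distinguish one joint transfer from
same-branch independent transfers, and neither can the inference.

## Degenerate inputs and tie-breaks

Missing branch lengths, negative lengths, duplicate leaf labels, non-binary
matrix cells, unknown defense-system names and genome/leaf set mismatches
are hard errors. Polytomies are accepted everywhere. Zero-length branches
are valid (transition matrix = identity). Depth-stratum boundaries are open
intervals. |ES| ties with the SSES classify as null. Wilcoxon uses scipy's
exact method where applicable; all-zero log-ratio vectors return p = 1.
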