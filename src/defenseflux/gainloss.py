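"""Maximum-likelihood two-state gain/loss model over gene families.

A gene family evolves on the fixed strain tree as a two-state (absent/present)
continuous-time Markov chain with gain rate ``g`` and loss rate ``l`` (events
per substitution/site).  Rate heterogeneity across families is modelled by a
single discretized gamma mixture (K categories, mean 1, shape ``alpha``) that
scales ``g`` and ``l`` jointly; the root state prior is the stationary
distribution (pi1 = g/(g+l)).

Per-branch posterior expected numbers of 0->1 and 1->0 transitions are
computed exactly by inside--outside pruning combined with uniformization of
the conditional chain, together with the posterior probability of at least
one event per branch (used for binary event calling downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammainc, gammaln, logsumexp
from sklearn.base import BaseEstimator

from .io import PresenceMatrix
from .tree import StrainTree

__all__ = [
    "GainLossModel",
    "BranchEvents",
    "TwoStateGainLoss",
    "transition_probability",
    "family_loglik",
    "fit_gainloss",
    "branch_expected_events",
    "discrete_gamma_rates",
]


# ------------------------------------------------------------- primitives

def transition_probability(g: float, l: float, t: float) -> np.ndarray:
    """2x2 transition matrix of the gain/loss chain over time ``t``.

    ``P[0, 1] = (g/(g+l)) * (1 - exp(-(g+l) t))``; rows sum to 1.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if g < 0 or l < 0 or g + l == 0:
        raise ValueError("need g, l >= 0 and g + l > 0")
    lam = g + l
    decay = np.exp(-lam * t)
    pi1 = g / lam
    pi0 = l / lam
    return np.array([
        [pi0 + pi1 * decay, pi1 * (1 - decay)],
        [pi0 * (1 - decay), pi1 + pi0 * decay],
    ])


def discrete_gamma_rates(alpha: float, K: int) -> np.ndarray:
    """Mean-1 discretized gamma rate multipliers (mean of each of K
    equal-probability sections of Gamma(alpha, 1/alpha))."""
    if K == 1:
        return np.ones(1)
    from scipy.stats import gamma as _gamma

    edges = _gamma.ppf(np.linspace(0, 1, K + 1), a=alpha, scale=1.0 / alpha)
    # partial expectations via the regularized incomplete gamma with shape a+1
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    rates = K * (upper - lower)
    return rates / rates.mean()


def _no_transition_probability(g, l, t):
    """Joint probabilities P(no 0->1 transition, X_t=y | X_0=x) and the
    1->0 analogue, each as a 2x2 array (closed forms)."""
    eg, el = np.exp(-g * t), np.exp(-l * t)
    if abs(g - l) < 1e-12 * max(g, l, 1.0):
        cross = l * t * np.exp(-l * t)
        cross_g = g * t * np.exp(-g * t)
    else:
        cross = l * (el - eg) / (g - l)
        cross_g = g * (eg - el) / (l - g)
    no01 = np.array([[eg, 0.0], [cross, el]])
    no10 = np.array([[eg, cross_g], [0.0, el]])
    return no01, no10


def _uniformization_tables(g, l, t, tail=1e-12):
    """Per-branch endpoint-conditioned event moments for one rate category.

    Returns ``(E01, E10, Pge1_01, Pge1_10)`` where ``E01[x, y]`` is the
    expected number of 0->1 transitions given endpoints (x, y) and
    ``Pge1_01[x, y]`` the probability of at least one such transition.
    Computed by uniformization at rate g+l, Poisson tail truncated below
    ``tail`` mass.
    """
    P = transition_probability(g, l, t)
    if t == 0:
        z = np.zeros((2, 2))
        return z, z.copy(), z.copy(), z.copy()
    lam = g + l
    lt = lam * t
    N = int(max(10, np.ceil(lt + 10 * np.sqrt(lt) + 10)))
    n = np.arange(N + 1)
    pois = np.exp(-lt + n * np.log(lt) - gammaln(n + 1))
    R = np.array([[1 - g / lam, g / lam], [l / lam, 1 - l / lam]])
    Rp = np.empty((N + 1, 2, 2))
    Rp[0] = np.eye(2)
    for m in range(1, N + 1):
        Rp[m] = Rp[m - 1] @ R
    Psafe = np.maximum(P, 1e-300)
    out = []
    for i, j in ((0, 1), (1, 0)):
        M = np.zeros((2, 2))
        for x in range(2):
            for y in range(2):
                conv = np.convolve(Rp[:, x, i], Rp[:, j, y])
                M[x, y] = R[i, j] * float(np.sum(pois[1:] * conv[:N]))
        out.append(M / Psafe)
    no01, no10 = _no_transition_probability(g, l, t)
    pge1_01 = np.clip(1.0 - no01 / Psafe, 0.0, 1.0)
    pge1_10 = np.clip(1.0 - no10 / Psafe, 0.0, 1.0)
    return out[0], out[1], pge1_01, pge1_10


# ----------------------------------------------------------------- model

@dataclass
class GainLossModel:
    """Fitted two-state model: rates, gamma shape and category count."""

    gain_rate: float
    loss_rate: float
    gamma_shape: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        if not (self.gain_rate > 0 and self.loss_rate > 0):
            raise ValueError("gain and loss rates must be > 0")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    @property
    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    @property
    def root_prior(self) -> np.ndarray:
        lam = self.gain_rate + self.loss_rate
        return np.array([self.loss_rate / lam, self.gain_rate / lam])


@dataclass
class BranchEvents:
    """Per-branch x per-family posterior event expectations."""

    branch_labels: list          # child-node labels, root excluded
    branch_lengths: np.ndarray
    is_terminal: np.ndarray      # bool per branch
    family_ids: list
    expected_gains: np.ndarray   # (n_branches, n_families)
    expected_losses: np.ndarray
    p_ge1_gain: np.ndarray
    p_ge1_loss: np.ndarray

    def aggregate(self, family_mask=None) -> pd.DataFrame:
        """Sum expectations over (a subset of) families per branch;
        probabilities are combined as P(>=1 event over the set)."""
        if family_mask is None:
            family_mask = np.ones(len(self.family_ids), dtype=bool)
        m = np.asarray(family_mask, dtype=bool)
        with np.errstate(divide="ignore"):
            p_gain = 1.0 - np.exp(
                np.log1p(-np.clip(self.p_ge1_gain[:, m], 0, 1 - 1e-15)).sum(axis=1))
            p_loss = 1.0 - np.exp(
                np.log1p(-np.clip(self.p_ge1_loss[:, m], 0, 1 - 1e-15)).sum(axis=1))
        return pd.DataFrame({
            "branch": self.branch_labels,
            "branch_length": self.branch_lengths,
            "is_terminal": self.is_terminal,
            "expected_gains": self.expected_gains[:, m].sum(axis=1),
            "expected_losses": self.expected_losses[:, m].sum(axis=1),
            "p_ge1_gain": p_gain,
            "p_ge1_loss": p_loss,
        })


# -------------------------------------------------------------- pruning

def _tree_arrays(tree: StrainTree):
    post = tree.postorder()
    leaf_idx = tree.leaf_indices
    return post, leaf_idx


def _branch_P(tree, g, l, cat_rates):
    """(n_nodes, K, 2, 2) transition matrices; entry for the root is I."""
    K = len(cat_rates)
    t = tree.lengths[:, None] * cat_rates[None, :]
    lam = g + l
    decay = np.exp(-lam * t)
    pi1, pi0 = g / lam, l / lam
    P = np.empty((tree.n_nodes, K, 2, 2))
    P[..., 0, 1] = pi1 * (1 - decay)
    P[..., 0, 0] = 1 - P[..., 0, 1]
    P[..., 1, 0] = pi0 * (1 - decay)
    P[..., 1, 1] = 1 - P[..., 1, 0]
    return P


def _up_pass(tree, leaf_states, g, l, cat_rates):
    """Inside (pruning) pass, vectorised over families and categories.

    Returns (up, logscale, P, loglik_k) where ``up`` is (n_nodes, K, nf, 2),
    logscale (K, nf), and loglik_k (K, nf) the per-category log-likelihoods.
    """
    K = len(cat_rates)
    nf = leaf_states.shape[1]
    nn = tree.n_nodes
    P = _branch_P(tree, g, l, cat_rates)
    up = np.zeros((nn, K, nf, 2))
    logscale = np.zeros((K, nf))
    leaf_rows = {int(v): r for r, v in enumerate(tree.leaf_indices)}
    for v in tree.postorder():
        v = int(v)
        if not tree.children[v]:
            s = leaf_states[leaf_rows[v]]
            up[v, :, :, 0] = (s == 0)
            up[v, :, :, 1] = (s == 1)
            continue
        prod = np.ones((K, nf, 2))
        for c in tree.children[v]:
            prod *= np.einsum("kxy,kfy->kfx", P[c], up[c])
        m = np.maximum(prod.max(axis=2), 1e-300)
        up[v] = prod / m[..., None]
        logscale += np.log(m)
    lam = g + l
    pi = np.array([l / lam, g / lam])
    root = np.maximum(up[0] @ pi, 1e-300)
    loglik_k = np.log(root) + logscale
    return up, logscale, P, loglik_k


def pattern_logliks(tree, leaf_states, model: GainLossModel) -> np.ndarray:
    """Category-averaged log-likelihood per family pattern.

    ``leaf_states``: (n_leaves, n_families) 0/1 array in the order of
    ``tree.leaf_indices``.
    """
    if leaf_states.shape[0] != tree.n_leaves:
        raise ValueError("pattern must cover all leaves")
    rates = model.category_rates
    _, _, _, loglik_k = _up_pass(
        tree, leaf_states, model.gain_rate, model.loss_rate, rates)
    return logsumexp(loglik_k, axis=0) - np.log(len(rates))


def family_loglik(tree: StrainTree, pattern: dict, model: GainLossModel) -> float:
    """Log-likelihood of a single family's 0/1 leaf pattern."""
    order = tree.leaf_labels
    missing = [lab for lab in order if lab not in pattern]
    if missing:
        raise ValueError(f"missing leaf state(s): {missing[:5]}")
    states = np.array([[pattern[lab]] for lab in order], dtype=np.int8)
    return float(pattern_logliks(tree, states, model)[0])


# -------------------------------------------------------------- estimator

class TwoStateGainLoss(BaseEstimator):
    """Sklearn-style estimator for the gamma-mixture gain/loss model.

    Parameters
    ----------
    n_categories : number of discretized-gamma rate categories (GLOOME-style
        default of 4).
    call_threshold : posterior probability above which a branch is called as
        carrying >= 1 event (used by :meth:`expected_events` consumers).
    tol : convergence tolerance on the mean per-family log-likelihood.

    Attributes (after fit)
    ----------------------
    gain_rate_, loss_rate_, gamma_shape_ : ML parameter estimates.
    loglik_ : total log-likelihood at the optimum.
    model_ : the fitted :class:`GainLossModel`.
    """

    def __init__(self, n_categories: int = 4, call_threshold: float = 0.5,
                 tol: float = 1e-8, max_iter: int = 200, n_starts: int = 2,
                 fit_subsample: int | None = None):
        self.n_categories = n_categories
        self.call_threshold = call_threshold
        self.tol = tol
        self.max_iter = max_iter
        self.n_starts = n_starts
        #: fit the (global) rate parameters on a deterministic evenly-spaced
        #: subset of at most this many families; posterior event
        #: expectations always use every family
        self.fit_subsample = fit_subsample

    # ---- data plumbing
    @staticmethod
    def _coerce(X, tree):
        if isinstance(X, PresenceMatrix):
            X = X.aligned_to(tree).df
        if isinstance(X, pd.DataFrame):
            fam_ids = list(X.columns)
            if list(X.index) != tree.leaf_labels:
                X = X.loc[tree.leaf_labels]
            states = X.to_numpy(dtype=np.int8)
        else:
            states = np.asarray(X, dtype=np.int8)
            fam_ids = [f"F{j}" for j in range(states.shape[1])]
        if states.shape[0] != tree.n_leaves:
            raise ValueError("X rows must match tree leaves")
        if not np.isin(states, (0, 1)).all():
            raise ValueError("X must be binary")
        return states, fam_ids

    def fit(self, X, y=None, *, tree: StrainTree):
        """Maximise the summed family log-likelihood over (g, l, alpha).

        Deterministic multi-start: a fixed grid of (g, l) multiples of the
        inverse mean root-to-tip depth crossed with alpha in {0.5, 1, 5},
        refined from the best grid point by L-BFGS-B on log parameters.
        """
        states, fam_ids = self._coerce(X, tree)
        nf = states.shape[1]
        if nf == 0:
            raise ValueError("empty matrix")
        variable = (states.min(axis=0) != states.max(axis=0))
        if not variable.any():
            raise ValueError("no signal: all family patterns are constant")
        K = int(self.n_categories)
        full_states = states
        if self.fit_subsample is not None and nf > self.fit_subsample:
            step = int(np.ceil(nf / self.fit_subsample))
            states = states[:, ::step]
            nf = states.shape[1]

        depths = tree.node_depths()
        height = float(np.mean(depths[tree.leaf_indices]))
        scale = 1.0 / max(height, 1e-12)

        def nll(theta):
            g, l = np.exp(theta[0]), np.exp(theta[1])
            alpha = np.exp(theta[2]) if K > 1 else 1.0
            rates = discrete_gamma_rates(alpha, K)
            _, _, _, llk = _up_pass(tree, states, g, l, rates)
            return -float(np.sum(logsumexp(llk, axis=0) - np.log(K))) / nf

        grid = []
        for g0 in (0.1, 1.0, 10.0):
            for l0 in (0.1, 1.0, 10.0):
                for a0 in ((0.5, 1.0, 5.0) if K > 1 else (1.0,)):
                    grid.append(np.log([g0 * scale, l0 * scale, a0]))
        grid_vals = [nll(th) for th in grid]
        order = np.argsort(grid_vals)
        best = None
        bounds = [(np.log(scale) - 9, np.log(scale) + 9)] * 2 + [
            (np.log(0.02), np.log(50.0))]
        for idx in order[:self.n_starts]:
            res = optimize.minimize(
                nll, grid[idx], method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": self.tol})
            if best is None or res.fun < best.fun:
                best = res
        g, l = np.exp(best.x[0]), np.exp(best.x[1])
        alpha = np.exp(best.x[2]) if K > 1 else 1.0
        self.gain_rate_ = float(g)
        self.loss_rate_ = float(l)
        self.gamma_shape_ = float(alpha)
        self.converged_ = bool(best.success)
        self.model_ = GainLossModel(self.gain_rate_, self.loss_rate_,
                                    self.gamma_shape_, K)
        if states.shape[1] != full_states.shape[1]:
            self.loglik_ = float(
                pattern_logliks(tree, full_states, self.model_).sum())
        else:
            self.loglik_ = -float(best.fun) * nf
        self.tree_ = tree
        self.family_ids_ = fam_ids
        self.n_features_in_ = nf
        return self

    def score(self, X, y=None, *, tree: StrainTree = None) -> float:
        tree = tree or self.tree_
        states, _ = self._coerce(X, tree)
        return float(pattern_logliks(tree, states, self.model_).sum())

    def expected_events(self, X=None, *, tree: StrainTree = None) -> BranchEvents:
        """Posterior expected gains/losses per branch x family."""
        tree = tree or self.tree_
        if X is None:
            raise ValueError("X (leaf patterns) required")
        states, fam_ids = self._coerce(X, tree)
        return branch_expected_events(tree, states, self.model_,
                                      family_ids=fam_ids)


def fit_gainloss(tree: StrainTree, matrix, K: int = 4) -> GainLossModel:
    """Functional wrapper over :class:`TwoStateGainLoss`."""
    est = TwoStateGainLoss(n_categories=K).fit(matrix, tree=tree)
    return est.model_


# ----------------------------------------------------- expected events

def branch_expected_events(tree: StrainTree, leaf_states, model: GainLossModel,
                           family_ids=None) -> BranchEvents:
    """Inside--outside pass: per-branch endpoint posteriors combined with
    uniformization tables, averaged over rate categories."""
    if isinstance(leaf_states, (PresenceMatrix, pd.DataFrame)):
        leaf_states, family_ids = TwoStateGainLoss._coerce(leaf_states, tree)
    leaf_states = np.asarray(leaf_states, dtype=np.int8)
    g, l = model.gain_rate, model.loss_rate
    rates = model.category_rates
    K = len(rates)
    nf = leaf_states.shape[1]
    nn = tree.n_nodes
    up, _, P, loglik_k = _up_pass(tree, leaf_states, g, l, rates)
    # per-family category weights
    w = np.exp(loglik_k - logsumexp(loglik_k, axis=0, keepdims=True))  # (K, nf)

    # per-branch per-category event tables
    E01 = np.zeros((nn, K, 2, 2))
    E10 = np.zeros((nn, K, 2, 2))
    G1 = np.zeros((nn, K, 2, 2))
    L1 = np.zeros((nn, K, 2, 2))
    for v in range(1, nn):
        t = tree.lengths[v]
        for k in range(K):
            E01[v, k], E10[v, k], G1[v, k], L1[v, k] = _uniformization_tables(
                g * rates[k], l * rates[k], t)

    lam = g + l
    pi = np.array([l / lam, g / lam])
    down = np.zeros((nn, K, nf, 2))
    down[0] = pi[None, None, :]
    eg = np.zeros((nn, nf))
    el = np.zeros((nn, nf))
    pg = np.zeros((nn, nf))
    pl = np.zeros((nn, nf))
    for v in tree.preorder():
        v = int(v)
        ch = tree.children[v]
        if not ch:
            continue
        Ms = [np.einsum("kxy,kfy->kfx", P[c], up[c]) for c in ch]
        nch = len(ch)
        prefix = [np.ones((K, nf, 2))]
        for M in Ms[:-1]:
            prefix.append(prefix[-1] * M)
        suffix = [np.ones((K, nf, 2))]
        for M in Ms[:0:-1]:
            suffix.append(suffix[-1] * M)
        suffix = suffix[::-1]
        for i, c in enumerate(ch):
            excl = prefix[i] * suffix[i]
            A = down[v] * excl  # (K, nf, x)
            # joint endpoint posterior, normalised per (k, f)
            J = A[:, :, :, None] * P[c][:, None, :, :] * up[c][:, :, None, :]
            Z = np.maximum(J.sum(axis=(2, 3)), 1e-300)
            J /= Z[:, :, None, None]
            eg[c] = np.einsum("kf,kfxy,kxy->f", w, J, E01[c])
            el[c] = np.einsum("kf,kfxy,kxy->f", w, J, E10[c])
            pg[c] = np.einsum("kf,kfxy,kxy->f", w, J, G1[c])
            pl[c] = np.einsum("kf,kfxy,kxy->f", w, J, L1[c])
            dc = np.einsum("kfx,kxy->kfy", A, P[c])
            down[c] = dc / np.maximum(dc.sum(axis=2, keepdims=True), 1e-300)

    branch_nodes = [v for v in range(1, nn)]
    if family_ids is None:
        family_ids = [f"F{j}" for j in range(nf)]
    return BranchEvents(
        branch_labels=[tree.labels[v] for v in branch_nodes],
        branch_lengths=tree.lengths[branch_nodes].copy(),
        is_terminal=np.array([tree.is_leaf(v) for v in branch_nodes]),
        family_ids=list(family_ids),
        expected_gains=eg[branch_nodes],
        expected_losses=el[branch_nodes],
        p_ge1_gain=np.clip(pg[branch_nodes], 0, 1),
        p_ge1_loss=np.clip(pl[branch_nodes], 0, 1),
    )
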