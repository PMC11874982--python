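"""Poisson phylogenetic GLMM with Laplace-approximate likelihood.

Model per species: gene counts ``Y_i ~ Poisson(mu_i)`` with
``log mu_i = beta0 + sum_j beta_j X_ij + eps_i`` and phylogenetic random
effects ``eps ~ N(0, sigma2_phy * C)``, where ``C[i, j]`` is the shared
root-to-MRCA path length of genomes i and j under Brownian motion on the
strain tree.  The non-phylogenetic counterpart replaces ``C`` by the
identity.  Estimation maximises the Laplace-approximate marginal likelihood;
``sigma2_phy`` is profiled on the log scale with an explicit boundary check
at zero.  Inference on the fixed effects is by Wald tests with
``cov(beta) = (X' (W^-1 + sigma2 C)^-1 X)^-1`` at the fit.

Model comparison uses the conditional AIC: ``-2 * conditional log-lik +
2 * rho`` with ``rho`` the trace of the working-response hat matrix
(Vaida--Blanchard effective degrees of freedom); at ``sigma2 = 0`` this is
exactly the AIC of the Poisson GLM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky, solve
from scipy.special import gammaln
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .io import TraitTable
from .tree import StrainTree

log = logging.getLogger("defenseflux")

__all__ = [
    "PhyloCovariance",
    "PoissonPGLMM",
    "brownian_covariance",
    "fit_poisson_pglmm",
    "fit_poisson_glmm_identity",
    "caic",
    "fit_species_battery",
]


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance: shared root-to-MRCA path lengths."""

    matrix: np.ndarray
    genome_ids: list

    def rescaled(self) -> "PhyloCovariance":
        """Unit mean diagonal (numerical conditioning; beta invariant)."""
        d = float(np.mean(np.diag(self.matrix)))
        if d <= 0:
            raise ValueError("covariance with non-positive mean diagonal")
        return PhyloCovariance(self.matrix / d, self.genome_ids)

    def reordered(self, genome_ids) -> "PhyloCovariance":
        idx = [self.genome_ids.index(g) for g in genome_ids]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(genome_ids))


def brownian_covariance(tree: StrainTree, rescale: bool = False) -> PhyloCovariance:
    """``C[i, j]`` = root-to-MRCA(i, j) path length; diagonal = root-to-leaf.

    Computed by a preorder sweep: every internal node at depth ``d``
    contributes ``d`` to all leaf pairs split between its child subtrees.
    """
    depths = tree.node_depths()
    leaves = tree.leaf_indices
    pos = {int(v): i for i, v in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for v in tree.preorder():
        v = int(v)
        ch = tree.children[v]
        if not ch:
            C[pos[v], pos[v]] = depths[v]
            continue
        sets = [np.array([pos[u] for u in tree.leaf_set(c)]) for c in ch]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                C[np.ix_(sets[i], sets[j])] = depths[v]
                C[np.ix_(sets[j], sets[i])] = depths[v]
    cov = PhyloCovariance(C, tree.leaf_labels)
    return cov.rescaled() if rescale else cov


class PoissonPGLMM(BaseEstimator):
    """Poisson GLMM with a tree-derived (or identity) random-effect
    covariance, fitted by Laplace approximation.

    Parameters
    ----------
    rescale_cov : divide C by its mean diagonal before fitting (the fixed
        effects and their tests are invariant; ``sigma2_phy_`` is then per
        unit of mean tree depth).
    log_sigma2_bounds : profiling interval for ``log sigma2``.

    Attributes (after fit)
    ---------------------
    intercept_, coef_ : fixed effects on the log scale.
    beta_se_, beta_pvalues_ : Wald SEs and two-sided p-values (coef order).
    sigma2_phy_ : random-effect variance (0 if the boundary wins).
    loglik_ : Laplace marginal log-likelihood at the optimum.
    caic_ : conditional AIC; ranef_ : posterior-mode random effects.
    """

    def __init__(self, rescale_cov: bool = True, tol: float = 1e-8,
                 max_inner: int = 100, log_sigma2_bounds=(-12.0, 4.0),
                 jitter: float = 1e-8):
        self.rescale_cov = rescale_cov
        self.tol = tol
        self.max_inner = max_inner
        self.log_sigma2_bounds = log_sigma2_bounds
        self.jitter = jitter

    # ------------------------------------------------------------ internals
    @staticmethod
    def _design(X):
        if X is None:
            return np.empty((0, 0)), []
        if isinstance(X, TraitTable):
            X = X.df
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X, [f"x{j}" for j in range(X.shape[1])]

    def _inner(self, T, y, sigma2, nb, u0=None):
        """Penalised Newton for (beta, a) at fixed sigma2; the random effect
        is parameterised as b = L a with C = L L' so the penalty is a'a."""
        n = len(y)
        q = T.shape[1] - nb
        u = np.zeros(T.shape[1]) if u0 is None else u0.copy()
        pen = np.zeros(T.shape[1])
        pen[nb:] = 1.0 / sigma2 if sigma2 > 0 else np.inf
        for _ in range(self.max_inner):
            eta = T @ u
            mu = np.exp(np.clip(eta, -30, 30))
            grad = T.T @ (y - mu)
            grad[nb:] -= u[nb:] / sigma2
            H = (T * mu[:, None]).T @ T
            H[nb:, nb:] += np.eye(q) / sigma2
            try:
                step = solve(H, grad, assume_a="pos")
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # step halving on the penalised objective
            def obj(uu):
                e = T @ uu
                return float(y @ e - np.exp(np.clip(e, -30, 30)).sum()
                             - 0.5 * uu[nb:] @ uu[nb:] / sigma2)
            f0 = obj(u)
            lamb = 1.0
            while lamb > 1e-8:
                u_new = u + lamb * step
                if obj(u_new) >= f0 - 1e-12:
                    break
                lamb /= 2
            u = u_new
            if np.max(np.abs(lamb * step)) < self.tol:
                break
        return u

    @staticmethod
    def _pois_ll(y, eta):
        mu = np.exp(np.clip(eta, -30, 30))
        return float(y @ eta - mu.sum() - gammaln(y + 1).sum())

    def _laplace(self, T, y, sigma2, nb, u0=None):
        """Laplace marginal log-likelihood and the inner optimum."""
        n = len(y)
        if sigma2 <= 0:
            u = self._inner_glm(T[:, :nb], y)
            full = np.zeros(T.shape[1])
            full[:nb] = u
            return self._pois_ll(y, T[:, :nb] @ u), full
        u = self._inner(T, y, sigma2, nb, u0)
        eta = T @ u
        mu = np.exp(np.clip(eta, -30, 30))
        a = u[nb:]
        L = T[:, nb:]
        # log det(I + sigma2 * L' W L)
        M = np.eye(L.shape[1]) + sigma2 * (L * mu[:, None]).T @ L
        sign, logdet = np.linalg.slogdet(M)
        ll = (self._pois_ll(y, eta) - 0.5 * (a @ a) / sigma2 - 0.5 * logdet)
        return ll, u

    def _inner_glm(self, X, y):
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(max(np.mean(y), 1e-8))
        for _ in range(self.max_inner):
            eta = X @ beta
            mu = np.exp(np.clip(eta, -30, 30))
            grad = X.T @ (y - mu)
            H = (X * mu[:, None]).T @ X
            try:
                step = solve(H, grad, assume_a="pos")
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            lamb = 1.0
            f0 = self._pois_ll(y, eta)
            while lamb > 1e-8:
                if self._pois_ll(y, X @ (beta + lamb * step)) >= f0 - 1e-12:
                    break
                lamb /= 2
            beta = beta + lamb * step
            if np.max(np.abs(lamb * step)) < self.tol:
                break
        return beta

    # ---------------------------------------------------------------- fit
    def fit(self, X, y, cov: PhyloCovariance | np.ndarray | None = None):
        """Fit the model.

        Parameters
        ----------
        X : (n, p) predictor matrix (binary defense presence or numeric),
            or None for an intercept-only model.
        y : (n,) non-negative integer counts.
        cov : phylogenetic covariance aligned to the rows of y; None for
            the identity (non-phylogenetic) model.
        """
        y = np.asarray(y, dtype=float).ravel()
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("y must be non-negative integer counts")
        n = len(y)
        Xmat, names = self._design(X)
        if Xmat.size and Xmat.shape[0] != n:
            raise ValueError("X and y have different lengths")
        Xd = np.column_stack([np.ones(n)] + ([Xmat] if Xmat.size else []))
        nb = Xd.shape[1]

        if cov is None:
            C = np.eye(n)
        elif isinstance(cov, PhyloCovariance):
            C = np.asarray(cov.matrix, dtype=float)
        else:
            C = np.asarray(cov, dtype=float)
        if C.shape != (n, n):
            raise ValueError("covariance shape does not match y")
        if self.rescale_cov:
            C = C / max(np.mean(np.diag(C)), 1e-300)
        Lc = cholesky(C + self.jitter * np.eye(n), lower=True)
        T = np.hstack([Xd, Lc])

        state = {"u": None}

        def neg_profile(ls2):
            ll, u = self._laplace(T, y, np.exp(ls2), nb, state["u"])
            state["u"] = u
            return -ll

        lo, hi = self.log_sigma2_bounds
        res = optimize.minimize_scalar(
            neg_profile, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6})
        ll_hat = -res.fun
        sigma2 = float(np.exp(res.x))
        ll0, u0 = self._laplace(T, y, 0.0, nb)
        if ll0 >= ll_hat - 1e-8 or res.x < lo + 1e-3:
            sigma2, ll_hat = 0.0, ll0
        converged = True

        ll_fin, u = self._laplace(T, y, sigma2, nb)
        beta = u[:nb]
        a = u[nb:]
        b = Lc @ a
        eta = Xd @ beta + b
        mu = np.exp(np.clip(eta, -30, 30))

        # Wald covariance for beta: (X' (W^-1 + s2 C)^-1 X)^-1
        Winv = 1.0 / np.maximum(mu, 1e-12)
        M = np.diag(Winv) + sigma2 * C
        cf = cho_factor(M + self.jitter * np.eye(n))
        XtMinvX = Xd.T @ cho_solve(cf, Xd)
        cov_beta = np.linalg.pinv(XtMinvX)
        se = np.sqrt(np.maximum(np.diag(cov_beta), 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2 * norm.sf(np.abs(z))

        # conditional AIC
        cond_ll = self._pois_ll(y, eta)
        if sigma2 > 0:
            W = mu
            TT = np.hstack([Xd, Lc])
            A = (TT * W[:, None]).T @ TT
            P = np.zeros_like(A)
            P[nb:, nb:] = np.eye(n) / sigma2
            rho = float(np.trace(solve(A + P, A)))
        else:
            rho = float(nb)
        caic_val = -2 * cond_ll + 2 * rho

        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.beta_ = beta
        self.beta_names_ = ["(Intercept)"] + names
        self.se_ = se
        self.pvalues_ = pvals
        self.beta_se_ = se[1:]
        self.beta_pvalues_ = pvals[1:]
        self.sigma2_phy_ = sigma2
        self.loglik_ = float(ll_fin)
        self.cond_loglik_ = cond_ll
        self.edf_ = rho
        self.caic_ = float(caic_val)
        self.converged_ = converged
        self.ranef_ = b
        self.n_genomes_ = n
        self.n_features_in_ = nb - 1
        return self

    def _edf_at(self, X, y, cov, sigma2: float) -> float:
        """Effective degrees of freedom (hat-matrix trace) at a given
        sigma2 on a dataset, for diagnostics."""
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        Xmat, _ = self._design(X)
        Xd = np.column_stack([np.ones(n)] + ([Xmat] if Xmat.size else []))
        nb = Xd.shape[1]
        C = cov.matrix if isinstance(cov, PhyloCovariance) else (
            np.eye(n) if cov is None else np.asarray(cov))
        if self.rescale_cov:
            C = C / max(np.mean(np.diag(C)), 1e-300)
        Lc = cholesky(C + self.jitter * np.eye(n), lower=True)
        T = np.hstack([Xd, Lc])
        if sigma2 <= 0:
            return float(nb)
        u = self._inner(T, y, sigma2, nb)
        mu = np.exp(np.clip(T @ u, -30, 30))
        A = (T * mu[:, None]).T @ T
        P = np.zeros_like(A)
        P[nb:, nb:] = np.eye(n) / sigma2
        return float(np.trace(solve(A + P, A)))

    def predict(self, X=None, n: int = None):
        """Population-level expected counts exp(beta0 + X beta)."""
        if X is None:
            size = n or 1
            return np.full(size, np.exp(self.intercept_))
        Xmat, _ = self._design(X)
        return np.exp(self.intercept_ + Xmat @ self.coef_)


# ------------------------------------------------------------- functional API

def fit_poisson_pglmm(y, X, cov: PhyloCovariance, **kwargs) -> PoissonPGLMM:
    """Phylogenetic Poisson GLMM (Brownian covariance from the tree)."""
    return PoissonPGLMM(**kwargs).fit(X, y, cov=cov)


def fit_poisson_glmm_identity(y, X, **kwargs) -> PoissonPGLMM:
    """Identity-covariance counterpart (same code path with C = I)."""
    return PoissonPGLMM(**kwargs).fit(X, y, cov=None)


def caic(fit: PoissonPGLMM) -> float:
    """Conditional AIC of a converged fit."""
    if not getattr(fit, "converged_", False):
        raise ValueError("cAIC requires a converged fit")
    return fit.caic_


def fit_species_battery(responses: dict, traits: TraitTable,
                        cov: PhyloCovariance, mode: str = "single",
                        extra_defense_count: bool = False,
                        species: str = "species") -> pd.DataFrame:
    """Fit the per-species battery of PGLMMs and their identity counterparts.

    ``responses``: mapping response name -> count vector aligned to
    ``cov.genome_ids``.  In ``single`` mode one model is fitted per
    (response, system); in ``joint`` mode one model per response with all
    systems as predictors.  Systems constant within the species are skipped.
    Optionally adds the count of other defense systems as a covariate.

    Returns a tidy DataFrame, one row per fitted coefficient.
    """
    if mode not in ("single", "joint"):
        raise ValueError("mode must be 'single' or 'joint'")
    tdf = traits.df.loc[cov.genome_ids]
    systems = list(tdf.columns)
    usable = [s for s in systems if 0 < tdf[s].mean() < 1]
    for s in systems:
        if s not in usable:
            log.info("battery: system %s skipped (constant predictor)", s)
    rows = []
    for resp_name, y in responses.items():
        y = np.asarray(y, dtype=float)
        groups = [[s] for s in usable] if mode == "single" else (
            [usable] if usable else [])
        for group in groups:
            Xdf = tdf[group].astype(float).copy()
            if extra_defense_count:
                others = [s for s in systems if s not in group]
                Xdf["other_defense_count"] = tdf[others].sum(axis=1).astype(float)
            try:
                fit_p = PoissonPGLMM().fit(Xdf, y, cov=cov)
                fit_i = PoissonPGLMM().fit(Xdf, y, cov=None)
            except Exception as exc:  # non-convergence -> excluded, logged
                log.warning("battery: fit failed for %s/%s: %s",
                            resp_name, group, exc)
                continue
            for j, s in enumerate(group):
                rows.append({
                    "species": species,
                    "response": resp_name,
                    "system": s,
                    "beta": fit_p.coef_[j],
                    "se": fit_p.beta_se_[j],
                    "p": fit_p.beta_pvalues_[j],
                    "sigma2_phy": fit_p.sigma2_phy_,
                    "caic_pglmm": fit_p.caic_,
                    "caic_identity": fit_i.caic_,
                    "delta_caic": fit_p.caic_ - fit_i.caic_,
                    "n_genomes": fit_p.n_genomes_,
                    "converged": fit_p.converged_ and fit_i.converged_,
                })
    return pd.DataFrame(rows)
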