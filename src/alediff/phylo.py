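"""Weighted Bayesian phylogenetic generalized least squares (BPGLS).

The model is

    y ~ MVN(X beta, sigma^2 * W^(-1/2) C(lambda) W^(-1/2))

where C is the Brownian-motion phylogenetic correlation matrix implied by
a time-calibrated tree, C(lambda) multiplies its off-diagonals by Pagel's
lambda in [0, 1], and W = diag(omega) holds per-species regression
weights derived from the posterior SEs sigma_i of the response:

    v_i = log(1/sigma_i + 1),   omega_i = v_i / max(v)

so omega in (0, 1] and the residual variance of species i scales with
1/omega_i.  Sampling is Gibbs for beta (conjugate normal) and sigma^2
(conjugate inverse-gamma) with Metropolis-Hastings for lambda, and models
are compared by the deviance information criterion (DIC).

Because C(lambda) = Q (lambda(L - 1) + 1) Q' for a single eigendecomposition
C = Q L Q', every lambda value shares one O(n^3) factorisation and each
MCMC iteration costs O(n p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .diff_metrics import zero_overlap

__all__ = [
    "PGLSConfig",
    "PGLSResult",
    "load_tree",
    "phylo_correlation",
    "lambda_transform",
    "regression_weights",
    "fit_bpgls",
    "dic",
    "graft_trees",
    "power_param_from_betas",
]


@dataclass(frozen=True)
class PGLSConfig:
    """Sampler and prior settings for the weighted BPGLS.

    Coefficient priors are independent Normal(0, variance 100); sigma^2
    has an inverse-gamma(0.01, 0.01) prior and lambda a uniform prior on
    [0, 1] updated by reflected-normal Metropolis-Hastings.
    """

    beta_prior_var: float = 100.0
    sigma2_prior_shape: float = 0.01
    sigma2_prior_rate: float = 0.01
    n_iter: int = 12_000
    burn_in: int = 2_000
    thinning: int = 5
    lambda_scale: float = 0.1
    adapt_interval: int = 50
    seed: int = 0
    estimate_lambda: bool = True
    fixed_lambda: float = 1.0

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class PGLSResult:
    """Posterior draws and summaries from a weighted BPGLS fit."""

    beta_draws: np.ndarray
    sigma2_draws: np.ndarray
    lambda_draws: np.ndarray
    predictor_names: list
    weights: np.ndarray
    dic: float
    pd_eff: float
    mean_deviance: float
    zero_overlaps: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.zero_overlaps = np.array(
            [zero_overlap(self.beta_draws[:, j]) for j in range(self.beta_draws.shape[1])]
        )

    def summary(self):
        import pandas as pd

        ci = np.quantile(self.beta_draws, [0.025, 0.975], axis=0)
        rows = pd.DataFrame(
            {
                "Mean": self.beta_draws.mean(axis=0),
                "SD": self.beta_draws.std(axis=0, ddof=1),
                "Lower CI": ci[0],
                "Upper CI": ci[1],
                "Zero overlap": self.zero_overlaps,
            },
            index=self.predictor_names,
        )
        extra = pd.DataFrame(
            {
                "Mean": [self.sigma2_draws.mean(), self.lambda_draws.mean()],
                "SD": [self.sigma2_draws.std(ddof=1), self.lambda_draws.std(ddof=1)],
                "Lower CI": np.quantile(
                    np.c_[self.sigma2_draws, self.lambda_draws], 0.025, axis=0
                ),
                "Upper CI": np.quantile(
                    np.c_[self.sigma2_draws, self.lambda_draws], 0.975, axis=0
                ),
                "Zero overlap": [np.nan, np.nan],
            },
            index=["Residual variance sigma2", "Pagel's lambda"],
        )
        return pd.concat([rows, extra])


def load_tree(path_or_string) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or string."""
    src = str(path_or_string)
    if src.lstrip().startswith("("):
        return dendropy.Tree.get(data=src, schema="newick")
    return dendropy.Tree.get(path=src, schema="newick")


def _tip_depths(tree: dendropy.Tree) -> dict:
    return {
        leaf.taxon.label: leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    }


def phylo_correlation(
    tree: dendropy.Tree, taxa, *, ultrametric_rtol: float = 1e-3
) -> np.ndarray:
    """Brownian-motion phylogenetic correlation among the requested taxa.

    Entry (i, j) is the shared root-to-MRCA depth divided by tree depth,
    i.e. the covariance of a Brownian trait scaled to unit diagonal; a
    star phylogeny therefore yields the identity.  The tree must be
    ultrametric within ``ultrametric_rtol``.
    """
    taxa = list(taxa)
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for name in taxa:
        if name not in labels:
            raise KeyError(f"taxon {name!r} is not a tip of the tree")
    depths = _tip_depths(tree)
    depth_vals = np.array([depths[t] for t in taxa])
    T = depth_vals.max()
    if T > 0 and (depth_vals.max() - depth_vals.min()) > ultrametric_rtol * T:
        raise ValueError("tree is not ultrametric within tolerance")

    pdm = tree.phylogenetic_distance_matrix()
    tax_map = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tax_map[taxa[i]], tax_map[taxa[j]])
            shared = 0.5 * (depths[taxa[i]] + depths[taxa[j]] - d)
            C[i, j] = C[j, i] = shared / T if T > 0 else 0.0
    return C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonals scaled by lam in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    C = np.asarray(C, dtype=float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def regression_weights(sds) -> np.ndarray:
    """Weights from response SEs: v = log(1/sd + 1), omega = v / max(v)."""
    s = np.asarray(sds, dtype=float)
    if np.any(s <= 0):
        raise ValueError("SEs must be strictly positive")
    v = np.log(1.0 / s + 1.0)
    return v / v.max()


def _reflect01(x: float) -> float:
    """Reflect a proposal back into [0, 1]."""
    x = x % 2.0
    return 2.0 - x if x > 1.0 else x


def fit_bpgls(
    y,
    X,
    tree: dendropy.Tree = None,
    sds=None,
    config: PGLSConfig = None,
    *,
    taxa=None,
    predictor_names=None,
) -> PGLSResult:
    """Fit the weighted Bayesian PGLS by Gibbs-within-Metropolis.

    Parameters
    ----------
    y, X : array-like
        Response vector and design matrix, rows aligned with ``taxa``.
    tree : dendropy.Tree, optional
        Time-calibrated ultrametric phylogeny; omit for independent
        residuals (C = I).
    sds : array-like, optional
        Per-species posterior SEs of the response; converted to weights
        via ``regression_weights``.  Omit for unit weights.
    taxa : sequence of str
        Tip labels in row order; required when ``tree`` is given.
    """
    if config is None:
        config = PGLSConfig()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError(
            f"design matrix is singular: rank {np.linalg.matrix_rank(X)} < {p} columns"
        )
    if tree is not None:
        if taxa is None:
            raise ValueError("taxa (row order of y/X) is required with a tree")
        C = phylo_correlation(tree, taxa)
    else:
        C = np.eye(n)
    omega = regression_weights(sds) if sds is not None else np.ones(n)
    w_half = np.sqrt(omega)

    # one eigendecomposition serves every lambda:
    # V(lam) = W^(-1/2) Q diag(lam*(L-1)+1) Q' W^(-1/2)
    L, Q = np.linalg.eigh(C)
    yt = Q.T @ (w_half * y)
    Xt = Q.T @ (w_half[:, None] * X)
    log_det_w = np.sum(np.log(omega))  # |W^(-1)| contribution

    def eigvals(lam):
        return np.clip(lam * (L - 1.0) + 1.0, 1e-12, None)

    rng = np.random.default_rng(config.seed)
    lam = config.fixed_lambda if not config.estimate_lambda else rng.uniform()
    sigma2 = 1.0
    beta = np.zeros(p)
    d = eigvals(lam)

    prior_prec = np.eye(p) / config.beta_prior_var
    a0, b0 = config.sigma2_prior_shape, config.sigma2_prior_rate
    lam_scale = config.lambda_scale
    n_keep = (config.n_iter - config.burn_in) // config.thinning
    beta_draws = np.empty((n_keep, p))
    sigma2_draws = np.empty(n_keep)
    lambda_draws = np.empty(n_keep)
    dev_draws = np.empty(n_keep)
    acc_window = 0
    k = 0

    def deviance(beta, sigma2, d):
        r = yt - Xt @ beta
        quad = np.sum(r * r / d)
        logdet = np.sum(np.log(d)) - log_det_w
        return n * np.log(2.0 * np.pi * sigma2) + logdet + quad / sigma2

    for it in range(config.n_iter):
        # beta | sigma2, lambda  (conjugate normal)
        Xd = Xt / d[:, None]
        prec = Xd.T @ Xt / sigma2 + prior_prec
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Xd.T @ yt / sigma2)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(chol.T, z)

        # sigma2 | beta, lambda  (conjugate inverse-gamma)
        r = yt - Xt @ beta
        quad = np.sum(r * r / d)
        sigma2 = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * quad))

        # lambda | beta, sigma2  (reflected-normal Metropolis-Hastings)
        if config.estimate_lambda:
            prop = _reflect01(lam + lam_scale * rng.standard_normal())
            d_prop = eigvals(prop)
            quad_prop = np.sum(r * r / d_prop)
            log_acc = -0.5 * (
                np.sum(np.log(d_prop)) - np.sum(np.log(d))
                + (quad_prop - quad) / sigma2
            )
            if np.log(rng.uniform()) < log_acc:
                lam, d = prop, d_prop
                acc_window += 1
            if it < config.burn_in and (it + 1) % config.adapt_interval == 0:
                rate = acc_window / config.adapt_interval
                lam_scale *= np.exp(rate - 0.3)
                acc_window = 0

        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0 and k < n_keep:
            beta_draws[k] = beta
            sigma2_draws[k] = sigma2
            lambda_draws[k] = lam
            dev_draws[k] = deviance(beta, sigma2, d)
            k += 1

    beta_draws = beta_draws[:k]
    sigma2_draws = sigma2_draws[:k]
    lambda_draws = lambda_draws[:k]
    dev_draws = dev_draws[:k]

    mean_dev = float(dev_draws.mean())
    dev_at_mean = float(
        deviance(beta_draws.mean(axis=0), sigma2_draws.mean(), eigvals(lambda_draws.mean()))
    )
    p_d = mean_dev - dev_at_mean
    names = (
        list(predictor_names)
        if predictor_names is not None
        else [f"beta{j}" for j in range(p)]
    )
    return PGLSResult(
        beta_draws=beta_draws,
        sigma2_draws=sigma2_draws,
        lambda_draws=lambda_draws,
        predictor_names=names,
        weights=omega,
        dic=mean_dev + p_d,
        pd_eff=p_d,
        mean_deviance=mean_dev,
    )


def dic(result: PGLSResult, y, X, tree=None, sds=None, *, taxa=None) -> float:
    """Deviance information criterion of a fitted BPGLS.

    DIC = mean deviance + pD with pD = mean deviance - deviance at the
    posterior means (Spiegelhalter's effective parameter count).  The
    deviance is recomputed from the stored draws, so the value is
    deterministic given the fit.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    C = phylo_correlation(tree, taxa) if tree is not None else np.eye(n)
    omega = regression_weights(sds) if sds is not None else np.ones(n)
    w_half = np.sqrt(omega)
    L, Q = np.linalg.eigh(C)
    yt = Q.T @ (w_half * y)
    Xt = Q.T @ (w_half[:, None] * X)
    log_det_w = np.sum(np.log(omega))

    def deviance(beta, sigma2, lam):
        d = np.clip(lam * (L - 1.0) + 1.0, 1e-12, None)
        r = yt - Xt @ beta
        return (
            n * np.log(2.0 * np.pi * sigma2)
            + np.sum(np.log(d))
            - log_det_w
            + np.sum(r * r / d) / sigma2
        )

    devs = np.array(
        [
            deviance(result.beta_draws[k], result.sigma2_draws[k], result.lambda_draws[k])
            for k in range(len(result.sigma2_draws))
        ]
    )
    mean_dev = devs.mean()
    dev_at_mean = deviance(
        result.beta_draws.mean(axis=0),
        result.sigma2_draws.mean(),
        result.lambda_draws.mean(),
    )
    return float(2.0 * mean_dev - dev_at_mean)


def _crown_depth(tree: dendropy.Tree) -> float:
    depths = list(_tip_depths(tree).values())
    if max(depths) - min(depths) > 1e-3 * max(depths):
        raise ValueError("tree is not ultrametric; cannot graft")
    return max(depths)


def graft_trees(
    tree_a: dendropy.Tree, tree_b: dendropy.Tree, root_age: float = 319.0
) -> dendropy.Tree:
    """Join two ultrametric trees under a common root of age ``root_age``.

    Each crown keeps its depth and is attached by a stem branch of length
    ``root_age - crown_depth``, so every tip of the grafted tree sits at
    distance ``root_age`` from the new root (319 MY is the median
    mammal-bird divergence time).
    """
    tips_a = {l.taxon.label for l in tree_a.leaf_node_iter()}
    tips_b = {l.taxon.label for l in tree_b.leaf_node_iter()}
    shared = tips_a & tips_b
    if shared:
        raise ValueError(f"trees share tip labels: {sorted(shared)[:5]}")
    parts = []
    for t in (tree_a, tree_b):
        depth = _crown_depth(t)
        if depth > root_age:
            raise ValueError(
                f"crown depth {depth:.3f} exceeds the root age {root_age}"
            )
        newick = t.as_string(
            schema="newick", suppress_rooting=True, suppress_annotations=True
        ).strip()
        parts.append(f"{newick.rstrip(';')}:{root_age - depth:.10g}")
    combined = f"({parts[0]},{parts[1]});"
    return dendropy.Tree.get(data=combined, schema="newick")


def power_param_from_betas(beta1: float, beta2: float) -> float:
    """Allometric power parameter gamma = -beta2/beta1 from the additive
    log-mass (or log-testis) coefficients of the BPGLS."""
    if beta1 == 0:
        raise ZeroDivisionError("beta1 must be nonzero to recover gamma")
    return -beta2 / beta1
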