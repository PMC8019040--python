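"""Phylogenetic comparative statistics on species-level complexity data.

All procedures are built on the Brownian-motion tip covariance matrix C of
a rooted, branch-length-bearing tree: C[i, j] is the shared root-to-MRCA
path length of tips i and j. Pagel's lambda rescales the off-diagonal of
C, interpolating between a star phylogeny (lambda = 0, i.i.d. residuals)
and full Brownian covariance (lambda = 1); every procedure here therefore
collapses to its classical counterpart on a star tree.

Implemented: ML estimation of Pagel's lambda with a likelihood-ratio
signal test, GLS ancestral-state reconstruction, PGLS regression with
jointly ML-estimated lambda, and simulation-based phylogenetic ANOVA /
MANOVA (classical statistic referenced to a Brownian null simulated on
the tree).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .errors import (
    CollinearityError,
    DesignError,
    DomainError,
    LabelMappingError,
    RankError,
    SizeError,
)

__all__ = [
    "Phylogeny",
    "ComparativeDataset",
    "PglsFit",
    "pagels_lambda",
    "ancestral_states",
    "pgls",
    "phyl_anova",
    "phyl_manova",
]


# ---------------------------------------------------------------------------
# tree handling
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted, branch-length tree with cached tip covariance.

    Branch lengths are in arbitrary time units (the study trees are in
    millions of years); only relative lengths matter for every statistic
    here, which is asserted by the branch-scaling invariance tests.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._labels: list[str] | None = None
        self._cov: np.ndarray | None = None

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        from pathlib import Path

        if "(" in source:
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=str(Path(source)), schema="newick")
        return cls(tree)

    @classmethod
    def star(cls, labels: list[str], branch_length: float = 1.0) -> "Phylogeny":
        newick = "(" + ",".join(f"{lab}:{branch_length}" for lab in labels) + ");"
        return cls.from_newick(newick)

    # -- basic structure ----------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        if self._labels is None:
            self._labels = sorted(
                leaf.taxon.label for leaf in self.tree.leaf_node_iter()
            )
        return self._labels

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def depths(self) -> dict:
        """Root-to-node path length for every node."""
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                out[node] = 0.0
            else:
                out[node] = out[node.parent_node] + (node.edge.length or 0.0)
        return out

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths()
        tip_d = np.array([d[leaf] for leaf in self.tree.leaf_node_iter()])
        return bool(np.ptp(tip_d) <= rel_tol * max(tip_d.max(), 1e-300))

    def covariance(self) -> tuple[list[str], np.ndarray]:
        """(sorted tip labels, BM covariance C) with C[i,j] = depth of MRCA."""
        if self._cov is None:
            depths = self.depths()
            leaves = list(self.tree.leaf_node_iter())
            labels = [lf.taxon.label for lf in leaves]
            order = np.argsort(labels)
            leaves = [leaves[i] for i in order]
            labels = [labels[i] for i in order]
            n = len(leaves)
            tip_depth = np.array([depths[lf] for lf in leaves])
            pdm = self.tree.phylogenetic_distance_matrix()
            D = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    D[i, j] = D[j, i] = pdm.patristic_distance(
                        leaves[i].taxon, leaves[j].taxon
                    )
            C = 0.5 * (tip_depth[:, None] + tip_depth[None, :] - D)
            np.fill_diagonal(C, tip_depth)
            self._labels = labels
            self._cov = C
        return self._labels, self._cov

    def pruned_to(self, labels) -> "Phylogeny":
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise LabelMappingError(f"labels absent from tree: {sorted(missing)}")
        tree = self.tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(tree)

    def scaled(self, factor: float) -> "Phylogeny":
        tree = self.tree.clone(depth=1)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return Phylogeny(tree)


def _as_phylogeny(tree) -> Phylogeny:
    if isinstance(tree, Phylogeny):
        return tree
    if isinstance(tree, dendropy.Tree):
        return Phylogeny(tree)
    return Phylogeny.from_newick(str(tree))


def _align(tree, values: pd.Series) -> tuple[Phylogeny, np.ndarray, np.ndarray, list[str]]:
    """Prune tree to the data, order data by sorted tip label, return C."""
    phy = _as_phylogeny(tree)
    values = pd.Series(values).dropna()
    labels = sorted(values.index.astype(str))
    extra = set(labels) - set(phy.tip_labels)
    if extra:
        raise LabelMappingError(f"species not in tree: {sorted(extra)}")
    if set(labels) != set(phy.tip_labels):
        phy = phy.pruned_to(labels)
    tip_order, C = phy.covariance()
    x = values.loc[tip_order].to_numpy(dtype=np.float64)
    return phy, x, C, tip_order


def _pagel_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _chol(V: np.ndarray) -> np.ndarray:
    """Cholesky with a tiny escalating ridge for near-singular trees
    (zero-length cherries make tip rows exactly duplicate)."""
    scale = float(np.trace(V)) / len(V)
    for ridge in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(V + ridge * scale * np.eye(len(V)))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance matrix is numerically singular")


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------


@dataclass
class LambdaResult:
    lambda_: float
    loglik: float
    p_value: float
    loglik0: float
    sigma2: float


def _bm_profile_loglik(x: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Profile ML log-likelihood of a GLS mean model under covariance V.

    The mean coefficients and the BM rate sigma^2 are profiled out
    analytically; returns (loglik, beta, sigma2_ml, XtVinvX_inv).
    """
    n = len(x)
    L = _chol(V)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Xw = np.linalg.solve(L, X)
    xw = np.linalg.solve(L, x)
    beta, *_ = np.linalg.lstsq(Xw, xw, rcond=None)
    resid = xw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    return loglik, beta, sigma2, xtx_inv, rss


def _optimize_lambda(x: np.ndarray, X: np.ndarray, C: np.ndarray):
    def nll(lam: float) -> float:
        return -_bm_profile_loglik(x, X, _pagel_cov(C, lam))[0]

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    best_lam, best_val = float(res.x), float(res.fun)
    for lam in (0.0, 1.0):  # bounded Brent can miss a boundary optimum
        v = nll(lam)
        if v < best_val - 1e-12:
            best_lam, best_val = lam, v
    return best_lam, -best_val


def pagels_lambda(tree, trait: pd.Series) -> LambdaResult:
    """ML Pagel's lambda and a likelihood-ratio signal test against lambda=0.

    lambda scales the off-diagonal BM covariance on [0, 1]; the p-value is
    from chi-square with 1 df on 2 * (logL(lambda_hat) - logL(0)).
    """
    phy, x, C, _ = _align(tree, trait)
    if len(x) < 4:
        raise SizeError("need at least 4 species")
    if not phy.is_ultrametric():
        warnings.warn("tree is not ultrametric; lambda is still defined but "
                      "interpretation assumes time calibration", stacklevel=2)
    X = np.ones((len(x), 1))
    lam, loglik = _optimize_lambda(x, X, C)
    loglik0 = _bm_profile_loglik(x, X, _pagel_cov(C, 0.0))[0]
    lr = max(2.0 * (loglik - loglik0), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    sigma2 = _bm_profile_loglik(x, X, _pagel_cov(C, lam))[2]
    return LambdaResult(lambda_=lam, loglik=loglik, p_value=p,
                        loglik0=loglik0, sigma2=sigma2)


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------


def ancestral_states(tree, trait: pd.Series) -> pd.Series:
    """ML (GLS) Brownian ancestral states at every internal node.

    The root estimate is the GLS grand mean; other nodes are the GLS
    predictions mu + c' C^{-1} (x - mu), with c the vector of shared path
    lengths between the node and each tip (equivalent to re-rooted
    phylogenetically weighted means).
    """
    phy, x, C, tip_order = _align(tree, trait)
    if len(x) < 2:
        raise SizeError("need at least 2 species")
    n = len(x)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    mu = float(one @ Cinv @ x / (one @ Cinv @ one))
    w = Cinv @ (x - mu * one)
    depths = phy.depths()
    tip_index = {lab: i for i, lab in enumerate(tip_order)}

    est = {}
    node_id = 0
    for node in phy.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        label = node.label or f"node{node_id}"
        node_id += 1
        desc = [tip_index[lf.taxon.label] for lf in node.leaf_iter()]
        c = np.empty(n)
        if len(desc) == n:  # root: zero shared path with the root itself
            c[:] = 0.0
        else:
            rep = desc[0]
            c[:] = C[rep, :]
        c[desc] = depths[node]
        est[label] = mu + float(c @ w)
    return pd.Series(est, name=trait.name if hasattr(trait, "name") else "state")


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------


@dataclass
class PglsFit:
    """PGLS regression fit with a Pagel residual correlation structure."""

    coef: pd.DataFrame  # index: term; columns: slope, se, t, p
    lambda_: float
    loglik: float
    n: int
    sigma2: float
    response: str
    predictors: list[str] = field(default_factory=list)

    @property
    def slopes(self) -> pd.Series:
        return self.coef["slope"]


@dataclass
class ComparativeDataset:
    """Species-level trait table paired with a phylogeny.

    ``traits`` is indexed by species label. ``log10`` lists the columns to
    log10-transform before modeling (positive values required); category
    columns (e.g. penis-tip class) are passed through untouched.
    """

    traits: pd.DataFrame
    tree: Phylogeny
    log10: tuple[str, ...] = ()

    def __post_init__(self):
        extra = set(self.traits.index.astype(str)) - set(self.tree.tip_labels)
        if extra:
            raise LabelMappingError(f"species not in tree: {sorted(extra)}")

    def model_frame(self, columns: list[str], subset: pd.Index | None = None) -> pd.DataFrame:
        df = self.traits[columns].copy()
        if subset is not None:
            df = df.loc[df.index.intersection(subset)]
        df = df.dropna()
        for col in columns:
            if col in self.log10:
                vals = df[col].to_numpy(dtype=float)
                if (vals <= 0).any():
                    raise DomainError(f"column {col!r} must be positive for log10")
                df[col] = np.log10(vals)
        return df


def pgls(
    dataset,
    tree=None,
    response: str = None,
    predictors: list[str] = (),
    lambda_: float | None = None,
) -> PglsFit:
    """PGLS regression of ``response`` on ``predictors``.

    ``dataset`` may be a :class:`ComparativeDataset` (tree embedded,
    log10 transforms applied per its flags) or a plain DataFrame indexed
    by species (then ``tree`` is required and values are used as-is).
    lambda is estimated by ML jointly with the coefficients unless fixed
    via ``lambda_``. Standard errors use the unbiased residual variance
    and p-values a t distribution with n - #coefficients df.
    """
    predictors = list(predictors)
    if isinstance(dataset, ComparativeDataset):
        df = dataset.model_frame([response] + predictors)
        tree = dataset.tree
    else:
        df = pd.DataFrame(dataset)[[response] + predictors].dropna()
    if tree is None:
        raise LabelMappingError("a tree is required")
    y = pd.Series(df[response].to_numpy(), index=df.index.astype(str))
    phy, yv, C, tip_order = _align(tree, y)
    n = len(yv)
    p = len(predictors) + 1
    if n <= p:
        raise SizeError(f"n={n} too small for {p} coefficients")
    X = np.column_stack(
        [np.ones(n)] + [df.loc[tip_order, c].to_numpy(dtype=float) for c in predictors]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("rank-deficient design matrix")

    if lambda_ is None:
        lam, loglik = _optimize_lambda(yv, X, C)
    else:
        lam = float(lambda_)
        loglik = _bm_profile_loglik(yv, X, _pagel_cov(C, lam))[0]
    _, beta, _, xtx_inv, rss = _bm_profile_loglik(yv, X, _pagel_cov(C, lam))
    sigma2 = rss / (n - p)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - p)
    coef = pd.DataFrame(
        {"slope": beta, "se": se, "t": tstat, "p": pvals},
        index=["intercept"] + predictors,
    )
    return PglsFit(coef=coef, lambda_=lam, loglik=loglik, n=n, sigma2=sigma2,
                   response=response, predictors=predictors)


# ---------------------------------------------------------------------------
# phylogenetic ANOVA / MANOVA
# ---------------------------------------------------------------------------


def _anova_f(Y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Classical one-way F for each row of Y (vectorized over simulations)."""
    Y = np.atleast_2d(Y)
    cats, inv = np.unique(groups, return_inverse=True)
    g = len(cats)
    n = Y.shape[1]
    G = np.zeros((n, g))
    G[np.arange(n), inv] = 1.0
    counts = G.sum(axis=0)
    tot = Y.sum(axis=1)
    gsum = Y @ G
    ssb = (gsum**2 / counts).sum(axis=1) - tot**2 / n
    sst = (Y**2).sum(axis=1) - tot**2 / n
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (g - 1)) / (ssw / (n - g))
    F[~np.isfinite(F)] = 0.0
    return F


def _bm_mle(x: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    n = len(x)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    mu = float(one @ Cinv @ x / (one @ Cinv @ one))
    r = x - mu
    sigma2 = float(r @ Cinv @ r) / n
    return mu, sigma2


@dataclass
class PhylAnovaResult:
    F: float
    p_phylo: float
    p_classical: float
    n_sim: int


def phyl_anova(tree, trait: pd.Series, groups: pd.Series,
               n_sim: int = 1000, seed: int = 0) -> PhylAnovaResult:
    """Phylogenetic ANOVA: classical F referenced to a Brownian null.

    The observed one-way F is compared with F statistics from ``n_sim``
    BM simulations on the tree (rate from the observed data);
    p = (1 + #{F_sim >= F_obs}) / (n_sim + 1).
    """
    phy, x, C, tip_order = _align(tree, pd.Series(trait))
    grp = pd.Series(groups).astype(str)
    missing = set(tip_order) - set(grp.index.astype(str))
    if missing:
        raise LabelMappingError(f"groups missing for: {sorted(missing)}")
    g = grp.loc[tip_order].to_numpy()
    if len(np.unique(g)) < 2:
        raise DesignError("need at least 2 groups")
    F_obs = float(_anova_f(x[None, :], g)[0])
    if np.allclose(x, x[0]):
        return PhylAnovaResult(F=0.0, p_phylo=1.0, p_classical=1.0, n_sim=n_sim)
    mu, sigma2 = _bm_mle(x, C)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(x)) * np.trace(C) / len(x))
    rng = np.random.default_rng(seed)
    sims = mu + np.sqrt(sigma2) * rng.standard_normal((n_sim, len(x))) @ L.T
    F_sim = _anova_f(sims, g)
    p_phylo = (1.0 + np.sum(F_sim >= F_obs)) / (n_sim + 1.0)
    cats = np.unique(g)
    dfb, dfw = len(cats) - 1, len(x) - len(cats)
    p_classical = float(stats.f.sf(F_obs, dfb, dfw))
    return PhylAnovaResult(F=F_obs, p_phylo=float(p_phylo),
                           p_classical=p_classical, n_sim=n_sim)


def _wilks(Y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Wilks' Lambda and its Rao F approximation for one-way MANOVA."""
    cats = np.unique(groups)
    n, p = Y.shape
    g = len(cats)
    grand = Y.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for c in cats:
        sub = Y[groups == c]
        m = sub.mean(axis=0)
        d = sub - m
        E += d.T @ d
        dm = (m - grand)[:, None]
        H += len(sub) * (dm @ dm.T)
    lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    # Rao's F approximation
    q = g - 1
    t_num = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4) / t_num) if t_num > 0 else 1.0
    w = n - g - (p - q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else np.inf
    return lam, float(F)


@dataclass
class PhylManovaResult:
    wilks: float
    F: float
    p_phylo: float
    p_classical: float
    n_sim: int


def phyl_manova(tree, scores: pd.DataFrame, groups: pd.Series,
                n_sim: int = 1000, seed: int = 0) -> PhylManovaResult:
    """Phylogenetic MANOVA: Wilks' Lambda referenced to a multivariate
    Brownian null with the evolutionary covariance estimated from the data."""
    scores = pd.DataFrame(scores)
    phy = _as_phylogeny(tree)
    labels = sorted(scores.index.astype(str))
    extra = set(labels) - set(phy.tip_labels)
    if extra:
        raise LabelMappingError(f"species not in tree: {sorted(extra)}")
    if set(labels) != set(phy.tip_labels):
        phy = phy.pruned_to(labels)
    tip_order, C = phy.covariance()
    Y = scores.loc[tip_order].to_numpy(dtype=float)
    grp = pd.Series(groups).astype(str).loc[tip_order].to_numpy()
    cats = np.unique(grp)
    if len(cats) < 2:
        raise DesignError("need at least 2 groups")
    n, p = Y.shape
    if p > n - len(cats):
        raise RankError(f"{p} response dimensions exceed n - groups = {n - len(cats)}")
    lam_obs, F_obs = _wilks(Y, grp)

    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    anc = (one @ Cinv @ Y) / (one @ Cinv @ one)
    R = (Y - anc).T @ Cinv @ (Y - anc) / (n - 1)
    R += 1e-12 * np.eye(p) * max(np.trace(R) / p, 1e-300)
    Lc = np.linalg.cholesky(C + 1e-12 * np.eye(n) * np.trace(C) / n)
    Lr = np.linalg.cholesky(R)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sim):
        Z = rng.standard_normal((n, p))
        Ys = anc + Lc @ Z @ Lr.T
        lam_s, _ = _wilks(Ys, grp)
        if lam_s <= lam_obs:  # smaller Wilks = stronger group separation
            count += 1
    p_phylo = (1.0 + count) / (n_sim + 1.0)
    q = len(cats) - 1
    t_num = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4) / t_num) if t_num > 0 else 1.0
    w = n - len(cats) - (p - q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    p_classical = float(stats.f.sf(F_obs, df1, max(df2, 1e-9)))
    return PhylManovaResult(wilks=lam_obs, F=F_obs, p_phylo=float(p_phylo),
                            p_classical=p_classical, n_sim=n_sim)
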