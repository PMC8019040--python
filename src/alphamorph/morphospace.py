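"""Multi-scale complexity profiles and (phylogenetic) PCA morphospaces.

A specimen's characteristic curve is summarized by the alpha-shape volume
fraction at six refinement coefficients equally spaced on the log scale,
spanning highly refined fits to convex hulls. Across a cohort these
six-variable profiles are ordinated by PCA on the correlation matrix; the
phylogenetic variant eigendecomposes the evolutionary correlation matrix
estimated under a Pagel-lambda model of the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alpha_engine import CharacteristicCurve
from .errors import DegenerateVariableError, DomainError, SizeError
from .phylo_comparative import _as_phylogeny, _optimize_lambda, _pagel_cov

__all__ = [
    "MultiScaleProfile",
    "MorphospaceResult",
    "default_sampled_k",
    "sample_profile",
    "pca",
    "phylo_pca",
]


def default_sampled_k() -> np.ndarray:
    """Six log-equally-spaced refinement coefficients spanning the grid."""
    return np.logspace(-1, 4, 6)  # 0.1, 1, 10, 100, 1000, 10000


@dataclass
class MultiScaleProfile:
    """Volume fractions at a handful of refinement scales."""

    specimen_id: str | None
    sampled_k: np.ndarray
    sampled_fractions: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.sampled_fractions,
            index=[f"k{v:g}" for v in self.sampled_k],
            name=self.specimen_id,
        )


@dataclass
class MorphospaceResult:
    """PCA scores, loadings and variance shares for a cohort."""

    scores: pd.DataFrame  # specimens/species x components
    loadings: pd.DataFrame  # variables x components
    variance_explained: pd.Series  # percent per component
    mode: str  # raw | species_mean | phylogenetic
    lambda_: float | None = None


def sample_profile(
    curve: CharacteristicCurve, sampled_k: np.ndarray | None = None
) -> MultiScaleProfile:
    """Fractions at the grid points nearest (in log k) to each requested k."""
    if sampled_k is None:
        sampled_k = default_sampled_k()
    sampled_k = np.asarray(sampled_k, dtype=np.float64)
    k_grid = np.asarray(curve.k_grid)
    lo, hi = k_grid[0], k_grid[-1]
    if (sampled_k < lo * (1 - 1e-12)).any() or (sampled_k > hi * (1 + 1e-12)).any():
        raise DomainError(f"sampled k outside the grid range [{lo}, {hi}]")
    idx = np.abs(np.log10(k_grid)[None, :] - np.log10(sampled_k)[:, None]).argmin(axis=1)
    return MultiScaleProfile(
        specimen_id=curve.specimen_id,
        sampled_k=k_grid[idx],
        sampled_fractions=np.asarray(curve.volume_fractions)[idx],
    )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude loading is positive."""
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return flip


def pca(profiles: pd.DataFrame, scale: bool = True) -> MorphospaceResult:
    """PCA via eigendecomposition of the correlation (or covariance) matrix.

    Variables are centered and, with ``scale=True``, standardized to unit
    variance first, matching the usual treatment of multi-scale volume
    fractions whose spread differs strongly across scales.
    """
    df = pd.DataFrame(profiles)
    if df.shape[0] < 3:
        raise SizeError("need at least 3 rows")
    if df.isna().any().any():
        raise DomainError("missing values in the profile matrix")
    X = df.to_numpy(dtype=np.float64)
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0.0)
    if scale and dead.size:
        names = [str(df.columns[i]) for i in dead]
        raise DegenerateVariableError(f"constant column(s): {names}")
    Z = X - X.mean(axis=0)
    if scale:
        Z = Z / sd
    S = Z.T @ Z / (len(Z) - 1)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order] * _fix_signs(evecs[:, order])
    comps = [f"PC{i + 1}" for i in range(len(evals))]
    return MorphospaceResult(
        scores=pd.DataFrame(Z @ evecs, index=df.index, columns=comps),
        loadings=pd.DataFrame(evecs, index=df.columns, columns=comps),
        variance_explained=pd.Series(100.0 * evals / evals.sum(), index=comps),
        mode="raw",
    )


def phylo_pca(
    species_profiles: pd.DataFrame,
    tree,
    lambda_: float | None = None,
) -> MorphospaceResult:
    """Phylogenetic PCA on the evolutionary correlation matrix.

    lambda is estimated by ML on the multivariate Pagel model (profiled
    per column and pooled by summed log-likelihood) unless given. The
    evolutionary covariance R = (X - a)' V^-1 (X - a) / (n - 1) is
    standardized to a correlation matrix, eigendecomposed, and scores are
    the standardized residuals from the phylogenetic mean projected on the
    eigenvectors. With lambda ~ 0 or on a star tree this reduces to
    ordinary correlation PCA.
    """
    df = pd.DataFrame(species_profiles)
    phy = _as_phylogeny(tree)
    labels = sorted(df.index.astype(str))
    if set(labels) - set(phy.tip_labels):
        from .errors import LabelMappingError

        raise LabelMappingError(
            f"species not in tree: {sorted(set(labels) - set(phy.tip_labels))}"
        )
    if set(labels) != set(phy.tip_labels):
        phy = phy.pruned_to(labels)
    tip_order, C = phy.covariance()
    X = df.loc[tip_order].to_numpy(dtype=np.float64)
    n, p = X.shape
    if n < 3:
        raise SizeError("need at least 3 species")

    if lambda_ is None:
        # pooled profile likelihood over columns
        from scipy.optimize import minimize_scalar

        ones = np.ones((n, 1))

        def nll(lam: float) -> float:
            from .phylo_comparative import _bm_profile_loglik

            V = _pagel_cov(C, lam)
            return -sum(_bm_profile_loglik(X[:, j], ones, V)[0] for j in range(p))

        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-6})
        cands = [(float(res.fun), float(res.x)), (nll(0.0), 0.0), (nll(1.0), 1.0)]
        lam = min(cands)[1]
    else:
        lam = float(lambda_)

    V = _pagel_cov(C, lam)
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    anc = (one @ Vinv @ X) / (one @ Vinv @ one)
    Xc = X - anc
    R = Xc.T @ Vinv @ Xc / (n - 1)
    sd = np.sqrt(np.diag(R))
    if (sd == 0).any():
        dead = [str(df.columns[i]) for i in np.flatnonzero(sd == 0)]
        raise DegenerateVariableError(f"constant column(s): {dead}")
    corr = R / np.outer(sd, sd)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order] * _fix_signs(evecs[:, order])
    comps = [f"PC{i + 1}" for i in range(len(evals))]
    Z = Xc / sd
    return MorphospaceResult(
        scores=pd.DataFrame(Z @ evecs, index=tip_order, columns=comps),
        loadings=pd.DataFrame(evecs, index=df.columns, columns=comps),
        variance_explained=pd.Series(100.0 * evals / evals.sum(), index=comps),
        mode="phylogenetic",
        lambda_=lam,
    )
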