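"""Proximity-based ordination and environmental correlation statistics.

The forest proximity matrix is a similarity; its complement D = 1 − P is
ordinated by classical principal-coordinates analysis (PCoA), with a
square-root correction when D is not Euclidean-embeddable (negative
eigenvalues). Environmental variables are related to the ordination by
least-squares vector fitting with a permutation test of R² (the vegan
``envfit`` procedure), and to each other by Spearman rank correlation with
average-linkage hierarchical ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .forest import ProximityMatrix
from .io_model import ValidationError


@dataclass
class OrdinationResult:
    """Sample scores on ordered axes with explained-variation fractions."""

    scores: pd.DataFrame  # samples × axes ("PC1", "PC2", ...)
    explained: pd.Series  # fraction of positive-eigenvalue variation per axis
    source: str = "proximity"

    def __post_init__(self) -> None:
        ex = self.explained.to_numpy()
        if len(ex) and (np.any(ex < -1e-9) or np.any(np.diff(ex) > 1e-9)):
            raise ValidationError("explained fractions must be non-increasing, >= 0")
        if ex.sum() > 1 + 1e-9:
            raise ValidationError("explained fractions sum above 1")


def _pcoa(D: np.ndarray, n_axes: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical PCoA (Gower double-centering) of a distance matrix."""
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def ordinate_from_proximity(P: ProximityMatrix, n_axes: int = 2) -> OrdinationResult:
    """PCoA of the proximity complement D = 1 − P.

    If D yields negative eigenvalues, the decomposition is repeated on
    sqrt(D) (the Lingoes-style square-root correction). Axes are ordered by
    eigenvalue; the explained fraction of an axis is its eigenvalue divided
    by the sum of positive eigenvalues. Axis signs are fixed so the sample
    with the lexicographically smallest id scores non-negatively.
    """
    D = 1.0 - P.values
    np.fill_diagonal(D, 0.0)
    eigvals, eigvecs = _pcoa(D, n_axes)
    if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
        eigvals, eigvecs = _pcoa(np.sqrt(D), n_axes)
    positive = eigvals > 1e-12 * max(abs(eigvals).max(), 1.0)
    rank = int(positive.sum())
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but rank is {rank}; truncating", stacklevel=2
        )
        n_axes = max(rank, 1)
    pos_sum = eigvals[positive].sum()
    used = eigvals[:n_axes].clip(min=0.0)
    coords = eigvecs[:, :n_axes] * np.sqrt(used)[None, :]
    explained = used / pos_sum if pos_sum > 0 else np.full(n_axes, 1.0 / n_axes)

    anchor = int(np.argmin(np.asarray(P.sample_ids, dtype=object)))
    for ax in range(n_axes):
        if coords[anchor, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    axis_names = [f"PC{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        scores=pd.DataFrame(coords, index=P.sample_ids, columns=axis_names),
        explained=pd.Series(explained, index=axis_names),
    )


@dataclass
class VectorFit:
    """Per-variable direction cosines, R² and permutation p-value."""

    table: pd.DataFrame  # columns: axis columns, r2, p_value
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def significant(self, p_cutoff: float = 0.001, r2_cutoff: float = 0.3) -> pd.DataFrame:
        """The study's display rule: p < 0.001 and R² > 0.3."""
        mask = (self.table["p_value"] < p_cutoff) & (self.table["r2"] > r2_cutoff)
        return self.table[mask]


def fit_environment_vectors(
    ordination: OrdinationResult,
    env: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
) -> VectorFit:
    """Least-squares fit of each environmental variable onto two axes.

    R² is the squared multiple correlation of the variable with the axis
    scores; its p-value is the permutation tail probability
    (#{permuted R² ≥ observed} + 1)/(n_perm + 1) under row permutation of
    the variable.
    """
    scores = ordination.scores.iloc[:, :2]
    env = env.loc[scores.index].astype(float)
    n = len(scores)
    S = scores.to_numpy() - scores.to_numpy().mean(axis=0)
    Q, _ = np.linalg.qr(S)
    rng = np.random.default_rng(seed)

    rows = {}
    for col in env.columns:
        y = env[col].to_numpy(dtype=float)
        yc = y - y.mean()
        sst = float(yc @ yc)
        if sst == 0:
            warnings.warn(f"constant environmental variable {col!r}", stacklevel=2)
            rows[col] = dict(axis1=0.0, axis2=0.0, r2=0.0, p_value=1.0)
            continue
        proj = Q.T @ yc
        r2 = float(proj @ proj) / sst
        b, *_ = np.linalg.lstsq(S, yc, rcond=None)
        norm = np.linalg.norm(b)
        direction = b / norm if norm > 0 else b
        perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)
        num = perms @ Q  # (n_perm × 2) projections onto the axis basis
        r2_perm = (num**2).sum(axis=1) / (perms**2).sum(axis=1)
        p = (np.sum(r2_perm >= r2) + 1) / (n_perm + 1)
        rows[col] = dict(axis1=direction[0], axis2=direction[1], r2=r2, p_value=float(p))
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "variable"
    return VectorFit(table, n_perm=n_perm)


@dataclass
class SpearmanCluster:
    rho: pd.DataFrame
    p_values: pd.DataFrame
    order: list[str]  # hierarchical leaf ordering
    significant: pd.DataFrame  # boolean, p < flag threshold

    def to_frame(self) -> pd.DataFrame:
        ordered = self.rho.loc[self.order, self.order].copy()
        return ordered


def spearman_correlation_cluster(
    env: pd.DataFrame, p_flag: float = 0.01
) -> SpearmanCluster:
    """Pairwise Spearman rho with average-linkage ordering on 1 − |rho|.

    Zero-variance columns yield undefined rho (NaN) and are placed at unit
    distance from everything for the clustering.
    """
    env = env.astype(float)
    if len(env) < 3:
        raise ValidationError("need at least 3 samples for rank correlation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(env.to_numpy(), axis=0)
    if env.shape[1] == 2:  # scipy collapses the 2-column case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    cols = list(env.columns)
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)

    dist = 1.0 - np.abs(np.nan_to_num(rho, nan=0.0))
    np.fill_diagonal(dist, 0.0)
    if len(cols) > 2:
        Z = linkage(squareform(dist, checks=False), method="average")
        order = [cols[i] for i in leaves_list(Z)]
    else:
        order = cols
    significant = (p_df < p_flag) & rho_df.notna()
    return SpearmanCluster(rho_df, p_df, order, significant)
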