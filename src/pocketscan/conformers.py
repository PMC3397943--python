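"""Conformational analysis of a superposed structure ensemble.

Principal component analysis of the Cartesian covariance matrix,
hierarchical clustering on pairwise RMSD with representative selection,
per-residue fluctuations, and the residue–residue cross-correlation map.

The covariance matrix C has elements

    C_ij = < (r_i - <r_i>) (r_j - <r_j>) >

where r runs over the 3N Cartesian coordinates of the superposed
ensemble and <.> is the ensemble average (divisor n; rescale by
n/(n-1) for the sample form).  Eigenvectors of C are the principal
components; eigenvalues are the variances (Å²) along them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structure import CoordinateSet, superpose

__all__ = [
    "EnsemblePCA",
    "PCAResults",
    "ClusterPartition",
    "covariance_matrix",
    "pca",
    "cluster_rmsd",
    "select_representatives",
    "rmsf",
    "dccm",
]


def covariance_matrix(cs: CoordinateSet) -> np.ndarray:
    """3N×3N Cartesian covariance matrix (Å²) of a superposed ensemble.

    Uses the population divisor n.  The input must already be in a
    common frame; this cannot be verified here and is part of the
    contract.
    """
    if cs.n_structures < 2:
        raise ValueError("need at least two structures")
    x = cs.flat()
    d = x - x.mean(axis=0)
    return d.T @ d / len(x)


class EnsemblePCA:
    """Principal component model of a superposed coordinate ensemble.

    Parameters
    ----------
    cs : CoordinateSet
        Superposed ensemble; rows of its flattened coordinate matrix
        are the observations.

    Examples
    --------
    >>> results = EnsemblePCA(cs).fit()
    >>> results.variance_fraction[0]      # fraction captured by PC1
    >>> scores = results.project(cs, n_modes=2)
    """

    def __init__(self, cs: CoordinateSet):
        if cs.n_structures < 2:
            raise ValueError("PCA needs at least two structures")
        self.cs = cs

    def fit(self) -> "PCAResults":
        c = covariance_matrix(self.cs)
        evals, evecs = np.linalg.eigh(c)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # sign convention: largest-magnitude component of each mode positive
        for m in range(evecs.shape[1]):
            i = np.argmax(np.abs(evecs[:, m]))
            if evecs[i, m] < 0:
                evecs[:, m] = -evecs[:, m]
        return PCAResults(
            mean=self.cs.flat().mean(axis=0),
            modes=evecs,
            eigenvalues=evals,
            n_atoms=self.cs.n_residues,
            labels=list(self.cs.labels),
            model=self,
        )


@dataclass
class PCAResults:
    """Fitted principal components of a coordinate ensemble.

    Attributes
    ----------
    mean : (3N,) ndarray — mean coordinates, Å
    modes : (3N, 3N) ndarray — orthonormal eigenvectors, columns
    eigenvalues : (3N,) ndarray — variances in Å², descending
    n_atoms : int
    labels : residue labels of the source ensemble
    """

    mean: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    n_atoms: int
    labels: list[str]
    model: EnsemblePCA | None = None

    @property
    def variance_fraction(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues

    def cumulative_variance(self, k: int) -> float:
        """Fraction of total variance captured by the first k components."""
        if not 1 <= k <= 3 * self.n_atoms:
            raise ValueError(f"k must be in [1, {3 * self.n_atoms}]")
        total = self.eigenvalues.sum()
        return float(self.eigenvalues[:k].sum() / total) if total > 0 else 0.0

    def project(
        self,
        cs: CoordinateSet,
        n_modes: int = 2,
        index_map: np.ndarray | None = None,
    ) -> np.ndarray:
        """Scores (Å) of conformers on the first ``n_modes`` components.

        ``cs`` must share the model's residue labels, or ``index_map``
        must give, for each model label, its position in ``cs.labels``.
        """
        if index_map is None:
            if list(cs.labels) != self.labels:
                raise ValueError(
                    "label mismatch between model and input; pass index_map"
                )
            x = cs.flat()
        else:
            x = cs.coords[:, index_map, :].reshape(cs.n_structures, -1)
        return (x - self.mean) @ self.modes[:, :n_modes]

    def summary(self) -> str:
        lines = [
            "Ensemble PCA",
            f"  atoms (Cα): {self.n_atoms}    components: {3 * self.n_atoms}",
            f"  total variance: {self.eigenvalues.sum():.3f} Å²",
            "  PC   eigenvalue(Å²)   var%    cum%",
        ]
        cum = 0.0
        for m in range(min(6, len(self.eigenvalues))):
            frac = self.variance_fraction[m]
            cum += frac
            lines.append(
                f"  {m + 1:<4d} {self.eigenvalues[m]:>12.4f} {100 * frac:>7.1f} {100 * cum:>7.1f}"
            )
        return "\n".join(lines)

    def plot_projection(self, cs: CoordinateSet, ax=None, **scatter_kw):
        """Scatter conformers on the PC1/PC2 plane, colored by state."""
        import matplotlib.pyplot as plt

        scores = self.project(cs, n_modes=2)
        if ax is None:
            _, ax = plt.subplots()
        for state in sorted(set(cs.states)):
            mask = np.array(cs.states) == state
            ax.scatter(scores[mask, 0], scores[mask, 1], label=state, **scatter_kw)
        ax.set_xlabel(f"PC1 ({100 * self.variance_fraction[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * self.variance_fraction[1]:.1f}%)")
        ax.legend()
        return ax


def pca(cs: CoordinateSet) -> PCAResults:
    """Convenience wrapper: ``EnsemblePCA(cs).fit()``."""
    return EnsemblePCA(cs).fit()


@dataclass
class ClusterPartition:
    """Group assignment of ensemble members.

    ``labels`` holds 1-based cluster indices ranked by population
    (cluster 1 is the largest); ``representatives`` maps cluster index
    to the member closest to the cluster mean (filled by
    :func:`select_representatives`).
    """

    labels: np.ndarray
    k: int
    representatives: dict[int, int] | None = None

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def cluster_rmsd(matrix: np.ndarray, k: int) -> ClusterPartition:
    """Average-linkage hierarchical clustering of a pairwise RMSD matrix.

    The dendrogram is cut into exactly ``k`` groups; groups are
    relabelled 1..k by decreasing population, ties broken by the lowest
    member index.  Deterministic.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if n == 1 or k == n:
        raw = np.arange(1, n + 1)
    else:
        z = linkage(squareform(matrix, checks=False), method="average")
        raw = fcluster(z, t=k, criterion="maxclust")
    # rank clusters by size descending, ties by earliest member
    sizes: dict[int, int] = {}
    first: dict[int, int] = {}
    for i, c in enumerate(raw):
        sizes[c] = sizes.get(c, 0) + 1
        first.setdefault(c, i)
    order = sorted(sizes, key=lambda c: (-sizes[c], first[c]))
    remap = {c: rank + 1 for rank, c in enumerate(order)}
    return ClusterPartition(labels=np.array([remap[c] for c in raw]), k=len(order))


def _cluster_mean(cs: CoordinateSet, members: np.ndarray) -> np.ndarray:
    """Mean coordinates of a cluster after mutual superposition.

    Members are fitted onto the first member, then once re-fitted onto
    the resulting mean.
    """
    coords = [cs.coords[m] for m in members]
    ref = coords[0]
    fitted = [superpose(c, ref)[0] for c in coords]
    mean = np.mean(fitted, axis=0)
    fitted = [superpose(c, mean)[0] for c in coords]
    return np.mean(fitted, axis=0)


def select_representatives(cs: CoordinateSet, part: ClusterPartition) -> dict[int, int]:
    """Pick, per cluster, the member with lowest RMSD to the cluster mean.

    Each member is superposed onto the mean before its RMSD is taken;
    ties go to the lowest structure index.  The partition's
    ``representatives`` field is filled in place and returned.
    """
    reps: dict[int, int] = {}
    for c in range(1, part.k + 1):
        members = part.members(c)
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        if len(members) == 1:
            reps[c] = int(members[0])
            continue
        mean = _cluster_mean(cs, members)
        rmsds = [superpose(cs.coords[m], mean)[1] for m in members]
        reps[c] = int(members[int(np.argmin(rmsds))])
    part.representatives = reps
    return reps


def rmsf(cs: CoordinateSet) -> pd.DataFrame:
    """Per-residue root-mean-square fluctuation and mean B-factor.

    RMSF_i = sqrt(< |r_i - <r_i>|² >) over the superposed ensemble.
    """
    d = cs.coords - cs.coords.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum(d**2, axis=2), axis=0))
    return pd.DataFrame(
        {"rmsf": fluct, "mean_bfactor": cs.bfactors.mean(axis=0)},
        index=pd.Index(cs.labels, name="residue"),
    )


def dccm(cs: CoordinateSet) -> np.ndarray:
    """Dynamical cross-correlation map of Cα displacements.

    Entry (i, j) is <Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>) in [-1, 1].
    Residues with zero fluctuation yield NaN rows/columns (undefined).
    """
    if cs.n_structures < 3:
        raise ValueError("need at least three structures")
    d = cs.coords - cs.coords.mean(axis=0)  # (n, N, 3)
    inner = np.einsum("nik,njk->ij", d, d) / cs.n_structures
    var = np.diag(inner).copy()
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = inner / denom
    c[denom == 0] = np.nan
    return c
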