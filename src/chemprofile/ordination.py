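"""Ordination of dissimilarity matrices (PCoA, NMDS) and the multivariate
dispersion test.

PCoA embeds a dissimilarity matrix in Euclidean space by eigendecomposition
of the Gower-centred matrix.  Semi-metric dissimilarities such as
Bray-Curtis produce negative eigenvalues; those axes are kept as an
"imaginary" block whose squared contributions are subtracted, which is what
the dispersion test needs to compute honest distances to group centroids.

The dispersion (homogeneity-of-variance) test compares groups by their mean
distance to the group centroid in PCoA space: an ordinary one-way F on those
distances, with significance by permuting the distances across groups.

NMDS finds a k-dimensional configuration whose inter-point distances are
monotone in the observed dissimilarities, minimising Kruskal stress-1
sqrt(sum(dhat - dtilde)^2 / sum dtilde^2); used for visualisation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .diversity import DistanceMatrix
from .permanova import gower_center

__all__ = ["OrdinationResult", "DispersionResult", "pcoa", "nmds", "dispersion_test"]

_EIG_TOL = 1e-8  # relative threshold below which eigenvalues count as zero


@dataclass
class OrdinationResult:
    """Coordinates of an ordination plus method-specific diagnostics."""

    method: str
    coordinates: np.ndarray  # (n_samples, k)
    sample_ids: tuple[str, ...]
    eigenvalues: np.ndarray | None = None  # PCoA, descending, may be negative
    imaginary_coordinates: np.ndarray | None = None  # PCoA negative axes
    stress: float | None = None  # NMDS Kruskal stress-1
    n_restarts: int | None = None
    converged: bool | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            index=list(self.sample_ids),
            columns=[f"axis{i+1}" for i in range(self.coordinates.shape[1])],
        )
        df.index.name = "sample_id"
        return df


def pcoa(D: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis keeping negative axes separately.

    Coordinates on axes with positive eigenvalue are eigenvectors scaled by
    sqrt(eigenvalue); axes with negative eigenvalue are returned as
    ``imaginary_coordinates`` scaled by sqrt(-eigenvalue).  ``k`` truncates
    the real axes only.
    """
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    G = gower_center(D)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = _EIG_TOL * max(abs(vals[0]), 1.0)
    if vals[0] <= tol:
        raise ValueError("no positive eigenvalue: invalid dissimilarity matrix")
    pos = vals > tol
    neg = vals < -tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    if k is not None:
        coords = coords[:, :k]
    return OrdinationResult(
        method="pcoa",
        coordinates=coords,
        sample_ids=D.sample_ids,
        eigenvalues=vals,
        imaginary_coordinates=imag,
    )


def kruskal_stress(D: DistanceMatrix | np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities.

    Disparities are the isotonic (monotone least-squares) regression of the
    configuration distances on the observed dissimilarities.
    """
    d_obs = (D.d if isinstance(D, DistanceMatrix) else np.asarray(D, float))[
        np.triu_indices(coordinates.shape[0], k=1)
    ]
    d_emb = pdist(coordinates)
    denom = (d_emb**2).sum()
    if denom == 0:
        return 0.0
    disparities = IsotonicRegression().fit_transform(d_obs, d_emb)
    return float(np.sqrt(((d_emb - disparities) ** 2).sum() / denom))


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric multidimensional scaling, best of random + PCoA starts.

    Runs ``n_restarts`` random-start SMACOF optimisations of the monotone
    stress plus one start from the PCoA configuration, and returns the
    configuration with the lowest Kruskal stress-1.
    """
    if k < 1 or n_restarts < 1:
        raise ValueError("k and n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    starts: list[np.ndarray | None] = [None] * n_restarts
    pco = pcoa(D)
    init = pco.coordinates[:, :k]
    if init.shape[1] < k:  # degenerate: pad with zeros
        init = np.hstack([init, np.zeros((init.shape[0], k - init.shape[1]))])
    starts.append(init)

    best = None
    for start in starts:
        coords, _, n_iter = smacof(
            D.d,
            metric=False,
            n_components=k,
            init=start,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            random_state=int(rng.integers(2**31)),
            return_n_iter=True,
            normalized_stress=True,
        )
        s1 = kruskal_stress(D, coords)
        if best is None or s1 < best[0]:
            best = (s1, coords, n_iter < max_iter)
    stress, coords, converged = best
    # centre and rotate to principal axes for a reproducible orientation
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    return OrdinationResult(
        method="nmds",
        coordinates=coords,
        sample_ids=D.sample_ids,
        stress=stress,
        n_restarts=n_restarts + 1,
        converged=bool(converged),
    )


@dataclass
class DispersionResult:
    """Group dispersions (mean distance to centroid) and the permutation test."""

    groups: list[str]
    group_means: np.ndarray
    distances: pd.Series  # per-sample distance to its group centroid
    f: float
    p: float
    n_perm: int
    seed: int | None


def _centroid_distances(pco: OrdinationResult, labels: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group centroid in full PCoA space.

    Squared distances combine the real and imaginary blocks as
    z^2 = |real|^2 - |imaginary|^2, floored at zero (the standard correction
    for semi-metric dissimilarities).
    """
    real, imag = pco.coordinates, pco.imaginary_coordinates
    z2 = np.empty(real.shape[0])
    for g in np.unique(labels):
        m = labels == g
        dr = real[m] - real[m].mean(axis=0)
        z2_g = (dr**2).sum(axis=1)
        if imag is not None and imag.shape[1]:
            di = imag[m] - imag[m].mean(axis=0)
            z2_g = z2_g - (di**2).sum(axis=1)
        z2[m] = np.maximum(z2_g, 0.0)
    return np.sqrt(z2)


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_between = ss_within = 0.0
    k = 0
    for g in np.unique(labels):
        v = values[labels == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
        k += 1
    df1, df2 = k - 1, len(values) - k
    if ss_within == 0:
        return 0.0 if ss_between == 0 else np.inf
    return (ss_between / df1) / (ss_within / df2)


def dispersion_test(
    D: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
) -> DispersionResult:
    """Permutation test for equal multivariate dispersion among groups.

    Computes each sample's distance to its group centroid in PCoA space
    (with the negative-eigenvalue correction), then a one-way F across
    groups; the null distribution permutes the computed distances across
    samples, leaving the group sizes fixed.
    """
    labels = np.asarray(list(groups))
    if labels.shape[0] != D.n:
        raise ValueError("groups must match distance matrix samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups of size 1 not allowed: {small}")
    pco = pcoa(D)
    dist = _centroid_distances(pco, labels)
    f_obs = _anova_f(dist, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += _anova_f(rng.permutation(dist), labels) >= f_obs
    p = (1.0 + count) / (1.0 + n_perm)
    means = np.array([dist[labels == g].mean() for g in uniq])
    return DispersionResult(
        groups=[str(g) for g in uniq],
        group_means=means,
        distances=pd.Series(dist, index=list(D.sample_ids), name="dist_to_centroid"),
        f=float(f_obs),
        p=float(p),
        n_perm=n_perm,
        seed=seed,
    )
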