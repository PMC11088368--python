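"""Alpha diversity (Shannon, richness), Bray-Curtis beta diversity, detectability.

Alpha diversity treats each sample's chromatogram as a "community" of
substances: richness is the number of detected substances and the Shannon
index H = -sum p_k ln p_k (natural log, nats) measures how evenly abundance
is spread over them.  Beta diversity between two samples is the Bray-Curtis
dissimilarity, sum|x-y| / sum(x+y), which ignores joint absences — two
samples are not similar merely because both lack the same substances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .peak_processing import AlignedPeakMatrix

__all__ = [
    "DistanceMatrix",
    "shannon_index",
    "richness",
    "alpha_diversity",
    "bray_curtis",
    "detectability_profile",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    sample_ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample_ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.d[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.sample_ids), columns=list(self.sample_ids))


def shannon_index(abundance_row: np.ndarray) -> float:
    """Shannon diversity H (nats) of one abundance vector.

    Proportions are taken over the positive entries; zeros carry no
    information.  Scale-invariant: H(x) == H(c*x).
    """
    x = np.asarray(abundance_row, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be >= 0")
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("Shannon index undefined for an all-zero profile")
    p = pos / pos.sum()
    return float(-(p * np.log(p)).sum())


def richness(abundance_row: np.ndarray) -> int:
    """Number of detected (strictly positive) substances."""
    x = np.asarray(abundance_row, dtype=float)
    return int((x > 0).sum())


def alpha_diversity(matrix: AlignedPeakMatrix) -> pd.DataFrame:
    """Per-sample Shannon index and richness as a tidy table."""
    rows = [
        {
            "sample_id": sid,
            "shannon": shannon_index(matrix.values[i]),
            "richness": richness(matrix.values[i]),
        }
        for i, sid in enumerate(matrix.sample_ids)
    ]
    return pd.DataFrame(rows)


def bray_curtis(matrix: AlignedPeakMatrix, *, accept_stages=("log_relative",)) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities among the matrix rows.

    By default requires the terminal log(X+1) relative-abundance stage; pass
    ``accept_stages=("relative", "log_relative")`` to allow untransformed
    relative abundances.
    """
    matrix.require_stage(*accept_stages)
    X = matrix.values
    row_sums = X.sum(axis=1)
    if (row_sums == 0).sum() >= 2:
        raise ValueError("two all-zero samples have undefined Bray-Curtis distance")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(tuple(matrix.sample_ids), d)


def detectability_profile(matrix: AlignedPeakMatrix) -> pd.DataFrame:
    """Per substance: consensus retention time and detection proportion.

    The proportion is the fraction of (non-blank) samples in which the
    substance has positive abundance; it reaches 1.0 for substances present
    in every sample.
    """
    matrix.require_stage("filtered", "relative", "log_relative")
    detected = (matrix.values > 0).sum(axis=0)
    return pd.DataFrame(
        {
            "consensus_rt": matrix.substance_rts,
            "n_detected": detected.astype(int),
            "detection_proportion": detected / matrix.n_samples,
        }
    )
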