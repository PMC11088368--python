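"""Distance-based PERMANOVA with sequential (type I) sums of squares,
balanced exclusion of paired samples, and the iterated test with a pooled
permutation P-value.

The test partitions the total sum of squared dissimilarities among samples
by the terms of a linear design (here: sex, days after laying, and their
interaction), using the Gower-centred inner-product matrix G = -1/2 C D^2 C.
For nested design matrices X_0 (intercept) c X_1 c ... c X_p, the sequential
sum of squares of term k is tr(H_k G) - tr(H_{k-1} G) with H_k the hat
matrix of X_k; the pseudo-F of each term uses the full-model residual.
Significance comes from free permutation of sample labels (equivalently,
simultaneous row/column permutation of G).

Samples from the two partners of a breeding pair are not independent, but
blocked permutation is impossible when most pairs contributed one sample.
Instead, each iteration randomly drops one partner from every complete pair
— constrained so the dropped set is sex-balanced — and re-runs the PERMANOVA
on the remaining independent samples.  Across iterations the per-term
permutation counts are pooled into a single P-value:

    P = sum_i (1 + sum_j I(F_j >= F_obs_i)) / (N_iter * (1 + N_perm)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as _all_permutations

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix, bray_curtis
from .peak_processing import AlignedPeakMatrix

__all__ = [
    "DEFAULT_TERMS",
    "PermanovaResult",
    "IteratedPermanovaResult",
    "gower_center",
    "design_matrices",
    "permanova_sequential",
    "balanced_exclusion",
    "iterated_permanova",
    "pool_permutation_pvalues",
]

DEFAULT_TERMS = ("sex", "days_after_laying", "sex:days_after_laying")


def gower_center(D: np.ndarray | DistanceMatrix) -> np.ndarray:
    """Gower-centred inner-product matrix G = -1/2 C A C, A_ij = d_ij^2.

    C = I - 11'/n is the centring projector.  G's rows sum to zero and
    tr(G) = sum_{i<j} d_ij^2 / n, the total sum of squares of the
    dissimilarity partition.
    """
    d = D.d if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    A = -0.5 * d**2
    A_row = A.mean(axis=1, keepdims=True)
    return A - A_row - A_row.T + A.mean()


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    r = np.linalg.matrix_rank(X)
    Q = Q[:, :r]
    return Q @ Q.T


def design_matrices(
    meta: pd.DataFrame, terms=DEFAULT_TERMS
) -> tuple[list[np.ndarray], list[int], list[str]]:
    """Nested design columns for the sequential decomposition.

    Sex is treatment-coded (female = reference), days after laying enters as
    a numeric covariate, and interactions are products of already-built
    columns.  Returns the per-term column blocks, their df, and names.
    """
    n = len(meta)
    built: dict[str, np.ndarray] = {}
    blocks: list[np.ndarray] = []
    dfs: list[int] = []
    X = np.ones((n, 1))
    rank = 1
    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            for t in (a, b):
                if t not in built:
                    raise ValueError(f"interaction {term!r} listed before main effect {t!r}")
            cols = built[a] * built[b]
        elif term == "sex":
            sex = meta["sex"].to_numpy()
            bad = set(sex) - {"female", "male"}
            if bad:
                raise ValueError(f"unknown sex levels {bad}")
            cols = (sex == "male").astype(float)[:, None]
        else:
            cols = meta[term].to_numpy(dtype=float)[:, None]
        built[term] = cols
        X = np.hstack([X, cols])
        new_rank = np.linalg.matrix_rank(X)
        if new_rank == rank:
            raise ValueError(f"design is rank-deficient: term {term!r} is aliased")
        blocks.append(cols)
        dfs.append(new_rank - rank)
        rank = new_rank
    return blocks, dfs, list(terms)


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table for one labelling of the samples."""

    terms: list[str]
    ss: np.ndarray
    df: np.ndarray
    r2: np.ndarray
    f: np.ndarray
    p: np.ndarray
    ss_residual: float
    df_residual: int
    ss_total: float
    n_perm: int
    seed: int | None
    exhaustive: bool = False
    #: per term, number of permuted F >= observed F (excludes the observed draw)
    exceed_counts: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "term": self.terms,
                "df": self.df,
                "SS": self.ss,
                "R2": self.r2,
                "F": self.f,
                "P": self.p,
            }
        )
        resid = pd.DataFrame(
            {
                "term": ["residual", "total"],
                "df": [self.df_residual, self.df_residual + int(self.df.sum())],
                "SS": [self.ss_residual, self.ss_total],
                "R2": [self.ss_residual / self.ss_total, 1.0],
                "F": [np.nan, np.nan],
                "P": [np.nan, np.nan],
            }
        )
        return pd.concat([rows, resid], ignore_index=True)


def _term_f_stats(G_batch: np.ndarray, hats: list[np.ndarray], dfs, df_resid: int):
    """F statistics for each term over a batch of (permuted) G matrices.

    G_batch has shape (..., n, n).  Sequential SS_k = tr(H_k G) - tr(H_{k-1} G)
    with H_0 the intercept hat (tr(H_0 G) = 0 for centred G).
    """
    traces = [np.einsum("ij,...ij->...", H, G_batch) for H in hats]
    ss_total = np.einsum("...ii->...", G_batch)
    ss_terms = np.stack(
        [traces[0]] + [traces[k] - traces[k - 1] for k in range(1, len(hats))], axis=-1
    )
    ss_resid = ss_total - traces[-1]
    dfs = np.asarray(dfs, dtype=float)
    ms_resid = ss_resid / df_resid
    f = (ss_terms / dfs) / ms_resid[..., None]
    return ss_terms, ss_resid, ss_total, f


def permanova_sequential(
    D: DistanceMatrix | np.ndarray,
    meta: pd.DataFrame,
    terms=DEFAULT_TERMS,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """Sequential-SS PERMANOVA on a distance matrix with free permutations.

    ``meta`` rows must correspond to the rows of ``D`` in order.  P-values
    are (1 + #{permuted F >= observed}) / (1 + n_perm); when the number of
    distinct sample permutations (n!) does not exceed ``n_perm``, all of
    them are enumerated instead and P is the exact fraction of relabellings
    with F >= observed (`exhaustive` is flagged in the result).
    """
    if isinstance(D, DistanceMatrix):
        if "sample_id" in meta.columns:
            meta = meta.set_index("sample_id").loc[list(D.sample_ids)].reset_index()
        dmat = D.d
    else:
        dmat = np.asarray(D, dtype=float)
    n = dmat.shape[0]
    if len(meta) != n:
        raise ValueError("metadata does not match distance matrix")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    blocks, dfs, names = design_matrices(meta, terms)
    G = gower_center(dmat)
    hats = []
    X = np.ones((n, 1))
    for b in blocks:
        X = np.hstack([X, b])
        hats.append(_hat(X))
    df_resid = n - 1 - int(sum(dfs))
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    ss, ss_resid, ss_total, f_obs = _term_f_stats(G, hats, dfs, df_resid)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exhaustive = math.factorial(n) <= n_perm
    if exhaustive:
        perms = np.array(list(_all_permutations(range(n))))
    else:
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
    G_perm = G[perms[:, :, None], perms[:, None, :]]
    _, _, _, f_perm = _term_f_stats(G_perm, hats, dfs, df_resid)
    if exhaustive:
        # identity is among the enumerated relabellings: exact P
        p = (f_perm >= f_obs - 1e-12).mean(axis=0)
        exceed = (f_perm >= f_obs - 1e-12).sum(axis=0)
        n_perm_eff = perms.shape[0]
    else:
        exceed = (f_perm >= f_obs).sum(axis=0)
        p = (1.0 + exceed) / (1.0 + n_perm)
        n_perm_eff = n_perm

    return PermanovaResult(
        terms=names,
        ss=ss,
        df=np.asarray(dfs),
        r2=ss / ss_total,
        f=f_obs,
        p=np.asarray(p, dtype=float),
        ss_residual=float(ss_resid),
        df_residual=df_resid,
        ss_total=float(ss_total),
        n_perm=int(n_perm_eff),
        seed=None if isinstance(seed, np.random.Generator) else seed,
        exhaustive=exhaustive,
        exceed_counts=np.asarray(exceed, dtype=int),
    )


# ---------------------------------------------------------------------------
# pair-balanced exclusion and the iterated test
# ---------------------------------------------------------------------------

def _complete_pairs(meta: pd.DataFrame) -> dict[str, pd.DataFrame]:
    biol = meta[~meta["is_blank"]] if "is_blank" in meta.columns else meta
    pairs = {}
    for pid, grp in biol[biol["pair_id"].notna()].groupby("pair_id"):
        if len(grp) == 2:
            pairs[str(pid)] = grp
    return pairs


def balanced_exclusion(
    meta: pd.DataFrame, seed: int | np.random.Generator | None = None
) -> list[str]:
    """Retain one partner per complete breeding pair, sex-balancing the drop.

    Among all ways of dropping exactly one member from each complete pair,
    only the patterns whose dropped set is maximally sex-balanced (equal
    females and males when the pair count is even) are admissible; one is
    drawn uniformly.  Samples without a sampled partner are always retained.
    Returns the retained sample ids in metadata order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    biol = meta[~meta["is_blank"]] if "is_blank" in meta.columns else meta
    pairs = _complete_pairs(meta)
    if not pairs:
        return list(biol["sample_id"])
    k = len(pairs)
    pair_ids = sorted(pairs)
    # enumerate drop patterns: bit b=1 drops the first-listed member
    patterns = []
    for mask in range(2**k):
        dropped_sex = []
        for b, pid in enumerate(pair_ids):
            grp = pairs[pid].sort_values("sample_id")
            dropped_sex.append(grp.iloc[(mask >> b) & 1]["sex"])
        nf = dropped_sex.count("female")
        patterns.append((abs(nf - (k - nf)), mask))
    best = min(im for im, _ in patterns)
    admissible = [mask for im, mask in patterns if im == best]
    if k % 2 == 0 and best != 0:
        raise ValueError(
            f"sex-balanced exclusion infeasible: best imbalance {best} over "
            f"{len(admissible)} patterns (same-sex pairs present?)"
        )
    mask = admissible[rng.integers(len(admissible))]
    dropped = set()
    for b, pid in enumerate(pair_ids):
        grp = pairs[pid].sort_values("sample_id")
        dropped.add(grp.iloc[(mask >> b) & 1]["sample_id"])
    return [sid for sid in biol["sample_id"] if sid not in dropped]


@dataclass
class IteratedPermanovaResult:
    """Median/IQR of the PERMANOVA table across balanced-exclusion iterations."""

    terms: list[str]
    summary: pd.DataFrame  # per term: median + IQR of SS, R2, F; pooled P
    pooled_p: np.ndarray
    n_iterations: int
    n_perm: int
    seed: int | None
    iteration_f: np.ndarray = field(repr=False, default=None)  # (n_iter, n_terms)
    iteration_ss: np.ndarray = field(repr=False, default=None)
    iteration_r2: np.ndarray = field(repr=False, default=None)


def pool_permutation_pvalues(exceed_counts: np.ndarray, n_perm: int) -> np.ndarray:
    """Pooled permutation P across iterations.

    ``exceed_counts[i, t]`` is the number of permuted F >= the observed F of
    iteration i for term t.  P_t = sum_i (1 + counts_it) / (N_iter * (1 + N_perm)),
    which reduces to the ordinary (1+c)/(1+N_perm) at a single iteration and
    is bounded in [1/(1+N_perm), 1].
    """
    counts = np.atleast_2d(np.asarray(exceed_counts, dtype=float))
    n_iter = counts.shape[0]
    return (1.0 + counts).sum(axis=0) / (n_iter * (1.0 + n_perm))


def iterated_permanova(
    matrix: AlignedPeakMatrix | DistanceMatrix,
    meta: pd.DataFrame,
    terms=DEFAULT_TERMS,
    n_iterations: int = 1000,
    n_perm: int = 9999,
    seed: int | None = None,
) -> IteratedPermanovaResult:
    """Iterated PERMANOVA over random sex-balanced exclusions of paired samples.

    Each iteration draws a balanced-exclusion subset (one partner retained
    per complete pair), restricts the Bray-Curtis matrix to it, and runs the
    sequential PERMANOVA with ``n_perm`` free permutations.  Reported per
    term: median and interquartile range of SS, R^2 and F across iterations,
    plus the pooled P-value (see `pool_permutation_pvalues`).

    A master seed spawns one independent substream per iteration, so the
    result is bit-reproducible from (seed, n_iterations, n_perm) and
    invariant to execution order.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    D = matrix if isinstance(matrix, DistanceMatrix) else bray_curtis(matrix)
    biol = meta[~meta["is_blank"]] if "is_blank" in meta.columns else meta
    biol = biol.set_index("sample_id").loc[list(D.sample_ids)].reset_index()

    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    ss = np.empty((n_iterations, len(terms)))
    r2 = np.empty_like(ss)
    f = np.empty_like(ss)
    exceed = np.empty((n_iterations, len(terms)), dtype=int)
    n_perm_eff = n_perm
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        try:
            retained = balanced_exclusion(biol, rng)
            sub_meta = biol.set_index("sample_id").loc[retained].reset_index()
            res = permanova_sequential(D.subset(retained), sub_meta, terms, n_perm, rng)
        except Exception as exc:
            raise RuntimeError(f"iteration {i} failed: {exc}") from exc
        ss[i], r2[i], f[i], exceed[i] = res.ss, res.r2, res.f, res.exceed_counts
        n_perm_eff = res.n_perm
    pooled = pool_permutation_pvalues(exceed, n_perm_eff)

    summary = pd.DataFrame({"term": list(terms)})
    for name, arr in (("SS", ss), ("R2", r2), ("F", f)):
        lo, mid, hi = np.percentile(arr, [25, 50, 75], axis=0)
        summary[f"{name}_median"] = mid
        summary[f"{name}_q1"] = lo
        summary[f"{name}_q3"] = hi
    summary["pooled_P"] = pooled
    return IteratedPermanovaResult(
        terms=list(terms),
        summary=summary,
        pooled_p=pooled,
        n_iterations=n_iterations,
        n_perm=n_perm_eff,
        seed=seed,
        iteration_f=f,
        iteration_ss=ss,
        iteration_r2=r2,
    )
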