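"""Similarity-space machinery.

Both brain and model data are compared in a common *similarity space*: each
data source is reduced to the lower triangle of its inter-scenario Pearson
correlation matrix, Fisher-z (arctanh) transformed, and vectorized.  With
S = 20 scenarios the similarity vector has S(S-1)/2 = 190 entries.

Triangle traversal order
------------------------
Vectors use the order produced by :func:`scipy.spatial.distance.squareform`
applied to the symmetric S x S matrix, i.e. the upper triangle read row by
row — identical to the lower triangle read column by column.  The same order
is used everywhere (models, brain data, group averages, exports), which is
all that correlation-based comparisons require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform

#: correlations are clipped to +/- (1 - ARCTANH_EPS) before arctanh so that
#: perfectly (anti)correlated patterns map to a large finite value.
ARCTANH_EPS = 1e-7

__all__ = [
    "SimilarityVector",
    "PartialRSAResult",
    "fisher_z",
    "n_scenarios_from_length",
    "similarity_matrix",
    "similarity_vector",
    "vector_to_matrix",
    "fuse_multimodal",
    "group_average_loo",
    "rsa_spearman",
    "rsa_permutation_test",
    "partial_rsa",
    "partial_rsa_permutation_test",
]


@dataclass
class SimilarityVector:
    """A Fisher-z inter-scenario similarity vector plus provenance tags."""

    values: np.ndarray
    n_scenarios: int
    source: str = "fmri"  # fmri | verbal | attribute | multimodal | group_average

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_scenarios * (self.n_scenarios - 1) // 2
        if self.values.shape != (expected,):
            raise ValueError(
                f"similarity vector for S={self.n_scenarios} must have "
                f"{expected} entries, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity vector contains non-finite entries")


@dataclass
class PartialRSAResult:
    rho: float
    z: float
    p_perm: float | None = None
    n_permutations: int = 0
    null: np.ndarray | None = field(default=None, repr=False)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """arctanh with clipping to avoid infinities at |r| = 1."""
    return np.arctanh(np.clip(r, -1.0 + ARCTANH_EPS, 1.0 - ARCTANH_EPS))


def n_scenarios_from_length(length: int) -> int:
    s = int(round((1 + np.sqrt(1 + 8 * length)) / 2))
    if s * (s - 1) // 2 != length:
        raise ValueError(f"{length} is not a triangular number S(S-1)/2")
    return s


def similarity_matrix(patterns: np.ndarray) -> np.ndarray:
    """S x S Pearson correlation matrix between scenario rows.

    Rows are scenarios, columns features (voxels, embedding dimensions,
    attributes).  Each row must have nonzero variance.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] < 3:
        raise ValueError("patterns must be a 2-D matrix with at least 3 scenario rows")
    sd = patterns.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance scenario rows: {bad.tolist()}")
    return np.corrcoef(patterns)


def similarity_vector(patterns: np.ndarray, source: str = "fmri") -> SimilarityVector:
    """Fisher-z similarity vector of an S x F scenario-by-feature matrix."""
    corr = similarity_matrix(patterns)
    z = fisher_z(corr)
    np.fill_diagonal(z, 0.0)
    vec = squareform(z, checks=False)
    return SimilarityVector(values=vec, n_scenarios=corr.shape[0], source=source)


def vector_to_matrix(values: np.ndarray) -> np.ndarray:
    """Re-fold a similarity (or residual) vector into its symmetric S x S matrix."""
    return squareform(np.asarray(values, dtype=float), checks=False)


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def fuse_multimodal(verbal: SimilarityVector, attribute: SimilarityVector) -> SimilarityVector:
    """Multimodal model: z-score each channel's vector and sum pointwise.

    z-scoring puts the two channels on a common scale before summation; the
    sum and the mean of the two z-scored vectors are rank-identical, so any
    rank-based comparison downstream is unaffected by that choice.
    """
    if verbal.values.shape != attribute.values.shape:
        raise ValueError("verbal and attribute similarity vectors differ in length")
    fused = _zscore(verbal.values) + _zscore(attribute.values)
    return SimilarityVector(values=fused, n_scenarios=verbal.n_scenarios, source="multimodal")


def group_average_loo(
    model_sims: list[SimilarityVector],
    exclude: int,
    space: str = "similarity",
    model_features: list[np.ndarray] | None = None,
) -> SimilarityVector:
    """Leave-one-out group-average (G-1) model for one test participant.

    ``space="similarity"`` averages the remaining participants' similarity
    vectors pointwise.  ``space="feature"`` averages their model feature
    matrices first and then computes a single similarity vector
    (``model_features`` required, aligned with ``model_sims``).
    """
    n = len(model_sims)
    if n < 2:
        raise ValueError("need at least 2 participants to build a G-1 average")
    if not 0 <= exclude < n:
        raise ValueError(f"exclude index {exclude} out of range for {n} participants")
    keep = [i for i in range(n) if i != exclude]
    if space == "similarity":
        stacked = np.stack([model_sims[i].values for i in keep])
        return SimilarityVector(
            values=stacked.mean(axis=0),
            n_scenarios=model_sims[0].n_scenarios,
            source="group_average",
        )
    if space == "feature":
        if model_features is None:
            raise ValueError("feature-space averaging requires model_features")
        avg = np.mean([np.asarray(model_features[i], dtype=float) for i in keep], axis=0)
        out = similarity_vector(avg, source="group_average")
        return out
    raise ValueError(f"unknown averaging space: {space!r}")


def rsa_spearman(a: SimilarityVector | np.ndarray, b: SimilarityVector | np.ndarray) -> float:
    """Spearman rank correlation between two similarity vectors (average ranks on ties)."""
    av = a.values if isinstance(a, SimilarityVector) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, SimilarityVector) else np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.size < 3:
        raise ValueError("inputs must be equal-length vectors with >= 3 entries")
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(av, bv).statistic)


def _triangle_indices(s: int) -> tuple[np.ndarray, np.ndarray]:
    # row-major upper triangle == squareform vectorization order
    return np.triu_indices(s, k=1)


def _permuted_triangles(matrix: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Extract the similarity triangle of ``matrix`` under each row/column shuffle.

    ``perms`` is (n_perm, S); returns (n_perm, S(S-1)/2) in squareform order.
    Simultaneous row/column permutation of M by p gives M[p][:, p], whose
    (i, j) entry is M[p[i], p[j]] — gathered directly for the triangle cells.
    """
    i_idx, j_idx = _triangle_indices(matrix.shape[0])
    return matrix[perms[:, i_idx], perms[:, j_idx]]


def _fraction_ge(null: np.ndarray, observed: float, plus_one: bool = False) -> float:
    """Permutation p: fraction of null statistics >= observed.

    The plain fraction can be 0; ``plus_one`` switches to the (b+1)/(B+1)
    estimator for users who want a guaranteed-positive p.
    """
    b = int(np.sum(null >= observed))
    if plus_one:
        return (b + 1) / (null.size + 1)
    return b / null.size


def rsa_permutation_test(
    fmri_corr_matrix: np.ndarray,
    model_sim: SimilarityVector | np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    plus_one: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Row/column-shuffle permutation test of a model-to-brain RSA.

    Scenario order is randomly shuffled; rows and columns of the brain
    similarity matrix (but not the model vector) are rearranged accordingly,
    the triangle is re-vectorized, and the Spearman coefficient recomputed.
    Returns ``(observed_rho, p, null)``.
    """
    m = np.asarray(fmri_corr_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("fmri_corr_matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("fmri_corr_matrix must be symmetric")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mv = model_sim.values if isinstance(model_sim, SimilarityVector) else np.asarray(model_sim)
    s = m.shape[0]
    m = m.copy()
    np.fill_diagonal(m, 0.0)
    observed_vec = squareform(m, checks=False)
    observed = rsa_spearman(observed_vec, mv)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.stack([rng.permutation(s) for _ in range(n_perm)])
    shuffled = _permuted_triangles(m, perms)

    model_rank = stats.rankdata(mv)
    shuffled_rank = stats.rankdata(shuffled, axis=1)
    null = _pearson_rows(shuffled_rank, model_rank)
    return observed, _fraction_ge(null, observed, plus_one), null


def _pearson_rows(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with ``y``."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (rc @ yc) / denom
    return out


def _partial_pearson(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial Pearson correlation of x and y controlling z."""
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom_sq = (1 - rxz**2) * (1 - ryz**2)
    if denom_sq <= 1e-24:
        raise ValueError("control vector is collinear with an input; partial correlation degenerate")
    return float((rxy - rxz * ryz) / np.sqrt(denom_sq))


def partial_rsa(
    fmri: SimilarityVector | np.ndarray,
    personal: SimilarityVector | np.ndarray,
    group: SimilarityVector | np.ndarray,
) -> float:
    """Spearman partial correlation: brain vs personal model, controlling G-1.

    All three vectors are ranked (average ranks on ties) and the first-order
    partial Pearson correlation is computed on the ranks.
    """
    xs = [
        v.values if isinstance(v, SimilarityVector) else np.asarray(v, dtype=float)
        for v in (fmri, personal, group)
    ]
    if not (xs[0].shape == xs[1].shape == xs[2].shape):
        raise ValueError("all three similarity vectors must have the same length")
    rx, ry, rz = (stats.rankdata(v) for v in xs)
    if np.array_equal(stats.rankdata(ry), stats.rankdata(rz)):
        raise ValueError("group-average vector is rank-identical to the personal model")
    return _partial_pearson(rx, ry, rz)


def partial_rsa_permutation_test(
    fmri: SimilarityVector | np.ndarray,
    personal: SimilarityVector | np.ndarray,
    group: SimilarityVector | np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    plus_one: bool = False,
) -> PartialRSAResult:
    """Residual-shuffle permutation test for the partial RSA coefficient.

    Shuffling the brain vector wholesale would break its relationship with
    the control (G-1) vector as well as with the personal model, so the null
    is built by permuting only the part of the brain vector not explained by
    the control (a Freedman–Lane style scheme):

    A. rank all three vectors;
    B. regress the ranked brain vector on the ranked G-1 vector (with
       intercept);
    C. fold the residuals into the S x S triangle positions, shuffle rows and
       columns together by a random scenario order, re-vectorize;
    D./E. add back the fitted G-1 component from B;
    F. partial-correlate the reconstructed vector against the ranked
       personal vector, controlling the ranked G-1 vector.

    With the identity shuffle, C–E reproduce the ranked brain vector exactly,
    so the observed coefficient is recovered.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    xs = [
        v.values if isinstance(v, SimilarityVector) else np.asarray(v, dtype=float)
        for v in (fmri, personal, group)
    ]
    if not (xs[0].shape == xs[1].shape == xs[2].shape):
        raise ValueError("all three similarity vectors must have the same length")
    s = n_scenarios_from_length(xs[0].size)

    rx, ry, rz = (stats.rankdata(v) for v in xs)
    observed = _partial_pearson(rx, ry, rz)

    design = np.column_stack([np.ones_like(rz), rz])
    beta, *_ = np.linalg.lstsq(design, rx, rcond=None)
    fitted = design @ beta
    resid = rx - fitted

    resid_matrix = vector_to_matrix(resid)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.stack([rng.permutation(s) for _ in range(n_perm)])
    shuffled = _permuted_triangles(resid_matrix, perms)
    reconstructed = shuffled + fitted  # (n_perm, L)

    # partial Pearson of each reconstructed vector with ry controlling rz:
    # correlate the residuals of both after projecting out [1, rz].
    hat = design @ np.linalg.solve(design.T @ design, design.T)
    y_res = ry - hat @ ry
    e_res = reconstructed - reconstructed @ hat.T
    null = _pearson_rows(e_res, y_res)
    null = null[np.isfinite(null)]

    p = _fraction_ge(null, observed, plus_one)
    return PartialRSAResult(
        rho=observed, z=float(fisher_z(observed)), p_perm=p, n_permutations=n_perm, null=null
    )
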