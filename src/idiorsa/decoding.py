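"""Pairwise identity decoding.

For a pair of participants, their two personal-model similarity vectors are
cross-correlated (Spearman) with both participants' brain similarity vectors,
giving four coefficients.  Each is Fisher-z transformed; the pairing is
scored correct (1) when the congruent sum z(i,i) + z(j,j) exceeds the
incongruent sum z(i,j) + z(j,i), otherwise 0.  Repeating over all unordered
pairs (325 for 26 participants) and averaging yields the decoding accuracy;
with no participant-specific model-to-brain relationship, 50% is expected.
Significance comes from re-running the full decode under random
participant-to-brain reassignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .rsa import SimilarityVector, fisher_z, rsa_spearman

__all__ = [
    "DecodingResult",
    "pair_decode",
    "decode_cohort",
    "decoding_permutation_test",
    "model_only_decode",
]


@dataclass
class DecodingResult:
    pair_outcomes: np.ndarray  # (P, P) symmetric, NaN on the diagonal
    accuracy: float  # percentage in [0, 100]
    n_pairs: int
    p_perm: float | None = None
    n_permutations: int = 0
    null_accuracies: np.ndarray | None = field(default=None, repr=False)


def _values(v: SimilarityVector | np.ndarray) -> np.ndarray:
    return v.values if isinstance(v, SimilarityVector) else np.asarray(v, dtype=float)


def pair_decode(
    model_i: SimilarityVector | np.ndarray,
    model_j: SimilarityVector | np.ndarray,
    fmri_i: SimilarityVector | np.ndarray,
    fmri_j: SimilarityVector | np.ndarray,
    tie: str = "zero",
) -> float:
    """Score one participant pair: 1 if the congruent pairing wins, else 0.

    An exact tie between congruent and incongruent sums scores 0 by default
    (conservative); ``tie="half"`` awards 0.5 credit instead.
    """
    if tie not in ("zero", "half"):
        raise ValueError("tie policy must be 'zero' or 'half'")
    z_ii = fisher_z(rsa_spearman(model_i, fmri_i))
    z_jj = fisher_z(rsa_spearman(model_j, fmri_j))
    z_ij = fisher_z(rsa_spearman(model_i, fmri_j))
    z_ji = fisher_z(rsa_spearman(model_j, fmri_i))
    congruent, incongruent = z_ii + z_jj, z_ij + z_ji
    if congruent > incongruent:
        return 1.0
    if congruent == incongruent and tie == "half":
        return 0.5
    return 0.0


def _cross_spearman_z(models: np.ndarray, fmri: np.ndarray) -> np.ndarray:
    """(P, P) Fisher-z Spearman matrix: entry (i, j) = model_i vs fmri_j."""
    rm = stats.rankdata(models, axis=1)
    rf = stats.rankdata(fmri, axis=1)
    rm = rm - rm.mean(axis=1, keepdims=True)
    rf = rf - rf.mean(axis=1, keepdims=True)
    norm_m = np.linalg.norm(rm, axis=1)
    norm_f = np.linalg.norm(rf, axis=1)
    if np.any(norm_m == 0) or np.any(norm_f == 0):
        raise ValueError("constant similarity vector; Spearman undefined")
    corr = (rm @ rf.T) / np.outer(norm_m, norm_f)
    return fisher_z(corr)


def _accuracy_from_z(zmat: np.ndarray, tie: str) -> tuple[np.ndarray, float]:
    p = zmat.shape[0]
    diag = np.diag(zmat)
    congruent = diag[:, None] + diag[None, :]
    incongruent = zmat + zmat.T
    outcomes = np.where(congruent > incongruent, 1.0, 0.0)
    if tie == "half":
        outcomes = np.where(congruent == incongruent, 0.5, outcomes)
    iu = np.triu_indices(p, k=1)
    accuracy = 100.0 * outcomes[iu].mean()
    full = outcomes.copy()
    np.fill_diagonal(full, np.nan)
    return full, float(accuracy)


def decode_cohort(
    models: list[SimilarityVector] | np.ndarray,
    fmri: list[SimilarityVector] | np.ndarray,
    tie: str = "zero",
) -> DecodingResult:
    """Pairwise decode over all unordered participant pairs.

    ``models`` and ``fmri`` are aligned per-participant similarity vectors;
    accuracy is reported as a percentage of the P(P-1)/2 pairs won.
    """
    if tie not in ("zero", "half"):
        raise ValueError("tie policy must be 'zero' or 'half'")
    m = np.stack([_values(v) for v in models])
    f = np.stack([_values(v) for v in fmri])
    if m.shape != f.shape:
        raise ValueError("model and brain similarity sets are misaligned")
    p = m.shape[0]
    if p < 2:
        raise ValueError("need at least 2 participants")
    zmat = _cross_spearman_z(m, f)
    outcomes, accuracy = _accuracy_from_z(zmat, tie)
    return DecodingResult(pair_outcomes=outcomes, accuracy=accuracy, n_pairs=p * (p - 1) // 2)


def decoding_permutation_test(
    models: list[SimilarityVector] | np.ndarray,
    fmri: list[SimilarityVector] | np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    tie: str = "zero",
) -> DecodingResult:
    """Permutation test: brain vectors are randomly reassigned to participants.

    Each of the ``n_perm`` permutations is a full random shuffle of the
    participant-to-brain mapping (fixed points allowed); the entire pairwise
    decode is re-run and p is the fraction of null accuracies >= observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    result = decode_cohort(models, fmri, tie=tie)
    m = np.stack([_values(v) for v in models])
    f = np.stack([_values(v) for v in fmri])
    zmat = _cross_spearman_z(m, f)
    p = zmat.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(p)
        _, null[k] = _accuracy_from_z(zmat[:, perm], tie)
    result.p_perm = float(np.mean(null >= result.accuracy))
    result.n_permutations = n_perm
    result.null_accuracies = null
    return result


def model_only_decode(
    verbal_sims: list[SimilarityVector] | np.ndarray,
    attribute_sims: list[SimilarityVector] | np.ndarray,
    tie: str = "zero",
) -> DecodingResult:
    """Behaviour-only decode: one channel plays 'model', the other 'data'."""
    return decode_cohort(verbal_sims, attribute_sims, tie=tie)
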