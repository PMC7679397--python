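"""Cohort-level inference and region selection.

Per-participant RSA coefficients (Fisher-z transformed) are compared to zero
with a one-tailed one-sample t-test per region; Cohen's d is t / sqrt(n).
p-values are corrected across regions (or voxels) with the Benjamini–Hochberg
false discovery rate.  The module also houses the two ROI-selection
procedures, the cross-participant model-agreement test, the cumulative
binomial summary used in figure captions, and the cube-searchlight analogue
of the region analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rsa import SimilarityVector, fisher_z, rsa_spearman, similarity_vector, partial_rsa

__all__ = [
    "GroupTestResult",
    "SearchlightMap",
    "one_sample_group_test",
    "fdr_adjust",
    "binomial_tail",
    "cross_participant_model_agreement",
    "select_rois_group_model",
    "select_rois_loo_personal",
    "searchlight_map",
]


@dataclass
class GroupTestResult:
    """One-tailed one-sample t-test of Fisher-z coefficients against zero."""

    roi_id: int | str
    t: float
    p_raw: float
    cohens_d: float
    n: int
    p_fdr: float | None = None


@dataclass
class SearchlightMap:
    """Voxel-wise group statistics from a moving-cube analysis."""

    t_map: np.ndarray  # 3-D, NaN outside analyzed centers
    p_fdr_map: np.ndarray  # 3-D, NaN outside analyzed centers
    mask: np.ndarray  # 3-D bool: voxels common to all participants
    radius_voxels: int
    centers: np.ndarray = field(default=None)  # type: ignore[assignment]  # (n, 3) analyzed centers


def one_sample_group_test(z_values: np.ndarray, roi_id: int | str = 0) -> GroupTestResult:
    """t-test (one-tailed, anticipating positive values) with d = t / sqrt(n)."""
    z = np.asarray(z_values, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 participants")
    if z.std(ddof=1) == 0:
        raise ValueError("zero variance across participants; t undefined")
    res = stats.ttest_1samp(z, 0.0, alternative="greater")
    t = float(res.statistic)
    return GroupTestResult(
        roi_id=roi_id, t=t, p_raw=float(res.pvalue), cohens_d=t / np.sqrt(z.size), n=z.size
    )


def fdr_adjust(p_values: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini–Hochberg (default) or Benjamini–Yekutieli adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if key is None:
        raise ValueError("method must be 'bh' or 'by'")
    return multipletests(p, method=key)[1]


def binomial_tail(n: int, p0: float, k: int) -> float:
    """Upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    return float(stats.binom.sf(k - 1, n, p0))


def cross_participant_model_agreement(
    model_sims: list[SimilarityVector],
) -> tuple[float, float, float, float]:
    """Spearman RSA between every unordered pair of participants' models.

    Returns (mean rho, SD of rho, t on Fisher-z values vs 0, two-tailed p).
    With 26 participants this evaluates 325 pairs.
    """
    n = len(model_sims)
    if n < 2:
        raise ValueError("need at least 2 participants")
    rhos = np.array(
        [
            rsa_spearman(model_sims[i], model_sims[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
    )
    z = fisher_z(rhos)
    res = stats.ttest_1samp(z, 0.0)
    return float(rhos.mean()), float(rhos.std(ddof=1)), float(res.statistic), float(res.pvalue)


def _roi_table(z_by_roi: dict[int, np.ndarray], q: float) -> pd.DataFrame:
    results = [one_sample_group_test(z, roi_id=roi) for roi, z in sorted(z_by_roi.items())]
    p_fdr = fdr_adjust(np.array([r.p_raw for r in results]))
    rows = []
    for r, pf in zip(results, p_fdr):
        r.p_fdr = float(pf)
        rows.append(
            {
                "roi": r.roi_id,
                "t": r.t,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "cohens_d": r.cohens_d,
                "n": r.n,
                "selected": r.p_fdr < q,
            }
        )
    return pd.DataFrame(rows).set_index("roi")


def select_rois_group_model(
    fmri_sims: dict[int, list[SimilarityVector]],
    group_sims: list[SimilarityVector],
    q: float = 0.05,
) -> tuple[list[int], pd.DataFrame]:
    """Regions whose brain data track the leave-one-out group-average model.

    For each region, RSA is run between every participant's brain similarity
    vector and *their* G-1 model; Fisher-z coefficients are tested against
    zero (one-tailed) and the region p-values are FDR-corrected.  Regions
    with adjusted p < ``q`` are returned.
    """
    n = len(group_sims)
    if n < 2:
        raise ValueError("need at least 2 participants")
    z_by_roi = {
        roi: fisher_z(np.array([rsa_spearman(sims[p], group_sims[p]) for p in range(n)]))
        for roi, sims in fmri_sims.items()
    }
    table = _roi_table(z_by_roi, q)
    return [int(r) for r in table.index[table["selected"]]], table


def select_rois_loo_personal(
    fmri_sims: dict[int, list[SimilarityVector]],
    personal_sims: list[SimilarityVector],
    target: int,
    q: float = 0.05,
) -> tuple[list[int], pd.DataFrame]:
    """Region selection for one participant using only the *other* participants.

    For each region, RSA between every held-out participant's brain data and
    their own personal model yields n-1 coefficients; regions significant
    after FDR (adjusted p < ``q``) are selected for the target, whose own data
    never enter the test.
    """
    n = len(personal_sims)
    if n < 3:
        raise ValueError("need at least 3 participants")
    if not 0 <= target < n:
        raise ValueError(f"target {target} out of range")
    others = [p for p in range(n) if p != target]
    z_by_roi = {
        roi: fisher_z(np.array([rsa_spearman(sims[p], personal_sims[p]) for p in others]))
        for roi, sims in fmri_sims.items()
    }
    table = _roi_table(z_by_roi, q)
    return [int(r) for r in table.index[table["selected"]]], table


def _cube_neighbors(
    center: tuple[int, int, int], radius: int, index_grid: np.ndarray
) -> np.ndarray:
    """Flat indices of in-mask voxels within a Chebyshev ``radius`` of center."""
    x, y, z = center
    sl = tuple(
        slice(max(c - radius, 0), min(c + radius + 1, n))
        for c, n in zip((x, y, z), index_grid.shape)
    )
    block = index_grid[sl]
    return block[block >= 0]


def searchlight_map(
    patterns: list[np.ndarray],
    mask: np.ndarray,
    model_sims: list[SimilarityVector],
    radius: int = 3,
    mode: str = "rsa_personal",
    group_sims: list[SimilarityVector] | None = None,
    min_voxels: int = 10,
    q: float = 0.05,
    restrict_centers: np.ndarray | None = None,
) -> SearchlightMap:
    """Moving-cube analogue of the region analysis.

    ``patterns`` holds one S x V scenario-pattern matrix per participant over
    the in-mask voxels (columns ordered by ``np.flatnonzero(mask)``); the mask
    marks voxels common to all participants.  A cube of side 2*radius + 1 is
    centered on every in-mask voxel; cubes intersected with the mask form the
    searchlight region (skipped below ``min_voxels``).  Per participant, the
    similarity vector of the cube patterns is compared to the requested model
    (``rsa_personal``: own model; ``rsa_group``: G-1 model; ``partial``:
    partial RSA of the personal model controlling G-1).  Fisher-z values go to
    the cube center, a one-tailed group t-test runs per center, and p-values
    are FDR-corrected across centers (each map separately).

    ``restrict_centers`` (boolean 3-D array) limits analysis to a subset of
    centers — used to restrict the partial map to centers already significant
    under the group-model map.
    """
    if mode not in ("rsa_personal", "rsa_group", "partial"):
        raise ValueError(f"unknown searchlight mode {mode!r}")
    if mode in ("rsa_group", "partial") and group_sims is None:
        raise ValueError(f"mode {mode!r} requires group_sims")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_participants = len(patterns)
    index_grid = np.full(mask.shape, -1, dtype=int)
    index_grid[mask] = np.arange(int(mask.sum()))

    t_map = np.full(mask.shape, np.nan)
    p_raw: list[float] = []
    centers: list[tuple[int, int, int]] = []
    for center in zip(*np.nonzero(mask)):
        if restrict_centers is not None and not restrict_centers[center]:
            continue
        cols = _cube_neighbors(center, radius, index_grid)
        if cols.size < min_voxels:
            continue
        z = np.empty(n_participants)
        degenerate = False
        for p in range(n_participants):
            sub = patterns[p][:, cols]
            try:
                brain = similarity_vector(sub)
                if mode == "rsa_personal":
                    coeff = rsa_spearman(brain, model_sims[p])
                elif mode == "rsa_group":
                    coeff = rsa_spearman(brain, group_sims[p])  # type: ignore[index]
                else:
                    coeff = partial_rsa(brain, model_sims[p], group_sims[p])  # type: ignore[index]
            except ValueError:
                degenerate = True
                break
            z[p] = fisher_z(coeff)
        if degenerate:
            warnings.warn(
                f"degenerate patterns at center {center}; skipped", RuntimeWarning, stacklevel=2
            )
            continue
        res = one_sample_group_test(z, roi_id=str(center))
        t_map[center] = res.t
        p_raw.append(res.p_raw)
        centers.append(center)

    p_fdr_map = np.full(mask.shape, np.nan)
    if centers:
        adjusted = fdr_adjust(np.array(p_raw))
        for c, pa in zip(centers, adjusted):
            p_fdr_map[c] = pa
    return SearchlightMap(
        t_map=t_map,
        p_fdr_map=p_fdr_map,
        mask=mask,
        radius_voxels=radius,
        centers=np.array(centers, dtype=int).reshape(-1, 3),
    )
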