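"""From preprocessed run time-series to scenario pattern matrices.

The stages mirror the analysis chain applied to each participant:

1. z-score every voxel series and every nuisance series within each run,
   regress the six head-motion parameters and a linear trend out of every
   voxel, and keep the residuals;
2. represent each scenario presentation by averaging the residual volumes in
   a fixed post-onset window (with TR = 2.5 s, the window (5 s, 15 s] covers
   exactly four volumes at onset offsets +2 … +5);
3. score voxel reliability as the mean Fisher-z inter-run correlation of its
   response profile across scenarios, and keep the top-k most stable voxels
   per region;
4. average the per-run replicates of each scenario and z-score each retained
   voxel across scenarios, yielding one S x V pattern matrix per region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "RunSeries",
    "ScenarioPatternSet",
    "zscore",
    "regress_nuisance",
    "window_offsets",
    "average_scenario_window",
    "voxel_stability",
    "select_stable_voxels",
    "build_scenario_patterns",
]


@dataclass
class RunSeries:
    """One run: time x voxel data, scenario onsets, and motion parameters."""

    data: np.ndarray  # (T, V)
    onsets: list[tuple[int, int]]  # (volume index, scenario id), strictly increasing
    motion: np.ndarray  # (T, 6)
    tr_seconds: float = 2.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion.shape != (self.data.shape[0], 6):
            raise ValueError(
                f"motion table shape {self.motion.shape} does not align with "
                f"{self.data.shape[0]} volumes"
            )
        vols = [v for v, _ in self.onsets]
        if any(b <= a for a, b in zip(vols, vols[1:])):
            raise ValueError("onset volume indices must be strictly increasing")


@dataclass
class ScenarioPatternSet:
    """Replicate-averaged, voxel-normalized S x V patterns for one region."""

    patterns: np.ndarray
    roi_id: int
    voxel_index: np.ndarray
    replicate_counts: np.ndarray
    scenario_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.scenario_ids is None:
            self.scenario_ids = np.arange(self.patterns.shape[0])


def zscore(x: np.ndarray, axis: int = 0, ddof: int = 0) -> np.ndarray:
    """z-score along ``axis`` (population SD by default); constant series -> 0."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x - mean) / sd
    return np.where(sd == 0, 0.0, out)


def regress_nuisance(run: RunSeries) -> np.ndarray:
    """Residuals of each voxel after regressing out motion and linear trend.

    Every voxel series and every nuisance series is z-scored within the run,
    then each voxel is OLS-regressed on the six z-scored motion parameters
    plus a z-scored linear trend (with intercept); residuals are returned.
    """
    t = run.data.shape[0]
    if t < 8:
        raise ValueError("need at least 8 time points (6 motion + trend + intercept)")
    y = zscore(run.data, axis=0)
    trend = zscore(np.arange(t, dtype=float))
    design = np.column_stack([np.ones(t), zscore(run.motion, axis=0), trend])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient nuisance design (duplicated or constant columns)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def window_offsets(tr_seconds: float, window: tuple[float, float] = (5.0, 15.0)) -> np.ndarray:
    """Volume offsets from onset covered by a post-onset window in seconds.

    Volumes are indexed 0-based from run start; the volume at offset ``m``
    covers [m*TR, (m+1)*TR) relative to onset.  A volume is included when its
    acquisition interval lies inside [start, end).  With TR = 2.5 and window
    (5, 15) this yields offsets +2, +3, +4, +5 — four volumes.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    # include offset m iff [m*TR, (m+1)*TR) lies inside [start, end)
    first = int(np.ceil(start / tr_seconds - 1e-9))
    last = int(np.floor(end / tr_seconds + 1e-9)) - 1
    offsets = np.arange(first, last + 1)
    if offsets.size == 0:
        raise ValueError(f"window {window} spans no whole volume at TR={tr_seconds}")
    return offsets


def average_scenario_window(
    residuals: np.ndarray,
    onsets: list[tuple[int, int]],
    tr_seconds: float,
    window: tuple[float, float] = (5.0, 15.0),
) -> list[tuple[int, np.ndarray]]:
    """One voxel vector per presentation: mean of the residual volumes in-window.

    Returns ``(scenario id, vector)`` per presentation.  A window running past
    the end of the run is truncated with a warning.
    """
    offsets = window_offsets(tr_seconds, window)
    t = residuals.shape[0]
    out: list[tuple[int, np.ndarray]] = []
    for onset, scenario in onsets:
        vols = onset + offsets
        if vols[-1] >= t:
            vols = vols[vols < t]
            warnings.warn(
                f"averaging window for onset {onset} truncated to {vols.size} volumes",
                RuntimeWarning,
                stacklevel=2,
            )
            if vols.size == 0:
                continue
        out.append((scenario, residuals[vols].mean(axis=0)))
    return out


def voxel_stability(per_run_patterns: np.ndarray, undefined: str = "zero") -> np.ndarray:
    """Mean Fisher-z inter-run correlation of each voxel's scenario profile.

    ``per_run_patterns`` is (R, S, V).  For every voxel and every pair of
    runs, the Pearson correlation across the S scenarios is computed and
    arctanh-transformed (clipped); the stability score is the mean over the
    C(R, 2) pairs (10 pairs for R = 5).  Pairs with a zero-variance profile
    have an undefined correlation and either contribute 0 (``"zero"``) or are
    dropped from the mean (``"drop"``).
    """
    x = np.asarray(per_run_patterns, dtype=float)
    if x.ndim != 3:
        raise ValueError("per_run_patterns must be (runs, scenarios, voxels)")
    r, s, v = x.shape
    if r < 2 or s < 3:
        raise ValueError("need at least 2 runs and 3 scenarios")
    if undefined not in ("zero", "drop"):
        raise ValueError("undefined policy must be 'zero' or 'drop'")

    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))  # (R, V)
    pair_z = np.empty((r * (r - 1) // 2, v))
    defined = np.empty_like(pair_z, dtype=bool)
    for k, (a, b) in enumerate(combinations(range(r), 2)):
        denom = norms[a] * norms[b]
        ok = denom > 0
        corr = np.zeros(v)
        corr[ok] = (centered[a, :, ok].T * centered[b, :, ok].T).sum(axis=0) / denom[ok]
        clip = 1.0 - 1e-7
        pair_z[k] = np.where(ok, np.arctanh(np.clip(corr, -clip, clip)), 0.0)
        defined[k] = ok
    if undefined == "zero":
        return pair_z.mean(axis=0)
    counts = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, pair_z.sum(axis=0) / np.maximum(counts, 1), 0.0)
    return out


def select_stable_voxels(
    stability: np.ndarray, roi_labels: np.ndarray, k: int
) -> dict[int, np.ndarray]:
    """Indices of the k most stable voxels within each region.

    Regions smaller than ``k`` return all their voxels.  Ties are broken by
    ascending voxel index (stable sort), making selection deterministic.
    Empty regions are skipped with a warning.  Region label 0 is treated as
    background and ignored.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    stability = np.asarray(stability, dtype=float)
    roi_labels = np.asarray(roi_labels)
    out: dict[int, np.ndarray] = {}
    for roi in np.unique(roi_labels):
        if roi == 0:
            continue
        idx = np.flatnonzero(roi_labels == roi)
        if idx.size == 0:
            warnings.warn(f"empty ROI {roi} skipped", RuntimeWarning, stacklevel=2)
            continue
        order = np.argsort(-stability[idx], kind="stable")
        out[int(roi)] = np.sort(idx[order[: min(k, idx.size)]])
    return out


def build_scenario_patterns(
    presentations: list[tuple[int, np.ndarray]],
    voxel_index: np.ndarray,
    roi_id: int = 0,
    scenario_ids: np.ndarray | None = None,
) -> ScenarioPatternSet:
    """Average replicates per scenario, then z-score each voxel across scenarios.

    ``presentations`` holds (scenario id, full-width voxel vector) for every
    kept presentation; ``voxel_index`` restricts to the selected voxels.
    Voxels with zero variance across scenarios are zeroed with a warning.
    """
    if not presentations:
        raise ValueError("no presentations supplied")
    voxel_index = np.asarray(voxel_index)
    if scenario_ids is None:
        scenario_ids = np.unique([s for s, _ in presentations])
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for scenario, vec in presentations:
        sub = np.asarray(vec, dtype=float)[voxel_index]
        sums[scenario] = sums.get(scenario, 0) + sub
        counts[scenario] = counts.get(scenario, 0) + 1
    missing = [s for s in scenario_ids if s not in counts]
    if missing:
        raise ValueError(f"scenarios with no presentation: {missing}")
    raw = np.stack([sums[s] / counts[s] for s in scenario_ids])
    sd = raw.std(axis=0)
    if np.any(sd == 0):
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance voxels zeroed in ROI {roi_id}",
            RuntimeWarning,
            stacklevel=2,
        )
    patterns = zscore(raw, axis=0)
    return ScenarioPatternSet(
        patterns=patterns,
        roi_id=roi_id,
        voxel_index=voxel_index,
        replicate_counts=np.array([counts[s] for s in scenario_ids]),
        scenario_ids=np.asarray(scenario_ids),
    )
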