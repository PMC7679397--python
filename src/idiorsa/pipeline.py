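"""End-to-end orchestration.

``run_synthetic_demo`` generates a cohort and runs the full chain —
personal models -> pattern preparation -> RSA -> partial RSA -> region
selection -> identity decoding (searchlight optional) — writing tables and a
run manifest.  ``run_real`` executes the same chain on disk-supplied inputs
laid out as by :func:`idiorsa.io.write_cohort`.

All stage functions are importable and operate on in-memory objects, so tests
and scripts can run any slice of the chain without touching disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .decoding import decode_cohort, decoding_permutation_test, model_only_decode
from .group import searchlight_map, select_rois_group_model, select_rois_loo_personal
from .models import (
    AttributeMatrix,
    build_verbal_matrix,
    normalize_attribute_ratings,
    ratings_from_frame,
)
from .prep import (
    average_scenario_window,
    build_scenario_patterns,
    regress_nuisance,
    select_stable_voxels,
    voxel_stability,
)
from .rsa import (
    SimilarityVector,
    fisher_z,
    group_average_loo,
    fuse_multimodal,
    partial_rsa_permutation_test,
    rsa_permutation_test,
    rsa_spearman,
    similarity_vector,
    vector_to_matrix,
)
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger("idiorsa")

STAGES = ("models", "prep", "rsa", "partial", "select", "decode", "searchlight")


@dataclass
class PipelineConfig:
    """Run configuration: exactly one of ``synthetic`` / ``data_dir`` is set."""

    synthetic: CohortConfig | None = None
    data_dir: str | None = None
    tr_seconds: float = 2.5  # real-data mode; synthetic runs carry their own TR
    voxel_k: int = 100
    n_perm_rsa: int = 1000
    n_perm_decode: int = 10000
    fdr_q: float = 0.05
    seed: int = 0
    window_seconds: tuple[float, float] = (5.0, 15.0)
    searchlight_radius: int = 3
    searchlight_min_voxels: int = 10
    run_searchlight: bool = False
    group_average_space: str = "similarity"  # or "feature"
    tie_policy: str = "zero"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.data_dir is None):
            raise ValueError("configure exactly one of a synthetic block or a data_dir")
        for name in ("voxel_k", "n_perm_rsa", "n_perm_decode"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        synth = raw.pop("synthetic", None)
        if synth is not None:
            if "grid_shape" in synth:
                synth["grid_shape"] = tuple(synth["grid_shape"])
            if "signal_rois" in synth:
                synth["signal_rois"] = tuple(synth["signal_rois"])
            synth = CohortConfig(**synth)
        if "window_seconds" in raw:
            raw["window_seconds"] = tuple(raw["window_seconds"])
        return cls(synthetic=synth, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out = asdict(self)
        return out

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class CohortData:
    """The pipeline's view of a cohort, independent of where it came from."""

    runs: list  # [participant][run] of RunSeries
    roi_labels: np.ndarray
    ratings: list[AttributeMatrix]
    descriptions: list[list[str]]
    lexicon: dict[str, np.ndarray]
    scenario_names: list[str]
    grid_shape: tuple[int, int, int] | None = None

    @property
    def n_participants(self) -> int:
        return len(self.runs)


def cohort_data_from_synthetic(cohort: SyntheticCohort) -> CohortData:
    return CohortData(
        runs=cohort.runs,
        roi_labels=cohort.roi_labels,
        ratings=[ratings_from_frame(df) for df in cohort.attribute_ratings],
        descriptions=cohort.descriptions,
        lexicon=cohort.vocab.as_dict(),
        scenario_names=cohort.scenario_names,
        grid_shape=cohort.config.grid_shape,
    )


def cohort_data_from_dir(data_dir: str | Path, tr_seconds: float = 2.5) -> CohortData:
    """Load an on-disk cohort (layout of :func:`idiorsa.io.write_cohort`)."""
    from .prep import RunSeries

    data_dir = Path(data_dir)
    atlas_path = data_dir / "atlas.nii.gz"
    if not atlas_path.exists():
        raise FileNotFoundError(f"atlas volume missing: {atlas_path}")
    roi_labels = io.read_atlas(atlas_path)
    lexicon = io.read_lexicon(data_dir / "vocab.txt")
    scenario_names = json.loads((data_dir / "scenarios.json").read_text())
    pdirs = sorted(d for d in data_dir.iterdir() if d.is_dir() and d.name.startswith("P"))
    if not pdirs:
        raise FileNotFoundError(f"no participant directories under {data_dir}")
    runs, ratings, descriptions = [], [], []
    for pdir in pdirs:
        run_files = sorted(pdir.glob("run*.nii.gz"))
        participant_runs = []
        for rf in run_files:
            stem = rf.name.removesuffix(".nii.gz")
            motion_path = pdir / f"{stem}_motion.txt"
            if not motion_path.exists():
                raise FileNotFoundError(f"motion file missing for run {rf}")
            data = io.read_run_nifti(rf)
            if data.shape[1] != roi_labels.size:
                raise ValueError(
                    f"{rf}: {data.shape[1]} voxels but atlas has {roi_labels.size}"
                )
            participant_runs.append(
                RunSeries(
                    data=data,
                    onsets=io.read_onsets(pdir / f"{stem}_onsets.tsv"),
                    motion=io.read_motion(motion_path),
                    tr_seconds=tr_seconds,
                )
            )
        runs.append(participant_runs)
        ratings.append(io.read_ratings(pdir / "ratings.tsv"))
        descriptions.append(io.read_descriptions(pdir / "descriptions.txt"))
    return CohortData(
        runs=runs,
        roi_labels=roi_labels,
        ratings=ratings,
        descriptions=descriptions,
        lexicon=lexicon,
        scenario_names=scenario_names,
    )


@dataclass
class ModelSet:
    """Per-participant personal models and derived similarity vectors."""

    verbal_sims: list[SimilarityVector]
    attribute_sims: list[SimilarityVector]
    multimodal_sims: list[SimilarityVector]
    group_sims: list[SimilarityVector]  # G-1 per test participant


def build_personal_models(data: CohortData, space: str = "similarity") -> ModelSet:
    """Verbal + attribute models per participant, fused, with G-1 controls."""
    verbal_sims, attribute_sims, multimodal_sims = [], [], []
    fused_features = []
    for p in range(data.n_participants):
        verbal = build_verbal_matrix(
            data.descriptions[p], data.lexicon, scenario_names=data.scenario_names
        )
        attrs = normalize_attribute_ratings(data.ratings[p])
        v_sim = similarity_vector(verbal.values, source="verbal")
        a_sim = similarity_vector(attrs.values, source="attribute")
        verbal_sims.append(v_sim)
        attribute_sims.append(a_sim)
        multimodal_sims.append(fuse_multimodal(v_sim, a_sim))
        fused_features.append(np.hstack([verbal.values, attrs.values]))
    group_sims = [
        group_average_loo(
            multimodal_sims, exclude=p, space=space, model_features=fused_features
        )
        for p in range(data.n_participants)
    ]
    return ModelSet(
        verbal_sims=verbal_sims,
        attribute_sims=attribute_sims,
        multimodal_sims=multimodal_sims,
        group_sims=group_sims,
    )


@dataclass
class PatternSet:
    """Brain similarity vectors per region, plus whole-grid patterns."""

    fmri_sims: dict[int, list[SimilarityVector]]  # roi -> per participant
    full_patterns: list[np.ndarray]  # per participant, S x V (all voxels, normalized)
    stability: list[np.ndarray]  # per participant, V stability scores


def prepare_patterns(
    data: CohortData,
    voxel_k: int = 100,
    window_seconds: tuple[float, float] = (5.0, 15.0),
) -> PatternSet:
    """Nuisance regression, window averaging, stability selection, patterns."""
    n_scenarios = len(data.scenario_names)
    scenario_ids = np.arange(n_scenarios)
    fmri_sims: dict[int, list[SimilarityVector]] = {}
    full_patterns: list[np.ndarray] = []
    stabilities: list[np.ndarray] = []
    for p, participant_runs in enumerate(data.runs):
        presentations: list[tuple[int, np.ndarray]] = []
        per_run = []
        for run in participant_runs:
            residuals = regress_nuisance(run)
            vecs = average_scenario_window(
                residuals, run.onsets, run.tr_seconds, window_seconds
            )
            presentations.extend(vecs)
            if len(vecs) == n_scenarios:  # complete run -> usable for stability
                order = np.argsort([s for s, _ in vecs])
                per_run.append(np.stack([vecs[i][1] for i in order]))
        stability = voxel_stability(np.stack(per_run))
        stabilities.append(stability)
        selected = select_stable_voxels(stability, data.roi_labels, voxel_k)
        for roi, idx in selected.items():
            pattern = build_scenario_patterns(
                presentations, idx, roi_id=roi, scenario_ids=scenario_ids
            )
            fmri_sims.setdefault(roi, []).append(
                similarity_vector(pattern.patterns, source="fmri")
            )
        full = build_scenario_patterns(
            presentations,
            np.arange(data.roi_labels.size),
            roi_id=0,
            scenario_ids=scenario_ids,
        )
        full_patterns.append(full.patterns)
        logger.info("participant %d: patterns built (%d ROIs)", p, len(selected))
    return PatternSet(fmri_sims=fmri_sims, full_patterns=full_patterns, stability=stabilities)


def rsa_stage(
    patterns: PatternSet,
    model_set: ModelSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per participant x region: RSA against the personal and the G-1 model."""
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for roi, sims in sorted(patterns.fmri_sims.items()):
        for p, brain in enumerate(sims):
            zmat = vector_to_matrix(brain.values)
            rho_personal, p_personal, _ = rsa_permutation_test(
                zmat, model_set.multimodal_sims[p], n_perm=n_perm, seed=rng
            )
            rho_group = rsa_spearman(brain, model_set.group_sims[p])
            rows.append(
                {
                    "roi": roi,
                    "participant": p,
                    "rho_personal": rho_personal,
                    "z_personal": float(fisher_z(rho_personal)),
                    "p_perm_personal": p_personal,
                    "rho_group": rho_group,
                    "z_group": float(fisher_z(rho_group)),
                }
            )
    return pd.DataFrame(rows)


def partial_stage(
    patterns: PatternSet,
    model_set: ModelSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Partial RSA (personal model controlling G-1) with permutation p-values."""
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for roi, sims in sorted(patterns.fmri_sims.items()):
        for p, brain in enumerate(sims):
            res = partial_rsa_permutation_test(
                brain, model_set.multimodal_sims[p], model_set.group_sims[p],
                n_perm=n_perm, seed=rng,
            )
            rows.append(
                {
                    "roi": roi,
                    "participant": p,
                    "rho_partial": res.rho,
                    "z_partial": res.z,
                    "p_perm": res.p_perm,
                }
            )
    return pd.DataFrame(rows)


def selection_stage(
    patterns: PatternSet, model_set: ModelSet, q: float = 0.05
) -> dict:
    """Both region-selection procedures on held-out data."""
    selected, table = select_rois_group_model(patterns.fmri_sims, model_set.group_sims, q=q)
    loo = {}
    for target in range(len(model_set.multimodal_sims)):
        loo_sel, _ = select_rois_loo_personal(
            patterns.fmri_sims, model_set.multimodal_sims, target, q=q
        )
        loo[target] = loo_sel
    return {"selected": selected, "table": table, "loo_selected": loo}


def decoding_stage(
    patterns: PatternSet,
    model_set: ModelSet,
    rois: list[int] | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    tie: str = "zero",
) -> dict:
    """Pairwise identity decoding per region plus the behaviour-only decode."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if rois is None:
        rois = sorted(patterns.fmri_sims)
    per_roi = {}
    for roi in rois:
        per_roi[roi] = decoding_permutation_test(
            model_set.multimodal_sims, patterns.fmri_sims[roi],
            n_perm=n_perm, seed=rng, tie=tie,
        )
    behaviour_only = model_only_decode(
        model_set.verbal_sims, model_set.attribute_sims, tie=tie
    )
    return {"per_roi": per_roi, "model_only": behaviour_only}


def searchlight_stage(
    patterns: PatternSet,
    model_set: ModelSet,
    grid_shape: tuple[int, int, int],
    radius: int = 3,
    min_voxels: int = 10,
    q: float = 0.05,
) -> dict:
    """Group-model and personal searchlight maps, plus the restricted partial map."""
    mask = np.ones(grid_shape, dtype=bool)
    reshaped = patterns.full_patterns
    group_map = searchlight_map(
        reshaped, mask, model_set.multimodal_sims, radius=radius,
        mode="rsa_group", group_sims=model_set.group_sims, min_voxels=min_voxels, q=q,
    )
    personal_map = searchlight_map(
        reshaped, mask, model_set.multimodal_sims, radius=radius,
        mode="rsa_personal", min_voxels=min_voxels, q=q,
    )
    significant = np.nan_to_num(group_map.p_fdr_map, nan=1.0) < q
    partial_map = None
    if significant.any():
        partial_map = searchlight_map(
            reshaped, mask, model_set.multimodal_sims, radius=radius,
            mode="partial", group_sims=model_set.group_sims,
            min_voxels=min_voxels, q=q, restrict_centers=significant,
        )
    return {"group": group_map, "personal": personal_map, "partial": partial_map}


def _write_table(frame: pd.DataFrame, path: Path, config_hash: str) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    data: CohortData,
    outdir: str | Path | None = None,
    until: str = "decode",
) -> dict:
    """Run the stage chain over prepared cohort data up to stage ``until``."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {STAGES}")
    limit = STAGES.index(until)
    bundle: dict = {"config": config, "data": data}
    log: list[str] = []

    model_set = build_personal_models(data, space=config.group_average_space)
    bundle["models"] = model_set
    log.append("models: built")
    if limit >= STAGES.index("prep"):
        patterns = prepare_patterns(data, config.voxel_k, config.window_seconds)
        bundle["patterns"] = patterns
        log.append(f"prep: {len(patterns.fmri_sims)} ROIs")
    if limit >= STAGES.index("rsa"):
        bundle["rsa"] = rsa_stage(
            bundle["patterns"], model_set, config.n_perm_rsa, config.seed
        )
        log.append("rsa: done")
    if limit >= STAGES.index("partial"):
        bundle["partial"] = partial_stage(
            bundle["patterns"], model_set, config.n_perm_rsa, config.seed + 1
        )
        log.append("partial: done")
    if limit >= STAGES.index("select"):
        bundle["selection"] = selection_stage(bundle["patterns"], model_set, config.fdr_q)
        log.append(f"select: {bundle['selection']['selected']}")
    if limit >= STAGES.index("decode"):
        rois = bundle["selection"]["selected"] or sorted(bundle["patterns"].fmri_sims)
        bundle["decoding"] = decoding_stage(
            bundle["patterns"], model_set, rois,
            config.n_perm_decode, config.seed + 2, config.tie_policy,
        )
        log.append("decode: done")
    if config.run_searchlight and limit >= STAGES.index("searchlight"):
        if data.grid_shape is None:
            raise ValueError("searchlight requires a known voxel grid shape")
        bundle["searchlight"] = searchlight_stage(
            bundle["patterns"], model_set, data.grid_shape,
            config.searchlight_radius, config.searchlight_min_voxels, config.fdr_q,
        )
        log.append("searchlight: done")
    bundle["log"] = log

    if outdir is not None:
        _write_bundle(bundle, Path(outdir), config)
    return bundle


def _write_bundle(bundle: dict, outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    written: list[Path] = []

    model_set: ModelSet = bundle["models"]
    sims = pd.DataFrame(
        {f"P{p:02d}": model_set.multimodal_sims[p].values
         for p in range(len(model_set.multimodal_sims))}
    )
    path = outdir / "multimodal_similarity.tsv"
    _write_table(sims, path, h)
    written.append(path)

    if "rsa" in bundle:
        path = outdir / "rsa.tsv"
        _write_table(bundle["rsa"], path, h)
        written.append(path)
    if "partial" in bundle:
        path = outdir / "partial_rsa.tsv"
        _write_table(bundle["partial"], path, h)
        written.append(path)
    if "selection" in bundle:
        path = outdir / "roi_selection.tsv"
        _write_table(bundle["selection"]["table"], path, h)
        written.append(path)
    if "decoding" in bundle:
        rows = [
            {
                "roi": roi,
                "accuracy_percent": res.accuracy,
                "n_pairs": res.n_pairs,
                "p_perm": res.p_perm,
                "n_permutations": res.n_permutations,
            }
            for roi, res in bundle["decoding"]["per_roi"].items()
        ]
        mo = bundle["decoding"]["model_only"]
        rows.append(
            {
                "roi": "model_only",
                "accuracy_percent": mo.accuracy,
                "n_pairs": mo.n_pairs,
                "p_perm": mo.p_perm,
                "n_permutations": mo.n_permutations,
            }
        )
        path = outdir / "decoding.tsv"
        _write_table(pd.DataFrame(rows).set_index("roi"), path, h)
        written.append(path)
        for roi, res in bundle["decoding"]["per_roi"].items():
            path = outdir / f"decoding_pairs_roi{roi}.tsv"
            io.write_pair_outcomes_tsv(res, path)
            written.append(path)
        path = outdir / "decoding.json"
        path.write_text(
            json.dumps(
                {
                    "config_hash": h,
                    "per_roi": {
                        str(roi): {
                            "accuracy_percent": res.accuracy,
                            "n_pairs": res.n_pairs,
                            "p_perm": res.p_perm,
                        }
                        for roi, res in bundle["decoding"]["per_roi"].items()
                    },
                    "model_only": {
                        "accuracy_percent": mo.accuracy,
                        "n_pairs": mo.n_pairs,
                    },
                },
                indent=2,
            )
        )
        written.append(path)
    if bundle.get("searchlight"):
        grid = bundle["data"].grid_shape
        for name, slmap in bundle["searchlight"].items():
            if slmap is None:
                continue
            for kind, arr in (("t", slmap.t_map), ("p_fdr", slmap.p_fdr_map)):
                path = outdir / f"searchlight_{name}_{kind}.nii.gz"
                io.write_searchlight_nifti(arr.reshape(grid), path)
                written.append(path)

    manifest = {
        "config_hash": h,
        "version": __version__,
        "config": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in written},
        "log": bundle["log"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_synthetic_demo(
    config: PipelineConfig, outdir: str | Path | None = None, until: str = "decode"
) -> dict:
    """Generate a synthetic cohort and run the analysis chain over it."""
    if config.synthetic is None:
        raise ValueError("config has no synthetic block")
    cohort = generate_cohort(config.synthetic)
    data = cohort_data_from_synthetic(cohort)
    bundle = run_pipeline(config, data, outdir=outdir, until=until)
    bundle["cohort"] = cohort
    return bundle


def run_real(
    config: PipelineConfig, outdir: str | Path | None = None, until: str = "decode"
) -> dict:
    """Run the analysis chain over an on-disk cohort."""
    if config.data_dir is None:
        raise ValueError("config has no data_dir")
    data = cohort_data_from_dir(config.data_dir, config.tr_seconds)
    return run_pipeline(config, data, outdir=outdir, until=until)


def _configure_logging() -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
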