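"""Readers and writers for the pipeline's on-disk formats.

Formats:

* 4-D NIfTI per run (time last axis) plus an integer atlas label volume;
* motion parameters as whitespace-delimited text, 6 columns, one row per
  volume;
* onset tables as TSV (columns ``volume``, ``scenario``);
* attribute ratings as TSV (rows scenarios, columns attributes, header row
  and index column of names);
* verbal descriptions as UTF-8 text, one file per participant, one line per
  scenario;
* word embeddings in the GloVe text dialect: ``word v1 ... vd``,
  space-separated, no header;
* similarity vectors as TSV with a comment header recording S, the triangle
  traversal order, and the source tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .models import AttributeMatrix, ratings_from_frame
from .prep import RunSeries
from .rsa import SimilarityVector

__all__ = [
    "read_lexicon",
    "write_lexicon",
    "read_motion",
    "write_motion",
    "read_onsets",
    "write_onsets",
    "read_ratings",
    "write_ratings",
    "read_descriptions",
    "write_descriptions",
    "read_run_nifti",
    "write_run_nifti",
    "read_atlas",
    "write_atlas",
    "write_similarity_vector",
    "read_similarity_vector",
    "write_cohort",
]


def read_lexicon(path: str | Path) -> dict[str, np.ndarray]:
    """Read a GloVe-dialect text embedding: one ``word v1 ... vd`` per line."""
    path = Path(path)
    lexicon: dict[str, np.ndarray] = {}
    dim: int | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'word v1 ... vd'")
            word, values = parts[0], parts[1:]
            try:
                vec = np.array([float(v) for v in values])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric vector entry") from exc
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ValueError(f"{path}:{lineno}: dimension {vec.size} != {dim}")
            lexicon[word] = vec
    if not lexicon:
        raise ValueError(f"{path}: empty lexicon")
    return lexicon


def write_lexicon(lexicon: dict[str, np.ndarray], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for word, vec in lexicon.items():
            fh.write(word + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def read_motion(path: str | Path) -> np.ndarray:
    """6-column whitespace-delimited motion table."""
    table = np.loadtxt(path, ndmin=2)
    if table.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, found {table.shape[1]}")
    return table


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(motion, dtype=float), fmt="%.10g")


def read_onsets(path: str | Path) -> list[tuple[int, int]]:
    frame = pd.read_csv(path, sep="\t")
    if not {"volume", "scenario"} <= set(frame.columns):
        raise ValueError(f"{path}: onset table needs 'volume' and 'scenario' columns")
    return [(int(v), int(s)) for v, s in zip(frame["volume"], frame["scenario"])]


def write_onsets(onsets: list[tuple[int, int]], path: str | Path) -> None:
    pd.DataFrame(onsets, columns=["volume", "scenario"]).to_csv(path, sep="\t", index=False)


def read_ratings(path: str | Path) -> AttributeMatrix:
    """Ratings TSV: header row of attribute names, first column scenario names."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ratings_from_frame(frame)


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings.to_csv(path, sep="\t")


def read_descriptions(path: str | Path) -> list[str]:
    """One description per line; blank lines are invalid."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if any(not line.strip() for line in lines) or not lines:
        raise ValueError(f"{path}: every scenario needs a non-empty description line")
    return lines


def write_descriptions(descriptions: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(descriptions) + "\n", encoding="utf-8")


def read_run_nifti(path: str | Path) -> np.ndarray:
    """4-D run volume -> (T, V) matrix, voxels flattened in C order."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got shape {data.shape}")
    t = data.shape[3]
    return data.reshape(-1, t, order="C").T


def write_run_nifti(
    data: np.ndarray, grid_shape: tuple[int, int, int], path: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    """(T, V) matrix -> 4-D NIfTI with the given spatial grid."""
    t = data.shape[0]
    vol = np.asarray(data, dtype=np.float32).T.reshape(*grid_shape, t, order="C")
    nib.save(nib.Nifti1Image(vol, affine if affine is not None else np.eye(4)), str(path))


def read_atlas(path: str | Path) -> np.ndarray:
    """Integer label volume -> flat (V,) label vector (C order)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label volume, got shape {data.shape}")
    return np.rint(data).astype(int).reshape(-1, order="C")


def write_atlas(
    labels: np.ndarray, grid_shape: tuple[int, int, int], path: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    vol = np.asarray(labels).reshape(grid_shape, order="C").astype(np.int16)
    nib.save(nib.Nifti1Image(vol, affine if affine is not None else np.eye(4)), str(path))


def write_searchlight_nifti(map3d: np.ndarray, path: str | Path,
                            affine: np.ndarray | None = None) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(map3d, dtype=np.float32),
                        affine if affine is not None else np.eye(4)),
        str(path),
    )


def write_patterns_tsv(patterns, path: str | Path) -> None:
    """Export a :class:`~idiorsa.prep.ScenarioPatternSet` as TSV.

    Rows are scenarios, columns the selected voxels (named by flat voxel
    index); a trailing column records the per-scenario replicate count.
    """
    frame = pd.DataFrame(
        patterns.patterns,
        index=[f"scenario{int(s):02d}" for s in patterns.scenario_ids],
        columns=[f"v{int(v)}" for v in patterns.voxel_index],
    )
    frame["n_replicates"] = patterns.replicate_counts
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# roi={patterns.roi_id}\n")
        frame.to_csv(fh, sep="\t")


def write_pair_outcomes_tsv(result, path: str | Path) -> None:
    """Decoding pair-outcome matrix as TSV with a summary row."""
    p = result.pair_outcomes.shape[0]
    names = [f"P{i:02d}" for i in range(p)]
    frame = pd.DataFrame(result.pair_outcomes, index=names, columns=names)
    with Path(path).open("w", encoding="utf-8") as fh:
        frame.to_csv(fh, sep="\t")
        fh.write(
            f"# accuracy_percent={result.accuracy!r}\tn_pairs={result.n_pairs}"
            f"\tp_perm={result.p_perm!r}\n"
        )


def write_similarity_vector(sim: SimilarityVector, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# n_scenarios={sim.n_scenarios}\n")
        fh.write("# ordering=lower-triangle-column-major (squareform)\n")
        fh.write(f"# source={sim.source}\n")
        fh.write("value\n")
        for v in sim.values:
            fh.write(f"{float(v)!r}\n")


def read_similarity_vector(path: str | Path) -> SimilarityVector:
    n_scenarios = None
    source = "fmri"
    values: list[float] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key == "n_scenarios":
                    n_scenarios = int(val)
                elif key == "source":
                    source = val
            elif line and line != "value":
                values.append(float(line))
    if n_scenarios is None:
        raise ValueError(f"{path}: missing n_scenarios header")
    return SimilarityVector(values=np.array(values), n_scenarios=n_scenarios, source=source)


def write_cohort(cohort, outdir: str | Path) -> Path:
    """Write a synthetic cohort to disk in the real-data layout.

    Layout::

        atlas.nii.gz
        vocab.txt
        scenarios.json
        P00/run0.nii.gz  P00/run0_motion.txt  P00/run0_onsets.tsv  ...
        P00/ratings.tsv  P00/descriptions.txt
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = cohort.config.grid_shape
    write_atlas(cohort.roi_labels, grid, outdir / "atlas.nii.gz")
    write_lexicon(cohort.vocab.as_dict(), outdir / "vocab.txt")
    (outdir / "scenarios.json").write_text(json.dumps(cohort.scenario_names))
    for p, participant_runs in enumerate(cohort.runs):
        pdir = outdir / f"P{p:02d}"
        pdir.mkdir(exist_ok=True)
        for r, run in enumerate(participant_runs):
            write_run_nifti(run.data, grid, pdir / f"run{r}.nii.gz")
            write_motion(run.motion, pdir / f"run{r}_motion.txt")
            write_onsets(run.onsets, pdir / f"run{r}_onsets.tsv")
        write_ratings(cohort.attribute_ratings[p], pdir / "ratings.tsv")
        write_descriptions(cohort.descriptions[p], pdir / "descriptions.txt")
    return outdir
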