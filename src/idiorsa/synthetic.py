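"""Synthetic cohorts with a known shared / person-specific mix.

The generator emulates the statistical structure the analysis assumes: every
participant's scenario representation is a convex blend of a group-common
latent geometry and an independent personal geometry,

    latent_p = (1 - lambda) * group + lambda * personal_p,

and all three observable channels derive from the same participant latents:

* **voxels** — each signal region reads the active scenario latent out
  through a shared linear map; the response is a boxcar delayed two volumes
  after prompt onset (no canonical-HRF assumption), on top of
  motion-correlated artifact, a linear scanner drift, and white noise;
* **attribute ratings** — latent projections affinely mapped to the 0–6
  Likert range and rounded (ties and end-clipping are expected and kept);
* **verbal descriptions** — the k vocabulary words nearest the scenario's
  latent projection in embedding space.

``idiosyncrasy`` (lambda) is the single dial for how person-specific the
cohort is: 0 gives a purely shared geometry (the null for identity
decoding), 1 gives independent participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .prep import RunSeries

__all__ = [
    "CohortConfig",
    "VocabularyEmbedding",
    "SyntheticCohort",
    "generate_vocabulary_embedding",
    "generate_cohort",
    "ground_truth_report",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters; defaults mirror the study design (26 participants,
    20 scenarios shown in 5 runs, 20 attributes, TR 2.5 s, 3-volume prompts)."""

    n_participants: int = 26
    n_scenarios: int = 20
    n_runs: int = 5
    n_attributes: int = 20
    grid_shape: tuple[int, int, int] = (12, 10, 8)
    n_rois: int = 6
    signal_rois: tuple[int, ...] = (1, 2)
    tr_seconds: float = 2.5
    stimulus_volumes: int = 3
    gap_volumes: int = 3
    initial_fixation_volumes: int = 3
    tail_volumes: int = 2
    response_delay_volumes: int = 2
    response_duration_volumes: int = 4
    latent_dim: int = 8
    idiosyncrasy: float = 0.5  # lambda
    signal_scale: float = 1.0
    noise_sd: float = 10.0
    motion_sd: float = 0.05
    motion_coupling: float = 0.5
    drift_slope: float = 0.5
    rating_noise_sd: float = 0.1
    vocab_size: int = 200
    embed_dim: int = 20
    n_topics: int = 10
    words_per_description: int = 8
    drop_first_presentation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.idiosyncrasy <= 1.0:
            raise ValueError("idiosyncrasy (lambda) must lie in [0, 1]")
        if self.n_scenarios < 3:
            raise ValueError("need at least 3 scenarios")
        if self.n_runs < 2:
            raise ValueError("need at least 2 runs")
        for name in (
            "n_participants", "n_attributes", "latent_dim", "vocab_size",
            "embed_dim", "n_topics", "words_per_description", "stimulus_volumes",
            "gap_volumes", "n_rois",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        n_voxels = int(np.prod(self.grid_shape))
        if n_voxels < self.n_rois:
            raise ValueError(
                f"grid of {n_voxels} voxels cannot hold {self.n_rois} regions"
            )
        if any(r < 1 or r > self.n_rois for r in self.signal_rois):
            raise ValueError("signal_rois must be region labels in 1..n_rois")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def volumes_per_run(self) -> int:
        per_trial = self.stimulus_volumes + self.gap_volumes
        return self.initial_fixation_volumes + self.n_scenarios * per_trial + self.tail_volumes


@dataclass
class VocabularyEmbedding:
    """A small word-embedding table organised around latent topics."""

    words: list[str]
    vectors: np.ndarray  # (vocab, dim)
    topics: np.ndarray  # (vocab,) topic index per word

    def as_dict(self) -> dict[str, np.ndarray]:
        return {w: self.vectors[i] for i, w in enumerate(self.words)}


@dataclass
class SyntheticCohort:
    config: CohortConfig
    runs: list[list[RunSeries]]  # [participant][run]
    roi_labels: np.ndarray  # (V,) region label per voxel, 1-based
    attribute_ratings: list[pd.DataFrame]  # per participant, S x A integers 0..6
    descriptions: list[list[str]]  # per participant, one text per scenario
    vocab: VocabularyEmbedding
    scenario_names: list[str]
    truth: dict = field(default_factory=dict)


def generate_vocabulary_embedding(
    vocab_size: int,
    embed_dim: int,
    seed: int | np.random.Generator,
    n_topics: int = 10,
    within_topic_sd: float = 0.25,
) -> VocabularyEmbedding:
    """Vocabulary of ``vocab_size`` words clustered around topic centroids.

    Centroids are unit vectors (mutually orthogonal when ``n_topics`` fits in
    ``embed_dim``); each word is its topic centroid plus isotropic noise of
    total norm ~``within_topic_sd``, so words of a topic stay far more
    cosine-similar to each other than to other topics' words, and additive
    composition of a word list recovers the topic geometry.
    """
    if vocab_size < 1 or embed_dim < 2 or n_topics < 1:
        raise ValueError("vocab_size, n_topics must be positive and embed_dim >= 2")
    if vocab_size < n_topics:
        raise ValueError("vocab_size must be at least the number of topics")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_topics <= embed_dim:
        q, _ = np.linalg.qr(rng.normal(size=(embed_dim, n_topics)))
        centroids = q.T
    else:
        centroids = rng.normal(size=(n_topics, embed_dim))
        centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    topics = np.arange(vocab_size) % n_topics
    noise = rng.normal(scale=within_topic_sd / np.sqrt(embed_dim), size=(vocab_size, embed_dim))
    vectors = centroids[topics] + noise
    words = [f"word{i:04d}" for i in range(vocab_size)]
    return VocabularyEmbedding(words=words, vectors=vectors, topics=topics)


def _ratings_from_latent(
    latent: np.ndarray, attr_map: np.ndarray, rng: np.random.Generator, noise_sd: float
) -> np.ndarray:
    """Affine-map latent projections into the 0–6 Likert range and round."""
    proj = latent @ attr_map  # (S, A)
    sd = proj.std(axis=0)
    sd[sd == 0] = 1.0
    z = (proj - proj.mean(axis=0)) / sd
    z = z + rng.normal(scale=noise_sd, size=z.shape)
    return np.clip(np.rint(3.0 + 1.5 * z), 0, 6).astype(int)


def _description_from_latent(
    point: np.ndarray, vocab: VocabularyEmbedding, k: int
) -> list[str]:
    """The k vocabulary words nearest the latent projection (cosine)."""
    v = vocab.vectors
    cos = (v @ point) / (np.linalg.norm(v, axis=1) * max(np.linalg.norm(point), 1e-12))
    order = np.argsort(-cos, kind="stable")[:k]
    return [vocab.words[i] for i in order]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort; bitwise-reproducible from ``config.seed``."""
    c = config
    root = np.random.SeedSequence(c.seed)
    keys = root.spawn(6)
    rng_latent = np.random.default_rng(keys[0])
    rng_vocab = np.random.default_rng(keys[1])
    rng_maps = np.random.default_rng(keys[2])
    rng_sched = np.random.default_rng(keys[3])
    rng_noise = np.random.default_rng(keys[4])
    rng_behav = np.random.default_rng(keys[5])

    s, d, p = c.n_scenarios, c.latent_dim, c.n_participants
    lam = c.idiosyncrasy

    group_latent = rng_latent.normal(size=(s, d))
    personal_latents = rng_latent.normal(size=(p, s, d))
    participant_latents = (1 - lam) * group_latent[None] + lam * personal_latents

    vocab = generate_vocabulary_embedding(
        c.vocab_size, c.embed_dim, rng_vocab, n_topics=c.n_topics
    )

    # shared readout maps (the geometry, not the map, is what differs by person)
    embed_map = rng_maps.normal(size=(d, c.embed_dim)) / np.sqrt(d)
    attr_map = rng_maps.normal(size=(d, c.n_attributes)) / np.sqrt(d)
    roi_labels = (np.arange(c.n_voxels) * c.n_rois // c.n_voxels) + 1
    roi_readout: dict[int, np.ndarray] = {}
    for roi in range(1, c.n_rois + 1):
        n_vox = int((roi_labels == roi).sum())
        if roi in c.signal_rois:
            roi_readout[roi] = rng_maps.normal(size=(d, n_vox)) / np.sqrt(d)
    motion_coupling = rng_maps.normal(size=(6, c.n_voxels)) * c.motion_coupling
    drift_weights = rng_maps.normal(size=c.n_voxels) * c.drift_slope

    t = c.volumes_per_run
    per_trial = c.stimulus_volumes + c.gap_volumes
    resp = np.arange(c.response_delay_volumes, c.response_delay_volumes + c.response_duration_volumes)

    runs: list[list[RunSeries]] = []
    ratings: list[pd.DataFrame] = []
    descriptions: list[list[str]] = []
    scenario_names = [f"scenario{i:02d}" for i in range(s)]
    attr_names = [f"attr{i:02d}" for i in range(c.n_attributes)]

    for pi in range(p):
        latent = participant_latents[pi]
        # voxel signal pattern per scenario across the whole grid
        signal = np.zeros((s, c.n_voxels))
        for roi, readout in roi_readout.items():
            signal[:, roi_labels == roi] = c.signal_scale * (latent @ readout)

        participant_runs: list[RunSeries] = []
        for ri in range(c.n_runs):
            order = rng_sched.permutation(s)
            onsets = [
                (c.initial_fixation_volumes + m * per_trial, int(scn))
                for m, scn in enumerate(order)
            ]
            data = np.zeros((t, c.n_voxels))
            for onset, scn in onsets:
                vols = onset + resp
                vols = vols[vols < t]
                data[vols] += signal[scn]
            motion = np.cumsum(rng_noise.normal(scale=c.motion_sd, size=(t, 6)), axis=0)
            data += motion @ motion_coupling
            data += np.outer(np.linspace(-1.0, 1.0, t), drift_weights)
            if c.noise_sd > 0:
                data += rng_noise.normal(scale=c.noise_sd, size=(t, c.n_voxels))
            if ri == 0 and c.drop_first_presentation:
                onsets = onsets[1:]  # first prompt lost to discarded volumes
            participant_runs.append(
                RunSeries(data=data, onsets=onsets, motion=motion, tr_seconds=c.tr_seconds)
            )
        runs.append(participant_runs)

        rate = _ratings_from_latent(latent, attr_map, rng_behav, c.rating_noise_sd)
        ratings.append(
            pd.DataFrame(rate, index=scenario_names, columns=attr_names)
        )
        embedded = latent @ embed_map
        descriptions.append(
            [
                " ".join(
                    _description_from_latent(embedded[si], vocab, c.words_per_description)
                )
                for si in range(s)
            ]
        )

    truth = {
        "idiosyncrasy": lam,
        "group_latent": group_latent,
        "personal_latents": personal_latents,
        "participant_latents": participant_latents,
        "embed_map": embed_map,
        "attr_map": attr_map,
        "signal_rois": tuple(c.signal_rois),
    }
    return SyntheticCohort(
        config=c,
        runs=runs,
        roi_labels=roi_labels,
        attribute_ratings=ratings,
        descriptions=descriptions,
        vocab=vocab,
        scenario_names=scenario_names,
        truth=truth,
    )


def ground_truth_report(cohort: SyntheticCohort) -> dict:
    """Ground-truth quantities for assertions: lambda, latent similarity, SNR."""
    from .rsa import similarity_vector  # local import to avoid a cycle

    c = cohort.config
    group_sim = similarity_vector(cohort.truth["group_latent"], source="group_average")
    participant_sims = [
        similarity_vector(cohort.truth["participant_latents"][i], source="multimodal")
        for i in range(c.n_participants)
    ]
    # per-voxel response power of the boxcar signal vs. the white-noise floor
    mean_signal_power = float(
        np.mean(cohort.truth["participant_latents"] ** 2) * c.signal_scale**2
    )
    voxel_snr = np.inf if c.noise_sd == 0 else mean_signal_power / c.noise_sd**2
    return {
        "idiosyncrasy": c.idiosyncrasy,
        "group_latent_similarity": group_sim,
        "participant_latent_similarities": participant_sims,
        "voxel_snr": voxel_snr,
        "rating_snr": np.inf if c.rating_noise_sd == 0 else 1.0 / c.rating_noise_sd**2,
        "noiseless": c.noise_sd == 0,
    }


def null_cohort_config(**overrides) -> CohortConfig:
    """A lambda = 0 configuration (shared geometry only), otherwise defaults."""
    return replace(CohortConfig(), idiosyncrasy=0.0, **overrides)
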