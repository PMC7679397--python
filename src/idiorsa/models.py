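"""Personal model construction.

Each participant contributes two behavioural channels per scenario:

* a free-text *verbal description*, modelled by summing the word-embedding
  vectors of its content words (naïve additive composition — word order and
  syntax are deliberately ignored);
* *experiential attribute ratings*: Likert 0–6 scores on 20 sensory / motor /
  cognitive / spatiotemporal / emotional attributes, standardized per
  attribute within the participant.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stopwords import DEFAULT_STOPLIST

#: the 20 experiential attributes, in rating-sheet order
ATTRIBUTE_NAMES: tuple[str, ...] = (
    "bright", "color", "motion", "touch", "audition", "music", "speech",
    "taste", "head", "upperlimb", "lowerlimb", "body", "path", "landmark",
    "time", "social", "communication", "cognition", "pleasant", "unpleasant",
)

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?")


class UnmodelableDescriptionError(ValueError):
    """Raised when no content word of a description is in the lexicon."""


@dataclass
class AttributeMatrix:
    """Scenario x attribute rating matrix for one participant."""

    values: np.ndarray
    scenario_names: list[str]
    attribute_names: list[str] = field(default_factory=lambda: list(ATTRIBUTE_NAMES))
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        s, a = self.values.shape
        if s != len(self.scenario_names) or a != len(self.attribute_names):
            raise ValueError("rating matrix shape does not match scenario/attribute names")
        if not self.normalized and (self.values.min() < 0 or self.values.max() > 6):
            raise ValueError("raw Likert ratings must lie in [0, 6]")


@dataclass
class VerbalMatrix:
    """Scenario x embedding-dimension matrix of composed description vectors."""

    values: np.ndarray
    scenario_names: list[str]
    word_lists: list[list[str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.scenario_names) or len(self.word_lists) != len(
            self.scenario_names
        ):
            raise ValueError("verbal matrix rows must match scenario names and word lists")
        if any(len(w) == 0 for w in self.word_lists):
            raise ValueError("every scenario must retain at least one content word")


def tokenize(description: str) -> list[str]:
    """Lowercase-fold and strip punctuation, keeping alphabetic tokens in order."""
    return _TOKEN_RE.findall(description.lower())


def extract_content_words(
    description: str,
    lexicon: dict[str, np.ndarray],
    stoplist: frozenset[str] | set[str] = DEFAULT_STOPLIST,
) -> list[str]:
    """Content words of a description: tokenized, stoplist- and lexicon-filtered.

    Original token order is preserved and duplicates are kept (they weight the
    additive composition).  Raises :class:`UnmodelableDescriptionError` when
    nothing survives filtering.
    """
    if not description or not description.strip():
        raise ValueError("description is empty")
    words = [w for w in tokenize(description) if w not in stoplist and w in lexicon]
    if not words:
        raise UnmodelableDescriptionError(
            f"no content word of {description!r} is covered by the lexicon"
        )
    return words


def compose_verbal_vector(words: list[str], lexicon: dict[str, np.ndarray]) -> np.ndarray:
    """Pointwise sum of the words' embedding vectors (order-invariant)."""
    if not words:
        raise ValueError("cannot compose an empty word list")
    missing = [w for w in words if w not in lexicon]
    if missing:
        raise KeyError(f"words absent from lexicon: {missing}")
    return np.sum([np.asarray(lexicon[w], dtype=float) for w in words], axis=0)


def build_verbal_matrix(
    descriptions: list[str],
    lexicon: dict[str, np.ndarray],
    scenario_names: list[str] | None = None,
    stoplist: frozenset[str] | set[str] = DEFAULT_STOPLIST,
) -> VerbalMatrix:
    """Compose one verbal vector per scenario description."""
    names = scenario_names or [f"scenario{i:02d}" for i in range(len(descriptions))]
    word_lists = [extract_content_words(d, lexicon, stoplist) for d in descriptions]
    values = np.stack([compose_verbal_vector(w, lexicon) for w in word_lists])
    return VerbalMatrix(values=values, scenario_names=list(names), word_lists=word_lists)


def normalize_attribute_ratings(raw: AttributeMatrix, ddof: int = 0) -> AttributeMatrix:
    """Standardize each attribute column within the participant.

    Subtracts the column mean (across scenarios) and divides by the column
    standard deviation.  ``ddof=0`` (population SD) is the default z-score
    convention; pass ``ddof=1`` for the sample convention.  Constant columns
    cannot be standardized: they are set to zero and a warning is emitted,
    preserving the matrix shape for similarity computation.
    """
    values = np.asarray(raw.values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 scenarios to normalize ratings")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    degenerate = sd == 0
    if np.any(degenerate):
        cols = [raw.attribute_names[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"constant attribute columns set to zero: {cols}", RuntimeWarning, stacklevel=2
        )
    out = np.zeros_like(values)
    ok = ~degenerate
    out[:, ok] = (values[:, ok] - mean[ok]) / sd[ok]
    return AttributeMatrix(
        values=out,
        scenario_names=list(raw.scenario_names),
        attribute_names=list(raw.attribute_names),
        normalized=True,
    )


def ratings_from_frame(frame: pd.DataFrame) -> AttributeMatrix:
    """Build an :class:`AttributeMatrix` from a scenarios x attributes DataFrame."""
    return AttributeMatrix(
        values=frame.to_numpy(dtype=float),
        scenario_names=[str(s) for s in frame.index],
        attribute_names=[str(c) for c in frame.columns],
    )
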