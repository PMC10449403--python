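"""Per-image semantic-information metrics from free-text scene descriptions.

Given ~100 one-sentence descriptions per image, three metrics summarize how
much meaning observers extracted:

* **median description length** — median word count per description
  (raw whitespace words, before stopword/punctuation removal, by default);
* **lexical entropy** — Shannon entropy of the word-type histogram pooled
  over all of the image's descriptions: more unique words and flatter
  usage mean more varied descriptions;
* **mean pairwise distance** — cosine distance (1 - cosine similarity)
  between every unordered pair of content-word tokens within a
  description, evaluated in a word-embedding space, averaged within and
  then across descriptions: less related words mean less standard context.

Tokenization lowercases, replaces ASCII punctuation with whitespace (so
hyphenated words split at the hyphen) and removes a frozen stopword list.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import shannon_entropy
from .stopwords import default_stopwords

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


class OOVError(KeyError):
    """Raised when a word is looked up that the embedding table does not hold."""


class EmptyCorpusError(ValueError):
    """Raised when no tokens (or no valid token pairs) survive preprocessing."""


@dataclass(frozen=True)
class DescriptionCorpus:
    """All free-text descriptions collected for one image."""

    image_id: str
    descriptions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.descriptions) < 2:
            raise ValueError(
                f"{self.image_id}: need at least 2 descriptions for entropy"
            )
        if any(d is None for d in self.descriptions):
            raise ValueError(f"{self.image_id}: null description")
        object.__setattr__(self, "descriptions", tuple(self.descriptions))


@dataclass(frozen=True)
class SemanticFeatures:
    """The three semantic-information numbers for one image."""

    image_id: str
    median_length: float
    lexical_entropy: float
    mean_pairwise_distance: float


class EmbeddingTable:
    """Fixed-dimension word vectors with strict out-of-vocabulary lookup."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ValueError("empty embedding table")
        dims = {np.asarray(v).shape for v in vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError("all vectors must be 1-D and share one dimension")
        self._vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        self.dim = next(iter(dims))[0]
        if self.dim < 2:
            raise ValueError("embedding dimension must be >= 2")

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    @property
    def vocabulary(self) -> set[str]:
        return set(self._vectors)

    def vector(self, word: str) -> np.ndarray:
        try:
            return self._vectors[word]
        except KeyError:
            raise OOVError(f"word not in embedding vocabulary: {word!r}") from None

    def matrix(self, words: Sequence[str]) -> np.ndarray:
        """Stack vectors for ``words`` (all must be in-vocabulary)."""
        return np.stack([self.vector(w) for w in words])


def tokenize(text: str, stopwords: Iterable[str] | None = None) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace, drop stopwords.

    Order and duplicates are preserved.  An empty string yields an empty
    list.
    """
    stops = default_stopwords() if stopwords is None else set(stopwords)
    words = text.lower().translate(_PUNCT_TABLE).split()
    return [w for w in words if w not in stops]


def description_length(text: str) -> int:
    """Word count of a raw description: whitespace-delimited words,
    before any punctuation or stopword removal."""
    return len(text.split())


def lexical_entropy(
    descriptions: Sequence[str], stopwords: Iterable[str] | None = None
) -> float:
    """Entropy (bits) of the pooled word-type histogram across descriptions."""
    tokens: list[str] = []
    for d in descriptions:
        tokens.extend(tokenize(d, stopwords))
    if not tokens:
        raise EmptyCorpusError("no tokens survive preprocessing")
    counts = pd.Series(tokens).value_counts().to_numpy(dtype=float)
    return shannon_entropy(counts / counts.sum())


def _cosine_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = vectors / norms
    sim = unit @ unit.T
    return 1.0 - np.clip(sim, -1.0, 1.0)


def mean_pairwise_distance(
    descriptions: Sequence[str],
    emb: EmbeddingTable,
    stopwords: Iterable[str] | None = None,
) -> float:
    """Mean cosine distance over all within-description token pairs.

    Each description contributes ``C(k, 2)`` unordered pairs for its ``k``
    surviving in-vocabulary tokens (duplicate tokens therefore contribute
    zero-distance pairs).  Pairs involving out-of-vocabulary tokens are
    skipped.  Per-description means are averaged across the descriptions
    that yielded at least one valid pair.

    Raises
    ------
    EmptyCorpusError
        If no description yields a valid pair.
    """
    per_description: list[float] = []
    for d in descriptions:
        toks = [w for w in tokenize(d, stopwords) if w in emb]
        if len(toks) < 2:
            continue
        dist = _cosine_distance_matrix(emb.matrix(toks))
        iu = np.triu_indices(len(toks), k=1)
        per_description.append(float(dist[iu].mean()))
    if not per_description:
        raise EmptyCorpusError("no description contributes >= 2 in-vocabulary tokens")
    return float(np.mean(per_description))


def aggregate_semantic_features(
    corpus: DescriptionCorpus,
    emb: EmbeddingTable,
    stopwords: Iterable[str] | None = None,
    length_after_tokenization: bool = False,
) -> SemanticFeatures:
    """All three semantic metrics for one image's description corpus.

    ``length_after_tokenization`` switches median length to count surviving
    tokens instead of raw words.
    """
    try:
        if length_after_tokenization:
            lengths = [len(tokenize(d, stopwords)) for d in corpus.descriptions]
        else:
            lengths = [description_length(d) for d in corpus.descriptions]
        return SemanticFeatures(
            image_id=corpus.image_id,
            median_length=float(np.median(lengths)),
            lexical_entropy=lexical_entropy(corpus.descriptions, stopwords),
            mean_pairwise_distance=mean_pairwise_distance(
                corpus.descriptions, emb, stopwords
            ),
        )
    except EmptyCorpusError as exc:
        raise EmptyCorpusError(f"{corpus.image_id}: {exc}") from exc


def semantic_feature_table(
    corpora: Sequence[DescriptionCorpus],
    emb: EmbeddingTable,
    stopwords: Iterable[str] | None = None,
    on_empty: str = "drop",
) -> pd.DataFrame:
    """Semantic features for many images, one row per image.

    Images whose descriptions yield no valid token pair are dropped with a
    warning when ``on_empty='drop'`` (the default), or re-raise with
    ``on_empty='raise'``.
    """
    import warnings

    rows = []
    for corpus in corpora:
        try:
            rows.append(aggregate_semantic_features(corpus, emb, stopwords))
        except EmptyCorpusError:
            if on_empty == "raise":
                raise
            warnings.warn(
                f"dropping image {corpus.image_id}: no valid token pairs",
                stacklevel=2,
            )
    return pd.DataFrame(
        {
            "image_id": [r.image_id for r in rows],
            "median_length": [r.median_length for r in rows],
            "lexical_entropy": [r.lexical_entropy for r in rows],
            "mean_pairwise_distance": [r.mean_pairwise_distance for r in rows],
        }
    )
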