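"""The three handcrafted linguistic features and the canonical feature vector.

Depressed speech tends to show (i) more words from a depression-associated
lexicon, (ii) more negative affective valence, and (iii) flatter syntax —
shorter average distances between tokens and their grammatical heads. This
module computes those three signals and assembles them, together with the
semantic projection ``emb_1`` from :mod:`lingscreen.embedding`, into the
model's canonical four-entry feature vector:

    (neg_words_r, emb_1, sent_neg, avg_dep_dist)

The sentiment scorer is a deliberately transparent lexicon-plus-negation
rule: token valences in [-4, +4], a full sign flip when a negator occurs
within a fixed window of preceding tokens, and no intensifier, punctuation
or capitalization rules — normalization has already removed those cues.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, UndefinedFeatureError
from .transcript_io import ParsedSentence, Transcript

FEATURE_NAMES = ("neg_words_r", "emb_1", "sent_neg", "avg_dep_dist")


# --------------------------------------------------------------------------
# Lexicons
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DepressionLexicon:
    """A curated set of depression-associated words (lowercase, apostrophe-free)."""

    words: frozenset[str]

    def __post_init__(self) -> None:
        if not self.words:
            raise ConfigError("depression lexicon is empty")

    def __contains__(self, token: str) -> bool:
        return token in self.words


@dataclass(frozen=True)
class ValenceLexicon:
    """Token valences in [-4, +4] plus negation cues.

    ``negation_window`` is the number of preceding tokens scanned for a
    negator; a hit flips the token's valence sign entirely. Negators are
    disjoint from the valence keys and score as neutral themselves.
    """

    valence: dict[str, float]
    negators: frozenset[str]
    negation_window: int = 3

    def __post_init__(self) -> None:
        if self.negation_window < 0:
            raise ConfigError("negation window must be >= 0")
        overlap = self.negators & set(self.valence)
        if overlap:
            raise ConfigError(f"negators overlap valence keys: {sorted(overlap)[:5]}")


def load_word_list(path: str | Path) -> frozenset[str]:
    """One word per line; '#' starts a comment; blank lines ignored."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        word = line.split("#", 1)[0].strip()
        if word:
            words.add(word.lower())
    return frozenset(words)


def load_valence_tsv(path: str | Path) -> dict[str, float]:
    """TSV of token<TAB>valence; '#' starts a comment."""
    out: dict[str, float] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        token, value = line.split("\t")
        out[token.strip().lower()] = float(value)
    return out


def _data_path(name: str) -> Path:
    return Path(str(resources.files("lingscreen").joinpath("data", name)))


def default_depression_lexicon() -> DepressionLexicon:
    return DepressionLexicon(words=load_word_list(_data_path("depression_lexicon.txt")))


def default_valence_lexicon(negation_window: int = 3) -> ValenceLexicon:
    return ValenceLexicon(
        valence=load_valence_tsv(_data_path("valence_lexicon.tsv")),
        negators=load_word_list(_data_path("negators.txt")),
        negation_window=negation_window,
    )


# --------------------------------------------------------------------------
# Feature vector
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureVector:
    """The four model inputs in canonical order."""

    neg_words_r: float
    emb_1: float
    sent_neg: float
    avg_dep_dist: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise UndefinedFeatureError(f"non-finite feature value in {arr}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.neg_words_r, self.emb_1, self.sent_neg, self.avg_dep_dist],
            dtype=float,
        )


# --------------------------------------------------------------------------
# Feature computations
# --------------------------------------------------------------------------


def negative_word_ratio(tokens: Sequence[str], lexicon: DepressionLexicon) -> float:
    """Proportion of tokens found in the depression lexicon (repeats count)."""
    if not tokens:
        raise UndefinedFeatureError("negative_word_ratio undefined on empty token list")
    hits = sum(1 for t in tokens if t in lexicon)
    return hits / len(tokens)


def negative_sentiment(tokens: Sequence[str], vlex: ValenceLexicon) -> float:
    """Normalized negative-valence mass of the token stream.

    Each token's effective valence is its lexicon valence, sign-flipped when
    any negator occurs within ``negation_window`` preceding tokens. The score
    is S_neg / (S_neg + S_pos + N_neu), where S_neg and S_pos are the summed
    magnitudes of effectively negative / positive tokens and N_neu counts the
    zero-valence tokens (negators included). Returns 0 when every token is
    neutral.
    """
    if not tokens:
        raise UndefinedFeatureError("negative_sentiment undefined on empty token list")
    s_neg = 0.0
    s_pos = 0.0
    n_neu = 0
    w = vlex.negation_window
    for i, tok in enumerate(tokens):
        v = vlex.valence.get(tok, 0.0)
        if v == 0.0:
            n_neu += 1
            continue
        lo = max(0, i - w)
        if any(tokens[j] in vlex.negators for j in range(lo, i)):
            v = -v
        if v < 0:
            s_neg += -v
        else:
            s_pos += v
    denom = s_neg + s_pos + n_neu
    if denom == 0:
        return 0.0
    return s_neg / denom


def avg_dependency_distance(sentences: Sequence[ParsedSentence]) -> float:
    """Mean |token index - head index| pooled over all sentences.

    Root tokens (head 0) and punctuation tokens (upos PUNCT) do not
    contribute; the average is token-level across the whole transcript, not
    a mean of per-sentence means.
    """
    distances: list[int] = []
    for sent in sentences:
        for idx, _form, head, upos in sent.tokens:
            if head == 0 or upos == "PUNCT":
                continue
            distances.append(abs(idx - head))
    if not distances:
        raise UndefinedFeatureError(
            "avg_dependency_distance undefined: no non-root, non-punctuation tokens"
        )
    return float(np.mean(distances))


def extract_features(
    transcript: Transcript,
    parses: Sequence[ParsedSentence],
    lexicon: DepressionLexicon,
    vlex: ValenceLexicon,
    projector,
    embedding_row: Optional[np.ndarray] = None,
    embed_fn=None,
) -> FeatureVector:
    """Assemble the canonical feature vector for one transcript.

    ``emb_1`` is the projection of the transcript's embedding onto the
    projector's selected right singular vector. Provide the precomputed
    ``embedding_row`` (the usual batch path) or an ``embed_fn`` mapping a
    text to a 1-D embedding.
    """
    from .embedding import project_component  # local import avoids cycle

    tokens = transcript.tokens
    try:
        nwr = negative_word_ratio(tokens, lexicon)
    except UndefinedFeatureError as exc:
        raise UndefinedFeatureError(f"neg_words_r ({transcript.id}): {exc}") from None
    try:
        sneg = negative_sentiment(tokens, vlex)
    except UndefinedFeatureError as exc:
        raise UndefinedFeatureError(f"sent_neg ({transcript.id}): {exc}") from None
    try:
        add = avg_dependency_distance(parses)
    except UndefinedFeatureError as exc:
        raise UndefinedFeatureError(f"avg_dep_dist ({transcript.id}): {exc}") from None
    if embedding_row is None:
        if embed_fn is None:
            raise ConfigError("extract_features needs embedding_row or embed_fn")
        embedding_row = np.asarray(embed_fn(transcript.normalized_text), dtype=float)
    emb1 = project_component(embedding_row, projector, projector.component_index)
    return FeatureVector(neg_words_r=nwr, emb_1=float(emb1), sent_neg=sneg, avg_dep_dist=add)
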