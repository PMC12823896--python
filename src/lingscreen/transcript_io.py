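"""Reading, filtering and normalizing interview transcripts and their parses.

Interview transcripts arrive as tab-separated files with ``start_time``,
``stop_time``, ``speaker`` and ``value`` columns (the DAIC-WOZ dialect), or as
plain text (one file = one participant's speech). Only participant speech is
modeled: interviewer turns are dropped so the classifier cannot learn dialogue
structure. Text is normalized to lowercase, punctuation-free, single-spaced
form; every downstream tokenization is a split of that normalized text on
single spaces.

Dependency parses are consumed as CoNLL-U; this module validates the head
structure but never produces parses itself.
"""

from __future__ import annotations

import csv
import io
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    ConfigError,
    EmptyTranscriptError,
    FormatError,
    ParseError,
)

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Utterance:
    """A single speaker turn, timestamped in seconds."""

    start_time: float
    stop_time: float
    speaker: str
    text: str

    def __post_init__(self) -> None:
        if self.stop_time < self.start_time:
            raise FormatError(
                f"utterance stop_time {self.stop_time} precedes start_time {self.start_time}"
            )
        if not self.speaker:
            raise FormatError("utterance speaker must be non-empty")


@dataclass
class Transcript:
    """One participant's interview: ordered utterances plus normalized text.

    ``label`` is the binary depression label (1 = depressed, per a PHQ-8
    cutoff) when known, else ``None``.
    """

    id: str
    utterances: list[Utterance] = field(default_factory=list)
    normalized_text: str = ""
    label: Optional[int] = None

    @property
    def tokens(self) -> list[str]:
        """Whitespace tokens of the normalized text."""
        return self.normalized_text.split() if self.normalized_text else []


@dataclass(frozen=True)
class ParsedSentence:
    """A dependency-parsed sentence: (1-based index, form, head, upos) per token.

    head 0 marks the root. Indices are contiguous 1..n, every head lies in
    0..n, at least one token is the root, and no token heads itself.
    """

    tokens: tuple[tuple[int, str, int, str], ...]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if n == 0:
            raise ParseError("empty sentence")
        indices = [t[0] for t in self.tokens]
        if indices != list(range(1, n + 1)):
            raise ParseError(f"non-contiguous token ids: {indices}")
        roots = 0
        for idx, _form, head, _upos in self.tokens:
            if not (0 <= head <= n):
                raise ParseError(f"head index {head} out of range for {n}-token sentence")
            if head == idx:
                raise ParseError(f"token {idx} is its own head")
            if head == 0:
                roots += 1
        if roots < 1:
            raise ParseError("sentence has no root token (head 0)")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class SplitSpec:
    """Sizes of the train/development/test partition plus the shuffle seed."""

    n_train: int
    n_dev: int
    n_test: int
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_dev, self.n_test) < 1:
            raise ConfigError("all split sizes must be >= 1")

    @property
    def total(self) -> int:
        return self.n_train + self.n_dev + self.n_test


# --------------------------------------------------------------------------
# Text normalization
# --------------------------------------------------------------------------

_ASCII_APOSTROPHE = "'"


def _is_punct(ch: str) -> bool:
    return ch == _ASCII_APOSTROPHE or unicodedata.category(ch).startswith("P")


def normalize_text(raw: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace.

    Removes every character in the Unicode punctuation categories (P*) plus
    the ASCII apostrophe — so contractions lose their apostrophe rather than
    being expanded ("don't" -> "dont") — then collapses whitespace runs to
    single spaces and trims. Idempotent.
    """
    lowered = raw.lower()
    kept = "".join(ch for ch in lowered if not _is_punct(ch))
    return " ".join(kept.split())


# --------------------------------------------------------------------------
# Transcript reading
# --------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("start_time", "stop_time", "speaker", "value")


def read_daic_transcript(
    path: str | Path,
    participant_label: str = "participant",
    transcript_id: Optional[str] = None,
) -> Transcript:
    """Read a DAIC-WOZ-style TSV transcript, keeping only participant rows.

    The speaker match is case-insensitive and exact; all other speakers
    (interviewer, system prompts) are silently dropped. The returned
    transcript's ``normalized_text`` is left empty — call
    :func:`normalize_transcript` to populate it.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty transcript file") from None
        colmap = {name.strip().lower(): i for i, name in enumerate(header)}
        for col in _REQUIRED_COLUMNS:
            if col not in colmap:
                raise FormatError(f"{path}: missing required column '{col}'")
        want = participant_label.lower()
        utterances: list[Utterance] = []
        for row in reader:
            if not row or all(not cell.strip() for cell in row):
                continue
            speaker = row[colmap["speaker"]].strip()
            if speaker.lower() != want:
                continue
            utterances.append(
                Utterance(
                    start_time=float(row[colmap["start_time"]]),
                    stop_time=float(row[colmap["stop_time"]]),
                    speaker=speaker,
                    text=row[colmap["value"]],
                )
            )
    if not utterances:
        raise EmptyTranscriptError(
            f"{path}: no rows with speaker '{participant_label}'; screening is "
            "undefined on an empty transcript"
        )
    return Transcript(id=transcript_id or path.stem, utterances=utterances)


def read_plain_transcript(path: str | Path, transcript_id: Optional[str] = None) -> Transcript:
    """Read a plain .txt file as one participant's entire speech."""
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    if not raw.strip():
        raise EmptyTranscriptError(f"{path}: empty transcript")
    utt = Utterance(start_time=0.0, stop_time=0.0, speaker="participant", text=raw)
    return Transcript(id=transcript_id or path.stem, utterances=[utt])


def normalize_transcript(transcript: Transcript) -> Transcript:
    """Populate ``normalized_text`` by normalizing each utterance and joining
    with single spaces (equivalently: normalizing the concatenation)."""
    parts = [normalize_text(u.text) for u in transcript.utterances]
    transcript.normalized_text = " ".join(p for p in parts if p)
    return transcript


# --------------------------------------------------------------------------
# CoNLL-U
# --------------------------------------------------------------------------


def read_conllu(source: str | Path | io.TextIOBase) -> list[ParsedSentence]:
    """Parse a CoNLL-U file into validated :class:`ParsedSentence` objects.

    Multiword-token ranges (ids like ``3-4``) and empty nodes (``5.1``) are
    skipped; comment lines start with ``#``; a blank line ends a sentence.
    Violations of the head-structure invariants raise :class:`ParseError`
    tagged with the 1-based sentence number.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    sentences: list[ParsedSentence] = []
    current: list[tuple[int, str, int, str]] = []
    sent_no = 1

    def _flush() -> None:
        nonlocal current, sent_no
        if current:
            try:
                sentences.append(ParsedSentence(tokens=tuple(current)))
            except ParseError as exc:
                raise ParseError(f"sentence {sent_no}: {exc}") from None
            current = []
            sent_no += 1

    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            _flush()
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ParseError(
                f"sentence {sent_no}: expected 10 tab-separated columns, got {len(cols)}"
            )
        tok_id = cols[0]
        if "-" in tok_id or "." in tok_id:
            continue  # multiword range / empty node
        try:
            idx = int(tok_id)
            head = int(cols[6])
        except ValueError:
            raise ParseError(f"sentence {sent_no}: non-integer id or head in '{line}'") from None
        current.append((idx, cols[1], head, cols[3]))
    _flush()
    return sentences


def write_conllu(sentences: Sequence[ParsedSentence], path: str | Path) -> None:
    """Write sentences in CoNLL-U (fields beyond index/form/upos/head are '_')."""
    lines: list[str] = []
    for sent in sentences:
        for idx, form, head, upos in sent.tokens:
            lines.append(
                "\t".join(
                    [str(idx), form, "_", upos, "_", "_", str(head), "_", "_", "_"]
                )
            )
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Dataset splitting
# --------------------------------------------------------------------------


def split_dataset(
    ids: Sequence[str],
    spec: SplitSpec,
    labels: Optional[dict[str, int]] = None,
) -> tuple[list[str], list[str], list[str]]:
    """Partition transcript ids into train/dev/test splits.

    Ids are sorted before the seeded shuffle, so the partition is a
    deterministic function of (set of ids, seed) regardless of input order.
    When ``labels`` is supplied the split is stratified: each class is
    shuffled and apportioned separately, with per-class counts proportional
    to the split sizes (largest-remainder rounding).
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate transcript ids")
    if spec.total != len(ids):
        raise ConfigError(
            f"split sizes {spec.n_train}+{spec.n_dev}+{spec.n_test} = {spec.total} "
            f"do not sum to corpus size {len(ids)}"
        )
    rng = np.random.default_rng(spec.seed)
    targets = np.array([spec.n_train, spec.n_dev, spec.n_test])

    if labels is None:
        order = sorted(ids)
        perm = rng.permutation(len(order))
        shuffled = [order[i] for i in perm]
        cut1, cut2 = spec.n_train, spec.n_train + spec.n_dev
        return shuffled[:cut1], shuffled[cut1:cut2], shuffled[cut2:]

    missing = [i for i in ids if i not in labels]
    if missing:
        raise ConfigError(f"no label for ids {missing[:5]}")
    splits: list[list[str]] = [[], [], []]
    # Stratify: apportion each class across splits by largest remainder,
    # tracking how many slots each split still has so totals come out exact.
    slots = targets.copy()
    for cls in sorted({labels[i] for i in ids}):
        members = sorted(i for i in ids if labels[i] == cls)
        perm = rng.permutation(len(members))
        members = [members[i] for i in perm]
        frac = slots / slots.sum() * len(members)
        take = np.floor(frac).astype(int)
        rem = frac - take
        for _ in range(len(members) - int(take.sum())):
            j = int(np.argmax(rem))
            take[j] += 1
            rem[j] = -1.0
        pos = 0
        for j in range(3):
            splits[j].extend(members[pos : pos + take[j]])
            pos += take[j]
        slots = slots - take
    return splits[0], splits[1], splits[2]


# --------------------------------------------------------------------------
# Corpus (JSON-lines) I/O
# --------------------------------------------------------------------------


def write_corpus_jsonl(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write a normalized corpus as JSON-lines: {id, text, label} per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in transcripts:
            fh.write(
                json.dumps({"id": t.id, "text": t.normalized_text, "label": t.label})
                + "\n"
            )


def read_corpus_jsonl(path: str | Path) -> list[Transcript]:
    """Read a JSON-lines corpus written by :func:`write_corpus_jsonl`."""
    out: list[Transcript] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                Transcript(
                    id=str(obj["id"]),
                    normalized_text=obj.get("text", ""),
                    label=obj.get("label"),
                )
            )
    return out
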