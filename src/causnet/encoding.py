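"""Encoding a language's corpus statistics as a stochastic training stream.

Each training item abstracts one corpus utterance to a (verb, construction)
pair: the input is a one-hot lexical vector over the verb inventory, a single
causative-context node, and the verb's four semantic ratings; the target is a
3-way choice among the less-transparent causative, the more-transparent
causative, and a catch-all "other" category.  Items are drawn i.i.d. with
probability proportional to the (verb, construction) corpus counts, so a
stream of n items is a multinomial sample from the normalized corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterator, Sequence

import numpy as np

from .corpus_io import LanguageInput, VerbEntry
from .errors import DegenerateInputError


class Target(IntEnum):
    """Output categories, in fixed network order."""

    LESS = 0
    MORE = 1
    OTHER = 2


#: number of non-lexical input units: causative flag + 4 semantic ratings
N_EXTRA_UNITS = 5


@dataclass(frozen=True)
class TrainingItem:
    """One encoded utterance."""

    verb_id: int
    causative_flag: int
    sem: tuple[float, float, float, float]
    target: Target

    def __post_init__(self) -> None:
        expected = 1 if self.target in (Target.LESS, Target.MORE) else 0
        if self.causative_flag != expected:
            raise ValueError(
                f"causative_flag={self.causative_flag} inconsistent with target {self.target!r}"
            )


class TrainingStream(Sequence[TrainingItem]):
    """An array-backed sequence of training items for one language.

    Behaves as a ``Sequence[TrainingItem]`` while exposing the flat
    ``verb_ids`` / ``targets`` arrays that vectorized training consumes.
    """

    def __init__(self, lang: LanguageInput, verb_ids: np.ndarray, targets: np.ndarray):
        self.lang = lang
        self.verb_ids = np.asarray(verb_ids, dtype=np.int64)
        self.targets = np.asarray(targets, dtype=np.int64)
        if self.verb_ids.shape != self.targets.shape:
            raise ValueError("verb_ids and targets must have equal length")

    def __len__(self) -> int:
        return len(self.verb_ids)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return TrainingStream(self.lang, self.verb_ids[i], self.targets[i])
        t = Target(int(self.targets[i]))
        return TrainingItem(
            verb_id=int(self.verb_ids[i]),
            causative_flag=1 if t in (Target.LESS, Target.MORE) else 0,
            sem=self.lang.verbs[int(self.verb_ids[i])].sem,
            target=t,
        )

    def __iter__(self) -> Iterator[TrainingItem]:
        for i in range(len(self)):
            yield self[i]

    def cell_counts(self) -> np.ndarray:
        """(n_verbs, 3) empirical counts of each (verb, construction) cell."""
        counts = np.zeros((self.lang.n_verbs, 3), dtype=np.int64)
        np.add.at(counts, (self.verb_ids, self.targets), 1)
        return counts


def build_training_stream(
    lang: LanguageInput,
    n_items: int,
    rng: np.random.Generator,
    included_verbs: set[int] | None = None,
) -> TrainingStream:
    """Sample ``n_items`` utterances i.i.d. from the corpus frequencies.

    ``included_verbs`` restricts sampling to those verb ids (used by the
    split-half protocol: held-out verbs never appear in the stream but keep
    their lexical input units in the architecture).
    """
    if n_items < 1:
        raise DegenerateInputError("n_items must be >= 1")
    counts = lang.counts()
    if included_verbs is not None:
        if not included_verbs:
            raise DegenerateInputError("included_verbs is empty")
        bad = set(included_verbs) - set(range(lang.n_verbs))
        if bad:
            raise DegenerateInputError(f"included_verbs not in language: {sorted(bad)}")
        mask = np.zeros(lang.n_verbs, dtype=bool)
        mask[list(included_verbs)] = True
        counts = counts * mask[:, None]
    total = counts.sum()
    if total <= 0:
        raise DegenerateInputError("all (verb, construction) counts are zero in the restricted set")
    p = (counts / total).ravel()
    flat = rng.choice(len(p), size=n_items, p=p)
    return TrainingStream(lang, verb_ids=flat // 3, targets=flat % 3)


def encode_input(item: TrainingItem, n_verbs: int) -> np.ndarray:
    """Encode one item as a vector of length ``n_verbs + 5``.

    Layout: [one-hot lexical | causative flag | event_merge, autonomy,
    requires, directive].
    """
    if not 0 <= item.verb_id < n_verbs:
        raise IndexError(f"verb_id {item.verb_id} out of range for n_verbs={n_verbs}")
    x = np.zeros(n_verbs + N_EXTRA_UNITS)
    x[item.verb_id] = 1.0
    x[n_verbs] = float(item.causative_flag)
    x[n_verbs + 1 :] = item.sem
    return x


def encode_target(target: Target) -> np.ndarray:
    """One-hot target over (LESS, MORE, OTHER)."""
    y = np.zeros(3)
    y[int(target)] = 1.0
    return y


def encode_query(verb: VerbEntry, n_verbs: int) -> np.ndarray:
    """Encode the test-time interrogation for a causative form of ``verb``.

    The lexical unit is on, the causative node is set to 1, and the semantic
    units carry the verb's stored ratings.
    """
    if not 0 <= verb.verb_id < n_verbs:
        raise IndexError(f"verb_id {verb.verb_id} out of range for n_verbs={n_verbs}")
    x = np.zeros(n_verbs + N_EXTRA_UNITS)
    x[verb.verb_id] = 1.0
    x[n_verbs] = 1.0
    x[n_verbs + 1 :] = verb.sem
    return x


def encode_stream(stream: TrainingStream) -> tuple[np.ndarray, np.ndarray]:
    """Encode a whole stream as (X, y) arrays for vectorized training.

    X has shape (n, n_verbs + 5); y holds integer targets.
    """
    lang = stream.lang
    n = len(stream)
    X = np.zeros((n, lang.n_verbs + N_EXTRA_UNITS))
    X[np.arange(n), stream.verb_ids] = 1.0
    causative = (stream.targets != int(Target.OTHER)).astype(float)
    X[:, lang.n_verbs] = causative
    X[:, lang.n_verbs + 1 :] = lang.sem_matrix()[stream.verb_ids]
    return X, stream.targets.copy()


def aggregate_stream(stream: TrainingStream) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse a stream to its unique (verb, construction) cells.

    Returns (X_unique, y_unique, weights) where weights are cell counts.
    Because the encoded input is a deterministic function of the (verb,
    target) pair, full-batch losses over the stream equal weighted losses
    over at most ``3 * n_verbs`` unique rows — a large speedup for the
    quasi-Newton baseline fit.
    """
    counts = stream.cell_counts()
    verb_ids, targets = np.nonzero(counts)
    w = counts[verb_ids, targets].astype(float)
    sub = TrainingStream(stream.lang, verb_ids, targets)
    X, y = encode_stream(sub)
    return X, y, w
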