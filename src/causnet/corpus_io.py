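"""Domain types and delimited-text I/O for language inputs, human trials and predictions.

A *language input* is one row per verb: token counts of the less-transparent
(transitive) causative, the more-transparent (periphrastic) causative, and all
other uses, plus four continuous semantic ratings (event-merge, autonomy,
requires, directive) on a unit scale and an optional valence rating.  These
counts and ratings are the model's entire training evidence for a language.

Human trial files hold one row per participant x verb x form (or prime):
binary accept/reject/equivocal judgments, elicited-production response
categories, or 1-5 continuous acceptability ratings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SEMANTIC_FEATURES = ("event_merge", "autonomy", "requires", "directive")

#: column roles a language-input file must provide
_REQUIRED_ROLES = ("label", "n_less", "n_more", "n_other") + SEMANTIC_FEATURES

#: default role -> column-name mapping (the package's own CSV dialect)
DEFAULT_DIALECT: dict[str, str] = {
    "label": "verb",
    "n_less": "n_less",
    "n_more": "n_more",
    "n_other": "n_other",
    "event_merge": "event_merge",
    "autonomy": "autonomy",
    "requires": "requires",
    "directive": "directive",
    "valence": "valence",
}

TASKS = ("binary_judgment", "production", "continuous_judgment")

#: legal response values per task (continuous ratings are validated numerically)
LEGAL_RESPONSES = {
    "binary_judgment": frozenset({"accept", "reject", "equivocal"}),
    "production": frozenset({"less", "more", "other_missing"}),
}


@dataclass(frozen=True)
class VerbEntry:
    """One verb's corpus counts and semantic ratings."""

    verb_id: int
    label: str
    n_less: int
    n_more: int
    n_other: int
    sem: tuple[float, float, float, float]
    valence: float | None = None

    def __post_init__(self) -> None:
        for name in ("n_less", "n_more", "n_other"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValidationError(
                    f"verb {self.label!r}: {name}={v!r} must be a non-negative integer"
                )
        if len(self.sem) != 4:
            raise ValidationError(f"verb {self.label!r}: sem must have 4 components")
        if any(not (0.0 <= s <= 1.0) for s in self.sem):
            raise ValidationError(
                f"verb {self.label!r}: semantic ratings {self.sem} outside [0, 1]"
            )

    @property
    def total(self) -> int:
        return self.n_less + self.n_more + self.n_other


@dataclass(frozen=True)
class LanguageInput:
    """An ordered collection of verbs for one language."""

    language: str
    verbs: tuple[VerbEntry, ...]

    def __post_init__(self) -> None:
        labels = [v.label for v in self.verbs]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate verb labels: {dupes}")
        ids = [v.verb_id for v in self.verbs]
        if ids != list(range(len(ids))):
            raise ValidationError("verb_id must be the dense 0-based file order")
        if self.verbs and all(v.total == 0 for v in self.verbs):
            raise ValidationError("at least one verb must have a positive total count")

    @property
    def n_verbs(self) -> int:
        return len(self.verbs)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(v.label for v in self.verbs)

    def counts(self) -> np.ndarray:
        """(n_verbs, 3) array of (less, more, other) token counts."""
        return np.array([[v.n_less, v.n_more, v.n_other] for v in self.verbs], dtype=float)

    def sem_matrix(self) -> np.ndarray:
        """(n_verbs, 4) array of semantic ratings."""
        return np.array([v.sem for v in self.verbs], dtype=float)

    def by_label(self, label: str) -> VerbEntry:
        for v in self.verbs:
            if v.label == label:
                return v
        raise KeyError(label)

    def with_sem_matrix(self, sem: np.ndarray) -> "LanguageInput":
        """Copy of this language with replaced semantic ratings (counts untouched)."""
        if sem.shape != (self.n_verbs, 4):
            raise ValidationError(f"sem matrix shape {sem.shape} != ({self.n_verbs}, 4)")
        verbs = tuple(
            replace(v, sem=tuple(float(x) for x in sem[i]))
            for i, v in enumerate(self.verbs)
        )
        return LanguageInput(self.language, verbs)


@dataclass(frozen=True)
class TrialTable:
    """Human trial data for one task.

    ``data`` columns: participant, age_group, verb, form (judgment tasks) or
    prime (production), response.  Equivocal binary responses are kept here and
    excluded only during aggregation.
    """

    task: str
    data: pd.DataFrame = field(compare=False)
    age_group: str | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}; expected one of {TASKS}")
        required = {"participant", "verb", self.form_column, "response"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"trial table missing columns: {sorted(missing)}")
        resp = self.data["response"]
        if self.task == "continuous_judgment":
            vals = pd.to_numeric(resp, errors="coerce")
            bad = vals.isna() | (vals < 1) | (vals > 5) | (vals != vals.round())
            if bad.any():
                raise ValidationError(
                    f"{int(bad.sum())} continuous responses outside the integer 1-5 scale"
                )
        else:
            legal = LEGAL_RESPONSES[self.task]
            bad = ~resp.isin(legal)
            if bad.any():
                raise ValidationError(
                    f"illegal {self.task} responses: {sorted(resp[bad].unique())}"
                )

    @property
    def form_column(self) -> str:
        return "prime" if self.task == "production" else "form"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return (
            self.task == other.task
            and self.age_group == other.age_group
            and self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited text file with a header row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # sniff the delimiter from the header line
    header = path.open().readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_language_input(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    language: str | None = None,
) -> LanguageInput:
    """Read a per-verb language-input file.

    ``dialect`` maps column roles (label, the three counts, the four semantic
    ratings, optionally valence) to the column names actually present, so any
    deposited file layout can be declared without code changes.  Semantic
    ratings outside [0, 1] are min-max rescaled per column with a warning.
    Verb ids follow file order.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = _read_delimited(path)
    for role in _REQUIRED_ROLES:
        if dialect[role] not in df.columns:
            raise FormatError(
                f"missing column {dialect[role]!r} for role {role!r} in {path}"
            )
    labels = df[dialect["label"]].astype(str)
    if labels.duplicated().any():
        raise ValidationError(
            f"duplicate verb labels: {sorted(labels[labels.duplicated()].unique())}"
        )

    sem = df[[dialect[f] for f in SEMANTIC_FEATURES]].astype(float).to_numpy()
    for j, feat in enumerate(SEMANTIC_FEATURES):
        col = sem[:, j]
        if col.min() < 0.0 or col.max() > 1.0:
            lo, hi = col.min(), col.max()
            sem[:, j] = (col - lo) / (hi - lo) if hi > lo else 0.5
            logger.warning(
                "column %r outside [0,1] (range %.3g..%.3g); min-max rescaled",
                feat, lo, hi,
            )

    has_valence = dialect.get("valence") in df.columns

    verbs = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        counts = {}
        for role in ("n_less", "n_more", "n_other"):
            raw = rowd[dialect[role]]
            val = float(raw)
            if not val.is_integer() or val < 0:
                raise ValidationError(
                    f"verb {labels.iloc[i]!r}: {role}={raw!r} is not a non-negative integer"
                )
            counts[role] = int(val)
        verbs.append(
            VerbEntry(
                verb_id=i,
                label=str(labels.iloc[i]),
                sem=tuple(float(x) for x in sem[i]),
                valence=float(rowd[dialect["valence"]]) if has_valence else None,
                **counts,
            )
        )
    lang = language or Path(path).stem
    return LanguageInput(language=lang, verbs=tuple(verbs))


def write_language_input(lang: LanguageInput, path: str | Path) -> Path:
    """Write a LanguageInput in the package's default CSV dialect."""
    path = Path(path)
    rows = {
        "verb": [v.label for v in lang.verbs],
        "n_less": [v.n_less for v in lang.verbs],
        "n_more": [v.n_more for v in lang.verbs],
        "n_other": [v.n_other for v in lang.verbs],
    }
    sem = lang.sem_matrix()
    for j, feat in enumerate(SEMANTIC_FEATURES):
        rows[feat] = sem[:, j]
    if any(v.valence is not None for v in lang.verbs):
        rows["valence"] = [v.valence for v in lang.verbs]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def read_human_trials(
    path: str | Path, task: str, age_group: str | None = None
) -> TrialTable:
    """Read a trial file for the given task.

    Rows whose response cannot be interpreted at all (empty/garbage) are
    dropped with a logged count; responses that parse but violate the task's
    scale (e.g. a rating of 6) raise a validation error.
    """
    if task not in TASKS:
        raise ValidationError(f"unknown task {task!r}")
    df = _read_delimited(path)
    form_col = "prime" if task == "production" else "form"
    required = {"participant", "verb", form_col, "response"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"trial file {path} missing columns: {sorted(missing)}")
    if "age_group" not in df.columns:
        df["age_group"] = age_group

    if task == "continuous_judgment":
        numeric = pd.to_numeric(df["response"], errors="coerce")
        unparseable = numeric.isna()
        out_of_scale = ~unparseable & ((numeric < 1) | (numeric > 5) | (numeric != numeric.round()))
        if out_of_scale.any():
            raise ValidationError(
                f"{int(out_of_scale.sum())} ratings outside the integer 1-5 scale in {path}"
            )
        df = df[~unparseable].copy()
        df["response"] = numeric[~unparseable].astype(int)
        n_dropped = int(unparseable.sum())
    else:
        legal = LEGAL_RESPONSES[task]
        ok = df["response"].isin(legal)
        n_dropped = int((~ok).sum())
        df = df[ok].copy()
    if n_dropped:
        logger.info("dropped %d unparseable responses from %s", n_dropped, path)

    cols = ["participant", "age_group", "verb", form_col, "response"]
    return TrialTable(task=task, data=df[cols].reset_index(drop=True), age_group=age_group)


def write_human_trials(table: TrialTable, path: str | Path) -> Path:
    table.data.to_csv(path, index=False)
    return Path(path)


PREDICTION_COLUMNS = ["run", "epoch", "verb", "p_less", "p_more", "p_other"]


def write_predictions(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format prediction table (run, epoch, verb, p_less, p_more, p_other).

    Probabilities are written with enough digits that a round trip reproduces
    them to at least 12 significant figures.
    """
    if records.empty:
        raise ValidationError("prediction table is empty")
    missing = set(PREDICTION_COLUMNS) - set(records.columns)
    if missing:
        raise FormatError(f"prediction table missing columns: {sorted(missing)}")
    out = records[PREDICTION_COLUMNS + [c for c in records.columns if c not in PREDICTION_COLUMNS]]
    out.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"prediction file {path} missing columns: {sorted(missing)}")
    return df
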