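"""Experimental protocols: multi-run trajectories, split-half hold-out,
semantics shuffling, corpus log loss, and the factorial hyperparameter grid.

Every condition is run as ``config.runs`` independent replicates differing in
their initial random weights (and, where applicable, their split-half
partition and semantic permutation); reported predictions are averaged over
runs.  Seeds are derived per (base seed, condition, run) so any condition is
reproducible in isolation.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import LanguageInput
from .encoding import TrainingStream, build_training_stream, encode_stream
from .errors import DegenerateInputError
from .learner import ModelConfig, Network, init_network, predict_all, train_one_epoch

PREDICTION_COLUMNS = [
    "run", "epoch", "verb", "p_less", "p_more", "p_other",
    "split_half", "semantics", "corpus", "held_out",
]


@dataclass(frozen=True)
class ConditionTags:
    """Protocol flags identifying one experimental condition."""

    split_half: bool = False
    semantics: str = "real"          # "real" | "shuffled"
    corpus: str = "adult_directed"   # "adult_directed" | "child_directed"

    def key(self) -> int:
        """Stable small integer identifying this condition (for seed derivation)."""
        tag = f"{self.split_half}|{self.semantics}|{self.corpus}"
        return zlib.crc32(tag.encode()) & 0x7FFFFFFF


def run_seed(base_seed: int, tags: ConditionTags, run: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, tags.key(), run])


def split_half_assign(
    verb_ids: set[int] | Sequence[int], rng: np.random.Generator
) -> tuple[set[int], set[int]]:
    """Uniformly random partition into train (ceil(n/2)) and held-out halves."""
    ids = np.array(sorted(verb_ids))
    if len(ids) < 2:
        raise DegenerateInputError("split-half needs at least 2 verbs")
    perm = rng.permutation(len(ids))
    n_train = -(-len(ids) // 2)
    return set(ids[perm[:n_train]].tolist()), set(ids[perm[n_train:]].tolist())


def shuffle_semantics(lang: LanguageInput, rng: np.random.Generator) -> LanguageInput:
    """Randomly permute the verb -> semantic-vector mapping.

    Destroys any systematic relation between a verb's semantics and its
    construction counts while preserving the multiset of rating vectors,
    the counts, labels and valence.
    """
    if lang.n_verbs < 2:
        return lang
    perm = rng.permutation(lang.n_verbs)
    return lang.with_sem_matrix(lang.sem_matrix()[perm])


def run_condition(
    lang: LanguageInput,
    config: ModelConfig,
    tags: ConditionTags = ConditionTags(),
    return_networks: bool = False,
):
    """Run one condition: ``config.runs`` training replicates over ``config.epochs``.

    Per run, a fresh network is initialized and trained epoch by epoch on
    streams sampled from the (possibly semantics-shuffled, possibly
    split-restricted) corpus; after every epoch each verb is queried in a
    causative context.  With ``config.epochs == 0`` the initialization
    predictions are recorded at epoch 0.

    Returns a long DataFrame with one row per run x epoch x verb (and the
    final per-run networks and their training languages if
    ``return_networks``).
    """
    rows = []
    networks: list[tuple[Network, LanguageInput]] = []
    for run in range(config.runs):
        rng = np.random.default_rng(run_seed(config.seed, tags, run))
        lang_r = shuffle_semantics(lang, rng) if tags.semantics == "shuffled" else lang
        if tags.split_half:
            train_ids, test_ids = split_half_assign(range(lang.n_verbs), rng)
        else:
            train_ids, test_ids = None, set()
        net = init_network(config, lang.n_verbs, rng)

        def record(epoch: int) -> None:
            probs = predict_all(net, lang_r)
            for v in range(lang.n_verbs):
                rows.append((
                    run, epoch, lang.verbs[v].label,
                    probs[v, 0], probs[v, 1], probs[v, 2],
                    tags.split_half, tags.semantics, tags.corpus,
                    v in test_ids,
                ))

        if config.epochs == 0:
            record(0)
        stream = None
        for epoch in range(config.epochs):
            if stream is None or config.resample_each_epoch:
                stream = build_training_stream(
                    lang_r, config.items_per_epoch, rng, included_verbs=train_ids
                )
            net, _ = train_one_epoch(net, stream, config)
            record(net.epoch)
        networks.append((net, lang_r))

    records = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    if return_networks:
        return records, networks
    return records


def mean_predictions(records: pd.DataFrame) -> pd.DataFrame:
    """Average probabilities over runs, per epoch x verb."""
    keep = ["epoch", "verb"]
    out = (
        records.groupby(keep, sort=False)[["p_less", "p_more", "p_other"]]
        .mean()
        .reset_index()
    )
    return out


def model_by_verb(
    records: pd.DataFrame, epoch: int | None = None, held_out_only: bool = False
) -> pd.DataFrame:
    """Run-averaged by-verb predictions at one epoch (default: the last).

    ``held_out_only`` restricts the average to runs in which the verb was
    held out of training (split-half conditions).  Adds a ``diff`` column
    (p_less - p_more), the model-side difference score.
    """
    if epoch is None:
        epoch = int(records["epoch"].max())
    sub = records[records["epoch"] == epoch]
    if held_out_only:
        sub = sub[sub["held_out"]]
    out = (
        sub.groupby("verb", sort=False)[["p_less", "p_more", "p_other"]]
        .mean()
        .reset_index()
    )
    out["diff"] = out["p_less"] - out["p_more"]
    return out


def held_out_mean_r(
    records: pd.DataFrame, target: pd.Series, epoch: int | None = None
) -> float:
    """Mean over runs of the per-run Pearson r between held-out-verb
    difference scores and a by-verb target.

    Correlating within each run before averaging matters: all verbs held out
    of the same run face the same trained network, so any run-level shift in
    the learned construction base rate (which depends on which verbs happened
    to be excluded from training) enters as an additive constant that Pearson
    r discards.  Correlating run-averaged predictions instead lets those
    composition shifts leak back in as spurious by-verb signal, because each
    verb is held out in a different subset of runs.
    """
    if epoch is None:
        epoch = int(records["epoch"].max())
    sub = records[(records["epoch"] == epoch) & records["held_out"]]
    rs = []
    for _, g in sub.groupby("run"):
        d = (g["p_less"] - g["p_more"]).to_numpy()
        t = target.reindex(g["verb"]).to_numpy(dtype=float)
        ok = ~np.isnan(t)
        if ok.sum() >= 3 and d[ok].std() > 0 and t[ok].std() > 0:
            rs.append(np.corrcoef(d[ok], t[ok])[0, 1])
    return float(np.mean(rs)) if rs else float("nan")


def corpus_log_loss(net: Network, lang: LanguageInput) -> float:
    """Mean negative log predicted probability of the true construction.

    Weighted by the corpus (verb, construction) counts, with the causative
    input node at 1 for causative tokens and 0 for "other" tokens.  A
    zero-weight network scores log 3; a perfect predictor scores 0.
    """
    counts = lang.counts()
    if counts.sum() <= 0:
        raise DegenerateInputError("corpus has zero total count")
    verb_ids, targets = np.nonzero(counts)
    w = counts[verb_ids, targets]
    sub = TrainingStream(lang, verb_ids, targets)
    X, y = encode_stream(sub)
    p = net.predict_proba(X)
    logp = np.log(np.clip(p[np.arange(len(y)), y], 1e-300, None))
    return float(-(w * logp).sum() / w.sum())


# ---------------------------------------------------------------------------
# hyperparameter grid
# ---------------------------------------------------------------------------

#: the full factorial design: 5 adult-directed languages plus the 3 languages
#: with child-directed corpora
DEFAULT_GRID_CORPORA = (
    "english_adult", "hebrew_adult", "hindi_adult", "japanese_adult", "kiche_adult",
    "english_child", "hebrew_child", "japanese_child",
)
DEFAULT_GRID = {
    "epochs": (2, 5, 15, 50),
    "hidden_layers": ((4,), (10,), (4, 4), (8, 8)),
    "dropout": (0.0, 0.75),
    "annealing": (0.0, 0.75),
}
DEFAULT_PROTOCOLS = {
    "split_half": (False, True),
    "semantics": ("real", "shuffled"),
}


@dataclass(frozen=True)
class GridCell:
    """One model of the factorial design."""

    corpus: str
    split_half: bool
    semantics: str
    epochs: int
    hidden_layers: tuple[int, ...]
    dropout: float
    annealing: float


def enumerate_grid(
    corpora: Sequence[str] = DEFAULT_GRID_CORPORA,
    grid: Mapping[str, Sequence] | None = None,
    protocols: Mapping[str, Sequence] | None = None,
) -> list[GridCell]:
    """Enumerate every distinct model of the factorial design.

    With the defaults this is 8 corpora x 2 split x 2 semantics x 4 epochs x
    4 architectures x 2 dropout x 2 annealing = 2,048 models.
    """
    g = {**DEFAULT_GRID, **(grid or {})}
    p = {**DEFAULT_PROTOCOLS, **(protocols or {})}
    cells = []
    for corpus, split, sem, ep, arch, dr, an in itertools.product(
        corpora, p["split_half"], p["semantics"],
        g["epochs"], g["hidden_layers"], g["dropout"], g["annealing"],
    ):
        cells.append(GridCell(corpus, split, sem, ep, tuple(arch), dr, an))
    return cells


def grid_search(
    lang_inputs: Mapping[str, LanguageInput],
    grid: Mapping[str, Sequence] | None = None,
    human_targets: Mapping[str, Mapping[str, pd.Series]] | None = None,
    base_config: ModelConfig | None = None,
    protocols: Mapping[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Run every grid cell and rank the results by corpus log loss.

    ``lang_inputs`` maps corpus name -> LanguageInput; only cells whose corpus
    is present are run.  ``human_targets`` maps corpus name -> {dataset name
    -> by-verb Series} of human measures; each cell gets a Pearson r per
    dataset (NaN when the corpus has no such target).  L1, L2 and the
    learning rate stay fixed at the base config's values (0.01 by default).

    Returns one row per cell with the config summary, ``log_loss`` (mean
    over runs of the final network's corpus log loss) and ``r_<dataset>``
    columns, sorted ascending by log loss with a dense ``rank``.
    """
    base = base_config or ModelConfig.extended((4,))
    human_targets = human_targets or {}
    cells = [
        c for c in enumerate_grid(tuple(lang_inputs), grid, protocols)
    ]
    dataset_names = sorted({d for t in human_targets.values() for d in t})
    rows = []
    for cell in cells:
        lang = lang_inputs[cell.corpus]
        config = replace(
            base,
            hidden_layers=cell.hidden_layers,
            epochs=cell.epochs,
            dropout=cell.dropout,
            annealing=cell.annealing,
        )
        tags = ConditionTags(
            split_half=cell.split_half, semantics=cell.semantics, corpus=cell.corpus
        )
        records, networks = run_condition(lang, config, tags, return_networks=True)
        log_loss = float(np.mean([corpus_log_loss(net, lr) for net, lr in networks]))
        row = {
            "corpus": cell.corpus,
            "split_half": cell.split_half,
            "semantics": cell.semantics,
            "epochs": cell.epochs,
            "hidden_layers": "x".join(map(str, cell.hidden_layers)),
            "dropout": cell.dropout,
            "annealing": cell.annealing,
            "log_loss": log_loss,
        }
        targets = human_targets.get(cell.corpus, {})
        model = model_by_verb(records).set_index("verb")["diff"]
        for name in dataset_names:
            target = targets.get(name)
            if target is None:
                row[f"r_{name}"] = float("nan")
            elif cell.split_half:
                # per-run correlation on each run's held-out half, averaged
                row[f"r_{name}"] = held_out_mean_r(records, target)
            else:
                row[f"r_{name}"] = _safe_r(model, target)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("log_loss", kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _safe_r(model: pd.Series, target: pd.Series | None) -> float:
    if target is None:
        return float("nan")
    shared = model.index.intersection(target.index)
    if len(shared) < 3:
        return float("nan")
    x, y = model.loc[shared].astype(float), target.loc[shared].astype(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
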