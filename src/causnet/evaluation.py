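"""Aggregating human trials to by-verb measures and scoring model-human fit.

By-verb measures: acceptance proportions from children's binary judgments
(equivocal responses excluded before the denominator), mean 1-5 ratings from
adults, production proportions (non-causative responses treated as missing),
and less-minus-more difference scores.  Model-human fit is summarized by
Pearson correlations with one-tailed critical values, and group-level
overgeneralization is classified by the child-minus-adult difference of
by-verb z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import TrialTable
from .errors import ConfigurationError, DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

MEASURE_COLUMNS = ["verb", "kind", "value", "n"]


def aggregate_judgments(trials: TrialTable) -> pd.DataFrame:
    """By-verb x form acceptance proportions (binary) or mean ratings (continuous).

    Binary: proportion *accept* among accept/reject responses, with equivocal
    responses excluded before the denominator.  Cells with zero usable
    responses get no value row but keep ``n = 0``.

    Returns a tidy frame (verb, kind, value, n) with kinds like
    ``accept_prop_less`` or ``mean_rating_more``.
    """
    if trials.task not in ("binary_judgment", "continuous_judgment"):
        raise ValidationError(f"aggregate_judgments got task {trials.task!r}")
    df = trials.data
    rows = []
    prefix = "accept_prop" if trials.task == "binary_judgment" else "mean_rating"
    for (verb, form), cell in df.groupby(["verb", "form"], sort=False):
        if trials.task == "binary_judgment":
            usable = cell[cell["response"].isin(["accept", "reject"])]
            n = len(usable)
            value = float((usable["response"] == "accept").mean()) if n else np.nan
        else:
            n = len(cell)
            value = float(cell["response"].astype(float).mean()) if n else np.nan
        rows.append((verb, f"{prefix}_{form}", value, n))
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


def aggregate_production(trials: TrialTable) -> pd.DataFrame:
    """By-verb proportion of less-transparent productions among causative responses.

    ``other_missing`` responses are excluded as missing data; ``n`` records
    the causative denominator.  Verbs with no causative response get
    ``value = NaN, n = 0``.
    """
    if trials.task != "production":
        raise ValidationError(f"aggregate_production got task {trials.task!r}")
    rows = []
    for verb, cell in trials.data.groupby("verb", sort=False):
        causative = cell[cell["response"].isin(["less", "more"])]
        n = len(causative)
        value = float((causative["response"] == "less").mean()) if n else np.nan
        rows.append((verb, "prod_prop_less", value, n))
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


def difference_scores(m_less: pd.DataFrame, m_more: pd.DataFrame) -> pd.DataFrame:
    """Per-verb less-minus-more difference scores.

    Computed on the intersection of verbs with values on both sides; excluded
    labels are logged.  Works identically for human measures and for model
    probabilities tabulated in the same (verb, kind, value, n) form.
    """
    less = m_less.dropna(subset=["value"]).set_index("verb")
    more = m_more.dropna(subset=["value"]).set_index("verb")
    shared = less.index.intersection(more.index)
    excluded = less.index.symmetric_difference(more.index)
    if len(excluded):
        logger.info("difference_scores: excluded verbs without both sides: %s",
                    sorted(excluded))
    rows = [
        (v, "diff_score",
         float(less.loc[v, "value"] - more.loc[v, "value"]),
         int(min(less.loc[v, "n"], more.loc[v, "n"])))
        for v in shared
    ]
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    critical_r_05: float
    critical_r_01: float
    significant_05: bool
    significant_01: bool


def critical_r(df: int, alpha: float, tails: str = "one") -> float:
    """Critical Pearson r at the given df: ``t / sqrt(t^2 + df)``.

    ``t`` is the upper-tail Student quantile at ``alpha`` (one-tailed) or
    ``alpha / 2`` (two-tailed).  At df = 58 the one-tailed values are 0.21
    (alpha .05) and 0.30 (alpha .01) to two decimals.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if df < 1:
        raise ConfigurationError("df must be >= 1")
    if tails not in ("one", "two"):
        raise ConfigurationError("tails must be 'one' or 'two'")
    a = alpha if tails == "one" else alpha / 2
    t = stats.t.ppf(1 - a, df)
    return float(t / np.sqrt(t * t + df))


def pearson_r(x, y, tails: str = "one") -> CorrelationResult:
    """Pearson product-moment correlation with one- or two-tailed critical values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson_r needs two equal-length vectors of >= 3 items")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("correlation undefined: zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    c05 = critical_r(n - 2, 0.05, tails)
    c01 = critical_r(n - 2, 0.01, tails)
    return CorrelationResult(
        r=r, n=n, critical_r_05=c05, critical_r_01=c01,
        significant_05=bool(abs(r) >= c05 if tails == "two" else r >= c05),
        significant_01=bool(abs(r) >= c01 if tails == "two" else r >= c01),
    )


@dataclass(frozen=True)
class OvergenClassification:
    verb: str
    delta_z: float
    category: str   # overgeneralization | undergeneralization | match
    threshold: float


def classify_overgeneralization(
    child: pd.DataFrame, adult: pd.DataFrame, threshold: float = 1.5
) -> list[OvergenClassification]:
    """Classify group-level over/under-generalization per verb.

    Both sides are z-scored across the shared verbs (sample standard
    deviation), so the classification is invariant to affine rescaling of
    either scale — child proportions and adult 1-5 means are directly
    comparable.  ``delta_z = z_child - z_adult``; values at or beyond
    ``+threshold`` are overgeneralization (the group accepts a form adults
    reject), at or beyond ``-threshold`` undergeneralization.
    """
    c = child.dropna(subset=["value"]).set_index("verb")["value"]
    a = adult.dropna(subset=["value"]).set_index("verb")["value"]
    shared = sorted(c.index.intersection(a.index))
    if len(shared) < 3:
        raise DegenerateInputError("need >= 3 shared verbs")
    cv = c.loc[shared].astype(float).to_numpy()
    av = a.loc[shared].astype(float).to_numpy()
    if cv.std(ddof=1) == 0 or av.std(ddof=1) == 0:
        raise DegenerateInputError("classification undefined: zero variance")
    zc = (cv - cv.mean()) / cv.std(ddof=1)
    za = (av - av.mean()) / av.std(ddof=1)
    out = []
    for verb, dz in zip(shared, zc - za):
        if dz >= threshold:
            cat = "overgeneralization"
        elif dz <= -threshold:
            cat = "undergeneralization"
        else:
            cat = "match"
        out.append(OvergenClassification(verb, float(dz), cat, threshold))
    return out


def expected_extreme_count(n_draws: int, q: float) -> float:
    """Expected number of Uniform(0,1) draws at or above ``q``: ``n * (1 - q)``.

    The sanity check for a large grid of correlation coefficients: even pure
    noise yields many nominally high values.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    if not 0.0 <= q <= 1.0:
        raise ConfigurationError("q must lie in [0, 1]")
    return float(n_draws) * (1.0 - q)
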