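"""Synthetic languages and simulated raters with known ground truth.

The generator emulates the statistical shape of the study's empirical
inputs so every pipeline stage is testable without any download:

* a latent internal-causation scalar ``theta`` in [0, 1] per verb (high =
  internally caused, *laugh*-like; low = externally caused, *break*-like);
* four noisy semantic ratings that load on ``theta`` with distinct signed
  weights, mimicking the redundant, intercorrelated human ratings;
* Zipf-skewed total verb frequencies, split into causative tokens (whose
  less/more division follows a ground-truth logistic in ``theta``) and
  "other" uses;
* adult 1-5 acceptability ratings, child binary judgments with an additive
  leniency bias toward acceptance, and primed child production with an
  optional prime effect and a missing-response fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .corpus_io import (
    LanguageInput,
    TrialTable,
    VerbEntry,
    write_human_trials,
    write_language_input,
)
from .errors import ConfigurationError

_EPS = 1e-6


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic world.

    The ground-truth construction preference is
    ``P(less | causative, theta) = expit(pref_intercept + pref_slope * (0.5 - theta))``:
    with a positive slope, externally-caused verbs (low ``theta``) prefer the
    transitive (less-transparent) causative.
    """

    n_verbs: int = 60
    theta_dist: str = "uniform"
    sem_loadings: tuple[float, float, float, float] = (0.9, 0.7, 0.8, 0.6)
    sem_noise_sd: float = 0.08
    freq_shape: float = 1.0
    total_tokens: int = 100_000
    p_causative: float = 0.15
    pref_intercept: float = 0.0
    pref_slope: float = 6.0
    kappa: float = 0.5            # attenuation of the more-form's dispreference
    adult_noise_sd: float = 0.5
    n_adults: int = 48
    n_children: int = 48
    child_leniency: float = 1.0
    equivocal_rate: float = 0.02
    prime_effect: float = 1.0
    other_missing_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_verbs < 2:
            raise ConfigurationError("n_verbs must be >= 2")
        if self.total_tokens < self.n_verbs:
            raise ConfigurationError("total_tokens must be >= n_verbs")
        if not np.isfinite(self.pref_slope) or not np.isfinite(self.pref_intercept):
            raise ConfigurationError("preference parameters must be finite")
        for name in ("p_causative", "kappa", "equivocal_rate", "other_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        if self.theta_dist != "uniform":
            raise ConfigurationError(f"unknown theta_dist {self.theta_dist!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class GroundTruth:
    """Per-verb latent state of a synthetic language (the recovery target)."""

    data: pd.DataFrame = field(compare=False)   # verb, theta, p_less_causative, total_freq, sem_*

    @property
    def theta(self) -> np.ndarray:
        return self.data["theta"].to_numpy()

    @property
    def p_less(self) -> np.ndarray:
        """True P(less-transparent | causative) per verb."""
        return self.data["p_less_causative"].to_numpy()

    def acceptability(self, form: str, kappa: float) -> np.ndarray:
        """Latent acceptability in [0, 1] of the given form per verb.

        The less-transparent form's acceptability equals P(less | causative);
        the more-transparent form's dispreference is attenuated by ``kappa``
        (periphrastic causatives are rarely fully unacceptable, so the scale
        is compressed: 1 - kappa * P(less)).
        """
        if form == "less":
            return self.p_less
        if form == "more":
            return 1.0 - kappa * self.p_less
        raise ValueError(f"unknown form {form!r}")

    @property
    def diff(self) -> np.ndarray:
        """Ground-truth less-minus-more preference per verb."""
        return 2.0 * self.p_less - 1.0

    @property
    def verbs(self) -> list[str]:
        return self.data["verb"].tolist()


def _true_p_less(spec: SyntheticSpec, theta: np.ndarray) -> np.ndarray:
    return expit(spec.pref_intercept + spec.pref_slope * (0.5 - theta))


def generate_language(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[LanguageInput, GroundTruth]:
    """Draw one synthetic language and its ground truth.

    Semantic rating j of verb v is ``clip(0.5 + loading_j * (0.5 - theta_v)
    + noise, 0, 1)``; total verb frequencies are a multinomial over
    Zipf(freq_shape) weights on a random frequency ranking; each verb's
    tokens split into causative vs other by ``p_causative`` and its causative
    tokens into less vs more by the ground-truth logistic.
    """
    n = spec.n_verbs
    theta = rng.uniform(0.0, 1.0, size=n)
    loadings = np.asarray(spec.sem_loadings, dtype=float)
    sem_mean = np.clip(0.5 + np.outer(0.5 - theta, loadings), 0.0, 1.0)
    sem = np.clip(sem_mean + rng.normal(0.0, spec.sem_noise_sd, size=(n, 4)), 0.0, 1.0)

    ranks = rng.permutation(n)
    w = 1.0 / (ranks + 1.0) ** spec.freq_shape
    totals = rng.multinomial(spec.total_tokens, w / w.sum())

    p_less = _true_p_less(spec, theta)
    n_caus = rng.binomial(totals, spec.p_causative)
    n_less = rng.binomial(n_caus, p_less)
    n_more = n_caus - n_less
    n_other = totals - n_caus

    verbs = tuple(
        VerbEntry(
            verb_id=i,
            label=f"v{i:03d}",
            n_less=int(n_less[i]),
            n_more=int(n_more[i]),
            n_other=int(n_other[i]),
            sem=tuple(float(x) for x in sem[i]),
        )
        for i in range(n)
    )
    lang = LanguageInput(language="synthetic", verbs=verbs)
    gt = GroundTruth(
        pd.DataFrame({
            "verb": [v.label for v in verbs],
            "theta": theta,
            "p_less_causative": p_less,
            "total_freq": totals,
            **{f"sem_mean_{j}": sem_mean[:, j] for j in range(4)},
        })
    )
    return lang, gt


def generate_adult_judgments(
    gt: GroundTruth, spec: SyntheticSpec, rng: np.random.Generator
) -> TrialTable:
    """Simulate adult 1-5 ratings: ``round(clip(1 + 4 * acceptability + noise, 1, 5))``."""
    rows = []
    for form in ("less", "more"):
        acc = gt.acceptability(form, spec.kappa)
        for p in range(spec.n_adults):
            noise = rng.normal(0.0, spec.adult_noise_sd, size=len(acc))
            ratings = np.clip(np.rint(1.0 + 4.0 * acc + noise), 1, 5).astype(int)
            for verb, r in zip(gt.verbs, ratings):
                rows.append((f"a{p:03d}", "adult", verb, form, r))
    df = pd.DataFrame(rows, columns=["participant", "age_group", "verb", "form", "response"])
    return TrialTable(task="continuous_judgment", data=df, age_group="adult")


def generate_child_trials(
    gt: GroundTruth, spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[TrialTable, TrialTable]:
    """Simulate child binary judgments and primed production.

    Judgments: ``P(accept) = expit(logit(acceptability) + child_leniency)``,
    with a small equivocal fraction.  Production: a trial per child x verb x
    prime; ``P(produce less) = expit(logit(P(less)) + prime_effect * s)``
    with ``s = +1`` after a less-transparent prime and ``-1`` after a
    more-transparent one; a fraction of trials is other_missing.
    """
    jrows, prows = [], []
    p_less = np.clip(gt.p_less, _EPS, 1.0 - _EPS)
    for form in ("less", "more"):
        acc = np.clip(gt.acceptability(form, spec.kappa), _EPS, 1.0 - _EPS)
        p_accept = expit(logit(acc) + spec.child_leniency)
        for p in range(spec.n_children):
            u = rng.random(len(acc))
            equivocal = rng.random(len(acc)) < spec.equivocal_rate
            for i, verb in enumerate(gt.verbs):
                if equivocal[i]:
                    resp = "equivocal"
                else:
                    resp = "accept" if u[i] < p_accept[i] else "reject"
                jrows.append((f"c{p:03d}", "child", verb, form, resp))
    for prime, s in (("less", 1.0), ("more", -1.0)):
        p_prod = expit(logit(p_less) + spec.prime_effect * s)
        for p in range(spec.n_children):
            missing = rng.random(len(p_prod)) < spec.other_missing_rate
            u = rng.random(len(p_prod))
            for i, verb in enumerate(gt.verbs):
                if missing[i]:
                    resp = "other_missing"
                else:
                    resp = "less" if u[i] < p_prod[i] else "more"
                prows.append((f"c{p:03d}", "child", verb, prime, resp))
    jdf = pd.DataFrame(jrows, columns=["participant", "age_group", "verb", "form", "response"])
    pdf = pd.DataFrame(prows, columns=["participant", "age_group", "verb", "prime", "response"])
    return (
        TrialTable(task="binary_judgment", data=jdf, age_group="child"),
        TrialTable(task="production", data=pdf, age_group="child"),
    )


def retreat_demo_language(
    n_external: int = 20,
    external_counts: tuple[int, int, int] = (250, 25, 1200),
    internal_counts: tuple[int, int, int] = (2, 40, 400),
    loadings: tuple[float, float, float, float] = (0.9, 0.7, 0.8, 0.6),
) -> LanguageInput:
    """A deterministic corpus exhibiting overgeneralize-then-retreat dynamics.

    Many high-frequency externally-caused verbs that overwhelmingly take the
    transitive (less-transparent) causative coexist with one low-frequency
    internally-caused verb (index ``n_external``, a *laugh* analogue) whose
    rare causative uses are periphrastic.  Early in training the model's
    prediction for the rare verb follows the corpus-wide transitive base
    rate (overgeneralization); with continued training its lexical and
    semantic evidence carves out the periphrastic preference.
    """
    loadings = np.asarray(loadings)

    def sem_for(theta: float) -> tuple[float, ...]:
        return tuple(float(x) for x in np.clip(0.5 + loadings * (0.5 - theta), 0, 1))

    verbs = []
    thetas = np.linspace(0.05, 0.30, n_external)
    for i, th in enumerate(thetas):
        less, more, other = external_counts
        verbs.append(VerbEntry(i, f"ext{i:02d}", less, more, other, sem_for(float(th))))
    less, more, other = internal_counts
    verbs.append(VerbEntry(n_external, "laughlike", less, more, other, sem_for(0.95)))
    return LanguageInput(language="retreat_demo", verbs=tuple(verbs))


def write_fixture_set(
    spec: SyntheticSpec, outdir: str | Path, rng: np.random.Generator | None = None
) -> dict[str, Path]:
    """Generate and write a complete fixture set (language, ground truth, trials)."""
    rng = rng or spec.rng()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lang, gt = generate_language(spec, rng)
    adults = generate_adult_judgments(gt, spec, rng)
    binary, production = generate_child_trials(gt, spec, rng)
    paths = {
        "language": write_language_input(lang, outdir / "language.csv"),
        "ground_truth": outdir / "ground_truth.csv",
        "adults": write_human_trials(adults, outdir / "adult_judgments.csv"),
        "child_binary": write_human_trials(binary, outdir / "child_binary.csv"),
        "child_production": write_human_trials(production, outdir / "child_production.csv"),
    }
    gt.data.to_csv(paths["ground_truth"], index=False, float_format="%.12g")
    return paths
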