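import numpy as np
import pytest

from causnet import (
    LanguageInput,
    SyntheticSpec,
    VerbEntry,
    generate_language,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_lang():
    """Three verbs including the worked break-like example."""
    return LanguageInput(
        language="tiny",
        verbs=(
            VerbEntry(0, "laugh", 1, 36, 400, (0.10, 0.20, 0.15, 0.25)),
            VerbEntry(1, "melt", 60, 12, 300, (0.70, 0.65, 0.60, 0.55)),
            VerbEntry(2, "break", 117, 30, 853, (0.90, 0.90, 0.87, 0.85)),
        ),
    )


@pytest.fixture(scope="session")
def synth_world():
    """The default synthetic language and its ground truth (seed 0)."""
    spec = SyntheticSpec()
    lang, gt = generate_language(spec, spec.rng())
    return spec, lang, gt
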