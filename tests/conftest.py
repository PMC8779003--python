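import pytest

from scmpep import SynthSpec, generate, load_reference_card, reference_bundle


@pytest.fixture(scope="session")
def ref_card():
    """The published propensity card (cutoff 301)."""
    return load_reference_card()


@pytest.fixture(scope="session")
def bundle():
    return reference_bundle()


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly composition-biased synthetic data (C/W/R vs I/K/V, bias 8)."""
    return generate(SynthSpec(n_pos=120, n_neg=120, bias=8.0, seed=7))


@pytest.fixture(scope="session")
def null_dataset():
    """No planted signal: bias 1 makes the classes exchangeable."""
    return generate(SynthSpec(n_pos=80, n_neg=80, bias=1.0, seed=11))
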