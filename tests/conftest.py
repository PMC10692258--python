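import pytest

import mcitriage as m
from mcitriage.vocabulary import CANONICAL_QUERIES, RESOURCE_QUERY


@pytest.fixture(scope="session")
def algorithms():
    """The seven bundled algorithm definitions, keyed by name."""
    return {a.name: a for a in m.load_all_bundled()}


def full_answers(**overrides) -> dict[str, str]:
    """A complete all-negative answer vector over the canonical vocabulary,
    with selected queries overridden.

    'All negative' means no finding present: breathing and obeying commands
    are coded 1 (present/normal), everything else 0.
    """
    answers = {q: "0" for q in CANONICAL_QUERIES}
    answers["spontaneous_breathing"] = "1"
    answers["breathing_after_airway_opening"] = "1"
    answers["obeys_commands"] = "1"
    answers[RESOURCE_QUERY] = "0"
    answers.update(overrides)
    return answers


@pytest.fixture
def vignette_factory():
    def make(vid="v1", ref=None, **overrides):
        return m.Vignette(id=vid, answers=full_answers(**overrides), reference_category=ref)

    return make
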