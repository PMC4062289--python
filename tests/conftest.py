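import pytest

from clinterm import fixtures, grammar, inventory


@pytest.fixture(scope="session")
def full_cascade():
    return grammar.default_cascade()


@pytest.fixture(scope="session")
def simplified_cascade():
    return grammar.default_cascade(mode="simplified")


@pytest.fixture(scope="session")
def examples_corpus():
    """The canned worked-example corpus and its analytic ground truth."""
    return fixtures.paper_examples_fixture()


@pytest.fixture(scope="session")
def examples_inventory(examples_corpus, full_cascade):
    sentences, _ = examples_corpus
    return inventory.aggregate(sentences, full_cascade)


def sentence_from(template_name):
    """Build a single Sentence from a built-in template (no final period)."""
    template = fixtures.BUILTIN_TEMPLATES[template_name]
    return fixtures._build_sentence(template.tokens)
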