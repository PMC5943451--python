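import pytest

from suicidality_nlp import (
    ClinicalDocument,
    default_attempt_gazetteer,
    default_ideation_config,
    default_rulebook,
    default_stopwords,
    default_trigger_lexicon,
    preprocess_document,
)


@pytest.fixture(scope="session")
def trigger_lexicon():
    return default_trigger_lexicon()


@pytest.fixture(scope="session")
def attempt_gazetteer():
    return default_attempt_gazetteer()


@pytest.fixture(scope="session")
def rulebook():
    return default_rulebook()


@pytest.fixture(scope="session")
def stopwords():
    return default_stopwords()


@pytest.fixture(scope="session")
def ideation_config():
    return default_ideation_config()


def make_doc(text, doc_id="d1", patient_id="p1", doc_type="event"):
    return ClinicalDocument(
        doc_id=doc_id, patient_id=patient_id, doc_type=doc_type, text=text
    )


@pytest.fixture
def doc_factory():
    return make_doc


@pytest.fixture
def preprocessed_factory():
    def _factory(text, **kwargs):
        return preprocess_document(make_doc(text, **kwargs))

    return _factory
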