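import pytest

from invarel import pipeline, synthetic
from invarel.corpus_io import (Corpus, Document, EntityMention,
                               RelationAnnotation)
from invarel.tagging import RuleTagger


@pytest.fixture(scope="session")
def tagger():
    return RuleTagger()


def make_tiny_corpus() -> Corpus:
    """One hand-built abstract with two mentions and one gold relation."""
    title = "A study ."
    abstract = "The potent agonist alprexate rapidly activates the kinoralin receptor pathway response ."
    doc = Document("D1", title, abstract)
    base = len(title) + 1
    c_start = base + abstract.index("alprexate")
    g_start = base + abstract.index("kinoralin")
    corpus = Corpus(
        documents=[doc],
        entities=[
            EntityMention("D1", "T1", "CHEMICAL", c_start, c_start + 9, "alprexate"),
            EntityMention("D1", "T2", "GENE_PROTEIN", g_start, g_start + 9, "kinoralin"),
        ],
        relations=[RelationAnnotation("D1", "CPR:3", "T1", "T2")])
    corpus.validate()
    return corpus


@pytest.fixture
def tiny_corpus() -> Corpus:
    return make_tiny_corpus()


@pytest.fixture(scope="session")
def synth_train():
    config = synthetic.SyntheticCorpusConfig(
        n_abstracts=30, negatives_fraction=0.25,
        multi_pair_sentence_rate=0.1, seed=11)
    return synthetic.generate_corpus(synthetic.default_templates(), config)


@pytest.fixture(scope="session")
def synth_test():
    config = synthetic.SyntheticCorpusConfig(
        n_abstracts=12, negatives_fraction=0.25, seed=77)
    return synthetic.generate_corpus(synthetic.default_templates(), config)


@pytest.fixture(scope="session")
def trained_model(synth_train):
    corpus, _, _ = synth_train
    return pipeline.train_pipeline(
        corpus, pipeline.PipelineConfig.for_mode("CPI", seed=11))
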