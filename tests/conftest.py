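import pytest

from disner.lexicon import Lexicon
from disner.synthetic import GeneratorConfig, generate_corpus, make_lexicon


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=7, n_docs=30, lexicon_size=20)


@pytest.fixture(scope="session")
def synth_lexicon(gen_config):
    return make_lexicon(gen_config)


@pytest.fixture(scope="session")
def synth_corpus(gen_config, synth_lexicon):
    return generate_corpus(synth_lexicon, gen_config)


@pytest.fixture(scope="session")
def toy_lexicon():
    """Small hand-built disease lexicon with real MeSH-style entries."""
    return Lexicon({
        "D003693": ("Delirium", []),
        "D011618": ("Psychotic Disorders", ["psychosis"]),
        "D058186": ("Acute Kidney Injury", ["acute kidney injury", "AKI"]),
        "D006261": ("Headache", ["head pain", "cephalalgia"]),
        "D010146": ("Pain", ["pain"]),
        "D007674": ("Kidney Diseases", ["kidney injury", "nephropathy"]),
    })
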