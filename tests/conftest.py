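"""Shared fixtures: small synthetic corpora prepared for model training."""

from __future__ import annotations

import pytest

from scidisc import CorpusSpec, generate_discourse_corpus
from scidisc.discourse import make_sequences
from scidisc.features import default_lexicon, extract_features


def corpus_sequences(seed: int, **spec_kwargs):
    """Generate a discourse corpus and return its per-paragraph sequences."""
    lexicon = default_lexicon()
    spec = CorpusSpec(seed=seed, **spec_kwargs)
    sequences = []
    for labeled in generate_discourse_corpus(spec):
        vectors = [
            extract_features(c, labeled.document, lexicon=lexicon)
            for c in labeled.clauses
        ]
        sequences.extend(make_sequences(labeled.clauses, labeled.document, vectors))
    return sequences


@pytest.fixture(scope="session")
def small_sequences():
    """~600 clauses in paragraph sequences; enough to train both models."""
    return corpus_sequences(1, n_documents=8)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()
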