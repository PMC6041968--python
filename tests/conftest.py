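import numpy as np
import pytest

from crossner.corpus_io import Corpus, Document, Span, tokenize


def random_corpus(rng: np.random.Generator, name: str = "rand") -> Corpus:
    """Small random corpus with valid, non-nested spans (shared helper for
    round-trip property tests)."""
    words = ["alpha", "Beta2", "p53", "x", "GAMMA", "delta-9", "mu", "Ω3"]
    docs = []
    for d in range(int(rng.integers(1, 5))):
        n = int(rng.integers(1, 15))
        text = " ".join(words[rng.integers(0, len(words))] for _ in range(n))
        tokens = tokenize(text)
        spans = []
        used: set[int] = set()
        for _ in range(int(rng.integers(0, 4))):
            if not tokens:
                break
            i = int(rng.integers(0, len(tokens)))
            j = min(len(tokens) - 1, i + int(rng.integers(0, 2)))
            if used & set(range(i, j + 1)):
                continue
            used.update(range(i, j + 1))
            start, end = tokens[i].start, tokens[j].end
            label = ["Gene", "Chem"][int(rng.integers(0, 2))]
            spans.append(Span(start, end, text[start:end], label))
        docs.append(Document(f"{name}_d{d}", text, spans))
    return Corpus(name, docs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_doc():
    text = "The BRCA1 gene binds p53 today"
    return Document(
        "doc1",
        text,
        [
            Span(4, 9, "BRCA1", "Gene"),
            Span(21, 24, "p53", "Gene"),
        ],
    )
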