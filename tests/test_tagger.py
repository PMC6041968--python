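"""CRF correctness: features, exact decoding, gradients, determinism."""

import itertools

import numpy as np
import pytest

from crossner.corpus_io import Document, Span, TaggedSequence, Token, tokenize
from crossner.tagger import (
    FeatureConfig,
    SequenceModel,
    TrainConfig,
    _nll_and_grad,
    _Batch,
    _build_design,
    featurize,
    predict_corpus,
    sequence_scores,
    train,
    viterbi_decode,
    word_shape,
)


def toks(*words):
    pos = 0
    out = []
    for w in words:
        out.append(Token(w, pos, pos + len(w)))
        pos += len(w) + 1
    return out


def random_model(rng, n_words=6, scale=1.0) -> SequenceModel:
    """Model with random weights over word-identity features only."""
    feats = {f"w=w{i}": i for i in range(n_words)}
    m = SequenceModel(
        labels=["O", "B-G", "I-G"],
        feature_index=feats,
        emission=rng.normal(0, scale, (n_words, 3)),
        transition=rng.normal(0, scale, (3, 3)),
        start=rng.normal(0, scale, 3),
        fcfg=FeatureConfig(window=0, use_disjunction=False, char_ngram_max=1,
                           use_word_shape=False),
    )
    return m


def brute_force_decode(model: SequenceModel, tokens) -> list[str]:
    """Exhaustive argmax over all 3^n label sequences, same tie-break
    (lexicographically earliest index sequence wins)."""
    E, T, pi = sequence_scores(model, tokens)
    n = len(tokens)
    best, best_score = None, -np.inf
    for labs in itertools.product(range(3), repeat=n):
        s = pi[labs[0]] + E[0, labs[0]]
        for t in range(1, n):
            s += T[labs[t - 1], labs[t]] + E[t, labs[t]]
        if s > best_score:  # strict: first (lexicographically smallest) wins
            best, best_score = labs, s
    return [model.labels[i] for i in best]


# ---------------------------------------------------------------------------
# features


@pytest.mark.parametrize(
    "word,expected_shape",
    [("BRCA", "X"), ("Brca1", "Xxd"), ("p53", "xd"), ("V600E", "XdX"),
     ("+", "+"), ("aa--BB", "x-X")],
)
def test_word_shape_collapses_runs(word, expected_shape):
    assert word_shape(word) == expected_shape


def test_token_feature_flags():
    cfg = FeatureConfig(window=0, use_disjunction=False, char_ngram_max=3)
    [feats] = featurize(toks("BRCA"), cfg)
    assert {"w=BRCA", "lw=brca", "sh=X", "AllCaps", "InitCap",
            "pre1=B", "pre2=BR", "pre3=BRC"} <= set(feats)
    [feats] = featurize(toks("53"), cfg)
    assert {"sh=d", "HasDigit", "AllDigit"} <= set(feats)
    assert "InitCap" not in feats
    [feats] = featurize(toks("+"), cfg)
    assert "sym=+" in feats


def test_context_and_disjunction_features():
    cfg = FeatureConfig(window=1, use_disjunction=True, disjunction_radius=2)
    feats = featurize(toks("a", "b", "c"), cfg)
    assert "w[-1]=<S>" in feats[0] and "w[1]=b" in feats[0]
    assert "w[-1]=b" in feats[2] and "w[1]=</S>" in feats[2]
    assert "dl=a" in feats[2] and "dr=c" in feats[0]


# ---------------------------------------------------------------------------
# decoding


def test_zero_weight_model_decodes_all_O():
    m = random_model(np.random.default_rng(0), scale=0.0)
    tags = viterbi_decode(m, toks("w0", "w1", "w2"))
    assert tags == ["O", "O", "O"]


def test_decoded_sequences_are_wellformed_iob2():
    rng = np.random.default_rng(3)
    for _ in range(50):
        m = random_model(rng, scale=3.0)
        n = int(rng.integers(1, 8))
        words = [f"w{rng.integers(0, 6)}" for _ in range(n)]
        tags = viterbi_decode(m, toks(*words))
        prev = "O"
        for t in tags:
            assert not (t.startswith("I-") and prev == "O")
            prev = t


def test_viterbi_matches_bruteforce_on_short_sequences():
    rng = np.random.default_rng(11)
    for _ in range(100):
        m = random_model(rng, scale=2.0)
        n = int(rng.integers(1, 7))
        words = [f"w{rng.integers(0, 6)}" for _ in range(n)]
        tokens = toks(*words)
        assert viterbi_decode(m, tokens) == brute_force_decode(m, tokens)


# ---------------------------------------------------------------------------
# training


def make_sequences(texts_and_entities):
    """Build TaggedSequences from (text, entity-word-set) pairs."""
    seqs = []
    for i, (text, ents) in enumerate(texts_and_entities):
        tokens = tokenize(text)
        tags = ["B-G" if t.text in ents else "O" for t in tokens]
        seqs.append(TaggedSequence(f"d{i}", tokens, tags))
    return seqs


def test_train_requires_positive_examples():
    seqs = make_sequences([("just plain words", set())])
    with pytest.raises(ValueError, match="no positive"):
        train(seqs)


def test_train_memorizes_separable_data():
    """Entity words unique to entity contexts: training F on the training
    set reaches 1.0 after convergence."""
    data = [
        ("GENEA binds stuff", {"GENEA"}),
        ("stuff binds GENEB", {"GENEB"}),
        ("GENEC and GENEA interact", {"GENEC", "GENEA"}),
        ("nothing here at all", set()),
    ] * 3
    seqs = make_sequences(data)
    model = train(seqs, FeatureConfig(window=1), TrainConfig(max_iterations=200))
    for s in seqs:
        assert viterbi_decode(model, s.tokens) == s.tags


def test_train_deterministic_given_seed():
    data = [("GENEA binds stuff", {"GENEA"}), ("other GENEB here", {"GENEB"})]
    m1 = train(make_sequences(data), tcfg=TrainConfig(seed=5))
    m2 = train(make_sequences(data), tcfg=TrainConfig(seed=5))
    assert np.array_equal(m1.emission, m2.emission)
    assert np.array_equal(m1.transition, m2.transition)
    assert m1.objective == m2.objective


def test_objective_decreases_from_zero_init():
    """The optimizer must improve on the zero-weight objective
    (n_tokens * log 3 per token, plus no penalty)."""
    data = [("GENEA binds stuff", {"GENEA"}), ("other GENEB here", {"GENEB"})]
    seqs = make_sequences(data)
    model = train(seqs)
    n_tokens = sum(len(s.tokens) for s in seqs)
    assert model.objective < n_tokens * np.log(3)


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(21)
    for _ in range(10):
        n_feat, n_lab = 4, 3
        n = int(rng.integers(2, 5))
        feats = {f"f{i}": i for i in range(n_feat)}
        featurized = [[[f"f{rng.integers(0, n_feat)}"] for _ in range(n)]]
        X = _build_design(featurized, feats)
        gold = [np.array([0] + [int(rng.integers(0, 3)) for _ in range(n - 1)])]
        # keep gold IOB2-valid: no I(2) right after O(0)
        for t in range(1, n):
            if gold[0][t] == 2 and gold[0][t - 1] == 0:
                gold[0][t] = 1
        batch = _Batch(X, [n], gold)
        tmask = np.zeros((3, 3)); tmask[0, 2] = -np.inf
        smask = np.zeros(3); smask[2] = -np.inf
        theta = rng.normal(0, 0.5, n_feat * n_lab + n_lab * n_lab + n_lab)
        _, g = _nll_and_grad(theta, batch, n_feat, n_lab, tmask, smask, 1.0)
        num = np.zeros_like(theta)
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fp, _ = _nll_and_grad(tp, batch, n_feat, n_lab, tmask, smask, 1.0)
            fm, _ = _nll_and_grad(tm, batch, n_feat, n_lab, tmask, smask, 1.0)
            num[i] = (fp - fm) / (2 * eps)
        rel = np.linalg.norm(g - num) / max(np.linalg.norm(num), 1e-12)
        assert rel < 1e-4


# ---------------------------------------------------------------------------
# corpus prediction


def test_predict_corpus_replaces_only_target_class():
    from crossner.corpus_io import Corpus

    data = [("GENEA binds stuff", {"GENEA"}), ("other GENEB here", {"GENEB"})]
    model = train(make_sequences(data))
    text = "GENEA binds stuff"
    doc = Document("t1", text, [Span(0, 5, "GENEA", "Other")])
    pred = predict_corpus(model, Corpus("c", [doc]), "G")
    labels = {s.label for s in pred.documents[0].spans}
    assert "Other" in labels  # untouched
    assert Span(0, 5, "GENEA", "G") in pred.documents[0].spans


def test_model_save_load_roundtrip(tmp_path):
    data = [("GENEA binds stuff", {"GENEA"})]
    m = train(make_sequences(data))
    m.save(tmp_path / "m.json")
    m2 = SequenceModel.load(tmp_path / "m.json")
    tokens = tokenize("GENEA binds nothing")
    assert viterbi_decode(m, tokens) == viterbi_decode(m2, tokens)
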