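"""Morphological feature registry, Fisher/BH statistics, balanced testing."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from crossner.corpus_io import Corpus, Document, Span
from crossner.ortho_stats import (
    FEATURE_NAMES,
    balanced_test,
    bh_fdr,
    collect_tokens,
    fingerprint,
    fisher_exact_two_sided,
    morph_features,
)


def fv(token):
    return dict(zip(FEATURE_NAMES, morph_features(token)))


# ---------------------------------------------------------------------------
# feature registry


def test_registry_has_31_distinct_features():
    assert len(FEATURE_NAMES) == 31
    assert len(set(FEATURE_NAMES)) == 31


@pytest.mark.parametrize(
    "token,on,off",
    [
        (
            "V600E",
            {"InitCap", "EndCap", "TwoCap", "ThreeDigit", "HasDigit", "Length3-5"},
            {"OneCap", "OneDigit", "AllDigits", "Plus"},
        ),
        ("+", {"Plus", "Length1"},
         {"InitCap", "AllCaps", "HasDigit", "OneCap"}),
        ("p53", {"HasDigit", "TwoDigit", "Length3-5"},
         {"InitCap", "AllCaps", "MixedCase", "OneCap", "ThreeDigit"}),
        ("BRCA1", {"AllCaps", "InitCap", "OneDigit", "Length3-5", "ThreeCap"}, {"EndCap"}),
        ("123", {"AllDigits", "ThreeDigit", "HasDigit", "Length3-5"}, {"OneDigit"}),
        ("interleukin-2", {"Hyphen", "OneDigit", "LengthGT10"}, {"InitCap"}),
        ("(R)-ibuprofen", {"Parenthesis", "Hyphen", "OneCap", "LengthGT10"},
         {"HasDigit"}),
    ],
)
def test_feature_vectors_on_representative_tokens(token, on, off):
    v = fv(token)
    for name in on:
        assert v[name] == 1, f"{token}: expected {name}=1"
    for name in off:
        assert v[name] == 0, f"{token}: expected {name}=0"


def test_empty_token_rejected():
    with pytest.raises(ValueError):
        morph_features("")


# ---------------------------------------------------------------------------
# collect_tokens


def test_collect_tokens_partitions_document():
    text = "The BRCA1 gene binds p53 protein complex today ok fine"
    doc = Document("d", text, [Span(4, 9, "BRCA1", "G")])
    corpus = Corpus("c", [doc])
    ent, nul = collect_tokens(corpus, "G")
    assert ent == ["BRCA", "1"]  # letter/digit split
    total = len(ent) + len(nul)
    from crossner.corpus_io import project_to_iob

    assert total == len(project_to_iob(doc, "G").tokens)


def test_collect_tokens_missing_class_errors():
    doc = Document("d", "no entities here", [])
    with pytest.raises(ValueError):
        collect_tokens(Corpus("c", [doc]), "G")


# ---------------------------------------------------------------------------
# Fisher exact: enumeration oracle


def fisher_oracle(n11, n12, n21, n22):
    """Two-sided p by enumerating all tables with the observed margins and
    summing those no more probable than the observed one (1e-7 relative
    tolerance on the probability comparison)."""
    r1, r2 = n11 + n12, n21 + n22
    c1 = n11 + n21
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(n11, n, r1, c1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def test_symmetric_table_p_one():
    assert fisher_exact_two_sided(5, 5, 5, 5) == pytest.approx(1.0)


def test_fisher_matches_enumeration_examples():
    for table in [(8, 2, 1, 9), (0, 10, 10, 0), (3, 7, 6, 4), (12, 0, 0, 12)]:
        assert fisher_exact_two_sided(*table) == pytest.approx(
            fisher_oracle(*table), abs=1e-9
        )


def test_fisher_zero_table():
    assert fisher_exact_two_sided(0, 0, 0, 0) == 1.0


def test_fisher_rejects_negative():
    with pytest.raises(ValueError):
        fisher_exact_two_sided(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# BH step-up: definition oracle


def bh_oracle(pvals):
    """q_i = min over j with p_(j) >= p_(i) of p_(j)*m/rank(j), capped at 1."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    for i in range(m):
        candidates = [
            pvals[order[j]] * m / (j + 1)
            for j in range(m)
            if pvals[order[j]] >= pvals[i] - 1e-300
        ]
        q[i] = min(1.0, min(candidates))
    return q


def test_bh_stepup_example():
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_single_and_dominance():
    assert bh_fdr([0.3]) == pytest.approx([0.3])
    rng = np.random.default_rng(5)
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)


def test_bh_matches_definition_oracle(rng):
    for _ in range(50):
        p = rng.uniform(size=int(rng.integers(1, 30)))
        assert bh_fdr(p) == pytest.approx(bh_oracle(p), abs=1e-12)


def test_bh_order_preserving_on_sorted_input(rng):
    p = np.sort(rng.uniform(size=20))
    q = bh_fdr(p)
    assert np.all(np.diff(q) >= -1e-12)


# ---------------------------------------------------------------------------
# balanced test


def variant_tokens(rng, n, plus_rate):
    out = []
    for _ in range(n):
        t = "ACGT"[rng.integers(0, 4)] + str(rng.integers(1, 999))
        if rng.random() < plus_rate:
            t += "+"
        out.append(t)
    return out


def null_tokens(rng, n, plus_rate=0.0):
    words = ["the", "binding", "of", "results", "show", "that"]
    out = []
    for _ in range(n):
        t = words[rng.integers(0, len(words))]
        if rng.random() < plus_rate:
            t += "+"
        out.append(t)
    return out


def test_n_reps_is_floor_ratio(rng):
    res = balanced_test(variant_tokens(rng, 500, 0.5), null_tokens(rng, 1500), seed=0)
    assert res.n_reps == 3
    res = balanced_test(variant_tokens(rng, 500, 0.5), null_tokens(rng, 500), seed=0)
    assert res.n_reps == 1
    assert np.all(res.sd_q == 0.0)


def test_identical_distribution_not_characteristic(rng):
    # same generator for both sides: no feature should show a difference
    a = null_tokens(rng, 300)
    res = balanced_test(a, list(a), seed=1)
    assert np.all(res.pct_diff == 0.0)
    assert not res.characteristic.any()


def test_planted_plus_feature_is_characteristic(rng):
    ent = null_tokens(rng, 500, plus_rate=0.9)
    nul = null_tokens(rng, 500, plus_rate=0.01)
    res = balanced_test(ent, nul, seed=2)
    plus = list(FEATURE_NAMES).index("Plus")
    assert res.characteristic[plus]
    assert res.pct_diff[plus] > 0
    # oracle check of the underlying Fisher significance
    ce, cn = int(res.count_entity[plus]), int(res.count_null[plus])
    assert fisher_oracle(ce, 500 - ce, cn, 500 - cn) < 1e-10


def test_balanced_test_requires_nonempty():
    with pytest.raises(ValueError):
        balanced_test([], ["a"], seed=0)


# ---------------------------------------------------------------------------
# fingerprint assembly


def make_corpus_with_plus_entities(name, rng):
    docs = []
    for i in range(20):
        ents = variant_tokens(rng, 2, plus_rate=1.0)
        nulls = null_tokens(rng, 8)
        words = nulls[:4] + [ents[0]] + nulls[4:] + [ents[1]]
        text = " ".join(words)
        spans = []
        pos = 0
        for w in words:
            if w in ents:
                spans.append(Span(pos, pos + len(w), w, "Variant"))
            pos += len(w) + 1
        docs.append(Document(f"{name}_d{i}", text, spans))
    return Corpus(name, docs)


def test_fingerprint_columns_grouped_and_shared_feature_flagged(rng):
    c1 = make_corpus_with_plus_entities("v1", rng)
    c2 = make_corpus_with_plus_entities("v2", rng)
    fp = fingerprint({"Variant": [c1, c2]}, seed=0)
    assert list(fp.characteristic.columns) == [("Variant", "v1"), ("Variant", "v2")]
    assert fp.characteristic.shape == (31, 2)
    plus = fp.characteristic.loc["Plus"]
    assert bool(plus[("Variant", "v1")]) and bool(plus[("Variant", "v2")])


def test_fingerprint_failed_column_marked_missing(rng):
    good = make_corpus_with_plus_entities("v1", rng)
    empty = Corpus("noent", [Document("d", "plain words only", [])])
    fp = fingerprint({"Variant": [good, empty]}, seed=0)
    assert fp.characteristic[("Variant", "noent")].isna().all()
    assert not fp.characteristic[("Variant", "v1")].isna().any()
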