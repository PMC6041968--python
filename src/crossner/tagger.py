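"""Linear-chain CRF sequence tagger with orthographic/contextual features.

A first-order conditional random field over IOB2 labels for a single entity
class.  The score of a label sequence y for a token sequence x is

    score(x, y) = pi[y_1] + sum_t  w(f(x, t)) . y_t  +  sum_t T[y_{t-1}, y_t]

with per-token binary feature vectors f, emission weights w, transition
matrix T and start scores pi.  Training maximizes the L2-penalized
conditional log-likelihood with L-BFGS; the objective is convex, weights are
initialized at zero, so the seed only affects data order.  Transitions that
would break the IOB2 scheme (start->I, O->I) carry a -inf structural mask, so
decoded sequences are well-formed by construction.

Feature templates follow the feature sets reported to help biomedical NER:
word identity and lowercase form, character prefixes/suffixes, collapsed word
shape, capitalization/digit/symbol indicators, positioned neighbor words
within a window, and an unordered disjunction-of-words bag on each side.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.sparse import csr_matrix
from scipy.special import logsumexp

from .corpus_io import (
    Corpus,
    Document,
    TaggedSequence,
    Token,
    iob_to_spans,
    tokenize,
)

__all__ = [
    "FeatureConfig",
    "TrainConfig",
    "SequenceModel",
    "featurize",
    "train",
    "viterbi_decode",
    "predict_corpus",
]

NEG_INF = -np.inf


@dataclass(frozen=True)
class FeatureConfig:
    window: int = 2
    use_disjunction: bool = True
    disjunction_radius: int = 4
    char_ngram_max: int = 4
    use_word_shape: bool = True

    def __post_init__(self) -> None:
        if self.window < 0 or self.char_ngram_max < 1:
            raise ValueError("window >= 0 and char_ngram_max >= 1 required")


@dataclass(frozen=True)
class TrainConfig:
    l2_sigma: float = 1.0
    max_iterations: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l2_sigma <= 0 or self.max_iterations < 1:
            raise ValueError("positive l2_sigma and max_iterations required")


def word_shape(w: str) -> str:
    """Collapsed shape: caps->X, lowercase->x, digit->d, other verbatim."""
    out = []
    prev = None
    for c in w:
        if c.isalpha() and c.isupper():
            k = "X"
        elif c.isalpha():
            k = "x"
        elif c.isdigit():
            k = "d"
        else:
            k = c
        if k != prev:
            out.append(k)
        prev = k
    return "".join(out)


def _token_features(w: str, cfg: FeatureConfig) -> list[str]:
    feats = [f"w={w}", f"lw={w.lower()}"]
    for n in range(1, min(cfg.char_ngram_max, len(w)) + 1):
        feats.append(f"pre{n}={w[:n]}")
        feats.append(f"suf{n}={w[-n:]}")
    if cfg.use_word_shape:
        feats.append(f"sh={word_shape(w)}")
    alpha = [c for c in w if c.isalpha()]
    if alpha:
        if w[0].isalpha() and w[0].isupper():
            feats.append("InitCap")
        if all(c.isupper() for c in alpha):
            feats.append("AllCaps")
        elif any(c.isupper() for c in alpha) and any(c.islower() for c in alpha):
            feats.append("MixedCase")
    if any(c.isdigit() for c in w):
        feats.append("HasDigit")
    if w.isdigit():
        feats.append("AllDigit")
    if len(w) == 1 and not w.isalnum():
        feats.append(f"sym={w}")
    return feats


def featurize(
    seq: TaggedSequence | list[Token], cfg: FeatureConfig
) -> list[list[str]]:
    """Per-token feature-string lists for a sequence."""
    tokens = seq.tokens if isinstance(seq, TaggedSequence) else seq
    words = [t.text for t in tokens]
    n = len(words)
    out: list[list[str]] = []
    for i in range(n):
        feats = _token_features(words[i], cfg)
        for d in range(-cfg.window, cfg.window + 1):
            if d == 0:
                continue
            j = i + d
            w = words[j] if 0 <= j < n else ("<S>" if j < 0 else "</S>")
            feats.append(f"w[{d}]={w}")
        if cfg.use_disjunction:
            left = {words[j] for j in range(max(0, i - cfg.disjunction_radius), i)}
            right = {
                words[j] for j in range(i + 1, min(n, i + 1 + cfg.disjunction_radius))
            }
            feats.extend(f"dl={w}" for w in sorted(left))
            feats.extend(f"dr={w}" for w in sorted(right))
        out.append(feats)
    return out


@dataclass
class SequenceModel:
    """Trained CRF: label set, feature index and weight tensors."""

    labels: list[str]  # [O, B-cls, I-cls]
    feature_index: dict[str, int]
    emission: np.ndarray  # (n_features, n_labels)
    transition: np.ndarray  # (n_labels, n_labels), structural mask applied at use
    start: np.ndarray  # (n_labels,)
    fcfg: FeatureConfig = field(default_factory=FeatureConfig)
    l2_sigma: float = 1.0
    seed: int = 0
    objective: float = float("nan")
    converged: bool = False

    @property
    def target_class(self) -> str:
        return self.labels[1][2:]

    def _masks(self) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.labels)
        tmask = np.zeros((n, n))
        smask = np.zeros(n)
        i_idx = [k for k, lab in enumerate(self.labels) if lab.startswith("I-")]
        o_idx = self.labels.index("O")
        for i in i_idx:
            tmask[o_idx, i] = NEG_INF  # O -> I forbidden
            smask[i] = NEG_INF  # start -> I forbidden
        return tmask, smask

    def save(self, path: str | os.PathLike) -> None:
        payload = {
            "format_version": 1,
            "labels": self.labels,
            "feature_index": self.feature_index,
            "emission": self.emission.tolist(),
            "transition": self.transition.tolist(),
            "start": self.start.tolist(),
            "fcfg": self.fcfg.__dict__,
            "l2_sigma": self.l2_sigma,
            "seed": self.seed,
            "objective": self.objective,
            "converged": self.converged,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "SequenceModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            labels=d["labels"],
            feature_index=d["feature_index"],
            emission=np.array(d["emission"]),
            transition=np.array(d["transition"]),
            start=np.array(d["start"]),
            fcfg=FeatureConfig(**d["fcfg"]),
            l2_sigma=d["l2_sigma"],
            seed=d["seed"],
            objective=d["objective"],
            converged=d["converged"],
        )


def _build_design(
    featurized: list[list[list[str]]], feature_index: dict[str, int]
) -> csr_matrix:
    """Stacked binary design matrix over all tokens of all sequences."""
    indptr = [0]
    indices: list[int] = []
    for seq in featurized:
        for feats in seq:
            cols = sorted({feature_index[f] for f in feats if f in feature_index})
            indices.extend(cols)
            indptr.append(len(indices))
    data = np.ones(len(indices))
    return csr_matrix(
        (data, np.array(indices, dtype=np.int64), np.array(indptr, dtype=np.int64)),
        shape=(len(indptr) - 1, len(feature_index)),
    )


class _Batch:
    """Padded batch view of sequences for vectorized forward-backward."""

    def __init__(self, X: csr_matrix, lengths: list[int], gold: list[np.ndarray]):
        self.X = X
        self.lengths = np.array(lengths)
        self.S = len(lengths)
        self.Lmax = int(self.lengths.max())
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        # flat token index -> (seq, pos) scatter map
        self.scatter = np.zeros((self.S, self.Lmax), dtype=np.int64)
        self.mask = np.zeros((self.S, self.Lmax), dtype=bool)
        for s, L in enumerate(lengths):
            self.scatter[s, :L] = np.arange(self.offsets[s], self.offsets[s] + L)
            self.mask[s, :L] = True
        self.gold = gold  # list of (L,) int arrays


def _nll_and_grad(
    theta: np.ndarray,
    batch: _Batch,
    n_feat: int,
    n_lab: int,
    tmask: np.ndarray,
    smask: np.ndarray,
    sigma: float,
) -> tuple[float, np.ndarray]:
    """Negative penalized log-likelihood and its gradient."""
    nW = n_feat * n_lab
    W = theta[:nW].reshape(n_feat, n_lab)
    T = theta[nW : nW + n_lab * n_lab].reshape(n_lab, n_lab) + tmask
    pi = theta[nW + n_lab * n_lab :] + smask

    flat_em = batch.X @ W  # (n_tokens, n_lab)
    E = np.full((batch.S, batch.Lmax, n_lab), 0.0)
    E[batch.mask] = flat_em[batch.scatter[batch.mask]]

    # forward
    alphas = np.empty((batch.Lmax, batch.S, n_lab))
    alpha = pi[None, :] + E[:, 0]
    alphas[0] = alpha
    for t in range(1, batch.Lmax):
        new = logsumexp(alpha[:, :, None] + T[None, :, :], axis=1) + E[:, t]
        alpha = np.where(batch.mask[:, t, None], new, alpha)
        alphas[t] = alpha
    logZ = logsumexp(alpha, axis=1)  # (S,)

    # backward
    betas = np.empty((batch.Lmax, batch.S, n_lab))
    beta = np.zeros((batch.S, n_lab))
    betas[batch.Lmax - 1] = beta
    for t in range(batch.Lmax - 2, -1, -1):
        inner = T[None, :, :] + (E[:, t + 1] + beta)[:, None, :]
        new = logsumexp(inner, axis=2)
        beta = np.where(batch.mask[:, t + 1, None], new, beta)
        betas[t] = beta

    # token marginals
    marg = np.exp(alphas.transpose(1, 0, 2) + betas.transpose(1, 0, 2) - logZ[:, None, None])
    marg[~batch.mask] = 0.0

    # pairwise expected transition counts
    gT = np.zeros((n_lab, n_lab))
    for t in range(1, batch.Lmax):
        act = batch.mask[:, t]
        if not act.any():
            break
        pair = (
            alphas[t - 1][act][:, :, None]
            + T[None, :, :]
            + (E[act, t] + betas[t][act])[:, None, :]
            - logZ[act][:, None, None]
        )
        gT += np.exp(pair).sum(axis=0)

    # empirical counts and gold score
    gold_flat = np.concatenate(batch.gold)
    nll = float(np.sum(logZ))
    g_pi = marg[:, 0].sum(axis=0)
    flat_marg = np.zeros((batch.X.shape[0], n_lab))
    flat_marg[batch.scatter[batch.mask]] = marg[batch.mask]
    flat_marg[np.arange(batch.X.shape[0]), gold_flat] -= 1.0
    gW = batch.X.T @ flat_marg

    for s in range(batch.S):
        y = batch.gold[s]
        em_score = flat_em[batch.offsets[s] : batch.offsets[s] + len(y)]
        nll -= pi[y[0]] + float(em_score[np.arange(len(y)), y].sum())
        if len(y) > 1:
            tr = T[y[:-1], y[1:]]
            nll -= float(tr.sum())
            np.add.at(gT, (y[:-1], y[1:]), -1.0)
        g_pi[y[0]] -= 1.0

    grad = np.concatenate([np.asarray(gW).ravel(), gT.ravel(), g_pi])
    # L2 penalty (Gaussian prior with sd sigma)
    nll += float(theta @ theta) / (2 * sigma**2)
    grad += theta / sigma**2
    return nll, grad


def train(
    sequences: list[TaggedSequence],
    fcfg: FeatureConfig | None = None,
    tcfg: TrainConfig | None = None,
) -> SequenceModel:
    """Fit the CRF on IOB2-tagged sequences for one entity class.

    Raises ``ValueError`` when no sequence carries a positive (non-O) tag.
    Weights start at zero and the objective is convex, so the result is
    deterministic; the seed only shuffles the sequence order.
    """
    fcfg = fcfg or FeatureConfig()
    tcfg = tcfg or TrainConfig()
    classes = {t[2:] for s in sequences for t in s.tags if t != "O"}
    if not classes:
        raise ValueError("training data contains no positive (non-O) examples")
    if len(classes) > 1:
        raise ValueError(f"expected a single entity class, found {sorted(classes)}")
    cls = classes.pop()
    labels = ["O", f"B-{cls}", f"I-{cls}"]
    lab_idx = {lab: i for i, lab in enumerate(labels)}

    rng = np.random.default_rng(tcfg.seed)
    order = rng.permutation(len(sequences))
    seqs = [sequences[i] for i in order if len(sequences[i].tokens) > 0]

    featurized = [featurize(s, fcfg) for s in seqs]
    feature_index: dict[str, int] = {}
    for seq in featurized:
        for feats in seq:
            for f in feats:
                if f not in feature_index:
                    feature_index[f] = len(feature_index)
    X = _build_design(featurized, feature_index)
    gold = [np.array([lab_idx[t] for t in s.tags]) for s in seqs]
    batch = _Batch(X, [len(s.tokens) for s in seqs], gold)

    n_feat, n_lab = len(feature_index), len(labels)
    model = SequenceModel(
        labels=labels,
        feature_index=feature_index,
        emission=np.zeros((n_feat, n_lab)),
        transition=np.zeros((n_lab, n_lab)),
        start=np.zeros(n_lab),
        fcfg=fcfg,
        l2_sigma=tcfg.l2_sigma,
        seed=tcfg.seed,
    )
    tmask, smask = model._masks()
    theta0 = np.zeros(n_feat * n_lab + n_lab * n_lab + n_lab)
    res = minimize(
        _nll_and_grad,
        theta0,
        args=(batch, n_feat, n_lab, tmask, smask, tcfg.l2_sigma),
        method="L-BFGS-B",
        jac=True,
        options={
            "maxiter": tcfg.max_iterations,
            "ftol": tcfg.tol,
            "gtol": 1e-6,
        },
    )
    nW = n_feat * n_lab
    model.emission = res.x[:nW].reshape(n_feat, n_lab)
    model.transition = res.x[nW : nW + n_lab * n_lab].reshape(n_lab, n_lab)
    model.start = res.x[nW + n_lab * n_lab :]
    model.objective = float(res.fun)
    model.converged = bool(res.success)
    return model


def sequence_scores(
    model: SequenceModel, tokens: list[Token]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(emissions, transition, start) score arrays with the IOB2 mask applied."""
    feats = featurize(tokens, model.fcfg)
    n_lab = len(model.labels)
    E = np.zeros((len(tokens), n_lab))
    for i, fs in enumerate(feats):
        for f in fs:
            j = model.feature_index.get(f)
            if j is not None:
                E[i] += model.emission[j]
    tmask, smask = model._masks()
    return E, model.transition + tmask, model.start + smask


def viterbi_decode(model: SequenceModel, tokens: list[Token]) -> list[str]:
    """Highest-scoring IOB2 label sequence; ties resolve to the earliest
    label in (O, B-, I-) order."""
    if not tokens:
        return []
    E, T, pi = sequence_scores(model, tokens)
    n, n_lab = E.shape
    # backward DP: best[t, y] = max score of the suffix starting at t in y;
    # the forward greedy reconstruction below then picks, at every position,
    # the earliest label among optimal continuations, which makes the result
    # the lexicographically smallest maximum-score path (O < B- < I-)
    best = np.empty((n, n_lab))
    best[n - 1] = E[n - 1]
    for t in range(n - 2, -1, -1):
        best[t] = E[t] + np.max(T + best[t + 1][None, :], axis=1)
    path = [int(np.argmax(pi + best[0]))]
    for t in range(1, n):
        path.append(int(np.argmax(T[path[-1]] + best[t])))
    return [model.labels[i] for i in path]


def predict_corpus(
    model: SequenceModel, corpus: Corpus, target_class: str | None = None
) -> Corpus:
    """Replace *target_class* spans in every document by decoded spans;
    spans of other classes are left untouched."""
    target_class = target_class or model.target_class
    if target_class != model.target_class:
        raise ValueError(
            f"model tags {model.target_class!r}, not {target_class!r}"
        )
    docs = []
    for doc in corpus.documents:
        tokens = tokenize(doc.text)
        tags = viterbi_decode(model, tokens)
        pred = iob_to_spans(TaggedSequence(doc.doc_id, tokens, tags), text=doc.text)
        keep = [s for s in doc.spans if s.label != target_class]
        docs.append(
            Document(doc.doc_id, doc.text, keep + pred, group_id=doc.group_id)
        )
    return Corpus(corpus.name, docs)
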