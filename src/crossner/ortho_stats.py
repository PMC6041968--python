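"""Orthographic feature fingerprints of entity classes.

Tokens inside entity spans of a class are compared with all remaining
("null") tokens over a registry of 31 binary morphological features —
capitalization patterns, digit counts, token length bands and punctuation/
symbol content.  The two samples are balanced by repeated random
down-sampling of the larger one; within each repetition every feature gets a
two-sided Fisher exact test and Benjamini-Hochberg FDR correction across the
31 features.  A feature is *characteristic* of a class when its mean q plus
one standard deviation stays below 0.05 and the feature is more frequent in
entity tokens than in null tokens.

Arranging the characteristic flags as features x (corpus, class) columns
yields a fingerprint matrix: corpora annotating the same class under the
same conventions share columns, while divergent annotation standards stand
out as discordant fingerprints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corpus_io import Corpus, Token, project_to_iob

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "morph_features",
    "collect_tokens",
    "fisher_exact_two_sided",
    "bh_fdr",
    "OrthoTestResult",
    "balanced_test",
    "Fingerprint",
    "fingerprint",
]


def _count_caps(w: str) -> int:
    return sum(1 for c in w if c.isalpha() and c.isupper())


def _count_digits(w: str) -> int:
    return sum(1 for c in w if c.isdigit())


def _has_alpha(w: str) -> bool:
    return any(c.isalpha() for c in w)


#: the frozen 31-feature registry: name -> predicate.  Data-driven so an
#: alternative list can be dropped in.
FEATURE_REGISTRY: dict[str, callable] = {
    # case (7)
    "InitCap": lambda w: w[0].isalpha() and w[0].isupper(),
    "EndCap": lambda w: w[-1].isalpha() and w[-1].isupper(),
    "AllCaps": lambda w: _has_alpha(w)
    and all(c.isupper() for c in w if c.isalpha()),
    "MixedCase": lambda w: any(c.isalpha() and c.isupper() for c in w)
    and any(c.isalpha() and c.islower() for c in w),
    "OneCap": lambda w: _count_caps(w) == 1,
    "TwoCap": lambda w: _count_caps(w) == 2,
    "ThreeCap": lambda w: _count_caps(w) >= 3,
    # digits (5)
    "HasDigit": lambda w: _count_digits(w) >= 1,
    "OneDigit": lambda w: _count_digits(w) == 1,
    "TwoDigit": lambda w: _count_digits(w) == 2,
    "ThreeDigit": lambda w: _count_digits(w) >= 3,
    "AllDigits": lambda w: w.isdigit(),
    # length (5)
    "Length1": lambda w: len(w) == 1,
    "Length2": lambda w: len(w) == 2,
    "Length3-5": lambda w: 3 <= len(w) <= 5,
    "Length6-10": lambda w: 6 <= len(w) <= 10,
    "LengthGT10": lambda w: len(w) > 10,
    # symbols (14)
    "Plus": lambda w: "+" in w,
    "Hyphen": lambda w: "-" in w,
    "Slash": lambda w: "/" in w,
    "Parenthesis": lambda w: "(" in w or ")" in w,
    "SquareBracket": lambda w: "[" in w or "]" in w,
    "Comma": lambda w: "," in w,
    "Period": lambda w: "." in w,
    "Colon": lambda w: ":" in w,
    "Semicolon": lambda w: ";" in w,
    "Apostrophe": lambda w: "'" in w,
    "Percent": lambda w: "%" in w,
    "Asterisk": lambda w: "*" in w,
    "Equals": lambda w: "=" in w,
    "Underscore": lambda w: "_" in w,
}

FEATURE_NAMES: tuple[str, ...] = tuple(FEATURE_REGISTRY)
assert len(FEATURE_NAMES) == 31


def morph_features(token: str) -> np.ndarray:
    """Binary vector over the 31-feature registry (fixed order)."""
    if not token:
        raise ValueError("empty token")
    return np.array(
        [int(bool(pred(token))) for pred in FEATURE_REGISTRY.values()],
        dtype=np.int8,
    )


def feature_matrix(tokens: list[str]) -> np.ndarray:
    return np.array([morph_features(t) for t in tokens], dtype=np.int64)


def collect_tokens(corpus: Corpus, target_class: str) -> tuple[list[str], list[str]]:
    """Split every document's tokens into entity tokens (inside a
    *target_class* span) and null tokens (everything else)."""
    entity: list[str] = []
    null: list[str] = []
    for doc in corpus.documents:
        seq = project_to_iob(doc, target_class)
        for tok, tag in zip(seq.tokens, seq.tags):
            (entity if tag != "O" else null).append(tok.text)
    if not entity:
        raise ValueError(
            f"corpus {corpus.name!r} has no {target_class!r} entity tokens"
        )
    return entity, null


def fisher_exact_two_sided(n11: int, n12: int, n21: int, n22: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[n11, n12], [n21, n22]]."""
    if min(n11, n12, n21, n22) < 0:
        raise ValueError("negative cell count")
    if n11 + n12 + n21 + n22 == 0:
        return 1.0
    return float(stats.fisher_exact([[n11, n12], [n21, n22]])[1])


def bh_fdr(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class OrthoTestResult:
    """Balanced resampled Fisher/BH results for one (corpus, class) pair."""

    feature_names: tuple[str, ...]
    count_entity: np.ndarray  # mean occurrence count per feature, entity side
    count_null: np.ndarray
    pct_diff: np.ndarray  # percentage-point difference per 100 balanced tokens
    mean_q: np.ndarray
    sd_q: np.ndarray
    n_reps: int
    characteristic: np.ndarray  # bool per feature

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count_entity": self.count_entity,
                "count_null": self.count_null,
                "pct_diff": self.pct_diff,
                "mean_q": self.mean_q,
                "sd_q": self.sd_q,
                "characteristic": self.characteristic,
            },
            index=list(self.feature_names),
        )


def balanced_test(
    entity_tokens: list[str], null_tokens: list[str], seed: int = 0
) -> OrthoTestResult:
    """Balanced, repeated Fisher exact testing of the 31 features.

    The larger sample is down-sampled (without replacement) to the size of
    the smaller one; this is repeated ``floor(larger/smaller)`` times
    (minimum 1) and q-values are summarized as mean +/- population sd across
    repetitions.
    """
    if not entity_tokens or not null_tokens:
        raise ValueError("both token samples must be non-empty")
    n_e, n_n = len(entity_tokens), len(null_tokens)
    balanced = min(n_e, n_n)
    if balanced < 20:
        logger.warning(
            "smaller class has only %d tokens; estimates are unstable", balanced
        )
    n_reps = max(1, (max(n_e, n_n) // balanced))
    M_e = feature_matrix(entity_tokens)
    M_n = feature_matrix(null_tokens)
    rng = np.random.default_rng(seed)

    qs = np.empty((n_reps, len(FEATURE_NAMES)))
    ce = np.empty((n_reps, len(FEATURE_NAMES)))
    cn = np.empty((n_reps, len(FEATURE_NAMES)))
    for r in range(n_reps):
        if n_e > balanced:
            e_counts = M_e[rng.choice(n_e, balanced, replace=False)].sum(axis=0)
            nl_counts = M_n.sum(axis=0)
        elif n_n > balanced:
            e_counts = M_e.sum(axis=0)
            nl_counts = M_n[rng.choice(n_n, balanced, replace=False)].sum(axis=0)
        else:
            e_counts = M_e.sum(axis=0)
            nl_counts = M_n.sum(axis=0)
        pvals = [
            fisher_exact_two_sided(
                int(e), int(balanced - e), int(nl), int(balanced - nl)
            )
            for e, nl in zip(e_counts, nl_counts)
        ]
        qs[r] = bh_fdr(pvals)
        ce[r] = e_counts
        cn[r] = nl_counts

    mean_q = qs.mean(axis=0)
    sd_q = qs.std(axis=0)  # population sd; 0 when n_reps == 1
    count_entity = ce.mean(axis=0)
    count_null = cn.mean(axis=0)
    pct_diff = 100.0 * (count_entity - count_null) / balanced
    characteristic = (mean_q + sd_q < 0.05) & (pct_diff > 0)
    return OrthoTestResult(
        feature_names=FEATURE_NAMES,
        count_entity=count_entity,
        count_null=count_null,
        pct_diff=pct_diff,
        mean_q=mean_q,
        sd_q=sd_q,
        n_reps=n_reps,
        characteristic=characteristic,
    )


@dataclass
class Fingerprint:
    """31 features x (corpus, class) matrix of characteristic flags."""

    characteristic: pd.DataFrame  # bool (NaN where the column failed)
    mean_q: pd.DataFrame
    results: dict[tuple[str, str], OrthoTestResult] = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        rows = []
        for (cls, corpus), res in self.results.items():
            frame = res.to_frame().reset_index(names="feature")
            frame.insert(0, "class", cls)
            frame.insert(0, "corpus", corpus)
            rows.append(frame)
        pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def fingerprint(
    corpora_by_class: dict[str, list[Corpus]], seed: int = 0
) -> Fingerprint:
    """Run the balanced test for every (corpus, class) pair and assemble the
    fingerprint matrix; columns are grouped by class.  Failing pairs (e.g. a
    corpus with no entity tokens for the class) are recorded as missing."""
    if not corpora_by_class:
        raise ValueError("no corpora supplied")
    columns: list[tuple[str, str]] = []
    char_cols = {}
    q_cols = {}
    results = {}
    col_i = 0
    for cls in sorted(corpora_by_class):
        for corpus in corpora_by_class[cls]:
            key = (cls, corpus.name)
            columns.append(key)
            try:
                ent, nul = collect_tokens(corpus, cls)
                res = balanced_test(ent, nul, seed=seed + col_i)
                results[key] = res
                char_cols[key] = res.characteristic.astype(float)
                q_cols[key] = res.mean_q
            except ValueError as e:
                logger.warning("fingerprint column %s failed: %s", key, e)
                char_cols[key] = np.full(len(FEATURE_NAMES), np.nan)
                q_cols[key] = np.full(len(FEATURE_NAMES), np.nan)
            col_i += 1
    idx = pd.MultiIndex.from_tuples(columns, names=["class", "corpus"])
    char = pd.DataFrame(char_cols, index=list(FEATURE_NAMES))
    char.columns = idx
    q = pd.DataFrame(q_cols, index=list(FEATURE_NAMES))
    q.columns = idx
    return Fingerprint(characteristic=char, mean_q=q, results=results)
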