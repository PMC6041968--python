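"""Synthetic multi-corpus NER data with controllable cross-corpus structure.

Real corpus collections differ along three axes that drive cross-corpus
generalizability: how much their entity lexicons overlap, how their entity
classes *look* (orthography — gene symbols vs. mutation nomenclature vs.
chemical names), and the annotation standard itself (e.g. a corpus that
annotates "KRAS gene mutant" phrases where others annotate "G12D").  The
generator controls each axis explicitly, so regimes such as "disjoint
lexicons with divergent orthography" or "80% shared lexicon, same
orthography" can be constructed exactly and the downstream learning-curve
and fingerprint analyses exercised without any external corpus.

Documents are streams of words from a fixed packaged null vocabulary with
entity surface forms inserted at a Poisson-distributed rate per document;
every insertion is recorded as a gold span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corpus_io import Corpus, Document, Span
from .power_analysis import CurvePoint, LearningCurve, power_law

__all__ = [
    "NULL_VOCABULARY",
    "OrthographyProfile",
    "CorpusSpec",
    "CurveSimSpec",
    "generate_corpus",
    "generate_corpus_family",
    "simulate_curve",
]

#: fixed null vocabulary: generic scientific-prose words, all lowercase
#: alphabetic, so entity orthography (caps, digits, symbols) stands apart
NULL_VOCABULARY: tuple[str, ...] = (
    "the", "of", "and", "in", "to", "a", "is", "was", "for", "with",
    "that", "by", "on", "as", "were", "are", "this", "from", "at", "an",
    "be", "or", "which", "have", "has", "not", "but", "also", "these",
    "been", "its", "may", "can", "both", "between", "during", "after",
    "observed", "measured", "analysis", "results", "study", "studies",
    "expression", "levels", "cells", "cell", "treatment", "control",
    "increased", "decreased", "significant", "significantly", "compared",
    "effect", "effects", "response", "pathway", "signaling", "binding",
    "activity", "activation", "inhibition", "function", "role", "data",
    "model", "method", "methods", "using", "used", "showed", "shown",
    "found", "identified", "associated", "related", "induced", "mediated",
    "dependent", "specific", "different", "similar", "higher", "lower",
    "patients", "samples", "tissue", "protein", "gene", "genes", "dna",
    "sequence", "region", "domain", "complex", "factor", "receptor",
    "level", "rate", "time", "group", "groups", "present", "previous",
    "reported", "described", "performed", "obtained", "determined",
    "suggest", "indicate", "consistent", "evidence", "furthermore",
    "however", "therefore", "moreover", "whereas", "although", "within",
)

#: distractor tokens mixed into the null stream: capitalized words, numbers
#: and abbreviations that share surface properties with entities, so taggers
#: cannot separate classes on orthography alone
DISTRACTOR_VOCABULARY: tuple[str, ...] = (
    "Figure", "Table", "The", "In", "However", "DNA", "RNA", "USA", "III",
    "II", "pH", "Fig", "et", "al", "P", "n", "CI", "SD", "2", "3", "10",
    "25", "50", "95", "100", "1a", "2b", "S1",
)


@dataclass(frozen=True)
class OrthographyProfile:
    """Surface-form templates for one entity class.

    ``kind`` selects the template family:

    * ``gene`` — short capitalized stems with trailing digits ("Brca1",
      "TP53");
    * ``variant`` — letter-digits-letter mutation codes with an optional
      trailing '+' ("V600E", "A123T+");
    * ``chemical`` — lowercase syllable chains with hyphens and optional
      parentheses ("2-(methyl)butanol"-like);
    * ``natural`` — multiword "<gene> gene mutant" phrases, emulating an
      annotation standard that labels descriptive phrases instead of
      nomenclature.
    """

    kind: str = "gene"
    plus_rate: float = 0.5  # variant kind: P(trailing '+')
    allcaps_rate: float = 0.5  # gene kind: P(fully uppercase stem)
    paren_rate: float = 0.3  # chemical kind: P(parenthesized infix)

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "variant", "chemical", "natural"):
            raise ValueError(f"unknown orthography kind {self.kind!r}")
        for p in (self.plus_rate, self.allcaps_rate, self.paren_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def sample_form(self, rng: np.random.Generator) -> str:
        consonants = "bcdfghklmnprstvz"
        vowels = "aeiou"

        def stem(k: int) -> str:
            return "".join(
                (consonants if i % 2 == 0 else vowels)[
                    rng.integers(0, len(consonants if i % 2 == 0 else vowels))
                ]
                for i in range(k)
            )

        if self.kind == "gene":
            s = stem(int(rng.integers(3, 6)))
            s = s.upper() if rng.random() < self.allcaps_rate else s.capitalize()
            return s + str(rng.integers(1, 100))
        if self.kind == "variant":
            letters = "ACDEFGHIKLMNPQRSTVWY"
            form = (
                letters[rng.integers(0, len(letters))]
                + str(rng.integers(1, 2000))
                + letters[rng.integers(0, len(letters))]
            )
            if rng.random() < self.plus_rate:
                form += "+"
            return form
        if self.kind == "chemical":
            parts = [str(rng.integers(1, 10)), stem(int(rng.integers(4, 7)))]
            if rng.random() < self.paren_rate:
                parts.insert(1, "(" + stem(3) + ")")
            return "-".join(parts[:2]) + ("" if len(parts) < 3 else parts[2] + "ol")
        # natural: "<gene> gene mutant" multiword phrase
        g = stem(int(rng.integers(3, 6))).upper()
        return f"{g} gene mutant"


@dataclass(frozen=True)
class CorpusSpec:
    name: str
    n_documents: int = 100
    tokens_per_doc_mean: float = 30.0
    tokens_per_doc_sd: float = 8.0
    entity_density: float = 2.0  # expected entities per document
    label: str = "Entity"
    lexicon: tuple[str, ...] | None = None  # explicit forms; else generated
    lexicon_size: int = 50
    lexicon_overlap: float = 0.0  # fraction of lexicon shared with partner
    overlap_partner: str | None = None
    orthography: OrthographyProfile = field(default_factory=OrthographyProfile)
    null_vocabulary: tuple[str, ...] = NULL_VOCABULARY
    distractor_rate: float = 0.1  # fraction of null tokens drawn from distractors
    docs_per_group: int = 1  # documents per simulated manuscript
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lexicon_overlap <= 1.0:
            raise ValueError("lexicon_overlap must lie in [0, 1]")
        if self.entity_density < 0:
            raise ValueError("entity_density must be >= 0")
        if not self.null_vocabulary:
            raise ValueError("null vocabulary must be non-empty")
        if not 0.0 <= self.distractor_rate <= 1.0:
            raise ValueError("distractor_rate must lie in [0, 1]")


def _generate_lexicon(
    profile: OrthographyProfile,
    size: int,
    rng: np.random.Generator,
    forbidden: set[str] = frozenset(),
) -> list[str]:
    forms: list[str] = []
    seen: set[str] = set(forbidden)
    attempts = 0
    while len(forms) < size:
        f = profile.sample_form(rng)
        attempts += 1
        if attempts > 1000 * size:
            raise RuntimeError("lexicon template space exhausted")
        if f not in seen:
            seen.add(f)
            forms.append(f)
    return forms


def generate_corpus(spec: CorpusSpec, lexicon: list[str] | None = None) -> Corpus:
    """Generate one annotated corpus per *spec* (deterministic given seed)."""
    rng = np.random.default_rng(spec.seed)
    lex = list(lexicon if lexicon is not None else (spec.lexicon or ()))
    if not lex:
        lex = _generate_lexicon(spec.orthography, spec.lexicon_size, rng)
    docs: list[Document] = []
    for i in range(spec.n_documents):
        n_tok = max(3, int(round(rng.normal(spec.tokens_per_doc_mean,
                                            spec.tokens_per_doc_sd))))
        words = []
        for _ in range(n_tok):
            if rng.random() < spec.distractor_rate:
                words.append(
                    DISTRACTOR_VOCABULARY[rng.integers(0, len(DISTRACTOR_VOCABULARY))]
                )
            else:
                words.append(
                    spec.null_vocabulary[rng.integers(0, len(spec.null_vocabulary))]
                )
        n_ent = min(int(rng.poisson(spec.entity_density)), n_tok)
        slots = sorted(rng.choice(n_tok, size=n_ent, replace=False).tolist())
        items: list[tuple[str, bool]] = [(w, False) for w in words]
        for s in slots:
            items[s] = (lex[rng.integers(0, len(lex))], True)
        text_parts: list[str] = []
        spans: list[Span] = []
        pos = 0
        for surface, is_entity in items:
            if text_parts:
                pos += 1  # joining space
            start = pos
            text_parts.append(surface)
            pos += len(surface)
            if is_entity:
                spans.append(Span(start, pos, surface, spec.label))
        text = " ".join(text_parts)
        group = f"{spec.name}_ms{i // max(1, spec.docs_per_group)}"
        docs.append(
            Document(f"{spec.name}_d{i}", text, spans, group_id=group)
        )
    return Corpus(spec.name, docs)


def generate_corpus_family(
    specs: list[CorpusSpec], shared_seed: int = 0
) -> list[Corpus]:
    """Generate corpora with exact pairwise lexicon-overlap fractions.

    Shared lexicon portions are constructed first (from the partner's
    lexicon), so ``lexicon_overlap`` is realized exactly: with overlap f and
    lexicon size L, exactly ``round(f*L)`` surface forms are common to the
    pair and the remainder is disjoint from the partner's entire lexicon.
    """
    lexicons: dict[str, list[str]] = {}
    corpora: list[Corpus] = []
    for i, spec in enumerate(specs):
        rng = np.random.default_rng((shared_seed, i))
        if spec.lexicon is not None:
            lex = list(spec.lexicon)
        elif spec.overlap_partner is not None:
            if spec.overlap_partner not in lexicons:
                raise ValueError(
                    f"{spec.name}: overlap partner {spec.overlap_partner!r} "
                    "must be generated first"
                )
            partner = lexicons[spec.overlap_partner]
            n_shared = int(round(spec.lexicon_overlap * spec.lexicon_size))
            if n_shared > len(partner):
                raise ValueError(
                    f"{spec.name}: partner lexicon too small for requested overlap"
                )
            shared = partner[:n_shared]
            fresh = _generate_lexicon(
                spec.orthography,
                spec.lexicon_size - n_shared,
                rng,
                forbidden=set(partner) | set(shared),
            )
            lex = shared + fresh
        else:
            lex = _generate_lexicon(spec.orthography, spec.lexicon_size, rng)
        lexicons[spec.name] = lex
        corpora.append(
            generate_corpus(replace(spec, seed=(shared_seed + spec.seed + 7919 * i) % (2**31)), lexicon=lex)
        )
    return corpora


@dataclass(frozen=True)
class CurveSimSpec:
    a: float = 0.2
    b: float = 0.5
    c: float = -0.3
    xs: tuple[int, ...] = tuple(range(10, 310, 10))
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.a <= 1 and self.b >= 0 and self.c <= 0 and self.noise_sd >= 0):
            raise ValueError("require 0<=a<=1, b>=0, c<=0, noise_sd>=0")


def simulate_curve(spec: CurveSimSpec) -> LearningCurve:
    """Draw a learning curve directly from the inverse power law, with
    optional Gaussian noise, clipped to [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    curve = LearningCurve("simulated", "simulated")
    for rep in range(spec.n_replicates):
        for x in spec.xs:
            y = float(power_law(x, spec.a, spec.b, spec.c))
            if spec.noise_sd > 0:
                y += float(rng.normal(0.0, spec.noise_sd))
            curve.points.append(CurvePoint(int(x), float(np.clip(y, 0.0, 1.0)), rep))
    return curve
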