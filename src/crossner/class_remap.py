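"""Remapping heterogeneous corpus labels onto shared superclasses.

Different corpora annotate related entities under different label names
("protein", "Gene_or_gene_product", "GENE", ...).  To train one model per
entity class across corpora, original labels are mapped onto a small set of
superclasses; a single mention may map to several classes at once (multiple
acyclic inheritance — e.g. an interleukin is both a gene product and a
chemical).  After remapping, a corpus is split into single-class copies, one
per class, so that each sequence model is a binary tagging problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus_io import Corpus, Document, Span

logger = logging.getLogger(__name__)

SUPERCLASSES = (
    "ChemicalDrug",
    "GeneProteinVariant",
    "Cell",
    "Anatomy",
    "Organism",
    "Tissue",
    "RNA",
    "Disease",
)

#: refined classes used after stratification: variants split from
#: genes/proteins; chemicals, drugs and metabolites kept corpus-specific
REFINED_CLASSES = ("GeneProtein", "Variant", "Chemical", "Drug", "Metabolite", "RNA")

#: reconstructed default mapping from common corpus label names to refined
#: classes; overridable via a TSV table (`load_mapping`)
DEFAULT_MAPPING: dict[str, frozenset[str]] = {
    k: frozenset(v)
    for k, v in {
        "gene": {"GeneProtein"},
        "protein": {"GeneProtein"},
        "gene_or_gene_product": {"GeneProtein"},
        "geneprotein": {"GeneProtein"},
        "mutation": {"Variant"},
        "variant": {"Variant"},
        "snp": {"Variant"},
        "dnamutation": {"Variant"},
        "proteinmutation": {"Variant"},
        "chemical": {"Chemical"},
        "drug": {"Drug"},
        "metabolite": {"Metabolite"},
        "mirna": {"RNA"},
        "rna": {"RNA"},
    }.items()
}


@dataclass
class ClassMapping:
    """original label (optionally corpus-qualified as ``corpus/label``) ->
    set of target class names.  Unmapped labels are dropped with a logged
    count."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def targets(self, corpus: str, label: str) -> frozenset[str]:
        qualified = f"{corpus}/{label}"
        if qualified in self.entries:
            return self.entries[qualified]
        return self.entries.get(label, frozenset())

    @classmethod
    def default(cls) -> "ClassMapping":
        return cls(dict(DEFAULT_MAPPING))


def load_mapping(path: str) -> ClassMapping:
    """Read a ``corpus<TAB>original_label<TAB>class[,class...]`` table.

    A ``*`` in the corpus column applies the row to every corpus.
    """
    entries: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            corpus, label, classes = parts
            key = label if corpus == "*" else f"{corpus}/{label}"
            entries[key] = frozenset(c for c in classes.split(",") if c)
    return ClassMapping(entries)


@dataclass
class EntityStats:
    """Per-class mention totals and unique (case-sensitive) surface forms."""

    total: dict[str, int] = field(default_factory=dict)
    unique: dict[str, int] = field(default_factory=dict)


def remap(corpus: Corpus, mapping: ClassMapping) -> Corpus:
    """Replace span labels by their mapped classes.

    A span mapping to several classes is replicated once per class at the
    same offsets; spans with unmapped labels are removed (count logged).
    Document text and offsets are never changed.
    """
    n_dropped = 0
    docs = []
    for doc in corpus.documents:
        spans: list[Span] = []
        for s in doc.spans:
            targets = mapping.targets(corpus.name, s.label)
            if not targets:
                n_dropped += 1
                continue
            for t in sorted(targets):
                spans.append(Span(s.start, s.end, s.text, t))
        docs.append(Document(doc.doc_id, doc.text, spans, group_id=doc.group_id))
    if n_dropped:
        logger.info("remap(%s): dropped %d spans with unmapped labels",
                    corpus.name, n_dropped)
    return Corpus(corpus.name, docs)


def split_single_class(corpus: Corpus) -> dict[str, Corpus]:
    """One corpus copy per entity class, each keeping all documents but only
    that class's spans.  Classes with zero spans are not emitted."""
    out: dict[str, Corpus] = {}
    for cls in sorted(corpus.labels):
        docs = [
            Document(
                d.doc_id,
                d.text,
                [s for s in d.spans if s.label == cls],
                group_id=d.group_id,
            )
            for d in corpus.documents
        ]
        out[cls] = Corpus(corpus.name, docs)
    return out


def entity_stats(corpus: Corpus) -> EntityStats:
    stats = EntityStats()
    forms: dict[str, set[str]] = {}
    for d in corpus.documents:
        for s in d.spans:
            stats.total[s.label] = stats.total.get(s.label, 0) + 1
            forms.setdefault(s.label, set()).add(s.text)
    stats.unique = {k: len(v) for k, v in forms.items()}
    return stats


def flag_sparse_classes(corpus: Corpus, min_mentions: int = 10) -> set[str]:
    """Classes with fewer than *min_mentions* mentions — too sparse for a
    representative learning-curve analysis.  Flag only; exclusion is the
    caller's choice."""
    stats = entity_stats(corpus)
    return {c for c, n in stats.total.items() if n < min_mentions}
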