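"""Reading, validating, repairing and tokenizing annotated NER corpora.

Supported interchange formats
-----------------------------
* **BioC XML** — collection/document/passage/annotation, offsets given as
  ``<location offset=... length=...>``.  This is the canonical on-disk format;
  every other format is converted to it.
* **brat standoff** — a ``.txt`` file plus a ``.ann`` file with lines of the
  form ``T1<TAB>Label start end<TAB>surface text``.
* **CoNLL-style IOB** — two tab-separated columns (token, IOB2 tag), one token
  per line, blank line between documents.  Offsets are synthesized by joining
  tokens with single spaces.

Internally all offsets are 0-based, half-open character offsets into the
document text.  Newlines are normalized to ``\\n`` on read, before any offset
repair, since mixed line endings are a common source of annotation index
mismatches.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

from lxml import etree

__all__ = [
    "Span",
    "Document",
    "Corpus",
    "Token",
    "TaggedSequence",
    "ValidationReport",
    "read_corpus",
    "write_bioc",
    "repair_offsets",
    "validate_corpus",
    "tokenize",
    "project_to_iob",
    "iob_to_spans",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


@dataclass(frozen=True, order=True)
class Span:
    """An entity mention: half-open character interval plus surface text."""

    start: int
    end: int
    text: str
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span interval [{self.start}, {self.end})")


@dataclass
class Document:
    doc_id: str
    text: str
    spans: list[Span] = field(default_factory=list)
    #: manuscript identifier — documents sharing a group never straddle a
    #: train/test split boundary
    group_id: str = ""

    def __post_init__(self) -> None:
        if not self.group_id:
            self.group_id = self.doc_id
        self.spans = sorted(set(self.spans))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Document):
            return NotImplemented
        return (
            self.doc_id == other.doc_id
            and self.group_id == other.group_id
            and self.text == other.text
            and self.spans == other.spans
        )


@dataclass
class Corpus:
    name: str
    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate document ids in corpus {self.name!r}")

    @property
    def labels(self) -> set[str]:
        return {s.label for d in self.documents for s in d.spans}

    def n_spans(self) -> int:
        return sum(len(d.spans) for d in self.documents)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.name == other.name and self.documents == other.documents


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


@dataclass
class TaggedSequence:
    """One document tokenized and projected to IOB2 tags for a single class."""

    doc_id: str
    tokens: list[Token]
    tags: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValueError("tokens and tags length mismatch")
        prev = "O"
        for t in self.tags:
            if t.startswith("I-") and (prev == "O"):
                raise ValueError("I- tag follows O or start of sequence")
            prev = t


@dataclass
class ValidationReport:
    corpus: str
    excluded: bool = False
    reasons: list[str] = field(default_factory=list)
    offset_mismatches: int = 0
    unrepairable: int = 0


def normalize_newlines(text: str) -> str:
    return text.replace("\r\n", "\n").replace("\r", "\n")


# ---------------------------------------------------------------------------
# tokenization


def tokenize(text: str, break_at: list[int] | None = None) -> list[Token]:
    """Split *text* into tokens.

    Whitespace separates tokens and is discarded.  Within a non-whitespace
    run, each maximal run of letters, each maximal run of digits, and each
    single other symbol is its own token ("p53" -> "p", "53").  Any offset in
    *break_at* additionally forces a token boundary, which is used to align
    tokens with annotation boundaries before IOB projection.
    """
    breaks = set(break_at or ())

    def char_class(c: str) -> str:
        if c.isspace():
            return "w"
        if c.isalpha():
            return "a"
        if c.isdigit():
            return "d"
        return "o"

    tokens: list[Token] = []
    start = None
    cls = ""
    for i, c in enumerate(text):
        k = char_class(c)
        boundary = (
            k != cls
            or k == "o"  # every symbol stands alone
            or i in breaks
        )
        if boundary:
            if start is not None and cls != "w":
                tokens.append(Token(text[start:i], start, i))
            start = i
            cls = k
    if start is not None and cls != "w":
        tokens.append(Token(text[start:], start, len(text)))
    return tokens


# ---------------------------------------------------------------------------
# IOB projection


def _resolve_overlaps(spans: list[Span]) -> list[Span]:
    """Leftmost-longest selection among same-class overlapping spans."""
    chosen: list[Span] = []
    for s in sorted(spans, key=lambda s: (s.start, -(s.end - s.start))):
        if all(s.start >= c.end or s.end <= c.start for c in chosen):
            chosen.append(s)
    return sorted(chosen)


def project_to_iob(doc: Document, target_class: str) -> TaggedSequence:
    """Tokenize *doc* and emit IOB2 tags for *target_class* spans.

    Tokenization is forced to break at every boundary of a target-class span,
    so a span can never partially overlap a token.  Overlapping same-class
    spans are resolved leftmost-longest first.
    """
    spans = _resolve_overlaps([s for s in doc.spans if s.label == target_class])
    breaks: list[int] = []
    for s in spans:
        breaks.extend((s.start, s.end))
    tokens = tokenize(doc.text, break_at=breaks)
    tags = []
    for tok in tokens:
        tag = "O"
        for s in spans:
            if s.start <= tok.start and tok.end <= s.end:
                tag = ("B-" if tok.start == s.start else "I-") + target_class
                break
        tags.append(tag)
    # a span starting inside whitespace cannot happen (spans slice real text),
    # but guard the IOB2 invariant anyway: first in-span token gets B-
    prev = "O"
    for i, t in enumerate(tags):
        if t.startswith("I-") and prev == "O":
            tags[i] = "B-" + t[2:]
        prev = tags[i]
    return TaggedSequence(doc.doc_id, tokens, tags)


def iob_to_spans(seq: TaggedSequence, text: str | None = None) -> list[Span]:
    """Reconstruct spans from contiguous B/I runs.

    *text* supplies the surface strings; when omitted it is reconstructed by
    placing tokens at their offsets and filling gaps with spaces.
    """
    if text is None:
        length = seq.tokens[-1].end if seq.tokens else 0
        chars = [" "] * length
        for tok in seq.tokens:
            chars[tok.start : tok.end] = tok.text
        text = "".join(chars)
    spans: list[Span] = []
    run_start = None
    run_label = ""
    run_end = 0

    def flush() -> None:
        if run_start is not None:
            spans.append(Span(run_start, run_end, text[run_start:run_end], run_label))

    for tok, tag in zip(seq.tokens, seq.tags):
        if tag.startswith("B-"):
            flush()
            run_start, run_end, run_label = tok.start, tok.end, tag[2:]
        elif tag.startswith("I-"):
            run_end = tok.end
        else:
            flush()
            run_start = None
    flush()
    return spans


# ---------------------------------------------------------------------------
# offset repair and validation


def repair_offsets(
    doc: Document, max_shift: int = 5
) -> tuple[Document, int, int]:
    """Shift-search repair of annotation indexing mismatches.

    For each span whose slice of the document text differs from its recorded
    surface text, shifts ``s`` are tried in order of increasing ``|s|``
    (negative before positive at ties) up to ``max_shift``; the first shift at
    which the slice equals the surface text is applied.  Spans that still fail
    are dropped and counted unrepairable.
    """
    shifts = [0]
    for k in range(1, max_shift + 1):
        shifts.extend((-k, k))
    repaired: list[Span] = []
    n_repaired = 0
    n_unrepairable = 0
    for s in doc.spans:
        fixed = None
        for sh in shifts:
            a, b = s.start + sh, s.end + sh
            if 0 <= a and b <= len(doc.text) and doc.text[a:b] == s.text:
                fixed = replace(s, start=a, end=b) if sh else s
                break
        if fixed is None:
            n_unrepairable += 1
        else:
            if fixed is not s:
                n_repaired += 1
            repaired.append(fixed)
    return (
        Document(doc.doc_id, doc.text, repaired, group_id=doc.group_id),
        n_repaired,
        n_unrepairable,
    )


def validate_corpus(
    corpus: Corpus,
    known_subsets: list[str] | None = None,
    abbreviation_corpora: list[str] | None = None,
    max_shift: int = 5,
) -> ValidationReport:
    """Apply the corpus exclusion rules and count offset mismatches.

    A corpus is excluded when it contains nested entities (one span strictly
    inside another, any label; identical intervals are allowed), when its name
    appears in *known_subsets* (a subset of an available superset corpus), or
    in *abbreviation_corpora* (declared to annotate abbreviations).  Offset
    mismatches are counted via :func:`repair_offsets` but do not by themselves
    exclude a corpus.
    """
    report = ValidationReport(corpus=corpus.name)
    if corpus.name in (known_subsets or ()):
        report.reasons.append("subset-of-superset")
    if corpus.name in (abbreviation_corpora or ()):
        report.reasons.append("abbreviation-annotations")
    nested = False
    for doc in corpus.documents:
        for i, a in enumerate(doc.spans):
            for b in doc.spans[i + 1 :]:
                if b.start >= a.end:
                    break
                inner = (a.start <= b.start and b.end <= a.end) or (
                    b.start <= a.start and a.end <= b.end
                )
                if inner and (a.start, a.end) != (b.start, b.end):
                    nested = True
        _, n_rep, n_unrep = repair_offsets(doc, max_shift=max_shift)
        report.offset_mismatches += n_rep
        report.unrepairable += n_unrep
    if nested:
        report.reasons.append("nested-entities")
    report.excluded = bool(report.reasons)
    return report


# ---------------------------------------------------------------------------
# BioC XML


def write_bioc(corpus: Corpus, path: str | os.PathLike) -> None:
    """Serialize *corpus* as a BioC collection (UTF-8)."""
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = corpus.name
    etree.SubElement(root, "date").text = ""
    etree.SubElement(root, "key").text = ""
    for doc in corpus.documents:
        d = etree.SubElement(root, "document")
        etree.SubElement(d, "id").text = doc.doc_id
        if doc.group_id != doc.doc_id:
            g = etree.SubElement(d, "infon", key="group")
            g.text = doc.group_id
        p = etree.SubElement(d, "passage")
        etree.SubElement(p, "offset").text = "0"
        etree.SubElement(p, "text").text = doc.text
        for i, s in enumerate(doc.spans):
            a = etree.SubElement(p, "annotation", id=f"T{i + 1}")
            inf = etree.SubElement(a, "infon", key="type")
            inf.text = s.label
            etree.SubElement(
                a, "location", offset=str(s.start), length=str(s.end - s.start)
            )
            etree.SubElement(a, "text").text = s.text
    tree = etree.ElementTree(root)
    tree.write(
        os.fspath(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _read_bioc(path: str) -> Corpus:
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as e:
        raise ParseError(f"{path}: malformed BioC XML: {e}") from e
    root = tree.getroot()
    name = root.findtext("source") or os.path.splitext(os.path.basename(path))[0]
    docs: list[Document] = []
    for d in root.iter("document"):
        doc_id = d.findtext("id") or f"doc_{len(docs)}"
        group = doc_id
        for inf in d.findall("infon"):
            if inf.get("key") == "group":
                group = inf.text or doc_id
        # passages are placed at their declared offsets; gaps become spaces
        pieces: list[tuple[int, str]] = []
        spans: list[Span] = []
        for p in d.findall("passage"):
            off = int(p.findtext("offset") or "0")
            ptext = p.findtext("text") or ""
            pieces.append((off, ptext))
            for a in p.findall("annotation"):
                label = None
                for inf in a.findall("infon"):
                    if inf.get("key") == "type":
                        label = inf.text
                loc = a.find("location")
                if loc is None or label is None:
                    raise ParseError(
                        f"{path}: annotation without location/type in {doc_id}"
                    )
                start = int(loc.get("offset"))
                end = start + int(loc.get("length"))
                spans.append(Span(start, end, a.findtext("text") or "", label))
        total = max((off + len(t) for off, t in pieces), default=0)
        chars = [" "] * total
        for off, t in pieces:
            chars[off : off + len(t)] = t
        text = normalize_newlines("".join(chars))
        docs.append(Document(doc_id, text, spans, group_id=group))
    return Corpus(name, docs)


# ---------------------------------------------------------------------------
# brat standoff


def _read_standoff_pair(txt_path: str, ann_path: str, doc_id: str) -> Document:
    with open(txt_path, encoding="utf-8") as fh:
        text = normalize_newlines(fh.read())
    spans: list[Span] = []
    with open(ann_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or not line.startswith("T"):
                continue  # only textbound annotations carry spans
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{ann_path}:{lineno}: malformed standoff line")
            fields = parts[1].split()
            if len(fields) != 3 or ";" in parts[1]:
                raise ParseError(
                    f"{ann_path}:{lineno}: unsupported or malformed span spec"
                )
            try:
                label, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ParseError(
                    f"{ann_path}:{lineno}: non-integer offsets in span spec"
                ) from e
            spans.append(Span(start, end, parts[2], label))
    return Document(doc_id, text, spans)


def _read_standoff(path: str) -> Corpus:
    if os.path.isdir(path):
        docs = []
        for fname in sorted(os.listdir(path)):
            if not fname.endswith(".txt"):
                continue
            base = fname[:-4]
            ann = os.path.join(path, base + ".ann")
            if os.path.exists(ann):
                docs.append(
                    _read_standoff_pair(os.path.join(path, fname), ann, base)
                )
        return Corpus(os.path.basename(os.path.normpath(path)), docs)
    base, _ = os.path.splitext(path)
    doc = _read_standoff_pair(base + ".txt", base + ".ann", os.path.basename(base))
    return Corpus(os.path.basename(base), [doc])


# ---------------------------------------------------------------------------
# CoNLL-style IOB


def _read_iob(path: str) -> Corpus:
    docs: list[Document] = []
    rows: list[tuple[str, str]] = []

    def flush() -> None:
        if not rows:
            return
        words = [w for w, _ in rows]
        text = " ".join(words)
        tokens = []
        pos = 0
        for w in words:
            tokens.append(Token(w, pos, pos + len(w)))
            pos += len(w) + 1
        spans: list[Span] = []
        run_start = None
        run_end = 0
        run_label = ""
        for tok, (_, tag) in zip(tokens, rows):
            if tag.startswith("B-") or (tag.startswith("I-") and run_start is None):
                if run_start is not None:
                    spans.append(
                        Span(run_start, run_end, text[run_start:run_end], run_label)
                    )
                run_start, run_end, run_label = tok.start, tok.end, tag[2:]
            elif tag.startswith("I-"):
                run_end = tok.end
            else:
                if run_start is not None:
                    spans.append(
                        Span(run_start, run_end, text[run_start:run_end], run_label)
                    )
                run_start = None
        if run_start is not None:
            spans.append(Span(run_start, run_end, text[run_start:run_end], run_label))
        docs.append(Document(f"doc_{len(docs)}", text, spans))
        rows.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected token and tag columns")
            word, tag = parts[0], parts[-1]
            if not (tag == "O" or tag.startswith(("B-", "I-"))):
                raise ParseError(f"{path}:{lineno}: unknown tag prefix {tag!r}")
            rows.append((word, tag))
    flush()
    return Corpus(os.path.splitext(os.path.basename(path))[0], docs)


def read_corpus(path: str | os.PathLike, format: str) -> Corpus:
    """Read an annotated corpus from *path* in the given *format*.

    ``format`` is one of ``bioc``, ``standoff`` (a ``.txt``/``.ann`` pair or a
    directory of such pairs) or ``iob``.
    """
    path = os.fspath(path)
    if format == "bioc":
        return _read_bioc(path)
    if format == "standoff":
        return _read_standoff(path)
    if format == "iob":
        return _read_iob(path)
    raise ValueError(f"unknown corpus format {format!r}")
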