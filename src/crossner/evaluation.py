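"""Entity-level precision/recall/F-score and cross-corpus aggregation.

Evaluation is strict (exact-match): a predicted mention counts as a true
positive only if an as-yet-unmatched gold mention with the identical
document, start, end and class exists.  The F-score is the harmonic mean of
precision and recall; 0/0 denominators evaluate to 0.

Two aggregation statistics summarize a set of per-corpus results: a
document-weighted mean (each corpus's F weighted by its document count) and
an equally-weighted mean where every corpus contributes the same.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus_io import Corpus

__all__ = ["EvalResult", "AggregateResult", "evaluate", "aggregate"]


@dataclass
class EvalResult:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fscore(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


@dataclass
class AggregateResult:
    per_corpus: dict[str, EvalResult] = field(default_factory=dict)
    document_weighted_mean: float = 0.0
    equal_weighted_mean: float = 0.0


def evaluate(
    gold: Corpus, pred: Corpus, target_class: str, partial: bool = False
) -> EvalResult:
    """Exact-match mention-level evaluation of *pred* against *gold*.

    With ``partial=True`` a prediction overlapping a gold mention of the same
    class counts as a match (sensitivity analysis only, never the default).
    Both corpora must contain the same document ids.
    """
    gold_ids = {d.doc_id for d in gold.documents}
    pred_ids = {d.doc_id for d in pred.documents}
    if gold_ids != pred_ids:
        missing = sorted(gold_ids ^ pred_ids)
        raise ValueError(f"document sets differ; mismatched ids: {missing}")
    pred_by_id = {d.doc_id: d for d in pred.documents}
    res = EvalResult()
    for gdoc in gold.documents:
        pdoc = pred_by_id[gdoc.doc_id]
        gspans = [s for s in gdoc.spans if s.label == target_class]
        pspans = [s for s in pdoc.spans if s.label == target_class]
        unmatched = list(gspans)
        for p in pspans:
            hit = None
            for g in unmatched:
                if partial:
                    if p.start < g.end and g.start < p.end:
                        hit = g
                        break
                elif (p.start, p.end) == (g.start, g.end):
                    hit = g
                    break
            if hit is not None:
                unmatched.remove(hit)
                res.tp += 1
            else:
                res.fp += 1
        res.fn += len(unmatched)
    return res


def aggregate(results: list[tuple[str, EvalResult, int]]) -> AggregateResult:
    """Document-weighted and equally-weighted mean F over per-corpus results.

    *results* holds (corpus name, EvalResult, document count) triples.
    """
    if not results:
        raise ValueError("no per-corpus results to aggregate")
    if any(n < 1 for _, _, n in results):
        raise ValueError("document counts must be >= 1")
    agg = AggregateResult()
    total_docs = sum(n for _, _, n in results)
    agg.per_corpus = {name: r for name, r, _ in results}
    agg.document_weighted_mean = (
        sum(r.fscore * n for _, r, n in results) / total_docs
    )
    agg.equal_weighted_mean = sum(r.fscore for _, r, _ in results) / len(results)
    return agg
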