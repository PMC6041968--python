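"""Generate the synthetic corpus families used by the downstream analyses.

Three regimes are written under results/corpora/:

* ``divergent/``  — two corpora, disjoint entity lexicons, one annotating
  gene-style nomenclature and one annotating natural-language
  "<gene> gene mutant" phrases (annotation-standard divergence);
* ``shared/``     — two gene-style corpora with an 80% shared lexicon;
* ``sequential/`` — two gene-style corpora plus one variant-style corpus,
  used for the sequential-addition analysis.

Each corpus is emitted as BioC XML together with an entity-statistics table.
"""

import os

from crossner.class_remap import entity_stats
from crossner.corpus_io import write_bioc
from crossner.synthetic_data import CorpusSpec, OrthographyProfile, generate_corpus_family

SEED = 20260920
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "corpora")

BASE = dict(n_documents=100, tokens_per_doc_mean=12.0, tokens_per_doc_sd=3.0,
            entity_density=2.0, lexicon_size=40, label="Entity")

FAMILIES = {
    "divergent": [
        CorpusSpec(name="geneCorpus", orthography=OrthographyProfile("gene"),
                   seed=1, **BASE),
        CorpusSpec(name="phraseCorpus", orthography=OrthographyProfile("natural"),
                   lexicon_overlap=0.0, overlap_partner="geneCorpus", seed=2, **BASE),
    ],
    "shared": [
        CorpusSpec(name="geneA", orthography=OrthographyProfile("gene"),
                   seed=1, **BASE),
        CorpusSpec(name="geneB", orthography=OrthographyProfile("gene"),
                   lexicon_overlap=0.8, overlap_partner="geneA", seed=2, **BASE),
    ],
    "sequential": [
        CorpusSpec(name="geneA", orthography=OrthographyProfile("gene"),
                   seed=1, **BASE),
        CorpusSpec(name="geneB", orthography=OrthographyProfile("gene"),
                   lexicon_overlap=0.5, overlap_partner="geneA", seed=2, **BASE),
        CorpusSpec(name="variantC", orthography=OrthographyProfile("variant"),
                   seed=3, **BASE),
    ],
}


def main() -> None:
    rows = ["family\tcorpus\tdocuments\tmentions\tunique_forms"]
    for family, specs in FAMILIES.items():
        out_dir = os.path.join(OUT, family)
        os.makedirs(out_dir, exist_ok=True)
        for corpus in generate_corpus_family(specs, shared_seed=SEED):
            write_bioc(corpus, os.path.join(out_dir, f"{corpus.name}.bioc.xml"))
            stats = entity_stats(corpus)
            rows.append(
                f"{family}\t{corpus.name}\t{len(corpus.documents)}\t"
                f"{stats.total.get('Entity', 0)}\t{stats.unique.get('Entity', 0)}"
            )
            print(f"[{family}] {corpus.name}: {len(corpus.documents)} docs, "
                  f"{stats.total.get('Entity', 0)} mentions "
                  f"({stats.unique.get('Entity', 0)} unique forms)")
    with open(os.path.join(OUT, "entity_stats.tsv"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(rows) + "\n")
    print(f"\nwrote corpora + entity_stats.tsv under {os.path.normpath(OUT)}")


if __name__ == "__main__":
    main()
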