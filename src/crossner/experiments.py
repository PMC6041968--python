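"""Composed cross-corpus experiment regimes on synthetic corpus families.

Each function builds a controlled multi-corpus regime with the synthetic
generator, runs the corresponding learning-curve design end to end (IOB
projection, CRF training, strict evaluation) and returns the summary
quantities of interest.  These are the regimes the analysis drivers and the
acceptance checks run:

* ``generalizability_experiment`` — two corpora; within- vs cross-corpus F
  as a function of lexicon overlap and orthographic divergence;
* ``sequential_jump_experiment`` — merged training with sequential corpus
  addition; how much a test corpus's F rises only once its own annotation
  style enters the pool;
* ``loco_vs_merged_experiment`` — for a high-overlap family, how close
  leave-corpus-out performance comes to fully merged performance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .power_analysis import (
    CorpusSplit,
    SplitSpec,
    build_curve_corpus_specific,
    build_curve_leave_corpus_out,
    build_curve_merged,
    split_corpus,
)
from .synthetic_data import CorpusSpec, OrthographyProfile, generate_corpus_family
from .tagger import FeatureConfig, TrainConfig

#: problem sizes for desk-scale runs: small documents keep CRF training fast
#: while leaving enough mentions for stable F-scores
DOC_MEAN_TOKENS = 12.0
DOC_SD_TOKENS = 3.0
ENTITY_DENSITY = 2.0
LEXICON_SIZE = 40

DEFAULT_TCFG = TrainConfig(l2_sigma=1.0, max_iterations=100, tol=1e-6)
DEFAULT_FCFG = FeatureConfig(window=1, use_disjunction=True, disjunction_radius=2)


def _family_splits(
    specs: list[CorpusSpec], seed: int
) -> list[CorpusSplit]:
    corpora = generate_corpus_family(specs, shared_seed=seed)
    splits = []
    for i, c in enumerate(corpora):
        tr, te = split_corpus(c, SplitSpec(train_fraction=0.8, seed=seed + i))
        splits.append(CorpusSplit(c.name, tr, te))
    return splits


@dataclass
class GeneralizabilityResult:
    within_f: float  # mean over the two within-corpus (source == target) cells
    cross_f: float  # mean over the two cross-corpus cells
    per_cell: dict[tuple[str, str], float]

    @property
    def gap(self) -> float:
        return self.within_f - self.cross_f


def generalizability_experiment(
    seed: int,
    lexicon_overlap: float,
    divergent_orthography: bool,
    n_documents: int = 100,
    tcfg: TrainConfig = DEFAULT_TCFG,
    fcfg: FeatureConfig = DEFAULT_FCFG,
) -> GeneralizabilityResult:
    """Two-corpus corpus-specific design: train on each corpus's full
    training split, evaluate every test split, compare the within-corpus
    diagonal with the cross-corpus off-diagonal."""
    profile_a = OrthographyProfile(kind="gene")
    # "natural" annotates descriptive "<gene> gene mutant" phrases — an
    # annotation standard orthographically disjoint from gene nomenclature
    profile_b = (
        OrthographyProfile(kind="natural")
        if divergent_orthography
        else profile_a
    )
    base = dict(
        n_documents=n_documents,
        tokens_per_doc_mean=DOC_MEAN_TOKENS,
        tokens_per_doc_sd=DOC_SD_TOKENS,
        entity_density=ENTITY_DENSITY,
        lexicon_size=LEXICON_SIZE,
        label="Entity",
    )
    specs = [
        CorpusSpec(name="corpusA", orthography=profile_a, seed=1, **base),
        CorpusSpec(
            name="corpusB",
            orthography=profile_b,
            lexicon_overlap=lexicon_overlap,
            overlap_partner="corpusA",
            seed=2,
            **base,
        ),
    ]
    splits = _family_splits(specs, seed)
    x_full = min(len(s.train.documents) for s in splits)
    curves = build_curve_corpus_specific(
        splits, "Entity", [x_full], tcfg=tcfg, fcfg=fcfg, seed=seed
    )
    per_cell = {
        (c.source, c.target_corpus): c.points[-1].y for c in curves if c.points
    }
    within = [f for (s, t), f in per_cell.items() if s == t]
    cross = [f for (s, t), f in per_cell.items() if s != t]
    return GeneralizabilityResult(
        within_f=sum(within) / len(within),
        cross_f=sum(cross) / len(cross),
        per_cell=per_cell,
    )


@dataclass
class SequentialJumpResult:
    target: str
    boundary: int  # pool position after which the target-style corpus is in
    f_before: float  # max F at x at or below the boundary
    f_after: float  # max F beyond the boundary
    points: list[tuple[int, float]]

    @property
    def jump(self) -> float:
        return self.f_after - self.f_before


def sequential_jump_experiment(
    seed: int,
    n_documents: int = 80,
    tcfg: TrainConfig = DEFAULT_TCFG,
    fcfg: FeatureConfig = DEFAULT_FCFG,
) -> SequentialJumpResult:
    """Three corpora added sequentially; the third is the only one whose
    lexicon and orthography match the test corpus of interest (itself), so
    its test F should rise only after its own boundary in the pool."""
    base = dict(
        n_documents=n_documents,
        tokens_per_doc_mean=DOC_MEAN_TOKENS,
        tokens_per_doc_sd=DOC_SD_TOKENS,
        entity_density=ENTITY_DENSITY,
        lexicon_size=LEXICON_SIZE,
        label="Entity",
    )
    gene = OrthographyProfile(kind="gene")
    variant = OrthographyProfile(kind="variant")
    specs = [
        CorpusSpec(name="geneA", orthography=gene, seed=1, **base),
        CorpusSpec(
            name="geneB",
            orthography=gene,
            lexicon_overlap=0.5,
            overlap_partner="geneA",
            seed=2,
            **base,
        ),
        CorpusSpec(name="variantC", orthography=variant, seed=3, **base),
    ]
    splits = _family_splits(specs, seed)
    order = [s.name for s in splits]
    sizes = {s.name: len(s.train.documents) for s in splits}
    boundary = sizes["geneA"] + sizes["geneB"]
    total = boundary + sizes["variantC"]
    xs = sorted({max(1, boundary // 3), boundary, total})
    curves = build_curve_merged(
        splits,
        "Entity",
        xs,
        tcfg=tcfg,
        fcfg=fcfg,
        seed=seed,
        addition_scheme="sequential",
        corpus_order=order,
    )
    target = next(c for c in curves if c.target_corpus == "variantC")
    pts = sorted((p.x, p.y) for p in target.points)
    before = [y for x, y in pts if x <= boundary]
    after = [y for x, y in pts if x > boundary]
    return SequentialJumpResult(
        target="variantC",
        boundary=boundary,
        f_before=max(before),
        f_after=max(after),
        points=pts,
    )


@dataclass
class LocoVsMergedResult:
    target: str
    merged_f: float
    loco_f: float

    @property
    def difference(self) -> float:
        return self.merged_f - self.loco_f


def loco_vs_merged_experiment(
    seed: int,
    n_documents: int = 80,
    lexicon_overlap: float = 0.8,
    tcfg: TrainConfig = DEFAULT_TCFG,
    fcfg: FeatureConfig = DEFAULT_FCFG,
) -> LocoVsMergedResult:
    """Three high-overlap, same-orthography corpora: compare the held-out
    corpus's F under leave-corpus-out training with its F under fully merged
    training (its own data included)."""
    gene = OrthographyProfile(kind="gene")
    base = dict(
        n_documents=n_documents,
        tokens_per_doc_mean=DOC_MEAN_TOKENS,
        tokens_per_doc_sd=DOC_SD_TOKENS,
        entity_density=ENTITY_DENSITY,
        lexicon_size=LEXICON_SIZE,
        label="Entity",
        orthography=gene,
    )
    specs = [
        CorpusSpec(name="srcA", seed=1, **base),
        CorpusSpec(
            name="srcB", lexicon_overlap=lexicon_overlap,
            overlap_partner="srcA", seed=2, **base,
        ),
        CorpusSpec(
            name="srcC", lexicon_overlap=lexicon_overlap,
            overlap_partner="srcA", seed=3, **base,
        ),
    ]
    splits = _family_splits(specs, seed)
    target = splits[-1].name
    pool_all = sum(len(s.train.documents) for s in splits)
    pool_loco = pool_all - len(splits[-1].train.documents)
    merged = build_curve_merged(
        splits, "Entity", [pool_all], tcfg=tcfg, fcfg=fcfg, seed=seed
    )
    loco = build_curve_leave_corpus_out(
        splits, "Entity", [pool_loco], tcfg=tcfg, fcfg=fcfg, seed=seed
    )
    merged_f = next(
        c.points[-1].y for c in merged if c.target_corpus == target
    )
    loco_f = next(c.points[-1].y for c in loco if c.target_corpus == target)
    return LocoVsMergedResult(target=target, merged_f=merged_f, loco_f=loco_f)
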