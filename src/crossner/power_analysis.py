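"""Learning curves over training-set size and inverse-power-law fits.

Test F-score as a function of the number of training documents x is modeled
by the inverse power law

    Yfs(x) = (1 - a) - b * x**c        0 <= a <= 1,  b >= 0,  c <= 0

where ``1 - a`` is the asymptotic maximum F-score (``a`` the minimum
achievable error), ``b`` the learning rate and ``c`` the decay rate.  Fitting
this curve answers the power-analysis question: is performance limited by the
quantity of annotated data, or has it effectively plateaued?

Three curve designs probe cross-corpus generalizability:

* corpus-specific — train on one corpus, evaluate every corpus's test set;
* merged — pool all corpora's training data (shuffled, or added sequentially
  one corpus at a time) and evaluate every test set as the pool grows;
* leave-corpus-out — train on the pooled data of all corpora except one and
  evaluate the held-out corpus's test set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .corpus_io import Corpus, Document, project_to_iob
from .evaluation import evaluate
from .tagger import FeatureConfig, TrainConfig, predict_corpus, train

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "CorpusSplit",
    "CurvePoint",
    "LearningCurve",
    "PowerLawFit",
    "split_corpus",
    "train_on_documents",
    "fscore_on_test",
    "build_curve_corpus_specific",
    "build_curve_merged",
    "build_curve_leave_corpus_out",
    "fit_power_law",
    "extrapolate",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    group_by_manuscript: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CorpusSplit:
    name: str
    train: Corpus
    test: Corpus


@dataclass(frozen=True)
class CurvePoint:
    x: int  # number of training documents
    y: float  # test F-score, proportion in [0, 1]
    replicate: int = 0


@dataclass
class LearningCurve:
    design: str  # corpus_specific | merged | leave_corpus_out
    target_corpus: str
    source: str = ""  # training source ("" = pooled)
    addition_scheme: str = "shuffled"  # shuffled | sequential
    points: list[CurvePoint] = field(default_factory=list)
    #: sequential scheme: corpus name -> cumulative document count at which
    #: that corpus's training data has been fully added
    boundaries: dict[str, int] = field(default_factory=dict)
    #: ids of every document that entered this curve's training pool
    pool_doc_ids: set[str] = field(default_factory=set)


@dataclass
class PowerLawFit:
    a: float
    b: float
    c: float
    rmse: float
    converged: bool
    c_identifiable: bool = True

    @property
    def asymptote(self) -> float:
        return 1.0 - self.a


# ---------------------------------------------------------------------------
# splitting


def split_corpus(corpus: Corpus, spec: SplitSpec) -> tuple[Corpus, Corpus]:
    """Random group-level train/test split.

    All documents sharing a ``group_id`` (same manuscript) land on the same
    side, so the test set never contains text from a training manuscript.
    The achieved train fraction is the closest the group granularity allows.
    """
    groups: dict[str, list[Document]] = {}
    for d in corpus.documents:
        key = d.group_id if spec.group_by_manuscript else d.doc_id
        groups.setdefault(key, []).append(d)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups/documents to split")
    rng = np.random.default_rng(spec.seed)
    names = sorted(groups)
    rng.shuffle(names)
    target = spec.train_fraction * len(corpus.documents)
    train_docs: list[Document] = []
    test_docs: list[Document] = []
    count = 0
    for i, g in enumerate(names):
        size = len(groups[g])
        remaining = sum(len(groups[n]) for n in names[i:])
        # keep both sides non-empty; otherwise pick the side that lands the
        # cumulative train count closest to the target
        if not train_docs and remaining == size:
            take = True
        elif not test_docs and i == len(names) - 1:
            take = False
        else:
            take = abs(count + size - target) <= abs(count - target) and (
                count < target
            )
        if take:
            train_docs.extend(groups[g])
            count += size
        else:
            test_docs.extend(groups[g])
    return (
        Corpus(corpus.name, train_docs),
        Corpus(corpus.name, test_docs),
    )


# ---------------------------------------------------------------------------
# curve construction


def train_on_documents(
    docs: list[Document],
    target_class: str,
    fcfg: FeatureConfig | None = None,
    tcfg: TrainConfig | None = None,
):
    """Project documents to IOB2 for *target_class* and fit the CRF."""
    seqs = [project_to_iob(d, target_class) for d in docs]
    return train(seqs, fcfg, tcfg)


def fscore_on_test(model, test: Corpus, target_class: str) -> float:
    pred = predict_corpus(model, test, target_class)
    return evaluate(test, pred, target_class).fscore


def _usable_xs(xs: list[int], pool_size: int, label: str) -> list[int]:
    ok = [x for x in xs if 1 <= x <= pool_size]
    for x in xs:
        if x > pool_size:
            logger.warning("%s: skipping x=%d (> %d available)", label, x, pool_size)
    return ok


def build_curve_corpus_specific(
    splits: list[CorpusSplit],
    target_class: str,
    xs: list[int],
    tcfg: TrainConfig | None = None,
    fcfg: FeatureConfig | None = None,
    seed: int = 0,
    n_replicates: int = 1,
) -> list[LearningCurve]:
    """Train on each corpus alone; evaluate on every corpus's test set.

    Emits one curve per (source, target) pair: the diagonal measures
    within-corpus performance, off-diagonal cells cross-corpus transfer.
    """
    curves = {
        (src.name, tgt.name): LearningCurve(
            "corpus_specific", tgt.name, source=src.name
        )
        for src in splits
        for tgt in splits
    }
    for rep in range(n_replicates):
        for src in splits:
            rng = np.random.default_rng((seed, rep, sorted(s.name for s in splits).index(src.name)))
            order = rng.permutation(len(src.train.documents))
            docs = [src.train.documents[i] for i in order]
            for x in _usable_xs(xs, len(docs), src.name):
                model = train_on_documents(docs[:x], target_class, fcfg,
                                           _rep_tcfg(tcfg, seed, rep))
                for tgt in splits:
                    y = fscore_on_test(model, tgt.test, target_class)
                    curves[(src.name, tgt.name)].points.append(
                        CurvePoint(x, y, rep)
                    )
    return list(curves.values())


def _rep_tcfg(tcfg: TrainConfig | None, seed: int, rep: int) -> TrainConfig:
    base = tcfg or TrainConfig()
    return TrainConfig(base.l2_sigma, base.max_iterations, base.tol,
                       seed=(base.seed + 1000003 * rep + seed) % (2**31))


def build_curve_merged(
    splits: list[CorpusSplit],
    target_class: str,
    xs: list[int],
    tcfg: TrainConfig | None = None,
    fcfg: FeatureConfig | None = None,
    seed: int = 0,
    addition_scheme: str = "shuffled",
    corpus_order: list[str] | None = None,
    n_replicates: int = 1,
) -> list[LearningCurve]:
    """Pool all corpora's training data; evaluate every fixed test set as the
    pool grows.

    ``shuffled`` permutes the pooled documents once per replicate;
    ``sequential`` concatenates corpora in *corpus_order* (list order by
    default) one document at a time, recording the cumulative boundary at
    which each corpus's data is fully in.
    """
    if addition_scheme not in ("shuffled", "sequential"):
        raise ValueError(f"unknown addition scheme {addition_scheme!r}")
    by_name = {s.name: s for s in splits}
    order_names = corpus_order or [s.name for s in splits]
    boundaries: dict[str, int] = {}
    cum = 0
    for name in order_names:
        cum += len(by_name[name].train.documents)
        boundaries[name] = cum
    curves = {
        tgt.name: LearningCurve(
            "merged",
            tgt.name,
            addition_scheme=addition_scheme,
            boundaries=dict(boundaries) if addition_scheme == "sequential" else {},
        )
        for tgt in splits
    }
    for rep in range(n_replicates):
        pool: list[Document] = []
        if addition_scheme == "sequential":
            for name in order_names:
                pool.extend(by_name[name].train.documents)
        else:
            for name in order_names:
                pool.extend(by_name[name].train.documents)
            rng = np.random.default_rng((seed, rep, 1))
            idx = rng.permutation(len(pool))
            pool = [pool[i] for i in idx]
        for x in _usable_xs(xs, len(pool), "merged"):
            model = train_on_documents(pool[:x], target_class, fcfg,
                                       _rep_tcfg(tcfg, seed, rep))
            for tgt in splits:
                y = fscore_on_test(model, tgt.test, target_class)
                curves[tgt.name].points.append(CurvePoint(x, y, rep))
    return list(curves.values())


def build_curve_leave_corpus_out(
    splits: list[CorpusSplit],
    target_class: str,
    xs: list[int],
    tcfg: TrainConfig | None = None,
    fcfg: FeatureConfig | None = None,
    seed: int = 0,
    n_replicates: int = 1,
) -> list[LearningCurve]:
    """For each corpus: train on the shuffled pooled training data of all the
    *other* corpora, evaluate on the held-out corpus's test set.

    A hard audit asserts that no held-out training document ever enters the
    pool.
    """
    if len(splits) < 2:
        raise ValueError("leave-corpus-out needs at least 2 corpora")
    curves = []
    for k, held in enumerate(splits):
        curve = LearningCurve("leave_corpus_out", held.name)
        held_train_ids = {d.doc_id for d in held.train.documents}
        held_test_ids = {d.doc_id for d in held.test.documents}
        for rep in range(n_replicates):
            pool = [
                d
                for s in splits
                if s.name != held.name
                for d in s.train.documents
            ]
            pool_ids = {d.doc_id for d in pool}
            # audit: the held-out corpus contributes nothing to training
            assert not (pool_ids & held_train_ids) and not (
                pool_ids & held_test_ids
            ), f"held-out corpus {held.name!r} leaked into the training pool"
            rng = np.random.default_rng((seed, rep, k))
            idx = rng.permutation(len(pool))
            pool = [pool[i] for i in idx]
            curve.pool_doc_ids |= pool_ids
            for x in _usable_xs(xs, len(pool), f"loco:{held.name}"):
                model = train_on_documents(pool[:x], target_class, fcfg,
                                           _rep_tcfg(tcfg, seed, rep))
                curve.points.append(
                    CurvePoint(x, fscore_on_test(model, held.test, target_class), rep)
                )
        curves.append(curve)
    return curves


# ---------------------------------------------------------------------------
# inverse power law fit


def power_law(x, a: float, b: float, c: float):
    return (1.0 - a) - b * np.asarray(x, dtype=float) ** c


def fit_power_law(
    points: list[CurvePoint],
    init_b: float = 0.2,
    init_c: float = -0.1,
) -> PowerLawFit:
    """Constrained least-squares fit of the inverse power law.

    Replicate points sharing an x are averaged first, then y is regressed on
    ``(1 - a) - b * x**c`` with bounds ``0 <= a <= 1``, ``b >= 0``,
    ``c <= 0``.  Initialization: ``a0 = max(0, 1 - max(y))``, ``b0``/``c0``
    from the arguments.  When the fitted ``b`` is ~0 the curve is flat and
    the decay rate carries no information (``c_identifiable=False``).
    """
    by_x: dict[int, list[float]] = {}
    for p in points:
        by_x.setdefault(p.x, []).append(p.y)
    if len(by_x) < 3:
        raise ValueError("need at least 3 distinct x values to fit")
    xs = np.array(sorted(by_x), dtype=float)
    ys = np.array([np.mean(by_x[int(x)]) for x in xs])

    # flat curve: (1-a) - b*x^c degenerates (c -> 0 absorbs b into the
    # constant), so report the unique interpretable solution b = 0 directly
    if float(np.ptp(ys)) < 1e-12:
        return PowerLawFit(
            a=float(np.clip(1.0 - ys[0], 0.0, 1.0)),
            b=0.0,
            c=init_c,
            rmse=0.0,
            converged=True,
            c_identifiable=False,
        )

    a0 = float(np.clip(1.0 - ys.max(), 0.0, 1.0))

    def residuals(theta):
        a, b, c = theta
        return power_law(xs, a, b, c) - ys

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = least_squares(
            residuals,
            x0=[a0, init_b, init_c],
            bounds=([0.0, 0.0, -np.inf], [1.0, np.inf, 0.0]),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=20000,
        )
    a, b, c = res.x
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    return PowerLawFit(
        a=float(a),
        b=float(b),
        c=float(c),
        rmse=rmse,
        converged=bool(res.status > 0),
        c_identifiable=bool(b > 1e-6 and c < -1e-6),
    )


def extrapolate(fit: PowerLawFit, x: float) -> float:
    """Predicted F-score at training size *x* (requires ``x >= 1``)."""
    if x < 1:
        raise ValueError("x must be >= 1")
    return float(power_law(x, fit.a, fit.b, fit.c))
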