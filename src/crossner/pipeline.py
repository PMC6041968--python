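"""End-to-end experiment orchestration from a single YAML config.

A config describes where corpora come from (files on disk, or a simulated
family), how classes are remapped, how corpora are split, which learning-
curve designs to run, and whether to fit power laws and compute fingerprints.
One global seed drives everything; each stage derives its own seed as
``crc32(stage_name) XOR global_seed`` so stages do not perturb each other's
random streams.  Re-running the same config reproduces identical artifacts.
"""

from __future__ import annotations

import json
import logging
import os
import zlib
from dataclasses import asdict, dataclass, field
from typing import Any

import yaml

from . import class_remap, corpus_io, ortho_stats, power_analysis, synthetic_data
from .power_analysis import CorpusSplit, SplitSpec
from .tagger import FeatureConfig, TrainConfig

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    return (zlib.crc32(stage.encode()) ^ global_seed) % (2**31)


@dataclass
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "experiment_out"
    corpora: list[dict] = field(default_factory=list)  # {path, format}
    simulate: list[dict] = field(default_factory=list)  # CorpusSpec dicts
    mapping: str | None = None  # TSV path; None = labels used as-is
    target_classes: list[str] = field(default_factory=list)
    split: dict = field(default_factory=dict)  # SplitSpec fields
    curves: dict = field(default_factory=dict)  # designs, xs, scheme, order
    fit: bool = True
    ortho: bool = True
    train: dict = field(default_factory=dict)  # TrainConfig fields
    features: dict = field(default_factory=dict)  # FeatureConfig fields

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        errors = validate_config(raw)
        if errors:
            raise ValueError(
                "invalid experiment config:\n  " + "\n  ".join(errors)
            )
        return cls(**raw)


_KNOWN_KEYS = {
    "seed", "output_dir", "corpora", "simulate", "mapping",
    "target_classes", "split", "curves", "fit", "ortho", "train", "features",
}

_KNOWN_DESIGNS = {"corpus_specific", "merged", "leave_corpus_out"}


def validate_config(raw: dict) -> list[str]:
    """All config problems at once, before any work starts."""
    errors = []
    for k in raw:
        if k not in _KNOWN_KEYS:
            errors.append(f"unknown key {k!r}")
    if not raw.get("corpora") and not raw.get("simulate"):
        errors.append("need either 'corpora' (files) or 'simulate' (specs)")
    for c in raw.get("corpora", []):
        if "path" not in c or "format" not in c:
            errors.append(f"corpus entry {c!r} needs 'path' and 'format'")
        elif not os.path.exists(c["path"]):
            errors.append(f"corpus path {c['path']!r} does not exist")
    if raw.get("mapping") and not os.path.exists(raw["mapping"]):
        errors.append(f"mapping file {raw['mapping']!r} does not exist")
    for d in raw.get("curves", {}).get("designs", []):
        if d not in _KNOWN_DESIGNS:
            errors.append(f"unknown curve design {d!r}")
    return errors


def _geometric_grid(pool_size: int, start: int = 10) -> list[int]:
    xs = []
    x = start
    while x < pool_size:
        xs.append(x)
        x *= 2
    xs.append(pool_size)
    return xs


def run_experiment(config: ExperimentConfig | str) -> dict[str, Any]:
    """Execute the configured stages in order, writing one artifact file per
    stage under ``output_dir`` plus a traceable ``summary.json``."""
    if isinstance(config, str):
        config = ExperimentConfig.from_yaml(config)
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed, "stages": []}

    # --- stage: load / simulate ------------------------------------------
    corpora: list[corpus_io.Corpus] = []
    for entry in config.corpora:
        corpora.append(corpus_io.read_corpus(entry["path"], entry["format"]))
    if config.simulate:
        specs = []
        for d in config.simulate:
            d = dict(d)
            if "orthography" in d:
                d["orthography"] = synthetic_data.OrthographyProfile(**d["orthography"])
            specs.append(synthetic_data.CorpusSpec(**d))
        corpora.extend(
            synthetic_data.generate_corpus_family(
                specs, shared_seed=stage_seed(config.seed, "simulate")
            )
        )
    for c in corpora:
        corpus_io.write_bioc(c, os.path.join(out, f"corpus_{c.name}.bioc.xml"))
    summary["stages"].append({"stage": "load", "corpora": [c.name for c in corpora]})

    # --- stage: validate --------------------------------------------------
    reports = [corpus_io.validate_corpus(c) for c in corpora]
    with open(os.path.join(out, "validation.tsv"), "w", encoding="utf-8") as fh:
        fh.write("corpus\texcluded\treasons\toffset_mismatches\tunrepairable\n")
        for r in reports:
            fh.write(
                f"{r.corpus}\t{r.excluded}\t{','.join(r.reasons)}\t"
                f"{r.offset_mismatches}\t{r.unrepairable}\n"
            )
    corpora = [c for c, r in zip(corpora, reports) if not r.excluded]
    summary["stages"].append(
        {"stage": "validate", "kept": [c.name for c in corpora]}
    )

    # --- stage: remap -----------------------------------------------------
    if config.mapping:
        mapping = class_remap.load_mapping(config.mapping)
        corpora = [class_remap.remap(c, mapping) for c in corpora]
        summary["stages"].append({"stage": "remap", "mapping": config.mapping})
    classes = config.target_classes or sorted(
        {lab for c in corpora for lab in c.labels}
    )

    # --- stage: split -----------------------------------------------------
    split_seed = stage_seed(config.seed, "split")
    spec = SplitSpec(seed=split_seed, **config.split)
    splits = []
    for c in corpora:
        tr, te = power_analysis.split_corpus(c, spec)
        splits.append(CorpusSplit(c.name, tr, te))
    summary["stages"].append(
        {
            "stage": "split",
            "sizes": {
                s.name: [len(s.train.documents), len(s.test.documents)]
                for s in splits
            },
        }
    )

    tcfg = TrainConfig(**config.train) if config.train else TrainConfig()
    fcfg = FeatureConfig(**config.features) if config.features else FeatureConfig()

    # --- stage: curves + fits --------------------------------------------
    curve_rows = []
    fits = {}
    curve_seed = stage_seed(config.seed, "curves")
    designs = config.curves.get("designs", [])
    for cls in classes:
        pool = sum(len(s.train.documents) for s in splits)
        xs = config.curves.get("xs") or _geometric_grid(pool)
        for design in designs:
            if design == "corpus_specific":
                curves = power_analysis.build_curve_corpus_specific(
                    splits, cls, xs, tcfg, fcfg, seed=curve_seed
                )
            elif design == "merged":
                curves = power_analysis.build_curve_merged(
                    splits, cls, xs, tcfg, fcfg, seed=curve_seed,
                    addition_scheme=config.curves.get("addition_scheme", "shuffled"),
                    corpus_order=config.curves.get("corpus_order"),
                )
            else:
                curves = power_analysis.build_curve_leave_corpus_out(
                    splits, cls, xs, tcfg, fcfg, seed=curve_seed
                )
            for curve in curves:
                for p in curve.points:
                    curve_rows.append(
                        (design, cls, curve.source, curve.target_corpus,
                         p.replicate, p.x, p.y)
                    )
                key = f"{design}/{cls}/{curve.source or 'pool'}->{curve.target_corpus}"
                if config.fit and len({p.x for p in curve.points}) >= 3:
                    fit = power_analysis.fit_power_law(curve.points)
                    fits[key] = asdict(fit) | {"asymptote": fit.asymptote}
    if curve_rows:
        with open(os.path.join(out, "curves.tsv"), "w", encoding="utf-8") as fh:
            fh.write("design\tclass\tsource\ttarget\treplicate\tx\tF\n")
            for row in curve_rows:
                fh.write("\t".join(str(v) for v in row) + "\n")
        summary["stages"].append({"stage": "curves", "n_points": len(curve_rows)})
    if fits:
        with open(os.path.join(out, "power_law_fits.json"), "w", encoding="utf-8") as fh:
            json.dump(fits, fh, indent=2)
        summary["stages"].append({"stage": "fit", "curves_fitted": len(fits)})

    # --- stage: orthographic fingerprint ---------------------------------
    if config.ortho:
        by_class = {
            cls: [c for c in corpora if cls in c.labels] for cls in classes
        }
        by_class = {k: v for k, v in by_class.items() if v}
        if by_class:
            fp = ortho_stats.fingerprint(
                by_class, seed=stage_seed(config.seed, "ortho")
            )
            fp.to_tsv(os.path.join(out, "fingerprint.tsv"))
            summary["stages"].append(
                {"stage": "ortho", "columns": len(fp.results)}
            )

    summary["fits"] = fits
    with open(os.path.join(out, "summary.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
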