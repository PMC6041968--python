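"""Inverse-power-law power analysis of learning curves.

Builds a merged-training learning curve over a geometric grid of training
sizes for the shared-lexicon family, fits Yfs(x) = (1-a) - b*x^c, and reports
the asymptotic maximum F (1-a), learning rate b, decay rate c and RMSE.
Also demonstrates recovery on simulated curves with known parameters.
"""

import json
import os

from crossner.experiments import DEFAULT_FCFG, DEFAULT_TCFG, _family_splits
from crossner.power_analysis import build_curve_merged, fit_power_law
from crossner.synthetic_data import CorpusSpec, CurveSimSpec, OrthographyProfile, simulate_curve

SEED = 20260920
OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    fits = {}

    # recovery sanity check on a simulated curve with known parameters
    spec = CurveSimSpec(a=0.2, b=0.5, c=-0.3, xs=tuple(range(10, 610, 20)),
                        noise_sd=0.02, seed=SEED % (2**31))
    fit = fit_power_law(simulate_curve(spec).points)
    print("== simulated curve (true a=0.2, b=0.5, c=-0.3, noise sd 0.02) ==")
    print(f"  fitted a={fit.a:.3f} b={fit.b:.3f} c={fit.c:.3f} "
          f"rmse={fit.rmse:.4f} asymptote={100 * fit.asymptote:.2f}%")
    fits["simulated"] = {"a": fit.a, "b": fit.b, "c": fit.c,
                         "rmse": fit.rmse, "asymptote_pct": 100 * fit.asymptote}

    # empirical curve: merged training on the shared-lexicon family
    base = dict(n_documents=100, tokens_per_doc_mean=12.0, tokens_per_doc_sd=3.0,
                entity_density=2.0, lexicon_size=40, label="Entity")
    specs = [
        CorpusSpec(name="geneA", orthography=OrthographyProfile("gene"),
                   seed=1, **base),
        CorpusSpec(name="geneB", orthography=OrthographyProfile("gene"),
                   lexicon_overlap=0.8, overlap_partner="geneA", seed=2, **base),
    ]
    splits = _family_splits(specs, SEED)
    pool = sum(len(s.train.documents) for s in splits)
    xs = [5, 10, 20, 40, 80, pool]
    curves = build_curve_merged(splits, "Entity", xs, tcfg=DEFAULT_TCFG,
                                fcfg=DEFAULT_FCFG, seed=SEED)
    print("\n== merged-training learning curves (shared family) ==")
    for curve in curves:
        fit = fit_power_law(curve.points)
        print(f"  test={curve.target_corpus}: "
              + ", ".join(f"F({p.x})={100 * p.y:.1f}%" for p in curve.points))
        print(f"    fit: a={fit.a:.3f} b={fit.b:.3f} c={fit.c:.3f} "
              f"rmse={fit.rmse:.4f} -> asymptotic max F = "
              f"{100 * fit.asymptote:.2f}%")
        fits[f"merged/{curve.target_corpus}"] = {
            "a": fit.a, "b": fit.b, "c": fit.c, "rmse": fit.rmse,
            "asymptote_pct": 100 * fit.asymptote,
            "points": [[p.x, p.y] for p in curve.points],
        }

    path = os.path.join(OUT, "power_law_fits.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fits, fh, indent=2)
    print(f"\nwrote {os.path.normpath(path)}")


if __name__ == "__main__":
    main()
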