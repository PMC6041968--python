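"""Merged-corpora training and leave-corpus-out cross-validation.

Two questions, two designs:

* sequential merging — adding corpora one document at a time in a fixed
  order, when does a stylistically isolated test corpus start being
  predicted?  (Its F should jump only after its own corpus's boundary.)
* leave-corpus-out — for a high-overlap family, how much does holding a
  corpus's training data out cost relative to fully merged training?
"""

import os

from crossner.experiments import loco_vs_merged_experiment, sequential_jump_experiment

SEED = 20260920
OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)

    jump = sequential_jump_experiment(seed=SEED)
    print("== sequential corpus addition (gene, gene, variant) ==")
    print(f"  variant-corpus boundary at x = {jump.boundary} training docs")
    rows = ["x\tfscore_pct"]
    for x, y in jump.points:
        marker = "  <- boundary crossed" if x > jump.boundary else ""
        print(f"  x={x:4d}: F = {100 * y:6.2f}%{marker}")
        rows.append(f"{x}\t{100 * y:.2f}")
    print(f"  jump after boundary: {100 * jump.jump:.2f} points")
    with open(os.path.join(OUT, "sequential_curve.tsv"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(rows) + "\n")

    res = loco_vs_merged_experiment(seed=SEED)
    print("\n== leave-corpus-out vs merged (80% lexicon overlap) ==")
    print(f"  merged training F on {res.target}:        {100 * res.merged_f:.2f}%")
    print(f"  leave-{res.target}-out training F:        {100 * res.loco_f:.2f}%")
    print(f"  cost of holding the corpus out: {100 * res.difference:.2f} points")
    with open(os.path.join(OUT, "loco_vs_merged.tsv"), "w", encoding="utf-8") as fh:
        fh.write("target\tmerged_pct\tloco_pct\tdifference_pct\n")
        fh.write(f"{res.target}\t{100 * res.merged_f:.2f}\t"
                 f"{100 * res.loco_f:.2f}\t{100 * res.difference:.2f}\n")
    print(f"\nwrote sequential_curve.tsv and loco_vs_merged.tsv under "
          f"{os.path.normpath(OUT)}")


if __name__ == "__main__":
    main()
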