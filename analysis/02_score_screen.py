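#!/usr/bin/env python
"""Score the simulated screen: offspring viability per instance, parental
exclusion, and severity classes.

Offspring viability = spores viable on the condition / spores viable on
rich medium.  Instances with a non-viable parent are excluded; the rest are
classified as `none` (< 1% loss), `potential_epistasis` (1-20% loss) or
`severe` (>= 20% loss).  Prints the class breakdown and checks it against
the planted truth.
"""

from pathlib import Path

from yeastdmi.io import read_table, write_table
from yeastdmi.screen import instances_from_tables, summarize_screen

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    table = read_table(OUT / "screen_table.tsv")
    parents = read_table(OUT / "parents.tsv")
    labels = read_table(OUT / "screen_labels.tsv")

    summary = summarize_screen(instances_from_tables(table, parents))
    meta = {"script": "02_score_screen"}
    write_table(summary.per_instance, OUT / "screen_instances.tsv", meta=meta)
    write_table(summary.matrix.fillna("excluded").reset_index(),
                OUT / "screen_matrix.tsv", meta=meta)

    print(f"{summary.n_total} instances, {summary.n_excluded} excluded for "
          f"parental non-viability, {summary.n_kept} analysed")
    print(f"  epistasis signal: {summary.n_epistasis}/{summary.n_kept} "
          f"({100 * summary.frac_epistasis:.1f}%)")
    print(f"  severe (>=20% loss): {summary.n_severe}/{summary.n_kept} "
          f"({100 * summary.frac_severe:.1f}%)")

    merged = summary.per_instance.merge(labels, on=["cross_id", "condition"])
    kept = merged[merged.category != "excluded"]
    affected = kept[kept.affected == 1]
    detected = (affected.category != "none").mean() if len(affected) else 0.0
    fp = (kept[kept.affected == 0].category != "none").mean()
    print(f"  planted incompatibilities detected: {100 * detected:.1f}%"
          f" (false-positive rate {100 * fp:.1f}%)")


if __name__ == "__main__":
    main()
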