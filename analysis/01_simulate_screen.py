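#!/usr/bin/env python
"""Simulate the cross-by-condition viability screen.

27 crosses x 20 conditions, 20 full tetrads per instance; 40% of crosses
carry a two-locus recessive incompatibility acting in a random subset of
conditions, and ~10% of instances have a non-viable parent so the exclusion
filter has something to do.  Writes the spore-level screen table, the
parental-viability table and the generating truth to results/.
"""

from pathlib import Path

from yeastdmi.io import write_table
from yeastdmi.simcross import simulate_screen

SEED = 20260928
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    table, parents, labels = simulate_screen(seed=SEED)
    meta = {"seed": SEED, "script": "01_simulate_screen"}
    write_table(table, OUT / "screen_table.tsv", meta=meta)
    write_table(parents, OUT / "parents.tsv", meta=meta)
    write_table(labels, OUT / "screen_labels.tsv", meta=meta)
    n_affected = int(labels.affected.sum())
    print(f"simulated {len(parents)} instances "
          f"({labels.cross_id.nunique()} crosses x "
          f"{labels.condition.nunique()} conditions)")
    print(f"  instances where an incompatibility acts: {n_affected}")
    print(f"  instances with a non-viable parent: {int(labels.parent_fail.sum())}")
    print(f"wrote screen_table.tsv, parents.tsv, screen_labels.tsv to {OUT}")


if __name__ == "__main__":
    main()
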