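#!/usr/bin/env python
"""Nonsense-mutation and tRNA-suppressor annotation.

Works the focal case end to end — a C>T substitution converting the CAA
codon at codon 39 of a respiratory gene into a premature TAA stop, and the
tyrosine-tRNA anticodon change GTA>TTA that creates a TAA suppressor — then
surveys a synthetic 100-strain population (Poisson-distributed nonsense
loads drawn over a shared gene pool) for per-class counts, gene sharing,
and suppressor-creating anticodon mutations.
"""

from pathlib import Path

import numpy as np

from yeastdmi.annot import (
    NonsenseCall,
    STOP_CODONS,
    call_nonsense,
    count_nonsense_by_class,
    detect_trna_suppressor,
    scan_trnas,
    shared_nonsense_genes,
)
from yeastdmi.io import write_table

SEED = 20260928
OUT = Path(__file__).resolve().parent.parent / "results"

# anticodons (DNA 5'->3') of a minimal standard tRNA set
TRNA_SET = [("tY1", "GTA"), ("tY2", "GTA"), ("tQ1", "TTG"), ("tE1", "TTC"),
            ("tW1", "CCA"), ("tL1", "TAA"), ("tS1", "TGA"), ("tK1", "TTT")]

_STOP_GAIN = {"TAA": "CAA", "TAG": "CAG", "TGA": "CGA"}


def make_orf(codon39: str) -> str:
    body = ["GCT"] * 118
    body[37] = codon39  # codon 39 of the ORF
    return "ATG" + "".join(body) + "TAA"


def synthetic_population(n_strains: int, rng) -> dict:
    """Poisson(10) nonsense calls per stop class per strain, drawn over a
    shared pool of 500 genes so some genes recur across strains."""
    gene_pool = [f"gene{i:04d}" for i in range(500)]
    per_strain = {}
    for s in range(n_strains):
        calls = []
        for stop, ref_codon in _STOP_GAIN.items():
            for _ in range(rng.poisson(10)):
                gene = gene_pool[rng.integers(0, len(gene_pool))]
                calls.append(NonsenseCall(gene_id=gene, codon_index=39,
                                          orf_nt_pos=115, ref_codon=ref_codon,
                                          alt_codon=stop))
        per_strain[f"strain{s:03d}"] = calls
    return per_strain


def main():
    # the focal pair of mutations
    orf = make_orf("CAA")
    call = call_nonsense(orf, [(115, "C", "T")], gene_id="resp_gene")[0]
    print(f"nonsense call: {call.gene_id} codon {call.codon_index}, "
          f"ORF position +{call.orf_nt_pos}, {call.ref_codon}->{call.alt_codon}"
          f" ({call.stop_class} class)")
    sup = detect_trna_suppressor("GTA", "TTA", trna_id="tY1")
    print(f"suppressor call: {sup.trna_id} anticodon "
          f"{sup.anticodon_before}->{sup.anticodon_after} reads the "
          f"{sup.suppressed_stop} stop")

    # population survey
    rng = np.random.default_rng(SEED)
    population = synthetic_population(100, rng)
    table = count_nonsense_by_class(population)
    write_table(table.reset_index(names="strain"),
                OUT / "nonsense_class_counts.tsv",
                meta={"seed": SEED, "script": "05_annotation"})
    means = ", ".join(f"{c}: {table[c].mean():.1f}" for c in STOP_CODONS)
    print(f"\n100 synthetic strains, mean nonsense calls per class ({means})")
    n_shared, n_total = shared_nonsense_genes(population)
    print(f"genes with nonsense mutations: {n_total}; shared by >= 2 strains: "
          f"{n_shared} ({100 * n_shared / n_total:.0f}%)")

    # suppressor scan: none without variants, one with the focal change
    assert scan_trnas(TRNA_SET) == []
    print("tRNA scan without variants: no suppressor of any anticodon class")
    hits = scan_trnas(TRNA_SET, {"tY1": [(1, "G", "T")]})
    print(f"tRNA scan with the focal anticodon change: "
          f"{len(hits)} suppressor ({hits[0].trna_id}, "
          f"{hits[0].suppressed_stop} class)")


if __name__ == "__main__":
    main()
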