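#!/usr/bin/env python
"""Bulk-segregant mapping of the two incompatibility loci.

Pools 80 inviable segregants (one per tetrad) from the focal cross,
sequences the pool in silico at 50x with 0.2% error over 1 marker/kb, and
maps the loci two ways: the driver locus as a run of consecutive markers
with reference-parent allele frequency < 0.1, and the rescuer locus as a
marker desert after emulating reference-based SNP calling (positions
without alternate-allele evidence yield no marker).  Overlaps the mapped
regions with a toy annotation to shortlist candidate genes.
"""

from pathlib import Path

import numpy as np

from yeastdmi.bsamap import (
    allele_frequencies,
    ascertain_markers,
    candidate_features,
    detect_low_af_regions,
    detect_marker_deserts,
)
from yeastdmi.io import write_counts_table, write_regions, write_table
from yeastdmi.simcross import (
    make_cross,
    simulate_bsa_counts,
    simulate_spore_pool,
    two_locus_case_model,
    yeast_genome,
)

SEED = 20260928
OUT = Path(__file__).resolve().parent.parent / "results"
DRIVER = ("chrV", 453_574)
RESCUER = ("chrX", 354_280)

# toy gene annotation: two candidates inside the true regions, two decoys
ANNOTATION = [
    ("resp_gene_chrV", "chrV", 453_000, 454_500),
    ("trna_tyr_chrX", "chrX", 354_100, 354_400),
    ("decoy_chrV", "chrV", 100_000, 101_500),
    ("decoy_chrXII", "chrXII", 500_000, 501_500),
]


def main():
    genome = yeast_genome(marker_spacing_bp=1000)
    model = two_locus_case_model()
    design = make_cross(genome, model, seed=SEED)
    rng = np.random.default_rng(SEED)

    pool = simulate_spore_pool(design, "glycerol", 80, "inviable", rng)
    counts = simulate_bsa_counts(pool, 50.0, 0.002, rng)
    meta = {"seed": SEED, "script": "04_bsa_mapping"}
    write_counts_table(counts, OUT / "pool_counts.tsv", meta=meta)

    called = ascertain_markers(counts)
    track = allele_frequencies(called, min_depth=10)
    write_table(track, OUT / "allele_frequencies.tsv", meta=meta)
    print(f"pool of {len(pool)} inviable segregants; "
          f"{len(track)} of {len(counts.records)} markers called, "
          f"genome-wide mean AF {track.af_ref.mean():.3f}")

    low_af = detect_low_af_regions(track)
    deserts = detect_marker_deserts(track, design.genome)
    regions = low_af + deserts
    write_regions(regions, OUT / "regions.bed", OUT / "regions.tsv", meta=meta)

    for region in regions:
        span = (region.end - region.start + 1) / 1000
        hit = ("contains driver locus" if region.contains(*DRIVER)
               else "contains rescuer locus" if region.contains(*RESCUER)
               else "")
        extra = (f"mean AF {region.mean_af:.3f}, {region.n_markers} markers"
                 if region.mean_af is not None else "no markers")
        print(f"  {region.kind}: {region.chrom}:{region.start:,}-"
              f"{region.end:,} ({span:.0f} kb, {extra}) {hit}")

    hits = candidate_features(regions, ANNOTATION)
    print(f"candidate genes overlapping mapped regions: {hits}")


if __name__ == "__main__":
    main()
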