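"""Bulk-segregant allele-frequency mapping.

In a pool of segregants selected for a phenotype, markers linked to a
causal locus show skewed parental allele frequencies while the genome-wide
background sits near 0.5.  Two complementary signals are detected:

* ``low_af_run`` — a run of consecutive markers where the reference-parent
  allele frequency falls below a threshold (default 0.1), marking a region
  where the pool is fixed for the alternate parent.  Isolated sub-threshold
  markers are treated as sequencing noise and dropped (run-length rule).
* ``marker_desert`` — an unusually long gap with no markers at all, the
  footprint of a region fixed for the reference parent when variants are
  called against the reference genome.

Coordinates are 1-based inclusive throughout; the BED writer converts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from yeastdmi.simcross import AlleleCountTrack, GenomeMap

__all__ = [
    "MappedRegion",
    "allele_frequencies",
    "ascertain_markers",
    "detect_low_af_regions",
    "detect_marker_deserts",
    "candidate_features",
]


@dataclass(frozen=True)
class MappedRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    kind: str   # 'low_af_run' | 'marker_desert'
    n_markers: int
    mean_af: float | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def _track_frame(counts) -> tuple:
    if isinstance(counts, AlleleCountTrack):
        return counts.records, counts.ref_parent_label
    return counts, "P1"


def allele_frequencies(counts, min_depth: int = 10) -> pd.DataFrame:
    """Per-marker reference-parent allele frequency.

    Returns columns chrom, pos, af_ref, depth, pass_depth; markers below
    ``min_depth`` keep their AF estimate but are flagged and excluded from
    region detection.
    """
    df, _label = _track_frame(counts)
    if (df[["ref_count", "alt_count"]].to_numpy() < 0).any():
        raise ValueError("negative read counts")
    depth = df["ref_count"] + df["alt_count"]
    with np.errstate(invalid="ignore"):
        af = df["ref_count"] / depth
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "af_ref": af,
            "depth": depth,
            "pass_depth": depth >= min_depth,
        }
    )
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def ascertain_markers(counts, min_alt_count: int = 2,
                      min_alt_fraction: float = 0.1) -> AlleleCountTrack:
    """Emulate reference-based SNP calling on the pool: a position is only
    called (kept as a marker) when the alternate-parent allele has at least
    ``min_alt_count`` reads and at least ``min_alt_fraction`` of the depth —
    pooled callers cannot distinguish lower fractions from sequencing noise.
    Regions fixed for the reference parent thereby become marker deserts."""
    df, label = _track_frame(counts)
    depth = df["ref_count"] + df["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, df["alt_count"] / depth, 0.0)
    kept = df[(df["alt_count"] >= min_alt_count)
              & (frac >= min_alt_fraction)].reset_index(drop=True)
    return AlleleCountTrack(records=kept, ref_parent_label=label)


def detect_low_af_regions(track: pd.DataFrame, af_threshold: float = 0.1,
                          min_run: int = 5, max_violations: int = 0) -> list:
    """Maximal runs of >= ``min_run`` consecutive depth-passing markers with
    af_ref < ``af_threshold``.

    Runs shorter than ``min_run`` are dropped as noise.  ``max_violations``
    allows that many above-threshold markers inside a run (merging runs
    separated by short violations); the default 0 requires every marker in
    the run to be sub-threshold.  Region bounds are the first and last
    sub-threshold marker positions of the run.
    """
    regions = []
    usable = track[track["pass_depth"]] if "pass_depth" in track else track
    for chrom, grp in usable.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        af = grp["af_ref"].to_numpy()
        low = af < af_threshold
        runs = _runs_with_tolerance(low, max_violations)
        for i0, i1 in runs:  # half-open marker-index interval
            idx = np.arange(i0, i1)
            sub = idx[low[idx]]
            if len(sub) < min_run:
                continue
            regions.append(
                MappedRegion(
                    chrom=str(chrom),
                    start=int(pos[sub[0]]),
                    end=int(pos[sub[-1]]),
                    kind="low_af_run",
                    n_markers=int(len(sub)),
                    mean_af=float(af[sub].mean()),
                )
            )
    return regions


def _runs_with_tolerance(low: np.ndarray, max_violations: int) -> list:
    """Maximal index runs of True values, allowing up to ``max_violations``
    interior False markers between True stretches."""
    runs = []
    n = len(low)
    i = 0
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        violations_end = j  # last True seen
        budget = max_violations
        while j < n:
            if low[j]:
                violations_end = j
                j += 1
            elif budget > 0:
                budget -= 1
                j += 1
            else:
                break
        runs.append((i, violations_end + 1))
        i = violations_end + 1
    return runs


def detect_marker_deserts(track: pd.DataFrame, genome: GenomeMap,
                          gap_factor: float = 10.0) -> list:
    """Inter-marker (and chromosome-end) gaps longer than ``gap_factor``
    times the chromosome's median marker spacing.

    The reported region is the marker-free interior of the gap.  Chromosomes
    with fewer than 10 markers are skipped (median spacing unstable).
    """
    regions = []
    lengths = genome.chrom_lengths
    for chrom, grp in track.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        if len(pos) < 10:
            continue
        spacing = np.diff(pos)
        cutoff = gap_factor * float(np.median(spacing))
        chrom_len = lengths.get(str(chrom))
        # interior gaps
        for left, right in zip(pos[:-1], pos[1:]):
            if right - left > cutoff:
                regions.append(
                    MappedRegion(chrom=str(chrom), start=int(left) + 1,
                                 end=int(right) - 1, kind="marker_desert",
                                 n_markers=0)
                )
        # chromosome-end gaps
        if pos[0] - 1 > cutoff:
            regions.append(
                MappedRegion(chrom=str(chrom), start=1, end=int(pos[0]) - 1,
                             kind="marker_desert", n_markers=0)
            )
        if chrom_len is not None and chrom_len - pos[-1] > cutoff:
            regions.append(
                MappedRegion(chrom=str(chrom), start=int(pos[-1]) + 1,
                             end=int(chrom_len), kind="marker_desert",
                             n_markers=0)
            )
    return regions


def candidate_features(regions, annotations) -> list:
    """Feature ids whose 1-based inclusive interval overlaps any region.

    ``annotations`` is an iterable of (feature_id, chrom, start, end) or a
    DataFrame with those columns.
    """
    if isinstance(annotations, pd.DataFrame):
        annotations = list(
            annotations[["feature_id", "chrom", "start", "end"]].itertuples(
                index=False, name=None
            )
        )
    hits = []
    for feature_id, chrom, start, end in annotations:
        if start > end:
            raise ValueError(f"invalid interval for {feature_id}")
        for region in regions:
            if region.chrom == chrom and start <= region.end and end >= region.start:
                hits.append(feature_id)
                break
    return hits
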