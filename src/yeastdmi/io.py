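"""Table readers/writers and run configuration.

Every writer prepends ``#``-prefixed header lines recording the tool
version, seed and parameters; every reader tolerates them.  Genomic
intervals are written both as BED (0-based half-open) and as human-facing
TSV with explicit 1-based inclusive columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from yeastdmi.simcross import AlleleCountTrack

__all__ = [
    "RunConfig",
    "read_config",
    "write_table",
    "read_table",
    "read_counts_table",
    "write_counts_table",
    "write_regions",
    "read_tetrad_counts",
    "write_growth_csv",
    "read_growth_csv",
]


class TableFormatError(ValueError):
    pass


_THRESHOLD_RANGES = {
    "af_threshold": (0.0, 1.0),
    "epistasis_threshold": (0.0, 1.0),
    "severe_threshold": (0.0, 1.0),
    "min_run": (1, 10_000),
    "min_depth": (0, 100_000),
}


@dataclass
class RunConfig:
    """Flat pipeline configuration; thresholds validated against their
    documented ranges and the seed recorded in every output header."""

    seed: int = 0
    out_dir: str = "results"
    paths: dict = field(default_factory=dict)
    af_threshold: float = 0.1
    min_run: int = 5
    min_depth: int = 10
    epistasis_threshold: float = 0.01
    severe_threshold: float = 0.20
    coverage: float = 50.0
    error_rate: float = 0.002
    pool_size: int = 80
    n_crosses: int = 27
    n_conditions: int = 20
    tetrads_per_instance: int = 20
    stages: tuple = ("simulate", "screen", "classify", "map", "annotate", "growth")

    def __post_init__(self):
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")

    def header_meta(self) -> dict:
        from yeastdmi import __version__

        return {
            "tool": f"yeastdmi {__version__}",
            "seed": self.seed,
            "af_threshold": self.af_threshold,
            "min_run": self.min_run,
            "min_depth": self.min_depth,
            "epistasis_threshold": self.epistasis_threshold,
            "severe_threshold": self.severe_threshold,
        }


def read_config(path) -> RunConfig:
    """Flat key=value config file; '#' comments and blank lines ignored."""
    fields = {f.name for f in RunConfig.__dataclass_fields__.values()}
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise TableFormatError(f"{path}:{lineno}: expected key=value")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "stages":
            kwargs[key] = tuple(s.strip() for s in value.split(","))
        elif key.startswith("path."):
            kwargs.setdefault("paths", {})[key[5:]] = value
        elif key in fields:
            current = RunConfig.__dataclass_fields__[key].default
            kwargs[key] = type(current)(value) if current is not None else value
        else:
            raise TableFormatError(f"{path}:{lineno}: unknown key {key!r}")
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# generic headered tables

def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                sep: str = "\t", index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep=sep, index=index)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


# ---------------------------------------------------------------------------
# allele-count tracks

_COUNT_COLS = ["chrom", "pos", "ref_count", "alt_count"]


def write_counts_table(track: AlleleCountTrack, path,
                       meta: dict | None = None) -> None:
    meta = dict(meta or {})
    meta.setdefault("ref_parent", track.ref_parent_label)
    write_table(track.records[_COUNT_COLS], path, meta=meta)


def _read_counts_vcf(path) -> pd.DataFrame:
    """Minimal VCF entry point: biallelic rows with per-sample AD depths."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise TableFormatError(f"{path}: VCF has no sample column with AD")
        for rec in vcf:
            sample = rec.samples[samples[0]]
            ad = sample.get("AD")
            if ad is None or len(ad) < 2:
                raise TableFormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks AD ref,alt depths"
                )
            rows.append((rec.chrom, rec.pos, int(ad[0]), int(ad[1])))
    return pd.DataFrame(rows, columns=_COUNT_COLS)


def read_counts_table(path) -> AlleleCountTrack:
    """Read pooled allele counts from TSV (chrom, pos, ref_count, alt_count)
    or a minimal VCF with AD-style depths.

    Duplicate positions are rejected; unsorted input is sorted with a
    warning.
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#") or line.startswith("##fileformat"):
                first = line
                break
    if path.suffix == ".vcf" or first.startswith("##fileformat=VCF"):
        df = _read_counts_vcf(path)
    else:
        df = read_table(path)
        missing = [c for c in _COUNT_COLS if c not in df.columns]
        if missing:
            raise TableFormatError(f"{path}: missing columns {missing}")
        df = df[_COUNT_COLS]
        bad = df[df[["pos", "ref_count", "alt_count"]].isna().any(axis=1)]
        if len(bad):
            raise TableFormatError(
                f"{path}: malformed row for {bad.iloc[0]['chrom']!r}"
            )
    if df.duplicated(["chrom", "pos"]).any():
        dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
        raise TableFormatError(f"{path}: duplicate position {dup.chrom}:{dup.pos}")
    sorted_df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if not df.reset_index(drop=True).equals(sorted_df):
        warnings.warn(f"{path}: positions unsorted; sorting", stacklevel=2)
    return AlleleCountTrack(records=sorted_df)


# ---------------------------------------------------------------------------
# mapped regions

def write_regions(regions, bed_path, tsv_path, meta: dict | None = None) -> None:
    """Regions as BED (0-based half-open) plus a 1-based inclusive TSV with
    mean AF and marker counts."""
    bed = pd.DataFrame(
        [(r.chrom, r.start - 1, r.end, r.kind) for r in regions],
        columns=["chrom", "start", "end", "name"],
    )
    Path(bed_path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(bed_path, sep="\t", index=False, header=False)
    tsv = pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.kind, r.n_markers,
             "" if r.mean_af is None else r.mean_af)
            for r in regions
        ],
        columns=["chrom", "start_1based", "end_1based", "kind", "n_markers",
                 "mean_af"],
    )
    write_table(tsv, tsv_path, meta=meta)


def read_tetrad_counts(path) -> dict:
    """TSV with columns viable_count, n_tetrads -> mapping."""
    df = read_table(path)
    for col in ("viable_count", "n_tetrads"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col}")
    return {int(r.viable_count): int(r.n_tetrads) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# growth curves

def write_growth_csv(curves, path, meta: dict | None = None) -> None:
    """Growth CSV: time_h column then one OD column per well, plus an
    adjacent well-map TSV (<path>.wells.tsv) with strain/plasmid labels."""
    times = curves[0].times
    data = {"time_h": times}
    wells = []
    for curve in curves:
        if len(curve.times) != len(times) or not (curve.times == times).all():
            raise TableFormatError("all curves must share the same time grid")
        data[curve.well_id] = curve.od
        wells.append((curve.well_id, curve.strain, curve.plasmid))
    write_table(pd.DataFrame(data), path, meta=meta, sep=",")
    wellmap = pd.DataFrame(wells, columns=["well", "strain", "plasmid"])
    write_table(wellmap, str(path) + ".wells.tsv", meta=meta)


def read_growth_csv(path, well_map_path=None) -> list:
    from yeastdmi.growth import GrowthCurve

    df = pd.read_csv(path, comment="#")
    if "time_h" not in df.columns:
        raise TableFormatError(f"{path}: missing time_h column")
    well_map_path = well_map_path or str(path) + ".wells.tsv"
    labels = {}
    if Path(well_map_path).exists():
        wm = read_table(well_map_path)
        labels = {r.well: (r.strain, r.plasmid) for r in wm.itertuples()}
    curves = []
    for col in df.columns:
        if col == "time_h":
            continue
        strain, plasmid = labels.get(col, ("", ""))
        curves.append(
            GrowthCurve(times=df["time_h"].to_numpy(), od=df[col].to_numpy(),
                        well_id=col, strain=str(strain), plasmid=str(plasmid))
        )
    return curves
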