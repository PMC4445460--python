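"""Synthetic cross simulator.

Emulates a haploid x haploid yeast cross segregating biallelic SNP markers:
meiosis into tetrads (2:2 segregation at every locus), condition-dependent
spore lethality under configurable incompatibility models, pooled-sequencing
allele counts, cross-by-condition screen tables, and growth phenotyping data.

Meiosis model
-------------
Each chromosome is simulated as a bivalent of four chromatids (two sisters
per parent).  Crossovers fall as a Poisson process along the genetic map
with no chiasma or chromatid interference (Haldane): each event exchanges
the distal segments of one chromatid from each homolog, chosen uniformly.
Chromatids are then packaged into the four spores by an independent uniform
permutation per chromosome, so markers on different chromosomes receive
independent uniform 2:2 spore partitions (the 6 partitions equiprobable),
which yields PD:NPD:TT = 1:1:4 for unlinked locus pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomeMap",
    "IncompatibilityModel",
    "CrossDesign",
    "Spore",
    "Tetrad",
    "AlleleCountTrack",
    "yeast_genome",
    "make_cross",
    "simulate_tetrad",
    "simulate_tetrads",
    "simulate_spore_pool",
    "simulate_bsa_counts",
    "simulate_screen",
    "simulate_growth_curve",
    "simulate_colony_sizes",
    "PoolFilterError",
]

P1, P2 = "P1", "P2"
MODEL_KINDS = ("none", "two_locus_unlinked", "two_locus_linked", "k_locus")

# S. cerevisiae chromosome sizes, rounded to the kb.
_YEAST_CHROMS = [
    ("chrI", 230_000), ("chrII", 813_000), ("chrIII", 317_000),
    ("chrIV", 1_532_000), ("chrV", 577_000), ("chrVI", 270_000),
    ("chrVII", 1_091_000), ("chrVIII", 563_000), ("chrIX", 440_000),
    ("chrX", 745_000), ("chrXI", 667_000), ("chrXII", 1_078_000),
    ("chrXIII", 924_000), ("chrXIV", 784_000), ("chrXV", 1_091_000),
    ("chrXVI", 948_000),
]


class ConfigurationError(ValueError):
    """Inconsistent simulation or model configuration."""


class PoolFilterError(RuntimeError):
    """Spore-pool filter made no progress (e.g. keep='inviable' with model='none')."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GenomeMap:
    """Marker map over named chromosomes.

    ``cm_per_kb`` sets the genetic map density used by the crossover model;
    the default 0.35 cM/kb is the S. cerevisiae genome average.
    """

    chromosomes: tuple  # of (name, length_bp)
    markers: tuple      # of (chrom, pos, marker_id)
    cm_per_kb: float = 0.35

    def __post_init__(self):
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names")
        lengths = dict(self.chromosomes)
        seen = set()
        for chrom, pos, _mid in self.markers:
            if chrom not in lengths:
                raise ConfigurationError(f"marker on unknown chromosome {chrom!r}")
            if not 1 <= pos <= lengths[chrom]:
                raise ConfigurationError(f"marker position {pos} outside {chrom}")
            if (chrom, pos) in seen:
                raise ConfigurationError(f"duplicate marker at {chrom}:{pos}")
            seen.add((chrom, pos))

    @property
    def chrom_lengths(self) -> dict:
        return dict(self.chromosomes)

    def with_markers(self, extra) -> "GenomeMap":
        existing = {(c, p) for c, p, _ in self.markers}
        new = [m for m in extra if (m[0], m[1]) not in existing]
        markers = sorted(
            list(self.markers) + list(new),
            key=lambda m: ([c[0] for c in self.chromosomes].index(m[0]), m[1]),
        )
        return replace(self, markers=tuple(markers))


def yeast_genome(marker_spacing_bp: int = 1000, chromosomes=None,
                 cm_per_kb: float = 0.35) -> GenomeMap:
    """A 16-chromosome genome with evenly spaced markers.

    The default 1 kb spacing mirrors the marker density of a
    S288c x wild-isolate cross (~60k SNPs genome-wide).
    """
    chromosomes = tuple(chromosomes or _YEAST_CHROMS)
    markers = []
    for name, length in chromosomes:
        for pos in range(marker_spacing_bp, length + 1, marker_spacing_bp):
            markers.append((name, pos, f"{name}_{pos}"))
    return GenomeMap(chromosomes=chromosomes, markers=tuple(markers),
                     cm_per_kb=cm_per_kb)


@dataclass(frozen=True)
class IncompatibilityModel:
    """A lethal allelic combination, its penetrance, and where it acts.

    ``lethal_loci`` are (chrom, pos, lethal_parent) triples: a spore dies in
    a listed condition iff it inherits the lethal parent's allele at every
    listed locus.  The worked two-locus case is the P2 allele at locus A
    (premature-stop allele of a respiratory gene) combined with the P1
    allele at locus B (absence of the tRNA suppressor).
    """

    kind: str
    lethal_loci: tuple = ()
    r: float | None = None
    penetrance: float = 1.0
    conditions: frozenset = frozenset()

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        loci = tuple(tuple(l) for l in self.lethal_loci)
        object.__setattr__(self, "lethal_loci", loci)
        object.__setattr__(self, "conditions", frozenset(self.conditions))
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigurationError("penetrance outside [0, 1]")
        for _c, _p, parent in loci:
            if parent not in (P1, P2):
                raise ConfigurationError(f"lethal_parent must be P1/P2, got {parent!r}")
        if self.kind.startswith("two_locus") and len(loci) != 2:
            raise ConfigurationError("two-locus kinds need exactly 2 lethal loci")
        if self.kind == "k_locus" and len(loci) < 1:
            raise ConfigurationError("k_locus needs k >= 1 loci")
        if self.kind == "two_locus_unlinked" and loci[0][0] == loci[1][0]:
            raise ConfigurationError("unlinked loci must lie on distinct chromosomes")
        if self.kind == "k_locus":
            chroms = [l[0] for l in loci]
            if len(set(chroms)) != len(chroms):
                raise ConfigurationError("k_locus loci must lie on distinct chromosomes")
        if self.kind == "two_locus_linked":
            if self.r is None or not 0.0 <= self.r <= 0.5:
                raise ConfigurationError("linked model needs r in [0, 0.5]")
            if loci[0][0] != loci[1][0]:
                raise ConfigurationError("linked loci must share a chromosome")

    @property
    def k(self) -> int:
        return len(self.lethal_loci)


def two_locus_case_model(penetrance: float = 1.0,
                         conditions=("glycerol",)) -> IncompatibilityModel:
    """The worked incompatibility geometry: driver on the right arm of chrV,
    rescuer on the left arm of chrX; lethal combination = P2 at the driver
    with P1 at the rescuer (no suppressor)."""
    return IncompatibilityModel(
        kind="two_locus_unlinked",
        lethal_loci=(("chrV", 453_574, P2), ("chrX", 354_280, P1)),
        penetrance=penetrance,
        conditions=frozenset(conditions),
    )


@dataclass(frozen=True)
class CrossDesign:
    """A reproducible cross: genome, marker order, parental alleles, model."""

    genome: GenomeMap
    model: IncompatibilityModel
    marker_table: pd.DataFrame = field(compare=False)  # chrom,pos,id,p1_allele,p2_allele
    seed: int = 0

    @property
    def n_markers(self) -> int:
        return len(self.marker_table)

    def marker_index(self, chrom: str, pos: int) -> int:
        hit = self.marker_table.index[
            (self.marker_table["chrom"] == chrom) & (self.marker_table["pos"] == pos)
        ]
        if len(hit) != 1:
            raise ConfigurationError(f"no marker at {chrom}:{pos}")
        return int(hit[0])

    @property
    def lethal_indices(self) -> list:
        return [
            (self.marker_index(c, p), parent)
            for c, p, parent in self.model.lethal_loci
        ]


@dataclass
class Spore:
    """One haploid meiotic product.

    ``origins`` is a uint8 vector over the design's marker order
    (0 = P1, 1 = P2); ``viability`` maps condition name -> bool.
    """

    origins: np.ndarray
    viability: dict
    design: CrossDesign = field(repr=False)
    spore_id: str = ""

    @property
    def genotype(self) -> dict:
        ids = self.design.marker_table["id"].to_numpy()
        return {m: (P2 if o else P1) for m, o in zip(ids, self.origins)}

    def origin_at(self, chrom: str, pos: int) -> str:
        return P2 if self.origins[self.design.marker_index(chrom, pos)] else P1


@dataclass
class Tetrad:
    """Four spores from one meiosis; 2:2 segregation at every marker."""

    tetrad_id: str
    spores: list

    @property
    def genotypes(self) -> np.ndarray:
        return np.stack([s.origins for s in self.spores])

    def n_viable(self, condition: str) -> int:
        return sum(s.viability.get(condition, True) for s in self.spores)


@dataclass
class AlleleCountTrack:
    """Per-marker pooled read counts toward the reference parent.

    ``records`` columns: chrom, pos (1-based), ref_count, alt_count,
    sorted by chromosome then position.
    """

    records: pd.DataFrame
    ref_parent_label: str = P1

    def __post_init__(self):
        df = self.records
        required = {"chrom", "pos", "ref_count", "alt_count"}
        if not required.issubset(df.columns):
            raise ConfigurationError(f"count track needs columns {sorted(required)}")
        if (df[["ref_count", "alt_count"]].to_numpy() < 0).any():
            raise ConfigurationError("negative read counts")
        for _c, grp in df.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ConfigurationError("positions unsorted within chromosome")


# ---------------------------------------------------------------------------
# cross construction

_BASES = np.array(list("ACGT"))


def make_cross(genome: GenomeMap, model: IncompatibilityModel,
               seed: int = 0) -> CrossDesign:
    """Build a reproducible cross design; identical seed => identical design.

    Model loci absent from the marker map are added as markers.  Parental
    alleles at each marker are arbitrary distinct bases (for table output);
    segregation tracks parental origin, not sequence.
    """
    chrom_names = {c[0] for c in genome.chromosomes}
    for chrom, pos, _parent in model.lethal_loci:
        if chrom not in chrom_names:
            raise ConfigurationError(f"lethal locus on unknown chromosome {chrom!r}")
    extra = [(c, p, f"{c}_{p}_locus") for c, p, _ in model.lethal_loci]
    genome = genome.with_markers(extra)

    rng = np.random.default_rng(seed)
    n = len(genome.markers)
    p1 = _BASES[rng.integers(0, 4, n)]
    shift = rng.integers(1, 4, n)
    p2 = _BASES[(np.searchsorted(_BASES, p1) + shift) % 4]
    table = pd.DataFrame(
        {
            "chrom": [m[0] for m in genome.markers],
            "pos": [m[1] for m in genome.markers],
            "id": [m[2] for m in genome.markers],
            "p1_allele": p1,
            "p2_allele": p2,
        }
    )
    return CrossDesign(genome=genome, model=model, marker_table=table, seed=int(seed))


# ---------------------------------------------------------------------------
# meiosis

def _chrom_blocks(design: CrossDesign):
    """Per-chromosome (marker slice, genetic positions in Morgans)."""
    tbl = design.marker_table
    morgan_per_bp = design.genome.cm_per_kb / 100.0 / 1000.0
    blocks = []
    start = 0
    for chrom, grp in tbl.groupby("chrom", sort=False):
        stop = start + len(grp)
        gpos = grp["pos"].to_numpy(dtype=float) * morgan_per_bp
        blocks.append((slice(start, stop), gpos))
        start = stop
    return blocks


def _meiosis_chromosome(gpos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Origins (4 chromatids x n markers) after Haldane crossing over,
    chromatids already permuted into spore order."""
    n = len(gpos)
    out = np.empty((4, n), dtype=np.uint8)
    cur = np.array([0, 0, 1, 1], dtype=np.uint8)
    span = gpos[-1] - gpos[0] if n > 1 else 0.0
    n_ev = rng.poisson(2.0 * span) if span > 0 else 0
    if n_ev:
        ev = np.sort(rng.uniform(gpos[0], gpos[-1], n_ev))
        chrom_a = rng.integers(0, 2, n_ev)   # chromatid of homolog 1
        chrom_b = rng.integers(2, 4, n_ev)   # chromatid of homolog 2
        start = 0
        for k in range(n_ev):
            stop = int(np.searchsorted(gpos, ev[k], side="right"))
            out[:, start:stop] = cur[:, None]
            start = stop
            i, j = chrom_a[k], chrom_b[k]
            cur[i], cur[j] = cur[j], cur[i]
        out[:, start:] = cur[:, None]
    else:
        out[:] = cur[:, None]
    return out[rng.permutation(4)]


def simulate_tetrad(design: CrossDesign, rng, tetrad_id: str = "t0") -> Tetrad:
    """One meiosis: 2:2 segregation at every marker, viability per condition.

    A spore carries the lethal combination iff its origin equals the lethal
    parent at every model locus; in each model condition such a spore is
    inviable with probability = penetrance.
    """
    rng = _as_rng(rng)
    n = design.n_markers
    geno = np.empty((4, n), dtype=np.uint8)
    for sl, gpos in _chrom_blocks(design):
        geno[:, sl] = _meiosis_chromosome(gpos, rng)

    model = design.model
    lethal = np.ones(4, dtype=bool) if model.lethal_loci else np.zeros(4, dtype=bool)
    for idx, parent in design.lethal_indices:
        lethal &= geno[:, idx] == (1 if parent == P2 else 0)

    spores = []
    for s in range(4):
        viability = {}
        for cond in sorted(model.conditions):
            dead = bool(lethal[s]) and (rng.random() < model.penetrance)
            viability[cond] = not dead
        spores.append(
            Spore(origins=geno[s], viability=viability, design=design,
                  spore_id=f"{tetrad_id}.{chr(ord('a') + s)}")
        )
    return Tetrad(tetrad_id=tetrad_id, spores=spores)


def simulate_tetrads(design: CrossDesign, n: int, rng) -> list:
    rng = _as_rng(rng)
    return [simulate_tetrad(design, rng, tetrad_id=f"t{i}") for i in range(n)]


# ---------------------------------------------------------------------------
# pools and pooled sequencing

def simulate_spore_pool(design: CrossDesign, condition: str, n_target: int,
                        keep: str, rng, max_tetrads: int | None = None) -> list:
    """Draw one random spore per independent tetrad, retain those matching
    the viability filter, until ``n_target`` are retained.

    Raises :class:`PoolFilterError` if the filter makes no progress within
    ``max_tetrads`` meioses (default ``max(1000, 100 * n_target)``).
    """
    if n_target < 1:
        raise ConfigurationError("n_target must be >= 1")
    if keep not in ("viable", "inviable"):
        raise ConfigurationError("keep must be 'viable' or 'inviable'")
    rng = _as_rng(rng)
    max_tetrads = max_tetrads or max(1000, 100 * n_target)
    pool: list = []
    for i in range(max_tetrads):
        tet = simulate_tetrad(design, rng, tetrad_id=f"pool_t{i}")
        spore = tet.spores[rng.integers(0, 4)]
        viable = spore.viability.get(condition, True)
        if (keep == "viable") == viable:
            pool.append(spore)
            if len(pool) == n_target:
                return pool
    raise PoolFilterError(
        f"retained only {len(pool)}/{n_target} spores after {max_tetrads} tetrads; "
        f"filter keep={keep!r} on condition {condition!r} may be impossible "
        f"under model kind {design.model.kind!r}"
    )


def simulate_bsa_counts(pool: list, coverage: float, error_rate: float,
                        rng) -> AlleleCountTrack:
    """Pooled-sequencing read counts at every marker.

    Depth per marker is Poisson(coverage); each read reports the allele of a
    uniformly random pool member, flipped with probability ``error_rate``
    (implemented through the equivalent binomial marginal).
    """
    if coverage <= 0:
        raise ConfigurationError("coverage must be positive")
    if not 0.0 <= error_rate <= 1.0:
        raise ConfigurationError("error_rate outside [0, 1]")
    if not pool:
        raise ConfigurationError("empty pool")
    rng = _as_rng(rng)
    design = pool[0].design
    geno = np.stack([s.origins for s in pool])        # spores x markers
    f_ref = (geno == 0).mean(axis=0)                  # pool frequency of P1 allele
    p_ref_read = f_ref * (1.0 - error_rate) + (1.0 - f_ref) * error_rate
    depth = rng.poisson(coverage, size=geno.shape[1])
    ref = rng.binomial(depth, p_ref_read)
    df = design.marker_table[["chrom", "pos"]].copy()
    df["ref_count"] = ref
    df["alt_count"] = depth - ref
    return AlleleCountTrack(records=df, ref_parent_label=P1)


# ---------------------------------------------------------------------------
# screen simulation

def _random_model(kind: str, genome: GenomeMap, conditions, rng) -> IncompatibilityModel:
    chroms = list(genome.chromosomes)
    if kind == "none":
        return IncompatibilityModel(kind="none")
    n_cond = max(1, rng.binomial(len(conditions), 0.3))
    affected = frozenset(rng.choice(list(conditions), size=n_cond, replace=False))
    if kind == "two_locus_linked":
        name, length = chroms[rng.integers(0, len(chroms))]
        a, b = np.sort(rng.integers(1, length + 1, 2))
        while a == b:
            a, b = np.sort(rng.integers(1, length + 1, 2))
        loci = ((name, int(a), P2), (name, int(b), P1))
        return IncompatibilityModel(kind=kind, lethal_loci=loci, r=0.2,
                                    conditions=affected)
    k = 2 if kind == "two_locus_unlinked" else int(rng.integers(3, 5))
    picks = rng.choice(len(chroms), size=k, replace=False)
    loci = tuple(
        (chroms[c][0], int(rng.integers(1, chroms[c][1] + 1)),
         P2 if i == 0 else (P1 if rng.random() < 0.5 else P2))
        for i, c in enumerate(picks)
    )
    return IncompatibilityModel(kind=kind, lethal_loci=loci, conditions=affected)


def simulate_screen(n_crosses: int = 27, n_conditions: int = 20,
                    mix: dict | None = None, tetrads_per_instance: int = 20,
                    parent_fail_rate: float = 0.10, seed=0,
                    marker_spacing_bp: int = 100_000):
    """Simulate a cross x condition viability screen.

    Each cross draws an incompatibility model kind from ``mix`` (a mapping
    model-kind -> proportion, default 60% none / 40% two_locus_unlinked);
    ``parent_fail_rate`` of instances are marked with a non-viable parent to
    exercise the exclusion filter (their spore data are still emitted).

    Returns ``(screen_table, parents_table, labels_table)`` data frames.
    ``screen_table`` is long format: cross_id, condition, tetrad_id,
    spore_id, viable_permissive, viable_condition.  ``labels_table`` carries
    the generating truth per instance (model kind, affected flag).
    """
    mix = mix or {"none": 0.6, "two_locus_unlinked": 0.4}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ConfigurationError("mix proportions must sum to 1")
    rng = _as_rng(seed)
    conditions = [f"cond{j + 1:02d}" for j in range(n_conditions)]
    genome = yeast_genome(marker_spacing_bp=marker_spacing_bp)
    kinds = list(mix)
    probs = np.array([mix[k] for k in kinds], dtype=float)

    screen_rows, parent_rows, label_rows = [], [], []
    for i in range(n_crosses):
        cross_id = f"cross{i + 1:02d}"
        kind = kinds[rng.choice(len(kinds), p=probs)]
        model = _random_model(kind, genome, conditions, rng)
        design = make_cross(genome, model, seed=int(rng.integers(0, 2**31)))
        tetrads = simulate_tetrads(design, tetrads_per_instance, rng)
        for cond in conditions:
            parent_fail = rng.random() < parent_fail_rate
            p1_ok, p2_ok = True, True
            if parent_fail:
                if rng.random() < 0.5:
                    p1_ok = False
                else:
                    p2_ok = False
            for tet in tetrads:
                for spore in tet.spores:
                    screen_rows.append(
                        (cross_id, cond, tet.tetrad_id, spore.spore_id, 1,
                         int(spore.viability.get(cond, True)))
                    )
            parent_rows.append((cross_id, cond, int(p1_ok), int(p2_ok)))
            label_rows.append(
                (cross_id, cond, model.kind, int(cond in model.conditions),
                 int(parent_fail))
            )

    screen_table = pd.DataFrame(
        screen_rows,
        columns=["cross_id", "condition", "tetrad_id", "spore_id",
                 "viable_permissive", "viable_condition"],
    )
    parents = pd.DataFrame(
        parent_rows, columns=["cross_id", "condition", "p1_viable", "p2_viable"]
    )
    labels = pd.DataFrame(
        label_rows,
        columns=["cross_id", "condition", "model_kind", "affected", "parent_fail"],
    )
    return screen_table, parents, labels


# ---------------------------------------------------------------------------
# phenotyping data

def simulate_growth_curve(rate: float, lag_h: float, carrying_capacity: float,
                          noise_sd: float, times, rng, od0: float = 0.05,
                          well_id: str = "", strain: str = "",
                          plasmid: str = ""):
    """Logistic OD trajectory with lag and i.i.d. Gaussian noise, floored at 0.

    Emulates a 48 h microculture read at fixed intervals: exponential growth
    at ``rate``/h after ``lag_h``, saturating at ``carrying_capacity``.
    """
    from yeastdmi.growth import GrowthCurve

    if rate <= 0:
        raise ConfigurationError("rate must be positive")
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ConfigurationError("times must be strictly increasing")
    rng = _as_rng(rng)
    t = np.maximum(times - lag_h, 0.0)
    k = carrying_capacity
    od = k / (1.0 + (k - od0) / od0 * np.exp(-rate * t))
    od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.maximum(od, 0.0)
    return GrowthCurve(times=times, od=od, well_id=well_id, strain=strain,
                       plasmid=plasmid)


def simulate_colony_sizes(strains, conditions, effects: dict | None = None,
                          n_replicates: int = 12, base_size: float = 400.0,
                          noise_cv: float = 0.05, seed=0,
                          reference_condition: str = "YPD") -> pd.DataFrame:
    """Colony-size grid for suppressor-vs-control plasmid phenotyping.

    ``effects`` maps (strain, condition) -> fractional fitness change of the
    suppressor arm relative to control (e.g. 0.2 = +20%); unlisted pairs get
    no effect.  Every (strain, plasmid) combination is also measured on the
    reference medium.  Multiplicative replicate noise with CV ``noise_cv``.
    """
    effects = effects or {}
    rng = _as_rng(seed)
    rows = []
    all_conditions = [reference_condition] + [
        c for c in conditions if c != reference_condition
    ]
    for strain in strains:
        for plasmid in ("SUP", "Ctrl"):
            for cond in all_conditions:
                eff = 1.0
                if plasmid == "SUP" and cond != reference_condition:
                    eff = 1.0 + effects.get((strain, cond), 0.0)
                mean = base_size * eff * (0.7 if cond != reference_condition else 1.0)
                for rep in range(1, n_replicates + 1):
                    size = mean * max(rng.normal(1.0, noise_cv), 0.0)
                    rows.append((strain, plasmid, cond, rep, size))
    return pd.DataFrame(
        rows, columns=["strain", "plasmid", "condition", "replicate", "colony_size"]
    )
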