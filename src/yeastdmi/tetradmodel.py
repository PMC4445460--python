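"""Analytic tetrad-class expectations and a segregation-pattern classifier.

Under a recessive-lethal allelic combination spanning k unlinked loci, each
locus segregates 2:2 in a tetrad and the four spores receive one of the six
2:2 partitions uniformly and independently per locus.  A spore dies iff it
inherits the lethal parent's allele at every locus, so the set of dead
spores is the intersection of the k lethal-carrier pairs.  For k = 2 this
gives the classic 1:4:1 ratio of tetrads with 4, 3 or 2 viable spores and a
mean spore loss of one-fourth.

Linked two-locus pairs use the Haldane (no interference) tetrad-type
probabilities as a function of the recombination fraction r:

    d   = -ln(1 - 2r) / 2                      (map distance, Morgans)
    TT  = 2/3 (1 - exp(-3d))
    NPD = 1/2 (1 - exp(-2d)) - 1/3 (1 - exp(-3d))
    PD  = 1 - TT - NPD

When the lethal alleles sit in repulsion (one from each parent, the
Dobzhansky-Muller configuration) PD tetrads have 4 viable spores, NPD 2 and
TT 3; in coupling PD and NPD swap roles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from yeastdmi.simcross import IncompatibilityModel, P1, P2

__all__ = [
    "TetradClassDistribution",
    "SegregationCall",
    "expected_tetrad_distribution",
    "expected_spore_inviability",
    "classify_segregation",
    "sample_viable_counts",
]

VIABLE_CLASSES = (4, 3, 2, 1, 0)

# the six 2:2 partitions of four spores, as the pair carrying a given allele
PARTITIONS = tuple(frozenset(c) for c in itertools.combinations(range(4), 2))


@dataclass(frozen=True)
class TetradClassDistribution:
    """Probability of a tetrad containing 4, 3, 2, 1 or 0 viable spores."""

    probs: dict

    def __post_init__(self):
        p = {c: float(self.probs.get(c, 0.0)) for c in VIABLE_CLASSES}
        if any(v < -1e-12 for v in p.values()):
            raise ValueError("negative class probability")
        if abs(sum(p.values()) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    def __getitem__(self, c: int) -> float:
        return self.probs[c]

    def as_array(self) -> np.ndarray:
        return np.array([self.probs[c] for c in VIABLE_CLASSES])

    def mean_inviability(self) -> float:
        return sum((4 - c) * p for c, p in self.probs.items()) / 4.0


@dataclass
class SegregationCall:
    """Model selected for an observed tetrad viable-count distribution."""

    best_model: str
    log_likelihoods: dict
    bic: dict
    fit_pvalue: float
    r_hat: float | None = None


# ---------------------------------------------------------------------------
# expectations

def _thin_penetrance(dead_class_probs: dict, penetrance: float) -> dict:
    """Each lethal-genotype spore dies independently with prob = penetrance."""
    out = {c: 0.0 for c in VIABLE_CLASSES}
    for n_dead_max, p in dead_class_probs.items():
        if p == 0.0:
            continue
        for d in range(n_dead_max + 1):
            q = math.comb(n_dead_max, d) * penetrance**d * (1 - penetrance) ** (n_dead_max - d)
            out[4 - d] += p * q
    return out


def _unlinked_dead_distribution(k: int) -> dict:
    """P(number of lethal-genotype spores) by enumerating all 6^k joint
    2:2 partitions; dead set = intersection of the k lethal-carrier pairs."""
    counts = {0: 0, 1: 0, 2: 0}
    for combo in itertools.product(PARTITIONS, repeat=k):
        dead = frozenset.intersection(*combo)
        counts[len(dead)] += 1
    total = 6**k
    return {n: c / total for n, c in counts.items()}


def haldane_tetrad_types(r: float) -> tuple:
    """(PD, NPD, TT) probabilities for two linked loci at recombination
    fraction r under the no-interference model."""
    if not 0.0 <= r <= 0.5:
        raise ValueError("r outside [0, 0.5]")
    if r >= 0.5 - 1e-12:
        return (1 / 6, 1 / 6, 2 / 3)
    d = -math.log(1.0 - 2.0 * r) / 2.0
    tt = 2.0 / 3.0 * (1.0 - math.exp(-3.0 * d))
    npd = 0.5 * (1.0 - math.exp(-2.0 * d)) - (1.0 / 3.0) * (1.0 - math.exp(-3.0 * d))
    pd_ = 1.0 - tt - npd
    return (pd_, npd, tt)


def _linked_dead_distribution(r: float, repulsion: bool) -> dict:
    pd_, npd, tt = haldane_tetrad_types(r)
    if repulsion:
        return {0: pd_, 1: tt, 2: npd}
    return {0: npd, 1: tt, 2: pd_}


def expected_tetrad_distribution(model: IncompatibilityModel,
                                 ) -> TetradClassDistribution:
    """Exact viable-spore-count distribution under an incompatibility model."""
    if model.kind == "none":
        dead = {0: 1.0}
    elif model.kind in ("two_locus_unlinked", "k_locus"):
        dead = _unlinked_dead_distribution(model.k)
    elif model.kind == "two_locus_linked":
        parents = {parent for _c, _p, parent in model.lethal_loci}
        repulsion = len(parents) == 2
        dead = _linked_dead_distribution(model.r, repulsion)
    else:  # pragma: no cover - guarded by IncompatibilityModel
        raise ValueError(f"unknown model kind {model.kind!r}")
    return TetradClassDistribution(_thin_penetrance(dead, model.penetrance))


def expected_spore_inviability(model: IncompatibilityModel) -> float:
    """Expected fraction of inviable spores among random meiotic products."""
    return expected_tetrad_distribution(model).mean_inviability()


# ---------------------------------------------------------------------------
# fast partition-level sampling

# rows: the six 2:2 partitions; True marks the two spores carrying the
# lethal parent's allele at a locus
_PARTITION_TABLE = np.array(
    [[s in part for s in range(4)] for part in PARTITIONS], dtype=bool
)


def sample_viable_counts(model: IncompatibilityModel, n: int,
                         rng) -> np.ndarray:
    """Viable-spore counts of ``n`` simulated tetrads, sampled directly at
    the 2:2-partition level (vectorised; distributionally equivalent to
    running full meioses for unlinked loci)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    if model.kind == "none":
        return np.full(n, 4, dtype=np.int64)
    if model.kind == "two_locus_linked":
        parents = {parent for _c, _p, parent in model.lethal_loci}
        pd_, npd, tt = haldane_tetrad_types(model.r)
        dead_by_type = np.array([0, 2, 1] if len(parents) == 2 else [2, 0, 1])
        types = rng.choice(3, size=n, p=[pd_, npd, tt])
        candidates = dead_by_type[types]
    else:
        carriers = _PARTITION_TABLE[rng.integers(0, 6, size=(n, model.k))]
        candidates = carriers.all(axis=1).sum(axis=1)
    if model.penetrance < 1.0:
        dead = rng.binomial(candidates, model.penetrance)
    else:
        dead = candidates
    return 4 - dead


# ---------------------------------------------------------------------------
# classification

_R_GRID = np.round(np.arange(0.0, 0.5001, 0.025), 4)


def _log_multinomial(counts: np.ndarray, probs: np.ndarray) -> float:
    n = counts.sum()
    log_coef = math.lgamma(n + 1) - sum(math.lgamma(c + 1) for c in counts)
    ll = log_coef
    for c, p in zip(counts, probs):
        if c == 0:
            continue
        if p <= 0.0:
            return -math.inf
        ll += c * math.log(p)
    return ll


def _candidate_spec(entry):
    """Normalize a candidate to (name, n_params, prob_fn or None)."""
    if isinstance(entry, IncompatibilityModel):
        probs = expected_tetrad_distribution(entry).as_array()
        return (entry.kind, 0, lambda counts, p=probs: (p, None))
    if isinstance(entry, tuple) and entry[0] == "k_locus":
        k = int(entry[1])
        model = IncompatibilityModel(
            kind="k_locus",
            lethal_loci=tuple((f"chr{i + 1}", 1000, P2) for i in range(k)),
        )
        probs = expected_tetrad_distribution(model).as_array()
        return (f"k_locus({k})", 0, lambda counts, p=probs: (p, None))
    name = str(entry)
    if name == "none":
        probs = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        return (name, 0, lambda counts, p=probs: (p, None))
    if name == "two_locus_unlinked":
        probs = expected_tetrad_distribution(
            IncompatibilityModel(
                kind="two_locus_unlinked",
                lethal_loci=(("chrV", 1, P2), ("chrX", 1, P1)),
            )
        ).as_array()
        return (name, 0, lambda counts, p=probs: (p, None))
    if name == "two_locus_linked":

        def profile(counts):
            # repulsion configuration (the DMI case): PD -> 4, TT -> 3, NPD -> 2
            best_ll, best_probs, best_r = -math.inf, None, None
            for r in _R_GRID:
                pd_, npd, tt = haldane_tetrad_types(r)
                probs = np.array([pd_, tt, npd, 0.0, 0.0])
                ll = _log_multinomial(counts, probs)
                if ll > best_ll:
                    best_ll, best_probs, best_r = ll, probs, float(r)
            return (best_probs, best_r)

        return (name, 1, profile)
    if name == "complex":

        def mle(counts):
            n = counts.sum()
            return (counts / n, None)

        return (name, 4, mle)
    raise ValueError(f"unknown candidate model {entry!r}")


def _exact_multinomial_pvalue(counts: np.ndarray, probs: np.ndarray) -> float:
    """Exact two-sided multinomial GOF p-value by full enumeration:
    total probability of outcomes no more probable than the observed one."""
    n = int(counts.sum())
    obs_ll = _log_multinomial(counts, probs)
    tol = 1e-9
    pval = 0.0
    k = len(probs)

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    for comp in compositions(n, k):
        ll = _log_multinomial(np.array(comp), probs)
        if ll <= obs_ll + tol:
            pval += math.exp(ll) if ll > -math.inf else 0.0
    return min(pval, 1.0)


def _mc_multinomial_pvalue(counts: np.ndarray, probs: np.ndarray,
                           n_draws: int = 100_000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    n = int(counts.sum())
    obs_ll = _log_multinomial(counts, probs)
    draws = rng.multinomial(n, probs, size=n_draws)
    lls = stats.multinomial.logpmf(draws, n, probs)
    hits = int(np.sum(lls <= obs_ll + 1e-9))
    return (hits + 1) / (n_draws + 1)


def _fit_pvalue(counts: np.ndarray, probs: np.ndarray, n_fitted: int) -> float:
    n = int(counts.sum())
    # observed count in a zero-probability class: impossible under the model
    if any(c > 0 and p <= 0.0 for c, p in zip(counts, probs)):
        return 0.0
    if n <= 30:
        return _exact_multinomial_pvalue(counts, probs)
    if n > 200:
        keep = probs > 0
        expected = probs[keep] * n
        ddof = min(n_fitted, keep.sum() - 2)
        stat, p = stats.chisquare(counts[keep], expected, ddof=max(ddof, 0))
        return float(p) if np.isfinite(p) else 1.0
    return _mc_multinomial_pvalue(counts, probs)


def classify_segregation(observed: dict, candidate_models,
                         compute_pvalue: bool = True) -> SegregationCall:
    """Select the incompatibility model best explaining observed tetrad
    viable-spore counts.

    ``observed`` maps viable count (0..4) -> number of tetrads.  Candidates
    may be kind names ('none', 'two_locus_unlinked', 'two_locus_linked',
    'complex'), ('k_locus', k) tuples, or IncompatibilityModel instances.
    Selection is by BIC (linked profiles its recombination fraction over a
    grid; 'complex' is the free multinomial); ties break toward fewer
    parameters, then lexicographic name.  ``fit_pvalue`` is the multinomial
    goodness of fit of the winner: exact enumeration for <= 30 tetrads,
    chi-square above 200, Monte Carlo (seed 0) in between.
    """
    candidate_models = list(candidate_models)
    if not candidate_models:
        raise ValueError("empty candidate list")
    counts = np.array([int(observed.get(c, 0)) for c in VIABLE_CLASSES])
    n = int(counts.sum())
    if n < 1:
        raise ValueError("need at least one observed tetrad")

    rows = []
    for entry in candidate_models:
        name, n_params, fn = _candidate_spec(entry)
        probs, r_hat = fn(counts)
        ll = _log_multinomial(counts, probs)
        bic = n_params * math.log(n) - 2.0 * ll
        rows.append((name, n_params, probs, r_hat, ll, bic))

    rows.sort(key=lambda row: (round(row[5], 9), row[1], row[0]))
    name, n_params, probs, r_hat, ll, bic = rows[0]
    return SegregationCall(
        best_model=name,
        log_likelihoods={r[0]: r[4] for r in rows},
        bic={r[0]: r[5] for r in rows},
        fit_pvalue=_fit_pvalue(counts, probs, n_params) if compute_pvalue
        else float("nan"),
        r_hat=r_hat,
    )
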