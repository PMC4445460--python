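"""Offspring-viability screen scoring and severity classification.

Offspring viability of a cross on a condition is the fraction of spores
viable on the test condition among those viable on permissive rich medium.
Instances where either parent fails to grow on the condition are excluded
(the phenotype is then uninformative about epistasis in the offspring).
Remaining instances are classified by viability loss: `severe` at >= 20%
loss, `potential_epistasis` between the detection threshold (default 1%)
and 20%, `none` below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = [
    "ScreenInstance",
    "ScreenSummary",
    "compute_viability",
    "filter_parental",
    "classify_instance",
    "summarize_screen",
    "instances_from_tables",
]

CATEGORIES = ("excluded", "none", "potential_epistasis", "severe")


class UndefinedViabilityError(ValueError):
    """No permissive-medium-viable spores: viability is undefined."""


@dataclass(frozen=True)
class ScreenInstance:
    cross_id: str
    condition: str
    spores_viable_permissive: int
    spores_viable_condition: int
    p1_viable: bool = True
    p2_viable: bool = True

    def __post_init__(self):
        if not 0 <= self.spores_viable_condition <= self.spores_viable_permissive:
            raise ValueError(
                "need 0 <= condition-viable <= permissive-viable spore counts"
            )


@dataclass
class ScreenSummary:
    n_total: int
    n_excluded: int
    n_epistasis: int
    n_severe: int
    per_instance: pd.DataFrame = field(repr=False)
    matrix: pd.DataFrame = field(repr=False)

    @property
    def n_kept(self) -> int:
        return self.n_total - self.n_excluded

    @property
    def frac_epistasis(self) -> float:
        return self.n_epistasis / self.n_kept if self.n_kept else float("nan")

    @property
    def frac_severe(self) -> float:
        return self.n_severe / self.n_kept if self.n_kept else float("nan")


def compute_viability(instance: ScreenInstance) -> float:
    """Condition-viable over permissive-viable spore count."""
    if instance.spores_viable_permissive < 1:
        raise UndefinedViabilityError(
            f"{instance.cross_id}/{instance.condition}: no spores viable on "
            "permissive medium"
        )
    return instance.spores_viable_condition / instance.spores_viable_permissive


def filter_parental(instances):
    """Split instances into (kept, excluded) by parental viability."""
    kept, excluded = [], []
    for inst in instances:
        (kept if inst.p1_viable and inst.p2_viable else excluded).append(inst)
    return kept, excluded


def classify_instance(viability: float, epistasis_threshold: float = 0.01,
                      severe_threshold: float = 0.20) -> str:
    """Severity category from viability loss = 1 - viability.

    The severe boundary is closed (loss exactly at the threshold counts),
    matching an "at least 20% non-viable" rule.
    """
    if not 0.0 <= viability <= 1.0:
        raise ValueError("viability outside [0, 1]")
    for name, thr in (("epistasis", epistasis_threshold), ("severe", severe_threshold)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name}_threshold outside [0, 1]")
    if epistasis_threshold > severe_threshold:
        raise ValueError("epistasis_threshold must not exceed severe_threshold")
    loss = 1.0 - viability
    eps = 1e-9  # keep the closed boundary closed under float roundoff
    if loss >= severe_threshold - eps:
        return "severe"
    if loss >= epistasis_threshold - eps:
        return "potential_epistasis"
    return "none"


def summarize_screen(instances, epistasis_threshold: float = 0.01,
                     severe_threshold: float = 0.20,
                     binomial_test: bool = False,
                     alpha: float = 0.05) -> ScreenSummary:
    """Aggregate a screen: per-instance viability and category plus the
    cross x condition viability matrix (excluded cells flagged).

    With ``binomial_test=True`` an instance is only flagged (either epistasis
    category) when an exact one-sided binomial test rejects the null that
    true viability is at least ``1 - epistasis_threshold`` at ``alpha``; by
    default the thresholds alone decide.
    """
    instances = list(instances)
    pairs = [(i.cross_id, i.condition) for i in instances]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (cross, condition) instances")

    rows = []
    for inst in instances:
        excluded = not (inst.p1_viable and inst.p2_viable)
        viability = compute_viability(inst)
        if excluded:
            category = "excluded"
        else:
            category = classify_instance(viability, epistasis_threshold,
                                         severe_threshold)
            if binomial_test and category != "none":
                n = inst.spores_viable_permissive
                k = inst.spores_viable_condition
                p = stats.binomtest(k, n, 1.0 - epistasis_threshold,
                                    alternative="less").pvalue
                if p > alpha:
                    category = "none"
        rows.append((inst.cross_id, inst.condition, viability, category))

    per_instance = pd.DataFrame(
        rows, columns=["cross_id", "condition", "viability", "category"]
    )
    cells = per_instance.assign(
        cell=lambda d: d["viability"].where(d["category"] != "excluded",
                                            other=float("nan"))
    )
    matrix = cells.pivot(index="cross_id", columns="condition", values="cell")

    cats = per_instance["category"]
    return ScreenSummary(
        n_total=len(instances),
        n_excluded=int((cats == "excluded").sum()),
        n_epistasis=int(cats.isin(["potential_epistasis", "severe"]).sum()),
        n_severe=int((cats == "severe").sum()),
        per_instance=per_instance,
        matrix=matrix,
    )


def instances_from_tables(screen_table: pd.DataFrame,
                          parents: pd.DataFrame) -> list:
    """Build instances from the long spore-level screen table plus the
    parental-viability table (one row per cross x condition)."""
    agg = (
        screen_table.groupby(["cross_id", "condition"])[
            ["viable_permissive", "viable_condition"]
        ]
        .sum()
        .reset_index()
    )
    merged = agg.merge(parents, on=["cross_id", "condition"], how="left")
    if merged[["p1_viable", "p2_viable"]].isna().any().any():
        missing = merged[merged["p1_viable"].isna()][["cross_id", "condition"]]
        raise ValueError(f"missing parental viability for {missing.values.tolist()}")
    return [
        ScreenInstance(
            cross_id=row.cross_id,
            condition=row.condition,
            spores_viable_permissive=int(row.viable_permissive),
            spores_viable_condition=int(row.viable_condition),
            p1_viable=bool(row.p1_viable),
            p2_viable=bool(row.p2_viable),
        )
        for row in merged.itertuples()
    ]
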