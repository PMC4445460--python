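"""Growth-based fitness quantification.

Liquid microcultures: the maximum specific growth rate (per hour) is the
largest least-squares slope of log(OD) over a sliding window of consecutive
time points, which estimates the exponential-phase rate while staying
robust to lag and saturation.  Suppressor-vs-control comparisons report the
percent variation of mean rates with a two-sided t-test.

Solid plates: colony sizes are normalised per replicate by the size on the
reference rich medium (pinning control), then the suppressor arm is
compared with the control arm per strain and condition; effects of at least
10% magnitude are flagged.  Phenotypic-variance differences across strains
use a two-sided F-test and the Brown-Forsythe (median-centred Levene) test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurve",
    "ColonyMeasure",
    "FitnessComparison",
    "fit_growth_rate",
    "growth_variation",
    "normalized_growth_ratio",
    "suppressor_effect",
    "variance_comparison",
]

log = logging.getLogger(__name__)

OD_FLOOR = 1e-4  # blank-subtracted readings can be <= 0


@dataclass
class GrowthCurve:
    times: np.ndarray
    od: np.ndarray
    well_id: str = ""
    strain: str = ""
    plasmid: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD values must be >= 0")


@dataclass(frozen=True)
class ColonyMeasure:
    strain: str
    plasmid: str  # 'SUP' | 'Ctrl'
    condition: str
    replicate: str | int
    colony_size: float

    def __post_init__(self):
        if self.plasmid not in ("SUP", "Ctrl"):
            raise ValueError("plasmid must be 'SUP' or 'Ctrl'")
        if self.colony_size < 0:
            raise ValueError("colony size must be >= 0")


@dataclass
class FitnessComparison:
    strain: str
    condition: str
    percent_variation: float
    n: int
    p_t: float | None = None
    p_F: float | None = None
    p_levene: float | None = None
    flagged: bool = False


def fit_growth_rate(curve, window: int = 15, min_od: float = 0.05,
                    od_floor: float = OD_FLOOR) -> float:
    """Maximum specific growth rate (per hour) by sliding-window log-slope.

    Windows of ``window`` consecutive points are fit by least squares on
    log(OD) and the largest slope is reported.  Points below ``min_od`` are
    dominated by read noise, so only windows entirely above it are used
    (all windows, if the whole curve sits below).  At 10-minute sampling the
    default 15-point window spans 2.3 h, long enough to average read noise
    yet short enough to stay inside the exponential phase.  A flat or
    non-growing curve yields rate 0 with a warning rather than an exception.
    """
    if isinstance(curve, GrowthCurve):
        times, od = curve.times, curve.od
    else:
        times, od = (np.asarray(a, dtype=float) for a in curve)
    if len(times) < max(window, 10):
        raise ValueError(f"need at least {max(window, 10)} points, got {len(times)}")
    logod = np.log(np.maximum(od, od_floor))

    starts = [
        i for i in range(len(times) - window + 1)
        if np.all(od[i:i + window] >= min_od)
    ]
    if not starts:
        starts = list(range(len(times) - window + 1))
    best = 0.0
    for i in starts:
        t = times[i:i + window]
        y = logod[i:i + window]
        slope = np.polyfit(t, y, 1)[0]
        if slope > best:
            best = float(slope)
    if best < 1e-6:
        warnings.warn("no growth detected (flat or declining curve); rate = 0",
                      stacklevel=2)
        return 0.0
    return best


def growth_variation(rates_sup, rates_ctrl, strain: str = "",
                     condition: str = "") -> FitnessComparison:
    """Percent variation of mean growth rate, suppressor vs control,
    with a two-sided two-sample t-test."""
    sup = np.asarray(list(rates_sup), dtype=float)
    ctrl = np.asarray(list(rates_ctrl), dtype=float)
    if len(sup) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 replicates per arm")
    if ctrl.mean() == 0:
        raise ZeroDivisionError("control mean rate is 0; variation undefined")
    pv = 100.0 * (sup.mean() - ctrl.mean()) / ctrl.mean()
    if np.ptp(sup) == 0 and np.ptp(ctrl) == 0:
        p_t = 1.0 if sup.mean() == ctrl.mean() else 0.0
    else:
        p_t = float(stats.ttest_ind(sup, ctrl).pvalue)
    return FitnessComparison(strain=strain, condition=condition,
                             percent_variation=float(pv),
                             n=len(sup) + len(ctrl), p_t=p_t)


def normalized_growth_ratio(size_condition: float, size_reference_medium: float,
                            ) -> float:
    """Colony size on a condition over size on the reference medium.

    A zero reference size yields NaN (flagged missing; excluded downstream).
    """
    if size_reference_medium < 0 or size_condition < 0:
        raise ValueError("colony sizes must be >= 0")
    if size_reference_medium == 0:
        log.warning("zero reference-medium colony size; ratio flagged missing")
        return float("nan")
    return size_condition / size_reference_medium


def suppressor_effect(colonies, reference_condition: str = "YPD",
                      flag_threshold: float = 10.0) -> pd.DataFrame:
    """Per (strain, condition) percent variation of normalised growth
    ratios, suppressor plasmid vs control plasmid.

    Ratios are computed per replicate (colony size on the condition divided
    by the same replicate's size on the reference medium), then arms are
    compared by their mean ratio with a t-test; |variation| >=
    ``flag_threshold`` percent is flagged.  Pairs missing either plasmid arm
    (or with < 2 replicates per arm) are skipped with a log entry.
    """
    if not isinstance(colonies, pd.DataFrame):
        colonies = pd.DataFrame([vars(c) for c in colonies])
    required = {"strain", "plasmid", "condition", "replicate", "colony_size"}
    if not required.issubset(colonies.columns):
        raise ValueError(f"colony table needs columns {sorted(required)}")

    ref = colonies[colonies["condition"] == reference_condition].set_index(
        ["strain", "plasmid", "replicate"]
    )["colony_size"]
    rows = []
    test = colonies[colonies["condition"] != reference_condition]
    for (strain, condition), grp in test.groupby(["strain", "condition"]):
        arms = {}
        for plasmid, arm in grp.groupby("plasmid"):
            ratios = []
            for rec in arm.itertuples():
                key = (rec.strain, rec.plasmid, rec.replicate)
                if key not in ref.index:
                    continue
                ratio = normalized_growth_ratio(rec.colony_size, ref.loc[key])
                if np.isfinite(ratio):
                    ratios.append(ratio)
            arms[plasmid] = ratios
        if len(arms.get("SUP", [])) < 2 or len(arms.get("Ctrl", [])) < 2:
            log.info("skipping %s/%s: missing plasmid arm or replicates",
                     strain, condition)
            continue
        comp = growth_variation(arms["SUP"], arms["Ctrl"], strain=strain,
                                condition=condition)
        # closed boundary, robust to float roundoff at exactly the threshold
        comp.flagged = abs(comp.percent_variation) >= flag_threshold - 1e-9
        rows.append(comp)
    return pd.DataFrame([vars(c) for c in rows])


def variance_comparison(sup_values, ctrl_values) -> tuple:
    """(two-sided F-test p, Brown-Forsythe Levene p) for variance equality.

    Zero variance in both arms returns (1, 1) by convention.
    """
    sup = np.asarray(list(sup_values), dtype=float)
    ctrl = np.asarray(list(ctrl_values), dtype=float)
    if len(sup) < 3 or len(ctrl) < 3:
        raise ValueError("need >= 3 values per arm")
    v_sup, v_ctrl = sup.var(ddof=1), ctrl.var(ddof=1)
    if v_sup == 0 and v_ctrl == 0:
        return 1.0, 1.0
    if v_ctrl == 0 or v_sup == 0:
        p_f = 0.0
    else:
        f = v_sup / v_ctrl
        dist = stats.f(len(sup) - 1, len(ctrl) - 1)
        p_f = float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))
    p_lev = float(stats.levene(sup, ctrl, center="median").pvalue)
    return p_f, p_lev
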