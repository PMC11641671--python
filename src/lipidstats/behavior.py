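"""Forced-swim-test behavior and lipid-behavior correlation.

The forced swim test (FST) yields two readouts per animal over a 10-min
session: total cumulative immobility and the latency to the first bout of
immobility (both in seconds, bounded by the 600 s test).  Arm-level
comparisons reuse the one-way ANOVA / Holm-Sidak machinery; associations
between lipid species (mol%) and latency are quantified with Spearman's
rank correlation, either over all treatment arms or over the
corticosterone arm plus its Ze 117 co-treatment arms only — the subset in
which the latency / lysophosphatidylethanolamine coupling is visible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantmatrix import QuantMatrix
from .structural_stats import GroupComparison, anova_holm_sidak

logger = logging.getLogger(__name__)

__all__ = [
    "FST_DURATION_S",
    "BehaviorRecord",
    "CorrelationResult",
    "SUBSETS",
    "read_behavior_table",
    "spearman",
    "correlate_lipids",
    "fst_group_stats",
    "select_subgroup",
]

FST_DURATION_S = 600.0

#: Named treatment-arm subsets for the correlation analysis.  The
#: co-treated subset pairs the corticosterone arm with all Ze 117
#: co-treatment arms; an escitalopram-including variant is provided but
#: is not the default.
SUBSETS: dict[str, tuple[str, ...]] = {
    "all-arms": ("CONTROL", "CORT", "CORT_ZE30", "CORT_ZE90", "CORT_ZE180", "CORT_ESC"),
    "cort-and-cotreated": ("CORT", "CORT_ZE30", "CORT_ZE90", "CORT_ZE180"),
    "cort-and-cotreated-esc": ("CORT", "CORT_ZE30", "CORT_ZE90", "CORT_ZE180", "CORT_ESC"),
}


@dataclass(frozen=True)
class BehaviorRecord:
    animal_id: str
    total_immobility_s: float
    latency_first_immobility_s: float

    def __post_init__(self):
        for v, what in [
            (self.total_immobility_s, "total immobility"),
            (self.latency_first_immobility_s, "latency to first immobility"),
        ]:
            if not 0 <= v <= FST_DURATION_S:
                raise ValueError(f"{what} must lie in [0, {FST_DURATION_S:.0f}] s, got {v}")


@dataclass(frozen=True)
class CorrelationResult:
    species: str
    subset: str
    rho: float
    p: float
    n: int


def read_behavior_table(path: str | Path) -> pd.DataFrame:
    """Read the behavior CSV (animal_id, total_immobility_s, latency_s)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {"animal_id", "total_immobility_s", "latency_first_immobility_s"}
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    df["animal_id"] = df["animal_id"].astype(str)
    # validate ranges through the record type
    for row in df.itertuples(index=False):
        BehaviorRecord(row.animal_id, row.total_immobility_s, row.latency_first_immobility_s)
    return df.set_index("animal_id")


def _exact_permutation_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    n = xr.size
    denom = xr.std() * yr.std()
    count = 0
    total = 0
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    for perm in permutations(range(n)):
        r = (xc[list(perm)] * yc).mean() / denom
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks; rho is the Pearson correlation of the
    ranks.  The p-value uses the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` with n-2 df; a perfect
    monotone arrangement (|rho| = 1) is reported at the continuity floor
    2/n! (its exact two-sided permutation p for untied ranks).  With
    ``exact=True`` (n <= 10) the full permutation distribution of rho is
    enumerated instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has no defined rank correlation")

    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p supported only for n <= 10")
        xr, yr = stats.rankdata(x), stats.rankdata(y)
        return rho, float(_exact_permutation_p(xr, yr, rho))
    if abs(rho) >= 1.0 - 1e-14:
        return rho, 2.0 / math.factorial(n)
    return rho, float(p)


def correlate_lipids(
    molpct: QuantMatrix,
    behavior: pd.DataFrame,
    subset: str = "cort-and-cotreated",
    measure: str = "latency_first_immobility_s",
) -> pd.DataFrame:
    """Correlate every species' mol% with a behavioral measure.

    ``behavior`` is indexed by animal_id (see :func:`read_behavior_table`).
    Samples whose animal lacks a behavior record are dropped with a
    logged count.  Species that are constant over the subset (e.g.
    all-censored) are skipped.

    Returns a DataFrame of :class:`CorrelationResult` rows.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {list(SUBSETS)}")
    arms = set(SUBSETS[subset])
    keep = [
        s
        for s in molpct.samples
        if s.arm.label in arms and s.animal_id in behavior.index
    ]
    dropped = sum(
        1
        for s in molpct.samples
        if s.arm.label in arms and s.animal_id not in behavior.index
    )
    if dropped:
        logger.info("dropped %d samples without behavior records", dropped)
    ids = [s.sample_id for s in keep]
    yvals = behavior.loc[[s.animal_id for s in keep], measure].to_numpy(dtype=float)
    X = molpct.amounts.loc[ids]

    rows = []
    for name in X.columns:
        xv = X[name].to_numpy(dtype=float)
        if np.all(xv == xv[0]) or np.all(yvals == yvals[0]):
            continue
        rho, p = spearman(xv, yvals)
        rows.append(CorrelationResult(name, subset, rho, p, len(ids)))
    return pd.DataFrame([r.__dict__ for r in rows])


def fst_group_stats(
    behavior: pd.DataFrame,
    arm_by_animal: Mapping[str, str],
    reference_arm: str = "CORT",
) -> dict[str, GroupComparison]:
    """Arm-level ANOVA + Holm-Sidak for both FST measures."""
    out = {}
    for measure in ("total_immobility_s", "latency_first_immobility_s"):
        by_arm: dict[str, list[float]] = {}
        for animal, arm in arm_by_animal.items():
            if animal in behavior.index:
                by_arm.setdefault(arm, []).append(float(behavior.loc[animal, measure]))
        out[measure] = anova_holm_sidak(by_arm, reference_arm, scope=measure)
    return out


def select_subgroup(
    values_by_animal: Mapping[str, float], k: int
) -> list[str]:
    """Trim an arm to its k most central animals by a behavioral value.

    The most extreme values are removed symmetrically — drop the current
    maximum, then the current minimum, alternating — until k animals
    remain.  Ties are broken by the input (animal id) order, making the
    rule deterministic.
    """
    animals = list(values_by_animal)
    if k > len(animals):
        raise ValueError(f"cannot select {k} animals from {len(animals)}")
    remaining = animals[:]
    drop_max = True
    while len(remaining) > k:
        vals = [values_by_animal[a] for a in remaining]
        target = max(vals) if drop_max else min(vals)
        remaining.remove(remaining[vals.index(target)])
        drop_max = not drop_max
    return remaining
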