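"""Structural summary statistics of a lipidome and their group comparisons.

Two scalar descriptors summarize the acyl-chain structure of a species
set: the average number of C=C double bonds (DB_av) and the average total
chain length in carbons (CL_av).  Both are mol%-weighted arithmetic means
over the species in scope,

    DB_av = sum_i DB_i * w_i / sum_i w_i,     w_i = mol% of species i,

and likewise for CL_av with total carbons in place of double bonds.  The
weighted mean is invariant to the normalization constant, so the same
formula serves the per-class scope and the "all analyzed lipids" scope.

The saturation partition splits a class' total mol% (per total lipids)
into the saturated (DB = 0) and unsaturated (DB >= 1) fractions — the
summary in which the hippocampal lysophosphatidylethanolamine response to
antidepressant co-treatment is expressed.

Group comparisons follow the study's scheme: one-way ANOVA over all arms,
then pairwise t-tests of each arm against a reference arm using the
pooled within-group variance, with Holm-Sidak step-down adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .nomenclature import LipidSpecies
from .quantmatrix import QuantMatrix

__all__ = [
    "StructuralSummary",
    "GroupComparison",
    "db_average",
    "chain_length_average",
    "saturation_partition",
    "structural_summary_table",
    "anova_holm_sidak",
    "holm_sidak",
]


@dataclass(frozen=True)
class StructuralSummary:
    """Per-sample structural descriptors for one scope.

    ``scope`` is either ``"all"`` or a lipid class code.  ``sat_molpct``
    and ``unsat_molpct`` are mol% per total lipids summed over the
    saturated / unsaturated species of the scope.
    """

    sample_id: str
    scope: str
    db_av: float
    cl_av: float
    sat_molpct: float
    unsat_molpct: float


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA plus Holm-Sidak-adjusted reference comparisons."""

    scope: str
    arm_means: pd.DataFrame  # index arm, columns mean / sem / n
    anova_F: float
    anova_p: float
    reference_arm: str
    comparisons: pd.DataFrame  # index arm, columns estimate / t / p / adj_p


def _weighted_mean(values: np.ndarray, weights: np.ndarray, what: str) -> float:
    total = weights.sum()
    if values.size == 0 or total <= 0:
        raise ValueError(f"{what}: scope is empty or has all-zero mol% weights")
    return float((values * weights).sum() / total)


def _scope_arrays(
    molpct_by_species: Mapping[str, float] | pd.Series,
    species_info: Mapping[str, LipidSpecies],
    scope: str,
    attr: str,
) -> tuple[np.ndarray, np.ndarray]:
    names = [
        n
        for n in molpct_by_species.keys()
        if scope == "all" or species_info[n].class_info.code == scope
    ]
    vals = np.array([getattr(species_info[n], attr) for n in names], dtype=float)
    wts = np.array([molpct_by_species[n] for n in names], dtype=float)
    if (wts < 0).any():
        raise ValueError("mol% weights must be non-negative")
    return vals, wts


def db_average(
    molpct_by_species: Mapping[str, float] | pd.Series,
    species_info: Mapping[str, LipidSpecies],
    scope: str = "all",
) -> float:
    """mol%-weighted average number of double bonds over the scope.

    Parameters
    ----------
    molpct_by_species : mapping species name -> mol%
        One sample's mol% values.  Weighting is invariant to the overall
        scale, so per-total or per-class normalization give the same
        answer.
    scope : ``"all"`` or a class code, e.g. ``"LPE"``.
    """
    vals, wts = _scope_arrays(molpct_by_species, species_info, scope, "total_double_bonds")
    return _weighted_mean(vals, wts, f"db_average(scope={scope!r})")


def chain_length_average(
    molpct_by_species: Mapping[str, float] | pd.Series,
    species_info: Mapping[str, LipidSpecies],
    scope: str = "all",
) -> float:
    """mol%-weighted average total acyl carbons over the scope."""
    vals, wts = _scope_arrays(molpct_by_species, species_info, scope, "total_carbons")
    return _weighted_mean(vals, wts, f"chain_length_average(scope={scope!r})")


def saturation_partition(
    molpct_by_species: Mapping[str, float] | pd.Series,
    species_info: Mapping[str, LipidSpecies],
    class_code: str,
) -> tuple[float, float]:
    """Split a class' mol% (per total lipids) by saturation.

    Returns ``(sat_molpct, unsat_molpct)``: the summed mol% of species
    with zero double bonds and with at least one, respectively.
    """
    names = [
        n for n in molpct_by_species.keys() if species_info[n].class_info.code == class_code
    ]
    if not names:
        raise ValueError(f"no species of class {class_code!r} in scope")
    sat = sum(molpct_by_species[n] for n in names if species_info[n].total_double_bonds == 0)
    unsat = sum(molpct_by_species[n] for n in names if species_info[n].total_double_bonds >= 1)
    return float(sat), float(unsat)


def structural_summary_table(
    molpct: QuantMatrix, scopes: Sequence[str] = ("all",)
) -> pd.DataFrame:
    """Per-sample :class:`StructuralSummary` rows for each scope (long format)."""
    if molpct.unit != "molpct":
        raise ValueError("structural summaries require a mol% matrix")
    info = molpct.species_by_name()
    rows = []
    for sid in molpct.sample_ids:
        series = molpct.amounts.loc[sid]
        for scope in scopes:
            if scope == "all":
                sat = sum(
                    series[n] for n in series.index if info[n].total_double_bonds == 0
                )
                unsat = float(series.sum()) - sat
            else:
                sat, unsat = saturation_partition(series, info, scope)
            rows.append(
                StructuralSummary(
                    sample_id=sid,
                    scope=scope,
                    db_av=db_average(series, info, scope),
                    cl_av=chain_length_average(series, info, scope),
                    sat_molpct=float(sat),
                    unsat_molpct=float(unsat),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def holm_sidak(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in input order.

    With raw p sorted ascending, adj_(i) = max_{j<=i} 1 - (1-p_(j))^(m-j+1),
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def anova_holm_sidak(
    values_by_arm: Mapping[str, Sequence[float]],
    reference_arm: str,
    scope: str = "",
) -> GroupComparison:
    """One-way ANOVA plus Holm-Sidak-adjusted comparisons vs a reference.

    Pairwise t statistics use the pooled within-group variance over all
    arms (residual df N - k), so every comparison shares one error
    estimate.  When all groups are exactly identical (zero between- and
    within-group variance) the F statistic is defined as 0 with p = 1.
    """
    arms = list(values_by_arm)
    if reference_arm not in values_by_arm:
        raise ValueError(f"reference arm {reference_arm!r} not among arms {arms}")
    groups = {a: np.asarray(values_by_arm[a], dtype=float) for a in arms}
    if len(groups) < 2 or any(g.size < 2 for g in groups.values()):
        raise ValueError("need >= 2 arms with >= 2 values each")

    n_total = sum(g.size for g in groups.values())
    k = len(groups)
    grand = np.concatenate(list(groups.values())).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_between, df_within = k - 1, n_total - k

    if ss_within == 0 and ss_between == 0:
        F, p_anova = 0.0, 1.0
    else:
        F, p_anova = stats.f_oneway(*groups.values())
        F, p_anova = float(F), float(p_anova)

    s2 = ss_within / df_within  # pooled residual mean square
    comp_arms = [a for a in arms if a != reference_arm]
    ref = groups[reference_arm]
    est, tstat, praw = [], [], []
    for a in comp_arms:
        g = groups[a]
        diff = g.mean() - ref.mean()
        se = np.sqrt(s2 * (1 / g.size + 1 / ref.size))
        if se == 0:
            t = 0.0 if diff == 0 else np.sign(diff) * np.inf
        else:
            t = diff / se
        est.append(diff)
        tstat.append(float(t))
        praw.append(
            1.0 if (se == 0 and diff == 0) else float(2 * stats.t.sf(abs(t), df_within))
        )
    adj = holm_sidak(praw)

    arm_means = pd.DataFrame(
        {
            "mean": [groups[a].mean() for a in arms],
            "sem": [groups[a].std(ddof=1) / np.sqrt(groups[a].size) for a in arms],
            "n": [groups[a].size for a in arms],
        },
        index=pd.Index(arms, name="arm"),
    )
    comparisons = pd.DataFrame(
        {"estimate": est, "t": tstat, "p": praw, "adj_p": adj},
        index=pd.Index(comp_arms, name="arm"),
    )
    return GroupComparison(
        scope=scope,
        arm_means=arm_means,
        anova_F=F,
        anova_p=p_anova,
        reference_arm=reference_arm,
        comparisons=comparisons,
    )
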