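"""Per-lipid treatment-effect testing with per-contrast FDR.

For every lipid a one-factor cell-means linear model is fitted over all
treatment arms jointly on the mol% scale; the residual variance is pooled
across arms (df = N - k).  Five contrasts of interest are then tested
with t-statistics sharing that pooled error:

* corticosterone vs control (the stress effect), and
* each co-treatment arm (Ze 117 at 30/90/180 mg/kg, escitalopram) vs
  corticosterone alone (the treatment effects).

A lipid enters a contrast only if both conditions contain at least one
value above the limit of detection (non-zero after LOD replacement);
excluded lipids are reported with ``included=False`` rather than dropped.
Multiple testing is adjusted per contrast across all included lipids of
one tissue with the Benjamini-Hochberg step-up FDR procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantmatrix import QuantMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "DEFAULT_CONTRASTS",
    "include_species",
    "fit_contrast",
    "bh_fdr",
    "run_contrasts",
    "volcano_table",
    "qq_table",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A tested difference ``arm_a - arm_b`` between two arm means."""

    name: str
    arm_a: str
    arm_b: str


DEFAULT_CONTRASTS: tuple[ContrastSpec, ...] = (
    ContrastSpec("CORT_vs_CONTROL", "CORT", "CONTROL"),
    ContrastSpec("ZE30+CORT_vs_CORT", "CORT_ZE30", "CORT"),
    ContrastSpec("ZE90+CORT_vs_CORT", "CORT_ZE90", "CORT"),
    ContrastSpec("ZE180+CORT_vs_CORT", "CORT_ZE180", "CORT"),
    ContrastSpec("ESC+CORT_vs_CORT", "CORT_ESC", "CORT"),
)


@dataclass(frozen=True)
class ContrastResult:
    species: str
    contrast: ContrastSpec
    included: bool
    n_a: int
    n_b: int
    estimate: float = np.nan  # mean(arm_a) - mean(arm_b), mol%
    log2fc: float = np.nan
    t: float = np.nan
    p: float = np.nan
    fdr: float = np.nan
    degenerate: bool = False  # zero pooled variance
    log2fc_undefined: bool = False  # a zero group mean


def include_species(
    values_a: Sequence[float], values_b: Sequence[float]
) -> bool:
    """Inclusion rule: at least one value above LOD in *both* conditions.

    Sub-LOD values have already been replaced by zero, so "above LOD"
    means non-zero here.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both condition vectors must be non-empty")
    return bool((a > 0).any() and (b > 0).any())


def fit_contrast(
    molpct_by_arm: Mapping[str, Sequence[float]],
    spec: ContrastSpec,
    species: str = "",
) -> ContrastResult:
    """Test one contrast for one lipid under the joint cell-means model.

    The residual variance pools over *all* arms supplied, not just the
    two being contrasted, with df = N - k; with exactly two arms this
    reduces to the classical pooled two-sample t-test.

    log2 fold change is ``log2(mean_a / mean_b)``; if either group mean
    is zero it is reported as missing with ``log2fc_undefined=True`` (no
    pseudo-count is invented).
    """
    groups = {a: np.asarray(v, dtype=float) for a, v in molpct_by_arm.items()}
    for arm in (spec.arm_a, spec.arm_b):
        if arm not in groups:
            raise ValueError(f"arm {arm!r} missing from supplied data")
    ga, gb = groups[spec.arm_a], groups[spec.arm_b]
    if not include_species(ga, gb):
        return ContrastResult(
            species=species, contrast=spec, included=False, n_a=ga.size, n_b=gb.size
        )

    n_total = sum(g.size for g in groups.values())
    k = len(groups)
    df = n_total - k
    if df <= 0:
        raise ValueError("need residual degrees of freedom > 0")
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    s2 = ss_within / df

    est = ga.mean() - gb.mean()
    se = np.sqrt(s2 * (1 / ga.size + 1 / gb.size))
    degenerate = s2 == 0
    if degenerate:
        t = 0.0 if est == 0 else np.sign(est) * np.inf
        p = 1.0 if est == 0 else 0.0
    else:
        t = est / se
        p = float(2 * stats.t.sf(abs(t), df))

    undefined = ga.mean() <= 0 or gb.mean() <= 0
    log2fc = np.nan if undefined else float(np.log2(ga.mean() / gb.mean()))
    return ContrastResult(
        species=species,
        contrast=spec,
        included=True,
        n_a=ga.size,
        n_b=gb.size,
        estimate=float(est),
        log2fc=log2fc,
        t=float(t),
        p=p,
        degenerate=bool(degenerate),
        log2fc_undefined=bool(undefined),
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    With p sorted ascending, q_(i) = min_{j>=i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _arm_groups(molpct: QuantMatrix) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for s in molpct.samples:
        groups.setdefault(s.arm.label, []).append(s.sample_id)
    return groups


def run_contrasts(
    molpct: QuantMatrix,
    contrasts: Sequence[ContrastSpec] = DEFAULT_CONTRASTS,
) -> pd.DataFrame:
    """Fit all contrasts for every species of a mol% matrix (vectorized).

    Returns a long DataFrame with one row per species per contrast
    (columns: species, contrast, included, n_a, n_b, estimate, log2fc,
    t, p, fdr, degenerate, log2fc_undefined).  FDR is computed per
    contrast across the included species only; excluded species keep
    NaN statistics with ``included=False``.
    """
    if molpct.unit != "molpct":
        raise ValueError("contrasts are tested on the mol% scale")
    arm_samples = _arm_groups(molpct)
    X = molpct.amounts  # samples x species
    n_total = len(X.index)
    k = len(arm_samples)
    df = n_total - k
    if df <= 0:
        raise ValueError("need residual degrees of freedom > 0")

    means = {a: X.loc[ids].mean(axis=0) for a, ids in arm_samples.items()}
    any_pos = {a: (X.loc[ids] > 0).any(axis=0) for a, ids in arm_samples.items()}
    ss_within = sum(
        ((X.loc[ids] - means[a]) ** 2).sum(axis=0) for a, ids in arm_samples.items()
    )
    s2 = ss_within / df

    frames = []
    for spec in contrasts:
        for arm in (spec.arm_a, spec.arm_b):
            if arm not in arm_samples:
                raise ValueError(f"arm {arm!r} has no samples")
        na, nb = len(arm_samples[spec.arm_a]), len(arm_samples[spec.arm_b])
        included = (any_pos[spec.arm_a] & any_pos[spec.arm_b]).to_numpy()
        est = (means[spec.arm_a] - means[spec.arm_b]).to_numpy()
        se = np.sqrt(s2.to_numpy() * (1 / na + 1 / nb))
        degenerate = se == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(degenerate, np.where(est == 0, 0.0, np.sign(est) * np.inf), est / np.where(se == 0, np.nan, se))
            p = np.where(
                degenerate,
                np.where(est == 0, 1.0, 0.0),
                2 * stats.t.sf(np.abs(t), df),
            )
            ma, mb = means[spec.arm_a].to_numpy(), means[spec.arm_b].to_numpy()
            undefined = (ma <= 0) | (mb <= 0)
            log2fc = np.where(undefined, np.nan, np.log2(np.where(undefined, 1.0, ma / mb)))

        fdr = np.full(included.shape, np.nan)
        if included.any():
            fdr[included] = bh_fdr(p[included])
        frame = pd.DataFrame(
            {
                "species": X.columns,
                "contrast": spec.name,
                "included": included,
                "n_a": na,
                "n_b": nb,
                "estimate": np.where(included, est, np.nan),
                "log2fc": np.where(included, log2fc, np.nan),
                "t": np.where(included, t, np.nan),
                "p": np.where(included, p, np.nan),
                "fdr": fdr,
                "degenerate": included & degenerate,
                "log2fc_undefined": included & undefined,
            }
        )
        n_excluded = int((~included).sum())
        logger.info(
            "contrast %s: %d species tested, %d excluded by the inclusion rule",
            spec.name,
            int(included.sum()),
            n_excluded,
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def volcano_table(
    results: pd.DataFrame, contrast: str, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Volcano-plot-ready table for one contrast.

    Columns: species, log2fc, neglog10_p, fdr, significant (fdr below
    the threshold).  Only included species appear.
    """
    sub = results[(results["contrast"] == contrast) & results["included"]].copy()
    sub["neglog10_p"] = -np.log10(sub["p"])
    sub["significant"] = sub["fdr"] < fdr_threshold
    return sub[["species", "log2fc", "neglog10_p", "fdr", "significant"]].reset_index(
        drop=True
    )


def qq_table(results: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Observed vs expected -log10 p quantiles for one contrast.

    Expected quantiles are uniform order statistics (i - 0.5)/m; under a
    null contrast the points lie near the diagonal.
    """
    sub = results[(results["contrast"] == contrast) & results["included"]]
    p = np.sort(sub["p"].to_numpy())
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {
            "expected_neglog10_p": -np.log10(expected),
            "observed_neglog10_p": -np.log10(p),
        }
    )
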