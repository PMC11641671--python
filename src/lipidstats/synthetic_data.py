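"""Synthetic six-arm lipidomics datasets with known ground truth.

The generator emulates the statistical structure of a chronic
corticosterone-stress / antidepressant rat study: six treatment arms
(control; corticosterone; corticosterone plus Ze 117 at 30/90/180 mg/kg;
corticosterone plus escitalopram 10 mg/kg) with eight animals per arm,
two tissues (plasma, ~696 lipid species; hippocampus, ~953 species),
lognormal species abundances spanning four orders of magnitude with
limit-of-detection censoring, multiplicative arm effects, and a
behavioral latency linearly coupled to each animal's hippocampal
unsaturated-lysophosphatidylethanolamine content.

Default effect sizes are calibrated to the study's reported anchors:

* plasma structural baseline tilted so the mol%-weighted averages sit at
  DB_av ~ 2.7 double bonds and CL_av ~ 33 carbons, with a broad stress
  upshift that raises CL_av toward ~36 in the corticosterone arms;
* hippocampal unsaturated LPE totalling ~0.22 mol% under corticosterone,
  rising dose-ordered under Ze 117 co-treatment to ~0.29 mol% at
  180 mg/kg and ~0.31 mol% under escitalopram (saturated LPE untouched);
* forced-swim latency ~69 s in the corticosterone arm and ~115 s under
  the highest Ze 117 dose, coupled through the unsaturated-LPE mol%.

Two random streams keep the design reproducible: the *catalog* stream
(fixed seed) draws the species catalog, baselines and effect-target
subsets, so different simulation seeds share identical ground-truth
structure; the *noise* stream (user seed) draws measurement noise and
behavioral noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .nomenclature import LipidSpecies, parse_species
from .quantmatrix import ARMS, ARM_ORDER, QuantMatrix, SampleMeta

__all__ = [
    "ClassCatalogEntry",
    "EffectSpec",
    "BehaviorCoupling",
    "SimConfig",
    "SimResult",
    "default_study_config",
    "null_config",
    "generate",
    "write_dataset",
]

#: Fixed seed of the catalog stream (species, baselines, effect subsets).
CATALOG_SEED = 710_246

#: Explicit LPE species list so the class always contains the saturated
#: members and the unsaturated members whose treatment response the study
#: design revolves around.
LPE_SPECIES = (
    "LPE 16:0",
    "LPE 16:1",
    "LPE 18:0",
    "LPE 18:1",
    "LPE 18:2",
    "LPE 20:0",
    "LPE 20:1",
    "LPE 20:2",
    "LPE 20:3",
    "LPE 20:4",
    "LPE 22:0",
    "LPE 22:4",
    "LPE 22:5",
    "LPE 22:6",
)


@dataclass(frozen=True)
class ClassCatalogEntry:
    """How many species a class contributes and from which (C, DB) grid."""

    code: str
    fraction: float  # share of the non-fixed species budget
    carbon_range: tuple[int, int]  # inclusive
    db_range: tuple[int, int]  # inclusive


# Class composition loosely follows shotgun profiles of the two matrices:
# plasma is rich in cholesteryl esters and triacylglycerols, brain tissue
# in diacyl- and ether glycerophospholipids.
PLASMA_CATALOG = (
    ClassCatalogEntry("CE", 0.06, (14, 22), (0, 6)),
    ClassCatalogEntry("TAG", 0.15, (40, 58), (0, 6)),
    ClassCatalogEntry("DAG", 0.04, (28, 40), (0, 6)),
    ClassCatalogEntry("PC", 0.16, (28, 44), (0, 8)),
    ClassCatalogEntry("PC O-", 0.05, (28, 44), (0, 8)),
    ClassCatalogEntry("PE", 0.08, (28, 44), (0, 8)),
    ClassCatalogEntry("PE O-", 0.05, (28, 44), (0, 8)),
    ClassCatalogEntry("PS", 0.03, (30, 42), (0, 8)),
    ClassCatalogEntry("PI", 0.04, (30, 42), (0, 8)),
    ClassCatalogEntry("PA", 0.02, (30, 42), (0, 8)),
    ClassCatalogEntry("PG", 0.02, (30, 42), (0, 8)),
    ClassCatalogEntry("CL", 0.02, (64, 76), (0, 10)),
    ClassCatalogEntry("LPC", 0.05, (14, 24), (0, 6)),
    ClassCatalogEntry("LPC O-", 0.02, (14, 24), (0, 6)),
    ClassCatalogEntry("LPE O-", 0.02, (14, 24), (0, 6)),
    ClassCatalogEntry("LPA", 0.01, (14, 24), (0, 6)),
    ClassCatalogEntry("LPI", 0.02, (14, 24), (0, 6)),
    ClassCatalogEntry("LPS", 0.01, (14, 24), (0, 6)),
    ClassCatalogEntry("Cer", 0.05, (30, 44), (0, 3)),
    ClassCatalogEntry("HexCer", 0.04, (30, 44), (0, 3)),
    ClassCatalogEntry("SM", 0.06, (28, 44), (0, 3)),
)

HIPPOCAMPUS_CATALOG = (
    ClassCatalogEntry("CE", 0.01, (14, 22), (0, 6)),
    ClassCatalogEntry("TAG", 0.03, (40, 58), (0, 6)),
    ClassCatalogEntry("DAG", 0.03, (28, 40), (0, 6)),
    ClassCatalogEntry("PC", 0.17, (26, 46), (0, 8)),
    ClassCatalogEntry("PC O-", 0.07, (28, 44), (0, 8)),
    ClassCatalogEntry("PE", 0.15, (26, 46), (0, 8)),
    ClassCatalogEntry("PE O-", 0.10, (28, 44), (0, 8)),
    ClassCatalogEntry("PS", 0.06, (30, 42), (0, 8)),
    ClassCatalogEntry("PI", 0.05, (30, 42), (0, 8)),
    ClassCatalogEntry("PA", 0.03, (30, 42), (0, 8)),
    ClassCatalogEntry("PG", 0.02, (30, 42), (0, 8)),
    ClassCatalogEntry("CL", 0.03, (64, 76), (0, 10)),
    ClassCatalogEntry("LPC", 0.04, (14, 24), (0, 6)),
    ClassCatalogEntry("LPC O-", 0.02, (14, 24), (0, 6)),
    ClassCatalogEntry("LPE O-", 0.02, (14, 24), (0, 6)),
    ClassCatalogEntry("LPA", 0.01, (14, 24), (0, 6)),
    ClassCatalogEntry("LPI", 0.02, (14, 24), (0, 6)),
    ClassCatalogEntry("LPS", 0.01, (14, 24), (0, 6)),
    ClassCatalogEntry("Cer", 0.05, (30, 44), (0, 3)),
    ClassCatalogEntry("HexCer", 0.04, (30, 44), (0, 3)),
    ClassCatalogEntry("SM", 0.05, (28, 44), (0, 3)),
)


@dataclass(frozen=True)
class EffectSpec:
    """A multiplicative treatment effect on a predicate-defined species set.

    A species is targeted when *all* supplied predicates hold:
    membership in ``classes``, its ``saturation`` status, membership in
    an explicit ``species`` list, and minimum carbon / double-bond
    counts.  ``fraction`` < 1 thins the targeted set to a random subset
    drawn from the catalog stream (so the subset is part of the ground
    truth, identical across simulation seeds).
    """

    name: str
    tissue: str
    log2fc_by_arm: Mapping[str, float]
    classes: tuple[str, ...] | None = None
    saturation: str | None = None  # "saturated" | "unsaturated"
    species: tuple[str, ...] | None = None
    min_carbons: int | None = None
    min_double_bonds: int | None = None
    fraction: float = 1.0

    def matches(self, sp: LipidSpecies) -> bool:
        if self.classes is not None and sp.class_info.code not in self.classes:
            return False
        if self.saturation == "saturated" and sp.total_double_bonds != 0:
            return False
        if self.saturation == "unsaturated" and sp.total_double_bonds == 0:
            return False
        if self.species is not None and sp.raw_name not in self.species:
            return False
        if self.min_carbons is not None and sp.total_carbons < self.min_carbons:
            return False
        if self.min_double_bonds is not None and sp.total_double_bonds < self.min_double_bonds:
            return False
        return True


@dataclass(frozen=True)
class BehaviorCoupling:
    """Linear latency / unsaturated-LPE coupling plus immobility draws.

    ``latency = stressed_intercept + slope * unsatLPE_molpct
    (+ control_offset for the unstressed arm) + N(0, noise_sd)``,
    truncated to the 600 s test.  The control offset encodes that
    unstressed animals keep a long latency (~160 s, roughly halved by
    chronic stress) without any hippocampal LPE shift — which is why
    pooling all arms abolishes the lipid-latency correlation that the
    corticosterone/co-treated subset shows.
    """

    slope_s_per_molpct: float = 660.0
    stressed_intercept_s: float = -76.0
    control_offset_s: float = 90.0
    latency_noise_sd_s: float = 20.0
    immobility_mean_s: Mapping[str, float] = field(
        default_factory=lambda: {
            "CONTROL": 185.0,
            "CORT": 256.5,
            "CORT_ZE30": 245.0,
            "CORT_ZE90": 220.0,
            "CORT_ZE180": 155.4,
            "CORT_ESC": 205.0,
        }
    )
    immobility_sd_s: float = 70.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_per_arm: int = 8
    arms: tuple[str, ...] = tuple(ARM_ORDER)
    n_species: Mapping[str, int] = field(
        default_factory=lambda: {"plasma": 696, "hippocampus": 953}
    )
    noise_cv: float = 0.20
    lod_quantile: float = 0.02
    baseline_log10_range: tuple[float, float] = (-1.3, 2.7)  # 0.05 .. 500 pmol
    catalog_seed: int = CATALOG_SEED
    effects: tuple[EffectSpec, ...] = ()
    behavior: BehaviorCoupling = field(default_factory=BehaviorCoupling)
    #: mol%-weighted (DB_av, CL_av) the baseline of a tissue is tilted to
    structural_targets: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    #: per-total shares the LPE class baseline is rescaled to
    lpe_share: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must lie in [0, 1)")
        for arm in self.arms:
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}")
        for t, n in self.n_species.items():
            if n < len(LPE_SPECIES):
                raise ValueError(f"{t}: need at least {len(LPE_SPECIES)} species")
        for eff in self.effects:
            if eff.tissue not in self.n_species:
                raise ValueError(f"effect {eff.name!r} references unknown tissue")
            for arm in eff.log2fc_by_arm:
                if arm not in self.arms:
                    raise ValueError(f"effect {eff.name!r} references unknown arm {arm!r}")
            if not all(np.isfinite(list(eff.log2fc_by_arm.values()))):
                raise ValueError(f"effect {eff.name!r} has non-finite log2fc")


@dataclass
class SimResult:
    config: SimConfig
    matrices: dict[str, QuantMatrix]  # tissue -> raw pmol matrix (lod set)
    behavior: pd.DataFrame  # index animal_id
    ground_truth: pd.DataFrame  # tissue, species, arm, log2fc
    metadata: pd.DataFrame  # sample_id, animal_id, tissue, arm


# Dose-ordered Ze 117 effects on unsaturated LPE; the 180 mg/kg and
# escitalopram values reproduce the reported class totals
# (0.22 -> 0.29 and 0.22 -> 0.31 mol%, i.e. log2 ratios 0.398 / 0.495);
# the 30/90 values interpolate the dose ordering.
LPE_LOG2FC = {
    "CORT_ZE30": 0.15,
    "CORT_ZE90": 0.28,
    "CORT_ZE180": float(np.log2(0.29 / 0.22)),
    "CORT_ESC": float(np.log2(0.31 / 0.22)),
}

_CORT_ARMS = ("CORT", "CORT_ZE30", "CORT_ZE90", "CORT_ZE180", "CORT_ESC")


def default_study_config(seed: int = 0) -> SimConfig:
    """The study-design defaults the package's analyses are exercised on."""
    effects = (
        # broad, pattern-free plasma upshift in every corticosterone arm
        EffectSpec(
            name="plasma_stress_upshift",
            tissue="plasma",
            fraction=0.60,
            log2fc_by_arm={a: 0.5 for a in _CORT_ARMS},
        ),
        # triacylglycerol surge (glucocorticoid-driven lipolysis / VLDL
        # export) lifts the chain-length average from ~33 to ~36 carbons
        EffectSpec(
            name="plasma_stress_tag",
            tissue="plasma",
            classes=("TAG",),
            log2fc_by_arm={a: 1.49 for a in _CORT_ARMS},
        ),
        # antidepressant co-treatment lowers the polyunsaturated share
        EffectSpec(
            name="plasma_treatment_desaturation",
            tissue="plasma",
            min_double_bonds=4,
            log2fc_by_arm={"CORT_ZE180": -0.3, "CORT_ESC": -0.3},
        ),
        # dose-ordered hippocampal rise of unsaturated LPE only
        EffectSpec(
            name="hippocampus_lpe_unsat",
            tissue="hippocampus",
            classes=("LPE",),
            saturation="unsaturated",
            log2fc_by_arm=dict(LPE_LOG2FC),
        ),
    )
    return SimConfig(
        seed=seed,
        effects=effects,
        structural_targets={"plasma": (2.70, 33.0)},
        lpe_share={"hippocampus": (0.0012, 0.0022)},  # (saturated, unsaturated)
    )


def null_config(
    seed: int = 0, n_species: int = 200, tissue: str = "plasma"
) -> SimConfig:
    """A no-effect dataset for type-I-error studies (single tissue)."""
    return SimConfig(seed=seed, n_species={tissue: n_species}, effects=())


# ----------------------------------------------------------------------
# catalog construction


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    raw = fractions / fractions.sum() * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _build_catalog(
    tissue: str, n_species: int, rng: np.random.Generator
) -> list[LipidSpecies]:
    entries = PLASMA_CATALOG if tissue == "plasma" else HIPPOCAMPUS_CATALOG
    species: list[LipidSpecies] = [parse_species(n) for n in LPE_SPECIES]
    budget = n_species - len(species)
    fractions = np.array([e.fraction for e in entries])
    counts = _largest_remainder_counts(fractions, budget)
    for entry, count in zip(entries, counts):
        c_lo, c_hi = entry.carbon_range
        d_lo, d_hi = entry.db_range
        grid = [
            (c, d)
            for c in range(c_lo, c_hi + 1)
            for d in range(d_lo, d_hi + 1)
            if d < c
        ]
        if count > len(grid):
            raise ValueError(
                f"{tissue}/{entry.code}: {count} species requested from a "
                f"{len(grid)}-combination carbon/double-bond grid"
            )
        picks = rng.choice(len(grid), size=count, replace=False)
        for idx in sorted(picks):
            c, d = grid[idx]
            species.append(parse_species(f"{entry.code} {c}:{d}".replace("- ", "-")))
    return species


def _tilt_baselines(
    baselines: np.ndarray,
    species: Sequence[LipidSpecies],
    targets: tuple[float, float],
) -> np.ndarray:
    """Exponentially tilt baselines to hit mol%-weighted (DB_av, CL_av)."""
    db = np.array([sp.total_double_bonds for sp in species], dtype=float)
    cl = np.array([sp.total_carbons for sp in species], dtype=float)
    db_t, cl_t = targets

    def residual(params):
        a, b = params
        w = baselines * np.exp(a * db + b * cl)
        w /= w.sum()
        return [float(w @ db) - db_t, float(w @ cl) - cl_t]

    sol = optimize.root(residual, x0=[0.0, 0.0], tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"baseline tilt failed to converge: {sol.message}")
    a, b = sol.x
    return baselines * np.exp(a * db + b * cl)


def _rescale_lpe(
    baselines: np.ndarray,
    species: Sequence[LipidSpecies],
    shares: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Rescale LPE baselines to fixed per-total shares (sat, unsat).

    Within the class the relative abundances are redrawn from a narrow
    (one order of magnitude) log-uniform spread: the LPE panel is the
    quantified, response-carrying part of the design, so none of its
    members may sit below the limit of detection.
    """
    sat_share, unsat_share = shares
    is_lpe = np.array([sp.class_info.code == "LPE" for sp in species])
    is_sat = np.array([sp.total_double_bonds == 0 for sp in species])
    other = baselines[~is_lpe].sum()
    total = other / (1.0 - sat_share - unsat_share)
    out = baselines.copy()
    out[is_lpe] = 10 ** rng.uniform(-0.5, 0.5, size=int(is_lpe.sum()))
    for mask, share in [(is_lpe & is_sat, sat_share), (is_lpe & ~is_sat, unsat_share)]:
        group = out[mask].sum()
        out[mask] = out[mask] / group * share * total
    return out


def _effect_log2fc(
    config: SimConfig,
    tissue: str,
    species: Sequence[LipidSpecies],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(species, arm) summed log2 fold changes and the ground-truth table."""
    names = [sp.raw_name for sp in species]
    log2fc = pd.DataFrame(0.0, index=names, columns=list(config.arms))
    gt_rows = []
    for eff in config.effects:
        if eff.tissue != tissue:
            continue
        hit = np.array([eff.matches(sp) for sp in species])
        if eff.fraction < 1.0:
            hit &= rng.random(len(species)) < eff.fraction
        if not hit.any():
            raise ValueError(f"effect {eff.name!r} matches no species")
        for arm, fc in eff.log2fc_by_arm.items():
            log2fc.loc[hit, arm] += fc
            for name in log2fc.index[hit]:
                gt_rows.append(
                    {
                        "tissue": tissue,
                        "species": name,
                        "arm": arm,
                        "effect": eff.name,
                        "log2fc": fc,
                    }
                )
    gt = pd.DataFrame(gt_rows, columns=["tissue", "species", "arm", "effect", "log2fc"])
    return log2fc, gt


# ----------------------------------------------------------------------
# generation


def generate(config: SimConfig) -> SimResult:
    """Draw one complete synthetic dataset under ``config``.

    Returns raw pmol matrices (one per tissue, with the quantile-derived
    LOD attached but not yet applied), the behavior table and the
    ground-truth effect table.  Byte-identical for identical configs.
    """
    config.validate()
    catalog_rng = np.random.default_rng(config.catalog_seed)
    noise_rng = np.random.default_rng(config.seed)

    arms = list(config.arms)
    n = config.n_per_arm
    animals = [f"R{i + 1:02d}" for i in range(len(arms) * n)]
    arm_of_animal = {a: arms[i // n] for i, a in enumerate(animals)}

    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    matrices: dict[str, QuantMatrix] = {}
    gt_frames = []
    meta_rows = []

    for tissue in config.n_species:
        species = _build_catalog(tissue, config.n_species[tissue], catalog_rng)
        lo, hi = config.baseline_log10_range
        baselines = 10 ** catalog_rng.uniform(lo, hi, size=len(species))
        if tissue in config.structural_targets:
            baselines = _tilt_baselines(
                baselines, species, config.structural_targets[tissue]
            )
        if tissue in config.lpe_share:
            baselines = _rescale_lpe(
                baselines, species, config.lpe_share[tissue], catalog_rng
            )
        log2fc, gt = _effect_log2fc(config, tissue, species, catalog_rng)
        gt_frames.append(gt)

        arm_mult = 2.0 ** log2fc.to_numpy()  # species x arms
        arm_index = {a: j for j, a in enumerate(arms)}
        rows = []
        sample_metas = []
        for animal in animals:
            arm = arm_of_animal[animal]
            mean = baselines * arm_mult[:, arm_index[arm]]
            noise = noise_rng.lognormal(
                mean=-(sigma**2) / 2.0, sigma=sigma, size=len(species)
            )
            rows.append(mean * noise)
            sid = f"{animal}_{tissue}"
            sample_metas.append(
                SampleMeta(sample_id=sid, animal_id=animal, tissue=tissue, arm=ARMS[arm])
            )
            meta_rows.append(
                {"sample_id": sid, "animal_id": animal, "tissue": tissue, "arm": arm}
            )
        amounts = pd.DataFrame(
            np.vstack(rows),
            index=pd.Index([m.sample_id for m in sample_metas], name="sample_id"),
            columns=[sp.raw_name for sp in species],
        )
        lod = (
            float(np.quantile(amounts.to_numpy(), config.lod_quantile))
            if config.lod_quantile > 0
            else 0.0
        )
        matrices[tissue] = QuantMatrix(
            amounts=amounts, samples=sample_metas, species=species, lod=lod
        )

    behavior = _draw_behavior(config, matrices, animals, arm_of_animal, noise_rng)
    ground_truth = (
        pd.concat(gt_frames, ignore_index=True)
        if gt_frames
        else pd.DataFrame(columns=["tissue", "species", "arm", "effect", "log2fc"])
    )
    metadata = pd.DataFrame(meta_rows)
    return SimResult(
        config=config,
        matrices=matrices,
        behavior=behavior,
        ground_truth=ground_truth,
        metadata=metadata,
    )


def _draw_behavior(
    config: SimConfig,
    matrices: Mapping[str, QuantMatrix],
    animals: Sequence[str],
    arm_of_animal: Mapping[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Latency coupled to hippocampal unsaturated-LPE mol%; immobility by arm."""
    bc = config.behavior
    unsat_lpe = None
    if "hippocampus" in matrices:
        m = matrices["hippocampus"]
        molpct = m.amounts.div(m.amounts.sum(axis=1), axis=0) * 100.0
        cols = [
            sp.raw_name
            for sp in m.species
            if sp.class_info.code == "LPE" and sp.total_double_bonds >= 1
        ]
        by_sample = molpct[cols].sum(axis=1)
        unsat_lpe = {
            s.animal_id: float(by_sample[s.sample_id]) for s in m.samples
        }

    rows = []
    for animal in animals:
        arm = arm_of_animal[animal]
        if unsat_lpe is not None:
            latency = (
                bc.stressed_intercept_s
                + bc.slope_s_per_molpct * unsat_lpe[animal]
                + (bc.control_offset_s if arm == "CONTROL" else 0.0)
            )
        else:
            latency = 90.0
        latency += rng.normal(0.0, bc.latency_noise_sd_s)
        immob = rng.normal(bc.immobility_mean_s.get(arm, 200.0), bc.immobility_sd_s)
        rows.append(
            {
                "animal_id": animal,
                "total_immobility_s": float(np.clip(immob, 0.0, 600.0)),
                "latency_first_immobility_s": float(np.clip(latency, 0.0, 600.0)),
            }
        )
    return pd.DataFrame(rows).set_index("animal_id")


def write_dataset(result: SimResult, outdir: str | Path) -> list[Path]:
    """Write quant / metadata / behavior / ground-truth CSVs; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for tissue, m in result.matrices.items():
        table = m.amounts.T  # species rows, sample columns
        table.insert(0, "lod", float(m.lod) if np.isscalar(m.lod) else m.lod)
        table.index.name = "species"
        path = outdir / f"quant_{tissue}.csv"
        table.to_csv(path)
        written.append(path)
    meta_path = outdir / "metadata.csv"
    result.metadata.to_csv(meta_path, index=False)
    written.append(meta_path)
    behavior_path = outdir / "behavior.csv"
    result.behavior.to_csv(behavior_path)
    written.append(behavior_path)
    gt_path = outdir / "ground_truth.csv"
    result.ground_truth.to_csv(gt_path, index=False)
    written.append(gt_path)
    return written
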