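"""End-to-end orchestration: filter -> normalize -> statistics -> tables.

The pipeline ties the modules together into one reproducible run over a
quantification table (real or simulated): identification/LOD filtering,
mol% normalization, per-sample structural summaries with arm-level
comparisons, the five treatment contrasts with per-contrast FDR plus
volcano/QQ tables, and lipid-behavior correlations.  Every run emits a
manifest recording the configuration hash, input digests, per-stage
species counts and the produced files, so identical inputs yield
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__, behavior, diff_abundance, quantmatrix, structural_stats
from .quantmatrix import QuantMatrix
from .synthetic_data import SimConfig, generate, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "analyze_tissue", "correlate_tissue", "run_all"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    package_version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _prepare(quant_path, meta_path) -> tuple[QuantMatrix, dict[str, int]]:
    m = quantmatrix.read_quant_table(quant_path, meta_path)
    counts = {"species_read": len(m.species)}
    m = quantmatrix.apply_identification_filter(m)
    counts["species_after_identification_filter"] = len(m.species)
    m = quantmatrix.apply_lod(m)
    counts["species_after_lod"] = len(m.species)
    return quantmatrix.to_molpct(m), counts


def analyze_tissue(
    quant_path: str | Path,
    meta_path: str | Path,
    out_dir: str | Path,
    tissue: str | None = None,
    fdr_threshold: float = 0.05,
    scopes: Sequence[str] = ("all", "LPE"),
    reference_arm: str = "CORT",
) -> tuple[list[Path], dict[str, int]]:
    """Run the per-tissue analysis chain; returns (written files, counts)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    molpct, counts = _prepare(quant_path, meta_path)
    if tissue is not None:
        keep = [s.sample_id for s in molpct.samples if s.tissue == tissue]
        if not keep:
            raise ValueError(f"no samples of tissue {tissue!r} in {quant_path}")
        molpct = molpct.subset_samples(keep)
    label = tissue or "all"
    written: list[Path] = []

    path = out / f"molpct_{label}.csv"
    quantmatrix.write_long_table(molpct, path)
    written.append(path)

    summary = structural_stats.structural_summary_table(molpct, scopes=scopes)
    path = out / f"structural_summary_{label}.csv"
    summary.to_csv(path, index=False)
    written.append(path)

    meta = molpct.meta_frame()
    comp_rows = []
    for scope in scopes:
        sub = summary[summary["scope"] == scope].set_index("sample_id")
        for metric in ("db_av", "cl_av", "sat_molpct", "unsat_molpct"):
            by_arm = {
                arm: sub.loc[ids, metric].to_list()
                for arm, ids in meta.groupby("arm").groups.items()
            }
            gc = structural_stats.anova_holm_sidak(by_arm, reference_arm, scope=scope)
            for arm, row in gc.comparisons.iterrows():
                comp_rows.append(
                    {
                        "scope": scope,
                        "metric": metric,
                        "arm": arm,
                        "mean": gc.arm_means.loc[arm, "mean"],
                        "sem": gc.arm_means.loc[arm, "sem"],
                        "n": gc.arm_means.loc[arm, "n"],
                        "anova_F": gc.anova_F,
                        "anova_p": gc.anova_p,
                        "estimate_vs_ref": row["estimate"],
                        "t": row["t"],
                        "p": row["p"],
                        "adj_p": row["adj_p"],
                    }
                )
    path = out / f"group_comparisons_{label}.csv"
    pd.DataFrame(comp_rows).to_csv(path, index=False)
    written.append(path)

    results = diff_abundance.run_contrasts(molpct)
    path = out / f"contrasts_{label}.csv"
    results.to_csv(path, index=False)
    written.append(path)
    counts["species_tested_any_contrast"] = int(
        results[results["included"]]["species"].nunique()
    )
    for spec in diff_abundance.DEFAULT_CONTRASTS:
        sub = results[results["contrast"] == spec.name]
        counts[f"excluded_{spec.name}"] = int((~sub["included"]).sum())
        tag = spec.name.replace("+", "_")
        path = out / f"volcano_{label}_{tag}.csv"
        diff_abundance.volcano_table(results, spec.name, fdr_threshold).to_csv(
            path, index=False
        )
        written.append(path)
        path = out / f"qq_{label}_{tag}.csv"
        diff_abundance.qq_table(results, spec.name).to_csv(path, index=False)
        written.append(path)
    return written, counts


def correlate_tissue(
    quant_path: str | Path,
    meta_path: str | Path,
    behavior_path: str | Path,
    out_dir: str | Path,
    tissue: str | None = "hippocampus",
    subsets: Sequence[str] = ("all-arms", "cort-and-cotreated"),
    reference_arm: str = "CORT",
) -> tuple[list[Path], dict[str, int]]:
    """Lipid-behavior correlations per subset plus arm-level FST statistics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    molpct, counts = _prepare(quant_path, meta_path)
    if tissue is not None:
        keep = [s.sample_id for s in molpct.samples if s.tissue == tissue]
        if not keep:
            raise ValueError(f"no samples of tissue {tissue!r} in {quant_path}")
        molpct = molpct.subset_samples(keep)
    label = tissue or "all"
    behav = behavior.read_behavior_table(behavior_path)
    written: list[Path] = []
    for subset in subsets:
        corr = behavior.correlate_lipids(molpct, behav, subset=subset)
        path = out / f"correlation_{label}_{subset}.csv"
        corr.to_csv(path, index=False)
        written.append(path)
        counts[f"species_correlated_{subset}"] = len(corr)

    arm_by_animal = {s.animal_id: s.arm.label for s in molpct.samples}
    fst = behavior.fst_group_stats(behav, arm_by_animal, reference_arm=reference_arm)
    rows = []
    for measure, gc in fst.items():
        for arm, row in gc.comparisons.iterrows():
            rows.append(
                {
                    "measure": measure,
                    "arm": arm,
                    "mean": gc.arm_means.loc[arm, "mean"],
                    "sem": gc.arm_means.loc[arm, "sem"],
                    "anova_F": gc.anova_F,
                    "anova_p": gc.anova_p,
                    "p": row["p"],
                    "adj_p": row["adj_p"],
                }
            )
    path = out / "fst_stats.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)
    return written, counts


def run_all(
    config: SimConfig,
    out_dir: str | Path,
    fdr_threshold: float = 0.05,
    subsets: Sequence[str] = ("all-arms", "cort-and-cotreated"),
) -> RunManifest:
    """Simulate a dataset and run the full analysis on every tissue.

    Writes the simulated tables, all analysis outputs and a
    ``manifest.json`` into ``out_dir``; identical configs produce
    identical manifests.
    """
    out = Path(out_dir)
    data_dir = out / "data"
    stage = "simulate"
    try:
        result = generate(config)
        data_files = write_dataset(result, data_dir)
        manifest = RunManifest(
            config_hash=hashlib.sha256(repr(config).encode()).hexdigest(),
            seed=config.seed,
            package_version=__version__,
            input_digests={p.name: _sha256(p) for p in data_files},
            outputs=[str(p.relative_to(out)) for p in data_files],
        )
        meta_path = data_dir / "metadata.csv"
        for tissue in result.matrices:
            stage = f"analyze:{tissue}"
            files, counts = analyze_tissue(
                data_dir / f"quant_{tissue}.csv",
                meta_path,
                out,
                tissue=tissue,
                fdr_threshold=fdr_threshold,
            )
            manifest.outputs += [str(p.relative_to(out)) for p in files]
            manifest.stage_counts.update({f"{tissue}:{k}": v for k, v in counts.items()})
        if "hippocampus" in result.matrices:
            stage = "correlate:hippocampus"
            files, counts = correlate_tissue(
                data_dir / "quant_hippocampus.csv",
                meta_path,
                data_dir / "behavior.csv",
                out,
                subsets=subsets,
            )
            manifest.outputs += [str(p.relative_to(out)) for p in files]
            manifest.stage_counts.update(
                {f"hippocampus:{k}": v for k, v in counts.items()}
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest.to_json(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest
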