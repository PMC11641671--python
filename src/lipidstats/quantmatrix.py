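"""Samples x species quantification with metadata, LOD handling and mol%.

The central container is :class:`QuantMatrix`: per-sample pmol amounts for
every identified species, joined to sample metadata (animal, tissue,
treatment arm), an optional per-species or global limit of detection, and
optional identification-QC columns (signal-to-noise, blank intensity).

Conventions
-----------
* Amounts are non-negative pmol; sub-LOD values are replaced by zero
  before any statistics, and the replaced cells are remembered so the
  per-contrast inclusion rule can audit them.
* mol% is carried on the 0-100 scale: per sample, each species' amount
  divided by the summed amount of all retained species, times 100.  Zeros
  (censored species) stay in the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nomenclature import LipidClassInfo, LipidSpecies, parse_species

logger = logging.getLogger(__name__)

__all__ = [
    "Tissue",
    "TreatmentArm",
    "ARMS",
    "ARM_ORDER",
    "SampleMeta",
    "QuantMatrix",
    "read_quant_table",
    "apply_identification_filter",
    "apply_lod",
    "to_molpct",
    "write_long_table",
]

#: Reserved quant-table column names that carry per-species QC values
#: rather than sample amounts.
RESERVED_COLUMNS = ("lod", "snr", "blank_intensity")


class Tissue(str, Enum):
    PLASMA = "plasma"
    HIPPOCAMPUS = "hippocampus"


@dataclass(frozen=True)
class TreatmentArm:
    """One of the six arms of the corticosterone / antidepressant design.

    ``dose_mgkg`` is the dose of the co-administered compound (Ze 117 or
    escitalopram); the corticosterone dose itself (40 mg/kg in every
    stressed arm) is a property of the design, not a per-arm variable.
    """

    label: str
    dose_mgkg: float
    corticosterone: bool


ARMS: dict[str, TreatmentArm] = {
    "CONTROL": TreatmentArm("CONTROL", 0.0, corticosterone=False),
    "CORT": TreatmentArm("CORT", 0.0, corticosterone=True),
    "CORT_ZE30": TreatmentArm("CORT_ZE30", 30.0, corticosterone=True),
    "CORT_ZE90": TreatmentArm("CORT_ZE90", 90.0, corticosterone=True),
    "CORT_ZE180": TreatmentArm("CORT_ZE180", 180.0, corticosterone=True),
    "CORT_ESC": TreatmentArm("CORT_ESC", 10.0, corticosterone=True),
}

ARM_ORDER = list(ARMS)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    animal_id: str
    tissue: str
    arm: TreatmentArm


@dataclass
class QuantMatrix:
    """Samples x species lipid amounts plus metadata and QC.

    Attributes
    ----------
    amounts : pandas.DataFrame
        Rows = samples (index: sample_id), columns = species raw names.
    samples : list of SampleMeta
        Aligned with ``amounts.index``.
    species : list of LipidSpecies
        Aligned with ``amounts.columns``.
    lod : float or pandas.Series
        Global scalar LOD, or per-species LOD indexed like the columns.
        Default 0 (no censoring).
    unit : str
        ``"pmol"`` or ``"molpct"``.
    lod_mask : pandas.DataFrame or None
        Boolean mask of cells zeroed by :func:`apply_lod`.
    """

    amounts: pd.DataFrame
    samples: list[SampleMeta]
    species: list[LipidSpecies]
    lod: float | pd.Series = 0.0
    snr: pd.Series | None = None
    blank_intensity: pd.Series | None = None
    unit: str = "pmol"
    lod_mask: pd.DataFrame | None = None

    def __post_init__(self):
        if list(self.amounts.index) != [s.sample_id for s in self.samples]:
            raise ValueError("amounts index must match sample metadata order")
        if list(self.amounts.columns) != [sp.raw_name for sp in self.species]:
            raise ValueError("amounts columns must match species order")
        if (self.amounts.to_numpy() < 0).any():
            raise ValueError("amounts must be non-negative")

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.amounts.index)

    @property
    def species_names(self) -> list[str]:
        return list(self.amounts.columns)

    def species_by_name(self) -> dict[str, LipidSpecies]:
        return {sp.raw_name: sp for sp in self.species}

    def meta_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample_id."""
        return pd.DataFrame(
            {
                "animal_id": [s.animal_id for s in self.samples],
                "tissue": [s.tissue for s in self.samples],
                "arm": [s.arm.label for s in self.samples],
                "dose_mgkg": [s.arm.dose_mgkg for s in self.samples],
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def arm_of(self, sample_id: str) -> str:
        return self.samples[self.sample_ids.index(sample_id)].arm.label

    def subset_samples(self, sample_ids: Sequence[str]) -> "QuantMatrix":
        keep = [s for s in self.samples if s.sample_id in set(sample_ids)]
        ids = [s.sample_id for s in keep]
        return QuantMatrix(
            amounts=self.amounts.loc[ids],
            samples=keep,
            species=self.species,
            lod=self.lod,
            snr=self.snr,
            blank_intensity=self.blank_intensity,
            unit=self.unit,
            lod_mask=None if self.lod_mask is None else self.lod_mask.loc[ids],
        )


def _parse_arm(label: str) -> TreatmentArm:
    try:
        return ARMS[label]
    except KeyError:
        raise ValueError(
            f"unknown treatment arm {label!r}; expected one of {ARM_ORDER}"
        ) from None


def read_metadata(meta_path: str | Path) -> dict[str, SampleMeta]:
    """Read the sample-metadata table (sample_id, animal_id, tissue, arm)."""
    meta = pd.read_csv(meta_path, sep=None, engine="python", dtype=str)
    required = {"sample_id", "animal_id", "tissue", "arm"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    out: dict[str, SampleMeta] = {}
    seen_animal_tissue = set()
    for row in meta.itertuples(index=False):
        key = (row.animal_id, row.tissue)
        if key in seen_animal_tissue:
            raise ValueError(f"more than one sample for animal/tissue {key}")
        seen_animal_tissue.add(key)
        out[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            animal_id=row.animal_id,
            tissue=Tissue(row.tissue).value,
            arm=_parse_arm(row.arm),
        )
    return out


def read_quant_table(
    path: str | Path,
    meta_path: str | Path,
    registry: Mapping[str, LipidClassInfo] | None = None,
) -> QuantMatrix:
    """Read a delimited species x samples quantification table.

    First column: species shorthand names; header: sample ids; values:
    pmol amounts.  Optional reserved columns ``lod``, ``snr`` and
    ``blank_intensity`` carry per-species QC values.  Every sample column
    must be present in the metadata file.
    """
    table = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].tolist()
        raise ValueError(f"duplicate species rows: {dupes}")

    qc = {c: table[c] for c in RESERVED_COLUMNS if c in table.columns}
    sample_cols = [c for c in table.columns if c not in RESERVED_COLUMNS]

    meta = read_metadata(meta_path)
    unmatched = [c for c in sample_cols if c not in meta]
    if unmatched:
        raise ValueError(f"sample ids missing from metadata: {unmatched}")

    values = table[sample_cols]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise ValueError(f"non-numeric amounts in sample columns: {bad}")

    species = [parse_species(name, registry) for name in table.index]
    amounts = numeric.T  # -> samples x species
    amounts.columns = [sp.raw_name for sp in species]
    amounts.index.name = "sample_id"
    samples = [meta[sid] for sid in amounts.index]

    lod: float | pd.Series = 0.0
    if "lod" in qc:
        lod = pd.to_numeric(qc["lod"])
        lod.index = amounts.columns
    snr = pd.to_numeric(qc["snr"]) if "snr" in qc else None
    if snr is not None:
        snr.index = amounts.columns
    blank = pd.to_numeric(qc["blank_intensity"]) if "blank_intensity" in qc else None
    if blank is not None:
        blank.index = amounts.columns

    return QuantMatrix(
        amounts=amounts.astype(float),
        samples=samples,
        species=species,
        lod=lod,
        snr=snr,
        blank_intensity=blank,
    )


def apply_identification_filter(
    m: QuantMatrix, snr_min: float = 5.0, blank_ratio_min: float = 5.0
) -> QuantMatrix:
    """Drop species failing the identification QC criteria.

    A species is retained only if its signal-to-noise ratio is strictly
    greater than ``snr_min`` and its signal intensity strictly more than
    ``blank_ratio_min``-fold the blank intensity.  Criteria whose QC
    column is absent are skipped with a warning (no-op when both are
    missing).
    """
    if m.snr is None and m.blank_intensity is None:
        logger.warning("no snr/blank_intensity columns; identification filter is a no-op")
        return m

    keep = pd.Series(True, index=m.amounts.columns)
    if m.snr is not None:
        keep &= m.snr > snr_min
    else:
        logger.warning("snr column absent; skipping signal-to-noise criterion")
    if m.blank_intensity is not None:
        # mean signal across samples versus blank; strict ">" per the
        # "k-fold higher than blank" rule
        signal = m.amounts.mean(axis=0)
        keep &= signal > blank_ratio_min * m.blank_intensity
    else:
        logger.warning("blank_intensity column absent; skipping blank criterion")

    removed = int((~keep).sum())
    logger.info("identification filter removed %d of %d species", removed, len(keep))
    kept_names = list(keep.index[keep])
    species = [sp for sp in m.species if sp.raw_name in set(kept_names)]
    return QuantMatrix(
        amounts=m.amounts[kept_names],
        samples=m.samples,
        species=species,
        lod=m.lod if np.isscalar(m.lod) else m.lod[kept_names],
        snr=None if m.snr is None else m.snr[kept_names],
        blank_intensity=None
        if m.blank_intensity is None
        else m.blank_intensity[kept_names],
        unit=m.unit,
        lod_mask=None if m.lod_mask is None else m.lod_mask[kept_names],
    )


def apply_lod(m: QuantMatrix) -> QuantMatrix:
    """Replace every amount strictly below the LOD by zero.

    The mask of replaced cells is kept on the returned matrix so the
    per-contrast inclusion rule can be audited.  Species that end up
    all-zero are retained: whether they are analyzed is decided per
    contrast, not here.
    """
    lod = m.lod
    if np.isscalar(lod):
        below = m.amounts < float(lod)
    else:
        below = m.amounts.lt(lod, axis=1)
    replaced = below & (m.amounts > 0)
    censored = m.amounts.mask(below, 0.0)
    logger.info("LOD censoring zeroed %d cells", int(replaced.to_numpy().sum()))
    return QuantMatrix(
        amounts=censored,
        samples=m.samples,
        species=m.species,
        lod=m.lod,
        snr=m.snr,
        blank_intensity=m.blank_intensity,
        unit=m.unit,
        lod_mask=below,
    )


def to_molpct(m: QuantMatrix) -> QuantMatrix:
    """Normalize each sample to mol% of its total lipid amount (0-100).

    Zeros stay in the denominator (a censored species contributes zero to
    the total).  A sample whose amounts are all zero cannot be normalized
    and raises, naming the sample.
    """
    totals = m.amounts.sum(axis=1)
    dead = totals.index[totals <= 0].tolist()
    if dead:
        raise ValueError(f"cannot compute mol% for all-zero sample(s): {dead}")
    molpct = m.amounts.div(totals, axis=0) * 100.0
    return QuantMatrix(
        amounts=molpct,
        samples=m.samples,
        species=m.species,
        lod=m.lod,
        snr=m.snr,
        blank_intensity=m.blank_intensity,
        unit="molpct",
        lod_mask=m.lod_mask,
    )


def write_long_table(m: QuantMatrix, path: str | Path) -> pd.DataFrame:
    """Write the matrix as tidy long CSV (sample_id, species, value, unit)."""
    long = (
        m.amounts.reset_index()
        .melt(id_vars="sample_id", var_name="species", value_name=m.unit)
        .sort_values(["sample_id", "species"], kind="stable")
    )
    long.to_csv(path, index=False)
    return long
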