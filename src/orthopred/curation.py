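"""Bioactivity curation: unit conversion, structure standardization and
activity filtering.

Active records are kept when they come from binding or functional assays
with a target-assignment confidence score strictly greater than 5 and
either a pChEMBL value (−log10 molar Ki/Kd/IC50/EC50) of at least 5
(i.e. 10 µM) or an activity comment declaring the compound active.
Structures are standardized (largest fragment, neutralized, canonical
tautomer) and filtered for drug-likeness: carbon required, molecular
weight in [100, 1000] Da, and no atoms from the forbidden atomic-number
ranges 21–32, 36–52 and ≥54 (iodine, Z=53, is allowed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: multiplicative factor taking a value in the given unit to molar
_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

#: standard_type values that carry a convertible affinity
AFFINITY_TYPES = {"Ki", "Kd", "IC50", "EC50"}

#: assay types eligible for active extraction
ELIGIBLE_ASSAY_TYPES = {"binding", "functional"}

#: canonical column order for curated bioactivity tables
BIOACTIVITY_COLUMNS = [
    "compound_id",
    "smiles",
    "target_accession",
    "species",
    "pchembl",
    "standard_type",
    "standard_units",
    "assay_type",
    "confidence",
    "activity_comment",
    "label",
    "record_date",
    "source",
]


class UnitError(ValueError):
    """Raised for affinities that cannot be converted to molar."""


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds applied during bioactivity curation.

    Parameters
    ----------
    pchembl_active_min : float
        Minimum −log10 molar affinity for a record to count as active
        (5.0 ⇔ 10 µM).
    confidence_min_exclusive : int
        Records must have a confidence score strictly greater than this.
    mw_min, mw_max : float
        Allowed molecular weight window in Daltons.
    forbidden_z_ranges : sequence of (lo, hi)
        Inclusive atomic-number intervals that disqualify a structure;
        ``hi=None`` means unbounded above.
    require_carbon : bool
        Reject carbon-free structures.
    min_actives : int
        Minimum number of active training compounds per target model.
    """

    pchembl_active_min: float = 5.0
    confidence_min_exclusive: int = 5
    mw_min: float = 100.0
    mw_max: float = 1000.0
    forbidden_z_ranges: tuple = ((21, 32), (36, 52), (54, None))
    require_carbon: bool = True
    min_actives: int = 10

    def __post_init__(self):
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        if not self.pchembl_active_min > 0:
            raise ValueError("pchembl_active_min must be positive")
        prev_hi = -1
        for lo, hi in self.forbidden_z_ranges:
            if lo <= prev_hi:
                raise ValueError("forbidden_z_ranges must be sorted and non-overlapping")
            prev_hi = math.inf if hi is None else hi


@dataclass(frozen=True)
class BioactivityRecord:
    """A single compound–target measurement."""

    compound_id: str
    smiles: str
    target_accession: str
    species: str
    pchembl: float | None
    standard_type: str = "other"
    standard_units: str | None = None
    assay_type: str = "binding"
    confidence: int | None = None
    activity_comment: str | None = None
    label: str = "unknown"
    record_date: str | None = None
    source: str = "chembl-like"

    def __post_init__(self):
        if self.confidence is not None and not 0 <= self.confidence <= 9:
            raise ValueError(f"confidence {self.confidence} outside [0, 9]")


@dataclass(frozen=True)
class CompoundRecord:
    """A standardized structure with the properties the filters need."""

    compound_id: str
    smiles: str
    molecular_weight: float
    element_set: frozenset[int]


def to_pchembl(value: float, units: str) -> float:
    """Convert an affinity magnitude with its unit to the pChEMBL scale.

    pChEMBL is −log10 of the molar value, so (10, 'uM') → 5.0 and
    (1, 'nM') → 9.0.

    Raises
    ------
    UnitError
        If the unit is not convertible to molar.
    ValueError
        If the value is not strictly positive.
    """
    if units not in _UNIT_TO_MOLAR:
        raise UnitError(f"unit {units!r} is not convertible to molar")
    if not value > 0:
        raise ValueError(f"affinity must be positive, got {value}")
    return -math.log10(value * _UNIT_TO_MOLAR[units])


def from_pchembl(pchembl: float, units: str = "M") -> float:
    """Inverse of :func:`to_pchembl`: recover the magnitude in ``units``."""
    if units not in _UNIT_TO_MOLAR:
        raise UnitError(f"unit {units!r} is not convertible to molar")
    return 10.0 ** (-pchembl) / _UNIT_TO_MOLAR[units]


_largest_fragment = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()
_tautomer = rdMolStandardize.TautomerEnumerator()


def standardize_structure(smiles: str) -> tuple[str | None, str | None]:
    """Standardize a SMILES string.

    Keeps the largest fragment (heavy-atom count, ties by canonical
    string order), neutralizes charges where valence allows, strips
    explicit hydrogens and picks a canonical tautomer.

    Returns
    -------
    (standardized_smiles, None) on success, (None, reason) on rejection.
    Idempotent: re-standardizing the output returns it unchanged.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None, f"unparseable SMILES: {smiles!r}"
    try:
        mol = _largest_fragment.choose(mol)
        mol = _uncharger.uncharge(mol)
        mol = Chem.RemoveHs(mol)
        mol = _tautomer.Canonicalize(mol)
    except Exception as exc:  # pragma: no cover - rdkit internal failures
        return None, f"standardization failed: {exc}"
    if mol is None or mol.GetNumAtoms() == 0:
        return None, "standardization produced an empty molecule"
    return Chem.MolToSmiles(mol), None


def compound_record(compound_id: str, standardized_smiles: str) -> CompoundRecord:
    """Build a :class:`CompoundRecord` from an already-standardized SMILES."""
    mol = Chem.MolFromSmiles(standardized_smiles)
    if mol is None:
        raise ValueError(f"smiles does not parse: {standardized_smiles!r}")
    return CompoundRecord(
        compound_id=compound_id,
        smiles=standardized_smiles,
        molecular_weight=Descriptors.MolWt(mol),
        element_set=frozenset(a.GetAtomicNum() for a in mol.GetAtoms()),
    )


def structure_filter(
    compound: CompoundRecord, config: CurationConfig | None = None
) -> tuple[bool, str | None]:
    """Apply the element and molecular-weight filters.

    Returns ``(True, None)`` on pass, else ``(False, reason)`` where the
    reason names the first failed rule (carbon, then element ranges,
    then weight).
    """
    config = config or CurationConfig()
    if config.require_carbon and 6 not in compound.element_set:
        return False, "no carbon atom"
    for z in sorted(compound.element_set):
        for lo, hi in config.forbidden_z_ranges:
            if z >= lo and (hi is None or z <= hi):
                hi_s = "inf" if hi is None else str(hi)
                return False, f"forbidden element Z={z} in range [{lo}, {hi_s}]"
    if not config.mw_min <= compound.molecular_weight <= config.mw_max:
        return False, (
            f"molecular weight {compound.molecular_weight:.1f} outside "
            f"[{config.mw_min:g}, {config.mw_max:g}]"
        )
    return True, None


def _is_declared_active(comment) -> bool:
    return isinstance(comment, str) and comment.strip().lower() == "active"


def select_actives(
    records: pd.DataFrame, config: CurationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract active records from a curated bioactivity table.

    A record is kept when its assay type is binding or functional, its
    confidence score is strictly greater than the configured minimum,
    and either pChEMBL ≥ the activity cutoff or the activity comment
    declares it active.  Duplicates on (smiles, target, species)
    collapse to the record with the earliest date (missing dates sort
    last; remaining ties break on compound_id for determinism).

    Returns
    -------
    (actives, rejections) — the rejection table carries a ``reason``
    column naming the first failed rule per record.
    """
    config = config or CurationConfig()
    df = records.copy()
    reasons = pd.Series([None] * len(df), index=df.index, dtype=object)

    missing_target = df["target_accession"].isna() | (
        df["target_accession"].astype(str).str.strip() == ""
    )
    reasons[missing_target] = "missing target accession"

    bad_assay = ~df["assay_type"].isin(ELIGIBLE_ASSAY_TYPES)
    reasons[reasons.isna() & bad_assay] = "assay type not binding/functional"

    conf = pd.to_numeric(df["confidence"], errors="coerce")
    low_conf = ~(conf > config.confidence_min_exclusive)
    reasons[reasons.isna() & low_conf] = (
        f"confidence not > {config.confidence_min_exclusive}"
    )

    pchembl = pd.to_numeric(df["pchembl"], errors="coerce")
    declared = df["activity_comment"].map(_is_declared_active)
    inactive = ~((pchembl >= config.pchembl_active_min) | declared)
    reasons[reasons.isna() & inactive] = (
        f"pchembl < {config.pchembl_active_min:g} and not declared active"
    )

    rejections = df[reasons.notna()].copy()
    rejections["reason"] = reasons[reasons.notna()]
    kept = df[reasons.isna()].copy()
    kept["label"] = "active"

    # earliest record per structure/target/species; NaT dates ordered last
    kept["_date"] = pd.to_datetime(kept["record_date"], errors="coerce")
    kept = kept.sort_values(
        ["smiles", "target_accession", "species", "_date", "compound_id"],
        na_position="last",
        kind="mergesort",
    )
    kept = kept.drop_duplicates(
        subset=["smiles", "target_accession", "species"], keep="first"
    )
    kept = kept.drop(columns="_date").reset_index(drop=True)
    logger.info("select_actives: %d in, %d kept, %d rejected", len(df), len(kept), len(rejections))
    return kept, rejections.reset_index(drop=True)


def resolve_conflicting_labels(
    chembl_records: pd.DataFrame, pubchem_records: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Merge curated active and inactive tables, actives winning conflicts.

    When the same (smiles, target) pair is active in the ChEMBL-like
    table and inactive in the PubChem-like table, the manually-curated
    active annotation is retained and the inactive row dropped.

    Returns the merged table and the number of conflicts resolved.
    """
    active_pairs = set(
        zip(chembl_records["smiles"], chembl_records["target_accession"])
    )
    inactive_keys = list(
        zip(pubchem_records["smiles"], pubchem_records["target_accession"])
    )
    conflict_mask = [key in active_pairs for key in inactive_keys]
    n_conflicts = int(sum(conflict_mask))
    kept_inactives = pubchem_records[[not c for c in conflict_mask]]
    merged = pd.concat([chembl_records, kept_inactives], ignore_index=True)
    if n_conflicts:
        logger.info("resolved %d active/inactive conflicts in favour of actives", n_conflicts)
    return merged, n_conflicts


def read_bioactivity_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a bioactivity CSV/TSV with the canonical named columns."""
    df = pd.read_csv(path, sep=sep, dtype={"compound_id": str, "target_accession": str})
    missing = [c for c in ("compound_id", "smiles", "target_accession") if c not in df.columns]
    if missing:
        raise ValueError(f"bioactivity table missing required columns: {missing}")
    for col in BIOACTIVITY_COLUMNS:
        if col not in df.columns:
            df[col] = None
    return df


def write_bioactivity_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    cols = [c for c in BIOACTIVITY_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep=sep, index=False, columns=cols)


def read_smiles_file(path) -> pd.DataFrame:
    """Read a ``smiles<TAB>id`` file into a two-column frame."""
    # no comment handling: '#' is a SMILES bond symbol
    return pd.read_csv(path, sep="\t", header=None, names=["smiles", "compound_id"],
                       dtype=str)


def curate_structures(
    df: pd.DataFrame, config: CurationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize and structure-filter every unique SMILES in a table.

    Rows whose structure fails standardization or the element/weight
    filters are moved to the rejection table with a reason; surviving
    rows get their ``smiles`` column replaced by the standardized form.
    """
    config = config or CurationConfig()
    results: dict[str, tuple[str | None, str | None]] = {}
    for smi in pd.unique(df["smiles"].astype(str)):
        std, reason = standardize_structure(smi)
        if std is None:
            results[smi] = (None, reason)
            continue
        ok, why = structure_filter(compound_record("", std), config)
        results[smi] = (std, None) if ok else (None, why)

    std_col = df["smiles"].astype(str).map(lambda s: results[s][0])
    reason_col = df["smiles"].astype(str).map(lambda s: results[s][1])
    rejected = df[std_col.isna()].copy()
    rejected["reason"] = reason_col[std_col.isna()]
    kept = df[std_col.notna()].copy()
    kept["smiles"] = std_col[std_col.notna()]
    logger.info("curate_structures: %d in, %d kept, %d rejected", len(df), len(kept), len(rejected))
    return kept.reset_index(drop=True), rejected.reset_index(drop=True)
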