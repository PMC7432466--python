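"""Curation of raw bioactivity tables into per-target pKi datasets.

Raw activity exports (one row per assay measurement, in the schema of a
ChEMBL activity download) are reduced to a deduplicated set of curated
compounds in seven audited steps:

1. acquisition (row count of the input table),
2. removal of records whose structure is absent or cannot be standardized
   (metal complexes, polymers, unparseable SMILES),
3. removal of records with a low target-assignment confidence score,
4. removal of records from small assays (document groups below a minimum
   size),
5. restriction to Ki-family standard types with exact ("=") relations,
   followed by conversion to pKi,
6. merging of duplicate measurements per InChIKey when their spread is
   small relative to the dataset range (inconsistent groups are dropped),
7. removal of compounds whose feature vectors are indistinguishable.

Each step appends its surviving record count to a :class:`CurationReport`,
so counts are monotonically non-increasing and fully auditable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

TARGETS = ("CB1", "CB2")

#: Standard-type labels accepted as "Ki-family" (matched case-insensitively).
DEFAULT_KI_TYPES = frozenset({"ki", "pki", "logki", "log ki"})

#: Unit label -> multiplier to molar concentration.
_UNIT_TO_MOLAR = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "μm": 1e-6,
    "nm": 1e-9,
    "pm": 1e-12,
}

#: Default column names of a ChEMBL-style activity export.
DEFAULT_COLUMNS = {
    "smiles": "canonical_smiles",
    "standard_type": "standard_type",
    "standard_value": "standard_value",
    "standard_units": "standard_units",
    "standard_relation": "standard_relation",
    "document_id": "document_chembl_id",
    "confidence_score": "confidence_score",
}

_METALS = frozenset(
    list(range(3, 5)) + list(range(11, 14)) + list(range(19, 33))
    + list(range(37, 52)) + list(range(55, 85)) + list(range(87, 104))
)


class SchemaError(ValueError):
    """The input table is missing a required column."""


class StandardizationError(ValueError):
    """A structure could not be standardized; ``reason`` is a short code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


class ConversionError(ValueError):
    """An activity value could not be converted to pKi."""


@dataclass(frozen=True)
class ActivityRecord:
    """One raw assay measurement for one target."""

    smiles: str | None
    standard_type: str
    standard_value: float | None
    standard_units: str | None
    standard_relation: str
    document_id: str
    confidence_score: int
    target: str

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if not (0 <= self.confidence_score <= 9):
            raise ValueError("confidence_score must be in [0, 9]")
        if self.standard_value is not None and self.standard_value < 0:
            raise ValueError("standard_value must be non-negative")


@dataclass(frozen=True)
class CuratedCompound:
    """A standardized structure with a consensus pKi for one target."""

    inchikey: str
    smiles: str
    pki: float
    target: str
    n_merged: int = 1

    def __post_init__(self):
        if not math.isfinite(self.pki):
            raise ValueError("pki must be finite")
        if self.n_merged < 1:
            raise ValueError("n_merged must be >= 1")


@dataclass
class CurationReport:
    """Per-step audit trail of record counts (non-increasing)."""

    target: str = ""
    steps: list[tuple[str, int]] = field(default_factory=list)
    row_errors: list[str] = field(default_factory=list)
    dropped_inconsistent_groups: list[str] = field(default_factory=list)
    dropped_feature_duplicates: list[str] = field(default_factory=list)
    removal_reasons: dict[str, int] = field(default_factory=dict)

    def add_step(self, name: str, count: int) -> None:
        if self.steps and count > self.steps[-1][1]:
            raise ValueError(
                f"step {name!r} count {count} exceeds previous {self.steps[-1]}"
            )
        self.steps.append((name, count))

    def count_at(self, name: str) -> int:
        for step, count in self.steps:
            if step == name:
                return count
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "steps": [{"step": s, "records": c} for s, c in self.steps],
            "row_errors": list(self.row_errors),
            "dropped_inconsistent_groups": list(self.dropped_inconsistent_groups),
            "dropped_feature_duplicates": list(self.dropped_feature_duplicates),
            "removal_reasons": dict(self.removal_reasons),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def load_activity_table(
    path: str | Path,
    target: str,
    columns: Mapping[str, str] | None = None,
    report: CurationReport | None = None,
) -> list[ActivityRecord]:
    """Read a CSV activity export into :class:`ActivityRecord` objects.

    Missing structure cells are preserved as ``None`` (filtered later, not
    here). Rows with unparseable numeric fields are skipped and logged on
    the report as row-level errors.

    Raises
    ------
    SchemaError
        If a required column is absent, naming the column.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for key, name in cols.items():
        if name not in df.columns:
            raise SchemaError(f"missing required column {name!r} (for {key})")
    records: list[ActivityRecord] = []
    for i, row in df.iterrows():
        smiles = row[cols["smiles"]].strip() or None
        raw_value = row[cols["standard_value"]].strip()
        try:
            value = float(raw_value) if raw_value else None
            conf = int(float(row[cols["confidence_score"]]))
            records.append(
                ActivityRecord(
                    smiles=smiles,
                    standard_type=row[cols["standard_type"]].strip(),
                    standard_value=value,
                    standard_units=row[cols["standard_units"]].strip() or None,
                    standard_relation=row[cols["standard_relation"]].strip() or "=",
                    document_id=row[cols["document_id"]].strip(),
                    confidence_score=conf,
                    target=target,
                )
            )
        except (ValueError, TypeError) as exc:
            if report is not None:
                report.row_errors.append(f"row {i}: {exc}")
    return records


def standardize_structure(smiles: str | None) -> tuple[Chem.Mol, str]:
    """Standardize a SMILES string to a parent structure and its InChIKey.

    Salts are stripped to the largest organic fragment, charges are
    neutralized and 2D coordinates generated.  Two encodings of the same
    molecule yield identical InChIKeys.

    Raises
    ------
    StandardizationError
        With reason code ``no_structure``, ``unparseable``, ``polymer``,
        ``metal_complex`` or ``not_organic``.
    """
    if smiles is None or not smiles.strip():
        raise StandardizationError("no_structure")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError("unparseable", smiles)
    if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        raise StandardizationError("polymer", smiles)
    had_metal = any(a.GetAtomicNum() in _METALS for a in mol.GetAtoms())
    try:
        mol = rdMolStandardize.FragmentParent(mol)
        mol = rdMolStandardize.Uncharger().uncharge(mol)
    except Exception as exc:  # rdkit raises bare Exceptions here
        raise StandardizationError("unparseable", str(exc)) from exc
    if any(a.GetAtomicNum() in _METALS for a in mol.GetAtoms()):
        raise StandardizationError("metal_complex", smiles)
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        # counter-ions of a metal complex survive parent selection with no
        # carbon left; report the underlying cause
        reason = "metal_complex" if had_metal else "not_organic"
        raise StandardizationError(reason, smiles)
    inchikey = Chem.MolToInchiKey(mol)
    if not inchikey:
        raise StandardizationError("unparseable", smiles)
    AllChem.Compute2DCoords(mol)
    return mol, inchikey


def to_pki(value: float, unit: str | None, standard_type: str) -> float:
    """Convert an activity value to pKi (−log10 of molar Ki).

    ``Ki``-type values require a recognized concentration unit (pM, nM,
    µM, mM, M); ``pKi`` passes through unchanged; ``logKi`` (log10 of a
    molar Ki) is negated.
    """
    stype = standard_type.strip().lower()
    if stype == "pki":
        return float(value)
    if stype in ("logki", "log ki"):
        return -float(value)
    if stype == "ki":
        if value <= 0:
            raise ConversionError(f"Ki value must be positive, got {value}")
        if unit is None or unit.strip().lower() not in _UNIT_TO_MOLAR:
            raise ConversionError(f"unrecognized unit {unit!r}")
        molar = value * _UNIT_TO_MOLAR[unit.strip().lower()]
        return -math.log10(molar)
    raise ConversionError(f"standard type {standard_type!r} is not Ki-family")


def filter_records(
    records: Sequence[ActivityRecord],
    min_confidence: int = 8,
    min_assay_size: int = 10,
    ki_types: frozenset[str] = DEFAULT_KI_TYPES,
    require_exact_relation: bool = True,
    report: CurationReport | None = None,
) -> list[ActivityRecord]:
    """Apply curation steps 2-5 in fixed order, appending counts to *report*.

    Order matters: the assay-size filter counts a document's records after
    the structure and confidence filters have run.  Non-exact relations
    (">", "<", ...) are dropped with the standard-type filter because
    censored values bias regression.
    """
    if not (0 <= min_confidence <= 9):
        raise ValueError("min_confidence must be in [0, 9]")
    if min_assay_size < 1:
        raise ValueError("min_assay_size must be >= 1")
    rep = report if report is not None else CurationReport()
    rep.add_step("acquisition", len(records))
    ki_types = frozenset(t.lower() for t in ki_types)

    kept = []
    for rec in records:
        try:
            standardize_structure(rec.smiles)
            kept.append(rec)
        except StandardizationError as exc:
            rep.removal_reasons[exc.reason] = rep.removal_reasons.get(exc.reason, 0) + 1
    rep.add_step("structure", len(kept))

    kept = [r for r in kept if r.confidence_score >= min_confidence]
    rep.add_step("confidence", len(kept))

    doc_sizes: dict[str, int] = {}
    for rec in kept:
        doc_sizes[rec.document_id] = doc_sizes.get(rec.document_id, 0) + 1
    kept = [r for r in kept if doc_sizes[r.document_id] >= min_assay_size]
    rep.add_step("assay_size", len(kept))

    kept = [
        r
        for r in kept
        if r.standard_type.lower() in ki_types
        and r.standard_value is not None
        and (not require_exact_relation or r.standard_relation == "=")
    ]
    rep.add_step("ki_type", len(kept))
    return kept


def merge_duplicates(
    df: pd.DataFrame,
    sd_fraction: float = 0.10,
    report: CurationReport | None = None,
) -> pd.DataFrame:
    """Collapse duplicate InChIKeys to consensus compounds.

    *df* must have columns ``inchikey``, ``smiles`` and ``pki``.  A group
    sharing an InChIKey is merged to its mean pKi when the group's
    population standard deviation is below ``sd_fraction`` times the
    dataset-wide pKi range; groups failing the rule are dropped entirely
    (inconsistent measurements are unreliable) and logged.  Singletons
    pass through with ``n_merged == 1``.
    """
    if df.empty:
        raise ValueError("dataset is empty")
    if not np.isfinite(df["pki"]).all():
        raise ValueError("all pki values must be finite")
    span = float(df["pki"].max() - df["pki"].min())
    tol = sd_fraction * span
    rows = []
    for key, grp in df.groupby("inchikey", sort=False):
        if len(grp) == 1:
            rows.append((key, grp["smiles"].iloc[0], float(grp["pki"].iloc[0]), 1))
            continue
        sd = float(np.std(grp["pki"].to_numpy(), ddof=0))
        if sd < tol:
            rows.append((key, grp["smiles"].iloc[0], float(grp["pki"].mean()), len(grp)))
        elif report is not None:
            report.dropped_inconsistent_groups.append(key)
    out = pd.DataFrame(rows, columns=["inchikey", "smiles", "pki", "n_merged"])
    if report is not None:
        report.add_step("duplicates", len(out))
    return out


def drop_feature_duplicates(
    df: pd.DataFrame,
    features: Mapping[str, np.ndarray],
    report: CurationReport | None = None,
) -> pd.DataFrame:
    """Remove all compounds whose feature vectors are bitwise identical.

    Compounds that the feature representation cannot tell apart (e.g.
    enantiomers under achiral descriptors and fingerprints) may carry
    different activities, so every member of an identical-vector group is
    removed rather than keeping an arbitrary representative.
    """
    missing = [k for k in df["inchikey"] if k not in features]
    if missing:
        raise KeyError(f"no feature vector for compound(s): {missing[:3]}")
    hashes = df["inchikey"].map(lambda k: np.asarray(features[k]).tobytes())
    counts = hashes.value_counts()
    mask = hashes.map(counts) == 1
    if report is not None:
        report.dropped_feature_duplicates.extend(df.loc[~mask, "inchikey"])
        report.add_step("feature_duplicates", int(mask.sum()))
    return df.loc[mask].reset_index(drop=True)


def curate(
    records: Sequence[ActivityRecord],
    target: str,
    min_confidence: int = 8,
    min_assay_size: int = 10,
    ki_types: frozenset[str] = DEFAULT_KI_TYPES,
    sd_fraction: float = 0.10,
    featurizer=None,
) -> tuple[pd.DataFrame, CurationReport]:
    """Run the full seven-step curation pipeline for one target.

    Parameters
    ----------
    featurizer
        Callable mapping a list of RDKit mols to a 2D feature matrix
        (rows aligned with the input), used for the final
        feature-duplicate step.  Defaults to the standard descriptor +
        fingerprint featurization of :mod:`cb2screen.features`.

    Returns
    -------
    (DataFrame, CurationReport)
        Curated dataset with columns ``inchikey, smiles, pki, n_merged,
        target`` and the per-step audit report.
    """
    report = CurationReport(target=target)
    kept = filter_records(
        records,
        min_confidence=min_confidence,
        min_assay_size=min_assay_size,
        ki_types=ki_types,
        report=report,
    )
    rows = []
    for rec in kept:
        mol, key = standardize_structure(rec.smiles)
        try:
            pki = to_pki(rec.standard_value, rec.standard_units, rec.standard_type)
        except ConversionError as exc:
            report.row_errors.append(f"{key}: {exc}")
            continue
        rows.append((key, Chem.MolToSmiles(mol), pki))
    df = pd.DataFrame(rows, columns=["inchikey", "smiles", "pki"])
    if df.empty:
        report.add_step("duplicates", 0)
        report.add_step("feature_duplicates", 0)
        df["n_merged"] = []
        df["target"] = []
        return df, report
    df = merge_duplicates(df, sd_fraction=sd_fraction, report=report)

    if featurizer is None:
        from .features import featurize_for_duplicates as featurizer  # noqa: PLC0415
    mols = [Chem.MolFromSmiles(s) for s in df["smiles"]]
    matrix = np.asarray(featurizer(mols))
    features = {k: matrix[i] for i, k in enumerate(df["inchikey"])}
    df = drop_feature_duplicates(df, features, report=report)
    df = df.assign(target=target)
    return df, report
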