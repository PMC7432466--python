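"""Molecular featurization: descriptors, Morgan fingerprints, Tanimoto.

A compound is represented by the concatenation of

* a block of 2D molecular descriptors (RDKit's full standard set) and,
  optionally, 3D conformer-derived shape descriptors (a single ETKDG
  conformer embedded with a fixed random seed, so values are
  deterministic), and
* a 1024-bit Morgan (circular) fingerprint of radius 3.

Descriptor columns are filtered on the *training* matrix only: columns
with population variance below a cutoff or containing any non-finite
value are removed, and the surviving column list is frozen in a
:class:`FeatureSpace` so screening-time compounds are projected onto the
identical feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, Descriptors3D, rdFingerprintGenerator

DEFAULT_N_BITS = 1024
DEFAULT_RADIUS = 3
DEFAULT_CONFORMER_SEED = 1905
DEFAULT_MIN_VARIANCE = 0.05

def _probe_3d_names() -> list[str]:
    m = Chem.AddHs(Chem.MolFromSmiles("C"))
    AllChem.EmbedMolecule(m, randomSeed=7)
    return list(Descriptors3D.CalcMolDescriptors3D(m))


_3D_NAMES = _probe_3d_names()


def _fp_generator(n_bits: int = DEFAULT_N_BITS, radius: int = DEFAULT_RADIUS):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def compute_descriptors(
    mol: Chem.Mol,
    include_3d: bool = True,
    conformer_seed: int = DEFAULT_CONFORMER_SEED,
) -> pd.Series:
    """Compute the named descriptor vector of one standardized structure.

    3D descriptors require an embedded conformer, generated internally
    with ETKDG at a fixed ``conformer_seed`` so repeated calls are
    bitwise identical.  Individual descriptor failures — including a
    failed conformer embedding — yield NaN markers which are filtered at
    matrix level, never silently imputed.
    """
    values = Descriptors.CalcMolDescriptors(mol)
    out = {k: _as_float(v) for k, v in values.items()}
    if include_3d:
        d3 = dict.fromkeys(_3D_NAMES, float("nan"))
        molh = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = conformer_seed
        if AllChem.EmbedMolecule(molh, params) == 0:
            try:
                d3.update(Descriptors3D.CalcMolDescriptors3D(molh))
            except Exception:
                pass
        out.update({k: _as_float(v) for k, v in d3.items()})
    return pd.Series(out, dtype=float)


def _as_float(v) -> float:
    try:
        f = float(v)
    except (TypeError, ValueError, OverflowError):
        return float("nan")
    return f


def descriptor_matrix(
    mols,
    include_3d: bool = True,
    conformer_seed: int = DEFAULT_CONFORMER_SEED,
) -> pd.DataFrame:
    """Descriptor vectors for a list of molecules, one row per molecule."""
    rows = [compute_descriptors(m, include_3d, conformer_seed) for m in mols]
    return pd.DataFrame(rows).reset_index(drop=True)


def filter_descriptor_matrix(
    matrix: pd.DataFrame, min_variance: float = DEFAULT_MIN_VARIANCE
) -> tuple[pd.DataFrame, list[str]]:
    """Drop low-information descriptor columns from a training matrix.

    A column is removed if it contains any non-finite entry or its
    population variance (ddof=0) is below ``min_variance``.  Returns the
    reduced matrix and the ordered list of retained column names (the
    frozen mask applied to all later inputs).
    """
    if matrix.empty:
        raise ValueError("descriptor matrix is empty")
    finite = np.isfinite(matrix.to_numpy()).all(axis=0)
    variance = np.nan_to_num(matrix.to_numpy().var(axis=0, ddof=0), nan=0.0)
    keep = finite & (variance >= min_variance)
    names = [c for c, k in zip(matrix.columns, keep) if k]
    if not names:
        raise ValueError("all descriptor columns were removed (degenerate dataset)")
    return matrix.loc[:, names], names


def compute_fingerprint(
    mol: Chem.Mol, n_bits: int = DEFAULT_N_BITS, radius: int = DEFAULT_RADIUS
) -> np.ndarray:
    """Morgan (circular) bit fingerprint as a uint8 vector of length *n_bits*."""
    return _fp_generator(n_bits, radius).GetFingerprintAsNumPy(mol).astype(np.uint8)


def fingerprint_matrix(
    mols, n_bits: int = DEFAULT_N_BITS, radius: int = DEFAULT_RADIUS
) -> np.ndarray:
    gen = _fp_generator(n_bits, radius)
    return np.stack([gen.GetFingerprintAsNumPy(m).astype(np.uint8) for m in mols])


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two equal-length bit vectors.

    Two all-zero vectors are defined as identical (coefficient 1.0).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def bulk_tanimoto(query: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Tanimoto of one fingerprint against each row of a fingerprint matrix."""
    q = np.asarray(query, dtype=bool)
    m = np.asarray(matrix, dtype=bool)
    inter = np.logical_and(m, q).sum(axis=1)
    union = np.logical_or(m, q).sum(axis=1)
    out = np.ones(len(m), dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def featurize_for_duplicates(mols) -> np.ndarray:
    """Stereochemistry-blind feature block used for duplicate detection.

    Exact (bitwise) comparability is what the duplicate-removal curation
    step needs, so this uses the 2D descriptor block plus the achiral
    Morgan fingerprint and skips conformer-derived 3D values, whose
    numeric jitter would make no two structures ever collide.
    """
    desc = descriptor_matrix(mols, include_3d=False).to_numpy()
    fps = fingerprint_matrix(mols)
    return np.hstack([desc, fps.astype(float)])


@dataclass
class FeatureSpace:
    """Frozen featurization learned on a training set.

    Holds the descriptor column mask, fingerprint geometry and conformer
    seed; :meth:`transform` projects any later molecules onto exactly
    this feature space (feature lock), so screening-time vectors align
    column-for-column with training vectors.
    """

    descriptor_names: list[str]
    include_3d: bool = True
    conformer_seed: int = DEFAULT_CONFORMER_SEED
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS
    min_variance: float = DEFAULT_MIN_VARIANCE

    @property
    def feature_names(self) -> list[str]:
        return list(self.descriptor_names) + [
            f"fp_{i}" for i in range(self.n_bits)
        ]

    @classmethod
    def fit(
        cls,
        mols,
        include_3d: bool = True,
        conformer_seed: int = DEFAULT_CONFORMER_SEED,
        n_bits: int = DEFAULT_N_BITS,
        radius: int = DEFAULT_RADIUS,
        min_variance: float = DEFAULT_MIN_VARIANCE,
    ) -> tuple["FeatureSpace", np.ndarray]:
        """Learn the variance mask on training molecules; return (space, X)."""
        desc = descriptor_matrix(mols, include_3d, conformer_seed)
        reduced, names = filter_descriptor_matrix(desc, min_variance)
        space = cls(names, include_3d, conformer_seed, n_bits, radius, min_variance)
        fps = fingerprint_matrix(mols, n_bits, radius)
        return space, np.hstack([reduced.to_numpy(float), fps.astype(float)])

    def fit_from_matrix(
        self, desc: pd.DataFrame, fps: np.ndarray
    ) -> np.ndarray:
        """Assemble X from precomputed blocks using this frozen mask."""
        return np.hstack(
            [desc.loc[:, self.descriptor_names].to_numpy(float), fps.astype(float)]
        )

    def transform(self, mols) -> np.ndarray:
        """Project molecules onto the frozen training feature space."""
        desc = descriptor_matrix(mols, self.include_3d, self.conformer_seed)
        missing = [n for n in self.descriptor_names if n not in desc.columns]
        if missing:
            raise ValueError(f"descriptor(s) unavailable at transform: {missing[:3]}")
        block = desc.loc[:, self.descriptor_names].to_numpy(float)
        fps = fingerprint_matrix(mols, self.n_bits, self.radius)
        return np.hstack([block, fps.astype(float)])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "descriptor_names": self.descriptor_names,
                    "include_3d": self.include_3d,
                    "conformer_seed": self.conformer_seed,
                    "n_bits": self.n_bits,
                    "radius": self.radius,
                    "min_variance": self.min_variance,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSpace":
        return cls(**json.loads(Path(path).read_text()))
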