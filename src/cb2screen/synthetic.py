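"""Synthetic bioactivity data with known ground truth.

Generates everything the pipeline consumes, without any downloads:

* diverse, standardizable SMILES from a combinatorial scaffold +
  substituent grammar (substituted aromatics, chromene-like cores,
  indoles, biphenyls) spanning roughly 150-600 Da, with a configurable
  fraction of deliberately broken entries;
* true CB1/CB2 pKi surfaces that are linear functions of computed
  physicochemical descriptors (so a QSAR model can genuinely learn
  them), with a configurable CB1-CB2 correlation, clamped to [4, 10];
* ChEMBL-schema activity tables with per-document grouping, mixed
  confidence scores, replicate measurements with Gaussian noise,
  non-Ki standard types and missing structures — every curation filter
  has planted prey, and the plants are bookkept exactly in a
  :class:`PlantManifest`;
* docking-score lists whose active/decoy separation is solved from a
  binormal model to hit a target ROC AUC in expectation.

Each planted violation is mutually exclusive with the others, so the
expected per-step curation counts can be predicted in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from scipy.stats import norm

# deliberately broken SMILES are part of the generator's contract
RDLogger.DisableLog("rdApp.error")

# -- structure grammar -------------------------------------------------------

SCAFFOLDS = (
    "c1cc({0})cc({1})c1{2}",           # trisubstituted benzene
    "c1ccc2cc({0})cc({1})c2c1",        # naphthalene
    "O=C({0})c1ccc({1})cc1{2}",        # aryl carbonyl
    "CC1(C)C=Cc2c(O1)cc({0})cc2{1}",   # 2H-chromene (cannabinoid-like core)
    "c1cc2c(cc1{0})[nH]c(c2)C{1}",     # indole
    "O=c1cc({0})oc2cc({1})ccc12",      # chromone
    "C1CCC(CC1)({0})c1ccc({1})cc1",    # cyclohexyl-phenyl
    "c1ccc(-c2ccc({0})cc2{1})cc1",     # biphenyl
    "c1cc({0})cc({1})c1-c2ccc({2})cc2",  # trisubstituted biphenyl
)

SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "CCCCC", "CCCCCCCC", "CCCCCCCCCCCC",
    "O", "OC", "OCC", "OCCCCCCCC", "Cl", "F", "Br",
    "C(=O)O", "C(=O)OC", "C(=O)N", "C(=O)NCCCCCCCC",
    "N", "N(C)C", "CCN(CC)CC", "C#N", "C(F)(F)F",
    "c2ccccc2", "Cc2ccccc2", "c2ccc(CCCCCC)cc2",
    "OCCO", "CC=C(C)C", "CCC=C(C)C", "S(=O)(=O)N", "OC(=O)C",
    "OCCCCCCCCCCCCCCCC", "C(=O)NCCCCCCCCCCCCCCCC", "N(CCCCCCCC)CCCCCCCC",
)

_INVALID_SMILES = ("C1CC(", "X[Zz]Q", "c1ccccc1(((", "C(C)(C)(C)(C)C")

#: Enantiomer pairs: distinct InChIKeys, identical 2D descriptors and
#: (achiral) Morgan fingerprints — prey for the feature-duplicate filter.
ENANTIOMER_PAIRS = (
    ("C[C@H](O)c1ccc(CCC)cc1", "C[C@@H](O)c1ccc(CCC)cc1"),
    ("CC[C@H](N)c1cccc(OC)c1", "CC[C@@H](N)c1cccc(OC)c1"),
    ("C[C@H](C(=O)O)c1ccc2ccccc2c1", "C[C@@H](C(=O)O)c1ccc2ccccc2c1"),
    ("CCCCC[C@H](O)c1ccc(F)cc1", "CCCCC[C@@H](O)c1ccc(F)cc1"),
)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``noise_sd`` is in pKi units; ``signal_sd`` scales the
    structure-driven part of the activity surface; the CB1/CB2 surfaces
    share a latent component sized so their correlation is
    ``cb1_cb2_correlation``.
    """

    n_compounds: int = 300
    n_documents: int = 12
    duplicate_rate: float = 0.15
    noise_sd: float = 0.2
    signal_sd: float = 1.2
    ruggedness: float = 0.8
    confidence_score_mix: dict = field(
        default_factory=lambda: {9: 0.6, 8: 0.25, 7: 0.15}
    )
    fraction_invalid_structures: float = 0.03
    fraction_non_ki_types: float = 0.10
    cb1_cb2_correlation: float = 0.7
    seed: int = 0

    def __post_init__(self):
        for name in (
            "duplicate_rate",
            "fraction_invalid_structures",
            "fraction_non_ki_types",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.cb1_cb2_correlation <= 1:
            raise ValueError("cb1_cb2_correlation must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_structures(
    n: int, seed: int, fraction_invalid: float = 0.0
) -> list[str]:
    """Deterministic list of *n* SMILES from the scaffold grammar.

    A ``fraction_invalid`` share of entries (rounded down) is replaced
    by deliberately unparseable strings at seeded positions, exercising
    the structure-removal curation step.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        scaffold = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
        n_sites = scaffold.count("{")
        subs = [SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))] for _ in range(n_sites)]
        smi = scaffold.format(*subs)
        if Chem.MolFromSmiles(smi) is not None:  # grammar is safe; belt and braces
            out.append(smi)
    n_bad = int(fraction_invalid * n)
    if n_bad:
        positions = rng.choice(n, size=n_bad, replace=False)
        for j, pos in enumerate(positions):
            out[pos] = _INVALID_SMILES[j % len(_INVALID_SMILES)]
    return out


_ACTIVITY_DESCRIPTORS = (
    "MolLogP", "TPSA", "MolWt", "NumRotatableBonds", "NumHDonors",
    "NumHAcceptors", "RingCount", "FractionCSP3", "HeavyAtomCount", "MolMR",
)


def _descriptor_block(mols) -> np.ndarray:
    funcs = dict(Descriptors.descList)
    return np.array(
        [[funcs[d](m) for d in _ACTIVITY_DESCRIPTORS] for m in mols], dtype=float
    )


def assign_true_pki(
    smiles: list[str], config: SyntheticConfig
) -> tuple[np.ndarray, np.ndarray]:
    """True (pKi_CB1, pKi_CB2) per structure, NaN for invalid entries.

    Each surface is a smooth part plus a rugged part:

        pKi_t = 7 + signal_sd · (√ρ·s + √(1−ρ)·u_t)
                  + ruggedness · sin(2s)·cos(2v),

    where s, u₁, u₂, v are orthonormalized random projections of the
    standardized physicochemical descriptor block (the latent weights).
    The smooth part fixes the in-sample CB1-CB2 correlation at ρ before
    clamping to [4, 10]; the bounded high-frequency term emulates the
    activity cliffs of real structure-activity landscapes — compounds in
    sparse regions of descriptor space are genuinely harder to predict,
    which is what gives the applicability-domain threshold its
    characteristic declining Q² curve.  Both parts are deterministic
    functions of computed descriptors, so the QSAR model can learn them.
    """
    mols = [Chem.MolFromSmiles(s) for s in smiles]
    valid = np.array([m is not None for m in mols])
    if valid.sum() < 5:
        raise ValueError("need at least 5 valid structures")
    rng = np.random.default_rng(config.seed + 7)
    Z = _descriptor_block([m for m, v in zip(mols, valid) if v])
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) == 0, 1, Z.std(axis=0))
    W = rng.normal(size=(Z.shape[1], 4))  # latent weights
    scores = Z @ W
    q, _ = np.linalg.qr(scores - scores.mean(axis=0))
    q *= np.sqrt(len(q))  # unit-variance orthogonal scores s, u1, u2, v
    rho = config.cb1_cb2_correlation
    a, b = np.sqrt(rho), np.sqrt(1 - rho)
    cliffs = config.ruggedness * np.sin(2 * q[:, 0]) * np.cos(2 * q[:, 3])
    y1 = 7 + config.signal_sd * (a * q[:, 0] + b * q[:, 1]) + cliffs
    y2 = 7 + config.signal_sd * (a * q[:, 0] + b * q[:, 2]) + cliffs
    pki_cb1 = np.full(len(smiles), np.nan)
    pki_cb2 = np.full(len(smiles), np.nan)
    pki_cb1[valid] = np.clip(y1, 4, 10)
    pki_cb2[valid] = np.clip(y2, 4, 10)
    return pki_cb1, pki_cb2


@dataclass
class PlantManifest:
    """Exact bookkeeping of planted curation violations.

    Counts refer to *records* (rows), not compounds, except where noted.
    The expected post-step record counts follow in closed form because
    each planted row violates exactly one rule.
    """

    n_total: int = 0
    n_missing_structure: int = 0
    n_invalid_structure: int = 0
    n_low_confidence: int = 0
    n_small_assay: int = 0
    n_non_ki: int = 0
    n_inconsistent_dup_groups: int = 0  # groups of 2 records each
    n_consistent_dup_records: int = 0   # extra replicate rows that merge away
    n_feature_dup_compounds: int = 0    # enantiomer-pair members (compounds)
    n_base_compounds: int = 0

    def expected_step_counts(self) -> dict[str, int]:
        after_structure = self.n_total - self.n_missing_structure - self.n_invalid_structure
        after_confidence = after_structure - self.n_low_confidence
        after_assay = after_confidence - self.n_small_assay
        after_ki = after_assay - self.n_non_ki
        after_dup = (
            after_ki
            - 2 * self.n_inconsistent_dup_groups
            - self.n_consistent_dup_records
        )
        after_feature = after_dup - self.n_feature_dup_compounds
        return {
            "acquisition": self.n_total,
            "structure": after_structure,
            "confidence": after_confidence,
            "assay_size": after_assay,
            "ki_type": after_ki,
            "duplicates": after_dup,
            "feature_duplicates": after_feature,
        }


def generate_activity_table(
    smiles: list[str],
    true_pki: np.ndarray,
    config: SyntheticConfig,
    target: str = "CB1",
) -> tuple[pd.DataFrame, PlantManifest]:
    """ChEMBL-schema activity table with exactly bookkept violations.

    The clean base assigns every valid structure one Ki record (nM,
    back-converted from the noisy true pKi) in a large document.  On top
    of that, mutually exclusive corruptions are planted as *extra* rows:
    missing/invalid structures, low confidence scores, small-assay
    documents, non-Ki standard types, consistent replicates (mergeable)
    and inconsistent duplicate pairs (dropped by the SD rule).
    Enantiomer feature-duplicate pairs are appended as clean records.
    """
    rng = np.random.default_rng(config.seed + 13)
    manifest = PlantManifest()
    rows: list[dict] = []

    def ki_nm(pki: float) -> float:
        return 10 ** (9 - pki)

    def add_row(smi, pki_observed, doc, conf=9, stype="Ki", relation="="):
        rows.append(
            {
                "canonical_smiles": smi,
                "standard_type": stype,
                "standard_value": round(ki_nm(pki_observed), 6),
                "standard_units": "nM",
                "standard_relation": relation,
                "document_chembl_id": doc,
                "confidence_score": conf,
                "target": target,
            }
        )

    # unique, valid base compounds (grammar can repeat a structure; exact
    # bookkeeping needs one base record per InChIKey)
    valid_idx, invalid_idx, seen_keys = [], [], set()
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            invalid_idx.append(i)
            continue
        key = Chem.MolToInchiKey(mol)
        if key not in seen_keys:
            seen_keys.add(key)
            valid_idx.append(i)
    manifest.n_base_compounds = len(valid_idx)

    # documents sized deterministically (round-robin) and large enough to
    # survive the assay-size filter
    n_docs = max(1, min(config.n_documents, len(valid_idx) // 12))
    doc_ids = [f"DOC{d:03d}" for d in range(n_docs)]
    base_value: dict[int, float] = {}
    for j, i in enumerate(valid_idx):
        conf = 9 if rng.random() < 0.7 else 8
        base_value[i] = true_pki[i] + rng.normal(0, config.noise_sd)
        add_row(smiles[i], base_value[i], doc_ids[j % n_docs], conf=conf)

    # consistent replicates: small within-compound spread, always mergeable
    n_rep = int(config.duplicate_rate * len(valid_idx))
    rep_idx = rng.choice(valid_idx, size=n_rep, replace=False) if n_rep else []
    for i in rep_idx:
        jitter = rng.normal(0, config.noise_sd / 10)
        add_row(smiles[i], base_value[i] + jitter, doc_ids[int(rng.integers(n_docs))])
    manifest.n_consistent_dup_records = n_rep

    # invalid / missing structures (extra rows, removed at the structure step)
    for i in invalid_idx:
        add_row(smiles[i], 7.0, doc_ids[0])
    n_missing = 3
    for _ in range(n_missing):
        add_row("", 7.0, doc_ids[0])
    manifest.n_invalid_structure = len(invalid_idx)
    manifest.n_missing_structure = n_missing

    # low-confidence plants: salt forms of known-good structures, so even
    # standardization-identical records never survive to later steps
    low_share = sum(v for k, v in config.confidence_score_mix.items() if k < 8)
    n_low = int(low_share * 0.3 * len(valid_idx))
    for j in range(n_low):
        i = valid_idx[int(rng.integers(len(valid_idx)))]
        add_row(smiles[i] + ".[Na+]", true_pki[i], doc_ids[0], conf=7)
    manifest.n_low_confidence = n_low

    # small-assay plants: fresh valid structures in undersized documents
    small = [
        s for s in generate_structures(6, config.seed + 101)
        if Chem.MolToInchiKey(Chem.MolFromSmiles(s)) not in seen_keys
    ]
    for j, smi in enumerate(small):
        add_row(smi, 6.5, f"SMALLDOC{j // 3}")
    manifest.n_small_assay = len(small)

    # non-Ki standard types in large documents
    n_nonki = int(config.fraction_non_ki_types * len(valid_idx))
    for j in range(n_nonki):
        i = valid_idx[int(rng.integers(len(valid_idx)))]
        stype = ("IC50", "EC50", "Kd")[j % 3]
        add_row(smiles[i] + ".[K+]", true_pki[i], doc_ids[0], stype=stype)
    manifest.n_non_ki = n_nonki

    # inconsistent duplicate pairs: fresh structures, pKi far apart, so the
    # 10%-of-range SD rule drops the whole group
    incon = [
        s for s in generate_structures(4, config.seed + 202)
        if Chem.MolToInchiKey(Chem.MolFromSmiles(s)) not in seen_keys
    ]
    incon = incon[: 2 * (len(incon) // 2)]
    for j in range(0, len(incon), 2):
        add_row(incon[j], 4.5, doc_ids[0])
        add_row(incon[j], 9.5, doc_ids[0])
    manifest.n_inconsistent_dup_groups = len(incon) // 2

    # enantiomer pairs: survive to the feature-duplicate step, then vanish
    for left, right in ENANTIOMER_PAIRS[:2]:
        add_row(left, 6.0, doc_ids[0])
        add_row(right, 8.5, doc_ids[0])
    manifest.n_feature_dup_compounds = 4

    manifest.n_total = len(rows)
    df = pd.DataFrame(rows)
    return df, manifest


def generate_clean_dataset(
    n: int, seed: int, noise_sd: float = 0.2, target: str = "CB1",
    cb1_cb2_correlation: float = 0.7, signal_sd: float = 1.2,
) -> pd.DataFrame:
    """Curated-format dataset (inchikey, smiles, pki) without corruption.

    Convenience path for model/validation studies that do not exercise
    curation: unique structures, noisy pKi, ready for
    :func:`cb2screen.validation.cross_validate`.
    """
    config = SyntheticConfig(
        n_compounds=n, seed=seed, noise_sd=noise_sd,
        cb1_cb2_correlation=cb1_cb2_correlation, signal_sd=signal_sd,
        fraction_invalid_structures=0.0,
    )
    # over-generate, then deduplicate by InChIKey to exactly n compounds
    # (the grammar occasionally repeats a structure)
    smiles, seen, batch = [], set(), 0
    while len(smiles) < n and batch < 10:
        for smi in generate_structures(n, seed + 1000 * batch):
            key = Chem.MolToInchiKey(Chem.MolFromSmiles(smi))
            if key not in seen:
                seen.add(key)
                smiles.append(smi)
            if len(smiles) == n:
                break
        batch += 1
    pki_cb1, pki_cb2 = assign_true_pki(smiles, config)
    true = pki_cb1 if target == "CB1" else pki_cb2
    rng = np.random.default_rng(seed + 23)
    rows = []
    for smi, pki in zip(smiles, true):
        mol = Chem.MolFromSmiles(smi)
        rows.append(
            (Chem.MolToInchiKey(mol), Chem.MolToSmiles(mol),
             pki + rng.normal(0, noise_sd))
        )
    return pd.DataFrame(
        rows, columns=["inchikey", "smiles", "pki"]
    ).assign(n_merged=1, target=target)


def generate_docking_scores(
    n_actives: int,
    n_decoys: int,
    target_auc: float,
    seed: int,
) -> pd.DataFrame:
    """Docking-score list achieving *target_auc* in expectation.

    Binormal model: decoy scores ~ N(0, 1), active scores ~
    N(−√2·Φ⁻¹(AUC), 1), lower-is-better, so the expected Mann–Whitney
    AUC equals the target.
    """
    if not 0.5 <= target_auc <= 1.0:
        raise ValueError("target_auc must be in [0.5, 1.0]")
    rng = np.random.default_rng(seed)
    sep = np.sqrt(2) * norm.ppf(min(target_auc, 1 - 1e-12))
    active_scores = rng.normal(-sep, 1, n_actives)
    decoy_scores = rng.normal(0, 1, n_decoys)
    return pd.DataFrame(
        {
            "ligand_id": [f"ACT{i:05d}" for i in range(n_actives)]
            + [f"DEC{i:05d}" for i in range(n_decoys)],
            "score": np.concatenate([active_scores, decoy_scores]),
            "label": ["active"] * n_actives + ["decoy"] * n_decoys,
        }
    )


def write_study_inputs(config: SyntheticConfig, out_dir: str | Path) -> dict:
    """Emit activity CSVs, a candidate SMILES file, labels and docking
    scores for one synthetic study; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    smiles = generate_structures(
        config.n_compounds, config.seed, config.fraction_invalid_structures
    )
    pki_cb1, pki_cb2 = assign_true_pki(smiles, config)
    files = {}
    for target, pki in (("CB1", pki_cb1), ("CB2", pki_cb2)):
        table, _ = generate_activity_table(smiles, pki, config, target)
        path = out / f"activity_{target.lower()}.csv"
        table.to_csv(path, index=False)
        files[f"activity_{target.lower()}"] = str(path)
    candidates = generate_structures(60, config.seed + 31)
    cand_path = out / "candidates.smi"
    cand_path.write_text(
        "".join(f"{s}\tCAND{i:04d}\n" for i, s in enumerate(candidates))
    )
    files["candidates"] = str(cand_path)
    docking = generate_docking_scores(50, 950, 0.8, config.seed + 41)
    docking[["ligand_id", "score"]].to_csv(out / "docking_scores.csv", index=False)
    docking[["ligand_id", "label"]].to_csv(out / "docking_labels.csv", index=False)
    files["docking_scores"] = str(out / "docking_scores.csv")
    files["docking_labels"] = str(out / "docking_labels.csv")
    return files
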