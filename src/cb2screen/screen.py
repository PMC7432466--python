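"""CB2-vs-CB1 selectivity screening of candidate compounds.

Candidates are filtered to a drug-like molecular-weight window, predicted
against the trained CB1 and CB2 models at a chosen applicability-domain
level, and scored by

* selectivity: dpKi = pKi(CB2) − pKi(CB1), flagged when dpKi ≥ 1, and
* novelty: the Tanimoto coefficient to the most similar training
  compound (union of both targets' training sets), flagged when < 0.5.

Out-of-domain candidates are reported with diagnostics but without a
selectivity call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .features import bulk_tanimoto, compute_fingerprint
from .model import QsarModel

DEFAULT_MW_LOW = 250.0
DEFAULT_MW_HIGH = 500.0
DEFAULT_DPKI_CUT = 1.0
DEFAULT_TC_CUT = 0.5


@dataclass(frozen=True)
class SelectivityResult:
    """Per-candidate selectivity and novelty assessment."""

    compound_id: str
    smiles: str
    pki_cb1: float | None
    pki_cb2: float | None
    dpki: float | None
    nearest_train_id: str
    nearest_train_tc: float
    selective: bool
    novel: bool

    def __post_init__(self):
        both = self.pki_cb1 is not None and self.pki_cb2 is not None
        if both != (self.dpki is not None):
            raise ValueError("dpki present iff both predictions present")
        if not (0.0 <= self.nearest_train_tc <= 1.0):
            raise ValueError("Tanimoto coefficient out of [0, 1]")


def mw_filter(
    mols, low: float = DEFAULT_MW_LOW, high: float = DEFAULT_MW_HIGH
) -> list[int]:
    """Indices of molecules with low ≤ MW ≤ high (bounds inclusive)."""
    return [
        i for i, m in enumerate(mols) if low <= Descriptors.MolWt(m) <= high
    ]


def screen(
    mols,
    ids,
    model_cb1: QsarModel,
    model_cb2: QsarModel,
    threshold_percentile: float = 100.0,
    dpki_cut: float = DEFAULT_DPKI_CUT,
    tc_cut: float = DEFAULT_TC_CUT,
) -> list[SelectivityResult]:
    """Predict both targets per candidate and score selectivity/novelty.

    The nearest training compound is found by maximizing the Tanimoto
    coefficient over the pooled CB1 + CB2 training fingerprints.
    """
    train_fps = np.vstack(
        [model_cb1.train_fingerprints, model_cb2.train_fingerprints]
    )
    train_ids = list(model_cb1.knn_index.ids) + list(model_cb2.knn_index.ids)
    results = []
    for mol, cid in zip(mols, ids):
        r1 = model_cb1.predict_one(mol, threshold_percentile)
        r2 = model_cb2.predict_one(mol, threshold_percentile)
        fp = compute_fingerprint(
            mol, model_cb1.feature_space.n_bits, model_cb1.feature_space.radius
        )
        tcs = bulk_tanimoto(fp, train_fps)
        j = int(np.argmax(tcs))
        both = r1.in_domain and r2.in_domain
        dpki = (r2.pki_pred - r1.pki_pred) if both else None
        results.append(
            SelectivityResult(
                compound_id=cid,
                smiles=Chem.MolToSmiles(mol),
                pki_cb1=r1.pki_pred,
                pki_cb2=r2.pki_pred,
                dpki=dpki,
                nearest_train_id=train_ids[j],
                nearest_train_tc=float(tcs[j]),
                selective=both and dpki >= dpki_cut,
                novel=float(tcs[j]) < tc_cut,
            )
        )
    return results


def classify_pair(
    pki_cb1: float, pki_cb2: float, dpki_cut: float = DEFAULT_DPKI_CUT
) -> tuple[float, bool]:
    """Selectivity call from a (CB1, CB2) prediction pair: (dpKi, selective)."""
    dpki = pki_cb2 - pki_cb1
    return dpki, dpki >= dpki_cut


def mean_abs_dpki(results) -> float:
    """Mean |dpKi| over results (or raw dpKi values) with both predictions."""
    values = [
        r.dpki if isinstance(r, SelectivityResult) else r
        for r in results
        if (r.dpki if isinstance(r, SelectivityResult) else r) is not None
    ]
    if not values:
        raise ValueError("no results with both predictions present")
    return float(np.mean(np.abs(values)))


def results_table(results) -> pd.DataFrame:
    """Report mirroring the screening-hit table layout."""
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "smiles": r.smiles,
                "pki_cb1": r.pki_cb1,
                "pki_cb2": r.pki_cb2,
                "dpki": r.dpki,
                "nearest_train_id": r.nearest_train_id,
                "nearest_train_tc": r.nearest_train_tc,
                "selective": r.selective,
                "novel": r.novel,
            }
            for r in results
        ]
    )
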