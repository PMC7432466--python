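"""Virtual-screening enrichment statistics for docking-score rankings.

Consumes externally produced (ligand, score) lists — docking itself is
out of scope — and computes the standard retrospective-screening
metrics:

* ROC AUC as the Mann–Whitney probability that a random active outranks
  a random decoy (ties contribute ½),
* enrichment factors EF(x%) = (actives recovered in the top x% of the
  ranking / total actives) / x%, and
* the active/decoy labelling rule for receptor-subtype selectivity:
  a compound measured on both targets is CB2-selective iff
  pKi(CB1) ≤ 5.5 and pKi(CB2) > 7.

Docking scores follow the lower-is-better convention by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

EF_FRACTIONS = (0.02, 0.05, 0.10)
SELECTIVE_CB1_MAX = 5.5
SELECTIVE_CB2_MIN = 7.0


@dataclass(frozen=True)
class ScoredLigand:
    """One docked ligand with its score and active/decoy label."""

    ligand_id: str
    score: float
    label: str  # "active" | "decoy"

    def __post_init__(self):
        if not math.isfinite(self.score):
            raise ValueError("score must be finite")
        if self.label not in ("active", "decoy"):
            raise ValueError(f"label must be active|decoy, got {self.label!r}")


def label_cb2_selective(
    cb1: pd.DataFrame,
    cb2: pd.DataFrame,
    cb1_max: float = SELECTIVE_CB1_MAX,
    cb2_min: float = SELECTIVE_CB2_MIN,
) -> pd.DataFrame:
    """Label compounds present in both curated datasets by selectivity.

    Matching is by InChIKey; ``selective`` is True iff pKi(CB1) ≤ cb1_max
    and pKi(CB2) > cb2_min (note the strict CB2 boundary).
    """
    merged = cb1.merge(
        cb2, on="inchikey", suffixes=("_cb1", "_cb2"), how="inner"
    )
    merged["selective"] = (merged["pki_cb1"] <= cb1_max) & (
        merged["pki_cb2"] > cb2_min
    )
    return merged[["inchikey", "pki_cb1", "pki_cb2", "selective"]]


def _scores_labels(ranked, lower_is_better: bool):
    if len(ranked) and isinstance(ranked[0], ScoredLigand):
        scores = np.array([r.score for r in ranked], dtype=float)
        labels = np.array([r.label == "active" for r in ranked])
    else:
        scores, labels = ranked
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=bool)
    if not lower_is_better:
        scores = -scores
    return scores, labels


def roc_auc(ranked, lower_is_better: bool = True) -> float:
    """Probability a random active outranks a random decoy (Mann–Whitney).

    Tied scores contribute ½ via midranks.  *ranked* is a list of
    :class:`ScoredLigand` or a (scores, is_active) pair.
    """
    scores, labels = _scores_labels(ranked, lower_is_better)
    n_act = int(labels.sum())
    n_dec = int(len(labels) - n_act)
    if n_act == 0 or n_dec == 0:
        raise ValueError("need at least one active and one decoy")
    ranks = rankdata(-scores)  # higher rank = better score
    u = ranks[labels].sum() - n_act * (n_act + 1) / 2
    return float(u / (n_act * n_dec))


def roc_curve_points(ranked, lower_is_better: bool = True) -> pd.DataFrame:
    """FPR/TPR pairs of the ranking, ties grouped, for ROC plotting."""
    scores, labels = _scores_labels(ranked, lower_is_better)
    order = np.argsort(scores, kind="stable")
    scores, labels = scores[order], labels[order]
    n_act, n_dec = labels.sum(), (~labels).sum()
    tpr = [0.0]
    fpr = [0.0]
    i = 0
    tp = fp = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tp += labels[i:j].sum()
        fp += (~labels[i:j]).sum()
        tpr.append(tp / n_act)
        fpr.append(fp / n_dec)
        i = j
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def enrichment_factor(ranked, fraction: float, lower_is_better: bool = True) -> float:
    """EF at a screening fraction, with deterministic tie handling.

    The top set holds ⌈fraction·N⌉ ligands.  A tie group straddling the
    cutoff contributes its actives pro-rata to the remaining slots,
    rounded down.  EF = (recovered actives / total actives) / fraction.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores, labels = _scores_labels(ranked, lower_is_better)
    n = len(scores)
    n_act = int(labels.sum())
    if n_act == 0:
        raise ValueError("need at least one active")
    m = math.ceil(fraction * n)
    order = np.argsort(scores, kind="stable")
    boundary = scores[order[m - 1]]
    strictly_better = scores < boundary
    tied = scores == boundary
    slots = m - int(strictly_better.sum())
    tie_total = int(tied.sum())
    tie_actives = int((tied & labels).sum())
    recovered = int((strictly_better & labels).sum())
    recovered += (slots * tie_actives) // tie_total
    return (recovered / n_act) / fraction


def enrichment_report(
    ranked,
    fractions=EF_FRACTIONS,
    lower_is_better: bool = True,
) -> dict:
    """EF at each fraction, ROC AUC, curve points and class counts."""
    scores, labels = _scores_labels(ranked, lower_is_better)
    return {
        "ef": {
            f"{int(round(f * 100))}%": enrichment_factor(
                (scores, labels), f
            )
            for f in fractions
        },
        "roc_auc": roc_auc((scores, labels)),
        "n_actives": int(labels.sum()),
        "n_decoys": int((~labels).sum()),
        "roc_points": roc_curve_points((scores, labels)),
    }


def load_scored_ligands(
    scores_csv: str | Path, labels_csv: str | Path | None = None
) -> list[ScoredLigand]:
    """Read (ligand_id, score[, label]) CSVs into :class:`ScoredLigand`.

    If *labels_csv* is given it must map ``ligand_id`` to ``label``;
    otherwise the scores file must already carry a ``label`` column.
    """
    df = pd.read_csv(scores_csv)
    if labels_csv is not None:
        labels = pd.read_csv(labels_csv)
        df = df.merge(labels[["ligand_id", "label"]], on="ligand_id")
    return [
        ScoredLigand(str(r.ligand_id), float(r.score), str(r.label))
        for r in df.itertuples()
    ]
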