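"""Cross-validated model assessment: Q² and the threshold sweep.

Q² is the cross-validated coefficient of determination,

    Q² = 1 − Σ (Yᵢ − Ŷᵢ)² / Σ (Yᵢ − Ȳ)²,

computed on out-of-sample predictions, with Ȳ the mean experimental pKi
of the evaluated subset.  Because each applicability-domain threshold
admits a different in-domain subset, Q² and the in-domain coverage are
reported per threshold level (20 levels, percentiles 5..100), producing
the characteristic declining Q²-vs-threshold curve: the tighter the
domain, the more reliable the retained predictions.

Everything learned from data — variance mask, hyperparameters, leaf
embedding, threshold grid — is refit inside each outer fold, so no
test-fold compound influences its own fold's training.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.model_selection import KFold

from .features import FeatureSpace, descriptor_matrix, fingerprint_matrix
from .model import (
    AD_PERCENTILES,
    DEFAULT_K,
    KnnIndex,
    build_ad_grid,
    embed,
    predict_batch,
    train_base_model,
)


def q_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Cross-validated determination coefficient 1 − SSE/SST.

    SST is centred on the mean of ``y_true`` over the evaluated subset.
    Raises ``ValueError`` for fewer than two points or a constant
    ``y_true`` (SST would be zero).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size < 2:
        raise ValueError("need at least two observations")
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("constant y_true: Q² undefined")
    sse = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - sse / sst


@dataclass
class CvResult:
    """Out-of-sample predictions of a k-fold run at every threshold level.

    ``predictions`` is (n_compounds, n_levels) with NaN marking
    out-of-domain; ``fold_assignment`` maps each compound to its single
    test fold; ``fold_thresholds`` holds each fold's own threshold grid.
    """

    y_true: np.ndarray
    predictions: np.ndarray
    fold_assignment: np.ndarray
    max_neighbor_distance: np.ndarray
    fold_thresholds: np.ndarray  # (n_folds, n_levels)
    percentiles: np.ndarray

    def coverage(self) -> np.ndarray:
        """In-domain fraction of the dataset per threshold level."""
        return np.isfinite(self.predictions).mean(axis=0)

    def q2_per_threshold(self) -> np.ndarray:
        """Q² over the in-domain subset per level; NaN when undefined."""
        out = np.full(self.predictions.shape[1], np.nan)
        for j in range(self.predictions.shape[1]):
            mask = np.isfinite(self.predictions[:, j])
            if mask.sum() < 2 or np.ptp(self.y_true[mask]) == 0:
                continue
            out[j] = q_squared(self.y_true[mask], self.predictions[mask, j])
        return out


def cross_validate(
    dataset: pd.DataFrame,
    folds: int = 5,
    seed: int = 0,
    include_3d: bool = True,
    param_grid: dict | None = None,
    k: int = DEFAULT_K,
) -> CvResult:
    """k-fold cross-validation of the full QSAR architecture.

    *dataset* needs columns ``smiles`` and ``pki``.  Per fold: the
    variance mask is learned on the training rows, hyperparameters are
    grid-searched in an inner CV, the fold's own AD threshold grid is
    built, and every test compound is predicted at all 20 levels.

    Descriptors and fingerprints are computed once per molecule up front
    (they depend only on the structure); all dataset-level learning
    stays inside the fold.
    """
    if len(dataset) < folds:
        raise ValueError("dataset smaller than the number of folds")
    mols = [Chem.MolFromSmiles(s) for s in dataset["smiles"]]
    y = dataset["pki"].to_numpy(float)
    desc = descriptor_matrix(mols, include_3d=include_3d)
    fps = fingerprint_matrix(mols)

    n = len(y)
    n_levels = len(AD_PERCENTILES)
    predictions = np.full((n, n_levels), np.nan)
    fold_assignment = np.empty(n, dtype=int)
    max_nd = np.empty(n, dtype=float)
    fold_thresholds = np.empty((folds, n_levels))

    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for f, (tr, te) in enumerate(splitter.split(desc)):
        fold_assignment[te] = f
        from .features import filter_descriptor_matrix  # noqa: PLC0415

        reduced, names = filter_descriptor_matrix(desc.iloc[tr])
        space = FeatureSpace(names, include_3d=include_3d)
        X_tr = space.fit_from_matrix(reduced, fps[tr])
        X_te = space.fit_from_matrix(desc.iloc[te], fps[te])
        ensemble = train_base_model(X_tr, y[tr], param_grid=param_grid, seed=seed)
        emb_tr = embed(ensemble, X_tr)
        emb_te = embed(ensemble, X_te)
        grid = build_ad_grid(emb_tr, k=k)
        fold_thresholds[f] = grid.thresholds
        index = KnnIndex(emb_tr, y[tr], [str(i) for i in tr])
        pred, md, _ = predict_batch(emb_te, index, grid.thresholds, k=k)
        predictions[te] = pred
        max_nd[te] = md
    return CvResult(
        y, predictions, fold_assignment, max_nd, fold_thresholds,
        AD_PERCENTILES.astype(float),
    )


def threshold_sweep_report(cv: CvResult) -> pd.DataFrame:
    """20-row table of (percentile, mean threshold, coverage, Q²)."""
    return pd.DataFrame(
        {
            "percentile": cv.percentiles,
            "threshold": cv.fold_thresholds.mean(axis=0),
            "coverage": cv.coverage(),
            "q2": cv.q2_per_threshold(),
        }
    )


def plot_threshold_sweep(report: pd.DataFrame, path=None, label: str = ""):
    """Q² against in-domain coverage (one point per threshold level)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(report["coverage"], report["q2"], "o-", label=label or None)
    ax.set_xlabel("in-domain coverage")
    ax.set_ylabel("Q² (5-fold CV)")
    if label:
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_prediction_scatter(cv: CvResult, level: int = -1, path=None, label: str = ""):
    """Out-of-sample predicted vs experimental pKi at one threshold level."""
    pred = cv.predictions[:, level]
    mask = np.isfinite(pred)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(cv.y_true[mask], pred[mask], s=12, alpha=0.6, label=label or None)
    lo = min(cv.y_true[mask].min(), pred[mask].min())
    hi = max(cv.y_true[mask].max(), pred[mask].max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel("experimental pKi")
    ax.set_ylabel("predicted pKi (out-of-sample)")
    if label:
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
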