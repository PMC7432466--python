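"""Gradient-boosted QSAR model with a leaf-embedding kNN applicability domain.

Architecture
------------
1. A LightGBM gradient-boosted tree ensemble is fitted to (features, pKi)
   with hyperparameters chosen by grid search in an inner 5-fold
   cross-validation (mean squared error).
2. Each compound is *embedded* as the vector of per-tree leaf output
   values — the real-valued contribution of the leaf it falls into in
   every tree.  Because LightGBM folds the boosting initialization into
   the first tree, the components of this embedding sum exactly to the
   ensemble prediction; the embedding therefore lives in
   "pKi-contribution" units and is used unscaled.
3. A k-nearest-neighbour model (k = 3, Euclidean metric) over the
   training embeddings predicts the mean *experimental* pKi of the
   query's neighbours — the boosted ensemble only shapes the space.
4. A prediction is in-domain only when all k neighbours lie within a
   distance threshold.  Candidate thresholds form a 20-point grid: the
   5th, 10th, ..., 100th percentiles of the training distribution of
   max-kNN distances (each training compound's distance to the farthest
   of its own k nearest neighbours, self excluded).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import GridSearchCV, KFold

DEFAULT_K = 3
AD_PERCENTILES = np.arange(5, 101, 5)  # 5, 10, ..., 100

# lightgbm's sklearn wrapper names ndarray columns internally, tripping
# sklearn's feature-name consistency warning on every predict
warnings.filterwarnings("ignore", message="X does not have valid feature names")

#: Default hyperparameter grid for the inner model selection.
DEFAULT_PARAM_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [-1, 6],
    "learning_rate": [0.05, 0.1],
}

#: Fixed (non-searched) base parameters; min_child_samples is lowered from
#: LightGBM's default of 20 so small curated datasets can still grow trees.
BASE_PARAMS = dict(min_child_samples=5, n_jobs=1, verbose=-1)


def train_base_model(
    features: np.ndarray,
    pki: np.ndarray,
    param_grid: dict | None = None,
    inner_folds: int = 5,
    seed: int = 0,
) -> lgb.LGBMRegressor:
    """Fit the gradient-boosted base model with inner-CV grid search.

    The grid point minimizing mean inner-CV squared error is refit on the
    full training input.  Deterministic given *seed*.

    Raises
    ------
    ValueError
        If the target has zero variance (degenerate) or there are fewer
        rows than inner folds.
    """
    features = np.asarray(features, dtype=float)
    pki = np.asarray(pki, dtype=float)
    if len(features) != len(pki):
        raise ValueError("features and pki must align")
    if len(pki) < inner_folds:
        raise ValueError(f"need at least {inner_folds} training rows")
    if np.ptp(pki) == 0:
        raise ValueError("degenerate target: pKi has zero variance")
    grid = param_grid if param_grid is not None else DEFAULT_PARAM_GRID
    search = GridSearchCV(
        lgb.LGBMRegressor(random_state=seed, **BASE_PARAMS),
        grid,
        scoring="neg_mean_squared_error",
        cv=KFold(n_splits=inner_folds, shuffle=True, random_state=seed),
        n_jobs=1,
        refit=True,
    )
    search.fit(features, pki)
    return search.best_estimator_


def _leaf_value_table(booster: lgb.Booster) -> list[np.ndarray]:
    """Per-tree arrays mapping leaf index -> leaf output value."""
    tables = []
    for tree in booster.dump_model()["tree_info"]:
        values: dict[int, float] = {}
        stack = [tree["tree_structure"]]
        while stack:
            node = stack.pop()
            if "leaf_index" in node:
                values[node["leaf_index"]] = node["leaf_value"]
            elif "leaf_value" in node:  # stump: a single implicit leaf 0
                values[0] = node["leaf_value"]
            else:
                stack.append(node["left_child"])
                stack.append(node["right_child"])
        tables.append(np.array([values[i] for i in range(len(values))]))
    return tables


def embed(ensemble: lgb.LGBMRegressor, features: np.ndarray) -> np.ndarray:
    """Leaf-value embedding: one component per tree.

    Component *t* is the output value of the leaf that the compound falls
    into in tree *t*.  Accepts a single feature vector or a matrix;
    returns an (n, n_trees) array (or (n_trees,) for a single vector).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    booster = ensemble.booster_ if isinstance(ensemble, lgb.LGBMRegressor) else ensemble
    leaf_idx = booster.predict(X, pred_leaf=True).astype(int)
    leaf_idx = np.atleast_2d(leaf_idx)
    tables = _leaf_value_table(booster)
    emb = np.empty(leaf_idx.shape, dtype=float)
    for t, table in enumerate(tables):
        emb[:, t] = table[leaf_idx[:, t]]
    if np.asarray(features).ndim == 1:
        return emb[0]
    return emb


def _knn_stable(
    queries: np.ndarray,
    reference: np.ndarray,
    k: int,
    exclude_self: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact kNN with ties broken by reference insertion order.

    Returns (indices, distances), each of shape (n_queries, k), neighbours
    ordered nearest first.  With ``exclude_self`` the i-th query is
    assumed to be the i-th reference row and is skipped.
    """
    d = cdist(np.atleast_2d(queries), np.atleast_2d(reference))
    if exclude_self:
        np.fill_diagonal(d, np.inf)
    n_ref = d.shape[1]
    order = np.lexsort((np.broadcast_to(np.arange(n_ref), d.shape), d), axis=1)
    idx = order[:, :k]
    dist = np.take_along_axis(d, idx, axis=1)
    return idx, dist


@dataclass(frozen=True)
class AdThresholdGrid:
    """20 percentile thresholds cut from the training max-kNN-distance
    distribution, together with that distribution."""

    thresholds: np.ndarray
    max_knn_distances: np.ndarray
    percentiles: np.ndarray = field(
        default_factory=lambda: AD_PERCENTILES.astype(float)
    )

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if len(t) != len(self.percentiles):
            raise ValueError("one threshold per percentile required")
        if (np.diff(t) < 0).any() or (t < 0).any():
            raise ValueError("thresholds must be non-negative and non-decreasing")

    def threshold_at(self, percentile: float) -> float:
        i = np.nonzero(self.percentiles == percentile)[0]
        if len(i) == 0:
            raise KeyError(f"no threshold at percentile {percentile}")
        return float(self.thresholds[i[0]])


def build_ad_grid(
    train_embeddings: np.ndarray, k: int = DEFAULT_K
) -> AdThresholdGrid:
    """Applicability-domain threshold grid from training embeddings.

    For each training compound the distance to the farthest of its k
    nearest training neighbours (self excluded) is recorded; the grid is
    the 5th-100th percentiles (step 5) of that distribution.
    """
    emb = np.atleast_2d(np.asarray(train_embeddings, dtype=float))
    if len(emb) < k + 1:
        raise ValueError(f"need at least {k + 1} training embeddings")
    _, dist = _knn_stable(emb, emb, k, exclude_self=True)
    max_d = dist[:, -1]
    thresholds = np.percentile(max_d, AD_PERCENTILES)
    return AdThresholdGrid(np.maximum.accumulate(thresholds), max_d)


@dataclass
class KnnIndex:
    """Training embeddings with their experimental pKi and identifiers."""

    embeddings: np.ndarray
    pki: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.embeddings = np.atleast_2d(np.asarray(self.embeddings, dtype=float))
        self.pki = np.asarray(self.pki, dtype=float)
        if not (len(self.embeddings) == len(self.pki) == len(self.ids)):
            raise ValueError("embeddings, pki and ids must align")

    def query(self, emb: np.ndarray, k: int = DEFAULT_K):
        idx, dist = _knn_stable(np.atleast_2d(emb), self.embeddings, k)
        return idx, dist


@dataclass(frozen=True)
class PredictionResult:
    """A single applicability-domain-gated pKi prediction."""

    pki_pred: float | None
    in_domain: bool
    max_neighbor_distance: float
    neighbor_ids: tuple[str, ...]
    threshold_used: float

    def __post_init__(self):
        if self.in_domain != (self.pki_pred is not None):
            raise ValueError("pki_pred must be present iff in_domain")


def predict(
    query_features: np.ndarray,
    ensemble: lgb.LGBMRegressor,
    knn_index: KnnIndex,
    threshold: float,
    k: int = DEFAULT_K,
) -> PredictionResult:
    """Predict pKi for one query, gated by the applicability domain.

    The query is embedded, its k nearest training compounds are found
    in leaf-value space, and — only if the farthest of them is within
    *threshold* — the prediction is the arithmetic mean of the
    neighbours' experimental pKi.  Diagnostics are always populated.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    emb = embed(ensemble, np.atleast_2d(query_features))
    idx, dist = knn_index.query(emb, k)
    max_d = float(dist[0, -1])
    neighbor_ids = tuple(knn_index.ids[j] for j in idx[0])
    if max_d <= threshold:
        return PredictionResult(
            float(knn_index.pki[idx[0]].mean()), True, max_d, neighbor_ids, threshold
        )
    return PredictionResult(None, False, max_d, neighbor_ids, threshold)


def predict_batch(
    query_embeddings: np.ndarray,
    knn_index: KnnIndex,
    thresholds: Sequence[float],
    k: int = DEFAULT_K,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized prediction of precomputed embeddings at many thresholds.

    Returns ``(pred, max_dist, neighbor_idx)`` where ``pred`` has shape
    (n_queries, n_thresholds) with NaN for out-of-domain entries,
    ``max_dist`` is the per-query max neighbour distance and
    ``neighbor_idx`` the (n_queries, k) neighbour rows.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds < 0).any():
        raise ValueError("thresholds must be non-negative")
    idx, dist = knn_index.query(query_embeddings, k)
    knn_mean = knn_index.pki[idx].mean(axis=1)
    max_d = dist[:, -1]
    in_dom = max_d[:, None] <= thresholds[None, :]
    pred = np.where(in_dom, knn_mean[:, None], np.nan)
    return pred, max_d, idx


@dataclass
class QsarModel:
    """A trained per-target model bundle.

    Packs everything screening needs: the frozen feature space, the
    boosted ensemble, the kNN index over training leaf embeddings, the
    threshold grid and the training fingerprints (for Tanimoto novelty).
    """

    target: str
    feature_space: "FeatureSpace"
    ensemble: lgb.LGBMRegressor
    knn_index: KnnIndex
    ad_grid: AdThresholdGrid
    train_fingerprints: np.ndarray
    train_smiles: list[str]
    seed: int
    k: int = DEFAULT_K

    @classmethod
    def train(
        cls,
        dataset: pd.DataFrame,
        target: str,
        seed: int = 0,
        include_3d: bool = True,
        param_grid: dict | None = None,
        k: int = DEFAULT_K,
    ) -> "QsarModel":
        """Train from a curated dataset (columns inchikey, smiles, pki)."""
        from rdkit import Chem  # noqa: PLC0415

        from .features import FeatureSpace, fingerprint_matrix  # noqa: PLC0415

        mols = [Chem.MolFromSmiles(s) for s in dataset["smiles"]]
        space, X = FeatureSpace.fit(mols, include_3d=include_3d)
        y = dataset["pki"].to_numpy(float)
        ensemble = train_base_model(X, y, param_grid=param_grid, seed=seed)
        train_emb = embed(ensemble, X)
        index = KnnIndex(train_emb, y, list(dataset["inchikey"]))
        grid = build_ad_grid(train_emb, k=k)
        fps = fingerprint_matrix(mols, space.n_bits, space.radius)
        return cls(
            target, space, ensemble, index, grid, fps,
            list(dataset["smiles"]), seed, k,
        )

    def predict_one(self, mol, threshold_percentile: float = 100.0) -> PredictionResult:
        X = self.feature_space.transform([mol])
        thr = self.ad_grid.threshold_at(threshold_percentile)
        return predict(X[0], self.ensemble, self.knn_index, thr, self.k)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        booster = (
            self.ensemble.booster_
            if isinstance(self.ensemble, lgb.LGBMRegressor)
            else self.ensemble
        )
        booster.save_model(str(d / "ensemble.txt"))
        self.feature_space.to_json(d / "feature_space.json")
        np.savetxt(d / "train_embeddings.csv", self.knn_index.embeddings, delimiter=",")
        np.savetxt(d / "train_fingerprints.csv", self.train_fingerprints, fmt="%d", delimiter=",")
        pd.DataFrame(
            {"inchikey": self.knn_index.ids, "smiles": self.train_smiles,
             "pki": self.knn_index.pki}
        ).to_csv(d / "training_set.csv", index=False)
        manifest = {
            "target": self.target,
            "seed": self.seed,
            "k": self.k,
            "ad_thresholds": self.ad_grid.thresholds.tolist(),
            "ad_percentiles": self.ad_grid.percentiles.tolist(),
            "ad_max_knn_distances": self.ad_grid.max_knn_distances.tolist(),
            "best_params": (
                self.ensemble.get_params()
                if isinstance(self.ensemble, lgb.LGBMRegressor)
                else {}
            ),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    @classmethod
    def load(cls, directory: str | Path) -> "QsarModel":
        from .features import FeatureSpace  # noqa: PLC0415

        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        booster = lgb.Booster(model_file=str(d / "ensemble.txt"))
        emb = np.loadtxt(d / "train_embeddings.csv", delimiter=",")
        train = pd.read_csv(d / "training_set.csv")
        fps = np.loadtxt(d / "train_fingerprints.csv", delimiter=",", dtype=int)
        grid = AdThresholdGrid(
            np.array(manifest["ad_thresholds"]),
            np.array(manifest["ad_max_knn_distances"]),
            np.array(manifest["ad_percentiles"]),
        )
        return cls(
            manifest["target"],
            FeatureSpace.from_json(d / "feature_space.json"),
            booster,
            KnnIndex(emb, train["pki"].to_numpy(), list(train["inchikey"])),
            grid,
            fps.astype(np.uint8),
            list(train["smiles"]),
            manifest["seed"],
            manifest["k"],
        )
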