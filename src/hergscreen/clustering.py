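"""Structural clustering: self-organizing map and hierarchical clustering.

The chemical library is clustered on its retained, z-scored descriptors
with a Kohonen self-organizing map (default 15x15 grid = 225 units,
matching the cluster count used to balance cluster number against
cluster size), and the active subset is organized with Ward-linkage
hierarchical clustering on Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist

from .curation import DescriptorMatrix
from .errors import ClusteringError


class SelfOrganizingMap:
    """Classic online Kohonen map with a decaying Gaussian neighborhood.

    Learning rate decays linearly from ``lr[0]`` to ``lr[1]`` and the
    neighborhood radius from half the grid diagonal to 1 over the
    training presentations (``epochs`` passes over the data, sample
    order reshuffled per epoch from the seeded RNG).
    """

    def __init__(self, grid: tuple[int, int] = (15, 15), epochs: int = 10,
                 lr: tuple[float, float] = (0.5, 0.01), seed: int = 0):
        self.grid = grid
        self.epochs = epochs
        self.lr = lr
        self.seed = seed
        rows, cols = grid
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        self._coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        self.codebook: np.ndarray | None = None
        self.qe_initial: float | None = None
        self.qe_final: float | None = None

    @property
    def n_units(self) -> int:
        return self.grid[0] * self.grid[1]

    def _bmu(self, X: np.ndarray) -> np.ndarray:
        return np.argmin(cdist(X, self.codebook), axis=1)

    def quantization_error(self, X: np.ndarray) -> float:
        d = cdist(X, self.codebook)
        return float(d[np.arange(len(X)), np.argmin(d, axis=1)].mean())

    def fit(self, X: np.ndarray) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ClusteringError("SOM requires a non-empty 2-D matrix")
        if not np.isfinite(X).all():
            raise ClusteringError("SOM input contains NaN/inf")
        rng = np.random.default_rng(self.seed)
        # random init across the data bounding box; training pulls units to data
        lo, hi = X.min(axis=0), X.max(axis=0)
        self.codebook = rng.uniform(lo, hi, size=(self.n_units, X.shape[1]))
        self.qe_initial = self.quantization_error(X)

        total = self.epochs * len(X)
        radius0 = max(np.hypot(*self.grid) / 2.0, 1.0)
        t = 0
        for _ in range(self.epochs):
            order = rng.permutation(len(X))
            for i in order:
                frac = t / max(total - 1, 1)
                lr = self.lr[0] + (self.lr[1] - self.lr[0]) * frac
                radius = radius0 + (1.0 - radius0) * frac
                bmu = int(np.argmin(((self.codebook - X[i]) ** 2).sum(axis=1)))
                d2 = ((self._coords - self._coords[bmu]) ** 2).sum(axis=1)
                h = np.exp(-d2 / (2.0 * radius ** 2))
                self.codebook += (lr * h)[:, None] * (X[i] - self.codebook)
                t += 1
        self.qe_final = self.quantization_error(X)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.codebook is None:
            raise ClusteringError("SOM not fitted")
        return self._bmu(np.asarray(X, dtype=float))


@dataclass
class SOMModel:
    som: SelfOrganizingMap
    ids: list[str]
    assignment: pd.Series          # chemical id -> unit index (0-based)
    feature_names: list[str]
    scale_mean: np.ndarray
    scale_sd: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.som.grid

    def assign(self, X: np.ndarray) -> np.ndarray:
        return self.som.predict((np.asarray(X, dtype=float) - self.scale_mean) / self.scale_sd)


def train_som(m: DescriptorMatrix, grid: tuple[int, int] = (15, 15),
              epochs: int = 10, seed: int = 0) -> SOMModel:
    """Train a SOM on the retained descriptors (z-scored internally)."""
    df = m.to_frame(retained_only=True)
    X = df.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ClusteringError("descriptor matrix contains NaN")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    som = SelfOrganizingMap(grid=grid, epochs=epochs, seed=seed).fit(Z)
    units = som.predict(Z)
    return SOMModel(som, list(df.index), pd.Series(units, index=df.index),
                    list(df.columns), mean, sd)


def cluster_enrichment_map(model: SOMModel, labels: pd.Series,
                           categories: pd.Series | None = None) -> pd.DataFrame:
    """Per-unit composition: size, active count and percent active.

    ``labels`` must align with the chemicals in the model. Optional
    ``categories`` (e.g. drug / pesticide / industrial) add per-category
    active percentages per unit.
    """
    labels = labels.reindex(model.ids)
    if labels.isna().any():
        raise ClusteringError("labels do not cover all clustered chemicals")
    df = pd.DataFrame({"unit": model.assignment, "active": labels.astype(bool)})
    if categories is not None:
        df["category"] = categories.reindex(model.ids)

    out = pd.DataFrame(index=pd.RangeIndex(model.som.n_units, name="unit"))
    grp = df.groupby("unit")
    out["size"] = grp.size().reindex(out.index, fill_value=0)
    out["n_active"] = grp["active"].sum().reindex(out.index, fill_value=0).astype(int)
    out["pct_active"] = np.where(out["size"] > 0, 100.0 * out["n_active"] / out["size"].clip(lower=1), 0.0)
    if categories is not None:
        for cat, sub in df.groupby("category"):
            g = sub.groupby("unit")["active"]
            size = g.size().reindex(out.index, fill_value=0)
            nact = g.sum().reindex(out.index, fill_value=0)
            out[f"pct_active_{cat}"] = np.where(size > 0, 100.0 * nact / size.clip(lower=1), 0.0)
    return out


@dataclass
class Dendrogram:
    linkage: np.ndarray            # scipy linkage matrix (Ward, Euclidean)
    ids: list[str]
    leaf_metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def cut(self, k: int) -> pd.Series:
        """Partition labels (1..k) at k clusters."""
        if len(self.ids) == 1:
            return pd.Series([1], index=self.ids)
        return pd.Series(hierarchy.fcluster(self.linkage, t=k, criterion="maxclust"),
                         index=self.ids)


def hcluster_actives(m: DescriptorMatrix, active_ids: list[str],
                     pic50: pd.Series | None = None,
                     categories: pd.Series | None = None,
                     standardize: bool = True) -> Dendrogram:
    """Ward-linkage tree over the active chemicals.

    Leaves carry potency (pIC50) and chemical-class annotations for
    rendering. A singleton input yields a trivial tree.
    """
    df = m.to_frame(retained_only=True).loc[[i for i in m.ids if i in set(active_ids)]]
    if df.empty:
        raise ClusteringError("no actives present in the descriptor matrix")
    meta = pd.DataFrame(index=df.index)
    if pic50 is not None:
        meta["pic50"] = pic50.reindex(df.index)
    if categories is not None:
        meta["category"] = categories.reindex(df.index)
    if len(df) == 1:
        return Dendrogram(np.empty((0, 4)), list(df.index), meta)
    X = df.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    return Dendrogram(Z, list(df.index), meta)
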