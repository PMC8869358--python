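"""Applicability domain scoring by PCA-centroid distance Z-scores.

The training descriptor space is summarized by a PCA restricted to the
smallest number of components covering at least 80% of the variance.
Every chemical's Euclidean distance to the training centroid in that
subspace is standardized against the training distance distribution,

    Z_i = (x_i - mean(x)) / sd(x),

and binned into zones: Z < 2 fully inside the domain, 2 <= Z <= 4 at the
border, Z > 4 outside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ADError

ZONE_INSIDE, ZONE_BORDER, ZONE_OUTSIDE = "inside", "border", "outside"


@dataclass
class ADModel:
    components: np.ndarray          # (n_dims, n_features) PCA basis rows
    center: np.ndarray              # feature-space mean
    explained_variance_ratio: np.ndarray
    n_dims: int
    centroid: np.ndarray            # training centroid in the n_dims space
    dist_mean: float
    dist_sd: float
    scale_mean: np.ndarray | None = None   # None when standardize=False
    scale_sd: np.ndarray | None = None
    border: tuple[float, float] = (2.0, 4.0)

    def project(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.center.size:
            raise ADError(f"expected {self.center.size} descriptors, got {X.shape[1]}")
        if self.scale_mean is not None:
            X = (X - self.scale_mean) / self.scale_sd
        return (X - self.center) @ self.components.T

    def distances(self, X: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.project(X) - self.centroid, axis=1)


def fit_ad(X_train: np.ndarray, var_target: float = 0.80,
           standardize: bool = True, border: tuple[float, float] = (2.0, 4.0)) -> ADModel:
    """Fit the applicability-domain model on training descriptors.

    ``standardize`` z-scores descriptor columns (training statistics) before
    the PCA; disable it when the inputs are already on one scale (the
    distance machinery itself is then equivariant under rigid rotations).
    """
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ADError("AD fitting needs >= 3 training chemicals")
    if not np.isfinite(X).all():
        raise ADError("training descriptors contain NaN/inf")
    col_sd = X.std(axis=0, ddof=0)
    if np.all(col_sd == 0):
        raise ADError("zero-variance training descriptors")

    scale_mean = scale_sd = None
    if standardize:
        if np.any(col_sd == 0):
            raise ADError("zero-variance descriptor column; run selection first")
        scale_mean, scale_sd = X.mean(axis=0), col_sd
        X = (X - scale_mean) / scale_sd

    pca = PCA()
    proj_full = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    n_dims = int(np.searchsorted(np.cumsum(evr), var_target) + 1)
    n_dims = min(n_dims, proj_full.shape[1])

    proj = proj_full[:, :n_dims]
    centroid = proj.mean(axis=0)        # ~origin by PCA centering; stored explicitly
    d = np.linalg.norm(proj - centroid, axis=1)
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    if sd <= 0:
        raise ADError("degenerate distance distribution (all training points coincide)")
    return ADModel(pca.components_[:n_dims], pca.mean_, evr, n_dims, centroid,
                   float(d.mean()), sd, scale_mean, scale_sd, border)


def z_score(model: ADModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-scores and domain zones for one or more chemicals.

    Returns ``(z, zone)`` arrays; zones are 'inside' (z < lower bound),
    'border' (lower <= z <= upper, boundaries closed on the border side)
    and 'outside' (z > upper).
    """
    d = model.distances(X)
    z = (d - model.dist_mean) / model.dist_sd
    lo, hi = model.border
    zone = np.where(z < lo, ZONE_INSIDE, np.where(z <= hi, ZONE_BORDER, ZONE_OUTSIDE))
    return z, zone


def score_table(model: ADModel, X: np.ndarray, ids: list[str]) -> pd.DataFrame:
    z, zone = z_score(model, X)
    return pd.DataFrame({"ad_z": z, "ad_zone": zone}, index=ids)
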