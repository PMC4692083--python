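"""Ensemble filtering by goodness-of-fit and conformational clustering.

Scored conformers are filtered on the R factor and on agreement of the
model Rg / Rxs-1 with the experimental reference values; the survivors
are superposed on a rigid anchor (typically the Fc core), reduced by PCA
on their flattened C-alpha coordinates, and grouped by average-linkage
hierarchical clustering of the first three principal components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

from .debye import FitResult
from .models import AtomisticModel, kabsch

__all__ = ["FilterSpec", "ClusterResult", "filter_models", "pca_cluster",
           "cluster_report"]


@dataclass(frozen=True)
class FilterSpec:
    """Survivor criteria: R ceiling (%) and fractional size tolerances."""

    r_ceiling: float = 7.0
    rg_tolerance: float = 0.10
    rxs1_tolerance: float = 0.10
    rg_ref: float | None = None
    rxs1_ref: float | None = None

    def __post_init__(self):
        if self.r_ceiling <= 0:
            raise ValueError("R ceiling must be positive")
        for t in (self.rg_tolerance, self.rxs1_tolerance):
            if not (0 < t < 1):
                raise ValueError("tolerances must lie in (0, 1)")


def filter_models(fits: list[FitResult], spec: FilterSpec) -> list[str]:
    """Ids of models passing all thresholds (bounds inclusive)."""
    out = []
    for f in fits:
        if f.r_factor > spec.r_ceiling:
            continue
        if spec.rg_ref is not None:
            if f.rg is None or abs(f.rg - spec.rg_ref) > spec.rg_tolerance * spec.rg_ref:
                continue
        if spec.rxs1_ref is not None:
            if f.rxs1 is None or abs(f.rxs1 - spec.rxs1_ref) > spec.rxs1_tolerance * spec.rxs1_ref:
                continue
        out.append(f.model_id)
    if not out:
        import warnings

        warnings.warn("no models survive the filter")
    return out


@dataclass
class ClusterResult:
    model_ids: list[str]
    projections: np.ndarray        # (n, 3) PC scores
    explained_variance: np.ndarray  # fractions per component
    labels: np.ndarray             # cluster label per model
    medoids: dict[int, str]        # cluster -> representative model id
    n_clusters: int

    def summary(self) -> str:
        ev = ", ".join(f"{v:.3f}" for v in self.explained_variance[:3])
        sizes = {int(k): int((self.labels == k).sum())
                 for k in np.unique(self.labels)}
        return (
            f"{self.n_clusters} clusters, sizes {sizes}, "
            f"explained variance [{ev}]"
        )


def _ca_matrix(models, ids, anchor):
    """Superpose on anchor atoms and return flattened CA coordinates."""
    ref = models[0]
    a_ref = np.where(ref.mask(**anchor))[0]
    if a_ref.size < 3:
        raise ValueError("anchor selection needs >= 3 atoms")
    rows = []
    for m in models:
        a = np.where(m.mask(**anchor))[0]
        if a.size != a_ref.size:
            raise ValueError("anchor atoms not shared across models")
        R, t, _ = kabsch(m.coords[a], ref.coords[a_ref])
        coords = m.coords @ R.T + t
        ca = coords[m.name == "CA"]
        rows.append(ca.ravel())
    n = min(len(r) for r in rows)
    return np.stack([r[:n] for r in rows])


def pca_cluster(
    models: list[AtomisticModel],
    model_ids: list[str] | None = None,
    anchor: dict | None = None,
    k: int | str = 4,
    n_components: int = 3,
) -> ClusterResult:
    """PCA + average-linkage clustering of superposed CA coordinates.

    ``anchor`` is a selection dict (chain/resid/name/segment) naming the
    rigid core used to remove global pose; ``k`` is the cluster count or
    ``'auto'`` (cut at the largest merge-height gap).  The medoid of each
    cluster minimizes the summed pairwise CA RMSD within it.
    """
    if model_ids is None:
        model_ids = [f"m{k:06d}" for k in range(len(models))]
    if len(models) < 1:
        raise ValueError("empty ensemble")
    anchor = anchor or {"segment": "core"}
    X = _ca_matrix(models, model_ids, anchor)
    n = X.shape[0]
    nc = min(n_components, n, X.shape[1])
    if np.allclose(X.var(axis=0), 0):
        labels = np.zeros(n, dtype=int)
        return ClusterResult(
            model_ids, np.zeros((n, nc)), np.zeros(nc), labels,
            {0: model_ids[0]}, 1,
        )
    pca = PCA(n_components=nc, svd_solver="full")
    proj = pca.fit_transform(X)
    if k == "auto":
        from scipy.cluster.hierarchy import average, fcluster
        from scipy.spatial.distance import pdist as _pdist

        Z = average(_pdist(proj))
        heights = Z[:, 2]
        if heights.size < 2:
            kk = 1
        else:
            gaps = np.diff(heights)
            kk = int(n - (np.argmax(gaps) + 1))
            kk = max(kk, 1)
        labels = fcluster(Z, t=kk, criterion="maxclust") - 1
    else:
        kk = int(k)
        if n < kk:
            raise ValueError("fewer models than clusters")
        ac = AgglomerativeClustering(n_clusters=kk, linkage="average")
        labels = ac.fit_predict(proj)

    # medoid: minimal summed pairwise CA RMSD within the cluster
    natoms = X.shape[1] // 3
    medoids = {}
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if idx.size == 1:
            medoids[int(lab)] = model_ids[idx[0]]
            continue
        sub = X[idx]
        d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2) / natoms
        rmsd = np.sqrt(d2)
        medoids[int(lab)] = model_ids[idx[int(np.argmin(rmsd.sum(axis=1)))]]
    return ClusterResult(
        list(model_ids), proj, pca.explained_variance_ratio_,
        np.asarray(labels), medoids, int(len(medoids)),
    )


def cluster_report(result: ClusterResult, fits: list[FitResult]) -> pd.DataFrame:
    """Per-cluster mean +/- sd of Rg, Rxs, R factor and hydrated volume."""
    by_id = {f.model_id: f for f in fits}
    missing = [i for i in result.model_ids if i not in by_id]
    if missing:
        raise ValueError(f"fits missing for {len(missing)} models")
    rows = []
    fields = ["rg", "rxs1", "rxs2", "r_factor", "hydrated_volume"]
    labels = np.asarray(result.labels)
    groups = [(f"cluster {int(k)}", labels == k) for k in np.unique(labels)]
    groups.append(("overall", np.ones(len(labels), dtype=bool)))
    for name, m in groups:
        ids = [i for i, keep in zip(result.model_ids, m) if keep]
        row = {"cluster": name, "n_models": len(ids)}
        for f in fields:
            vals = np.array(
                [getattr(by_id[i], f) for i in ids
                 if getattr(by_id[i], f) is not None],
                dtype=float,
            )
            row[f"{f}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{f}_sd"] = vals.std(ddof=0) if vals.size else np.nan
        if name != "overall":
            row["medoid"] = result.medoids[int(name.split()[-1])]
        rows.append(row)
    return pd.DataFrame(rows)
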