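"""Cell-phenotype discovery: capping, standardisation, K-means, consensus
clustering with PAC-based model selection, Davies-Bouldin marker
down-selection, and patient-level cluster profiles.

The number of phenotypes is chosen by consensus clustering: for each
candidate k the cells are repeatedly subsampled and re-clustered, pairwise
co-assignment frequencies are accumulated among co-sampled pairs, and the
proportion of ambiguously clustered pairs (PAC: consensus values inside an
intermediate window, default (0.1, 0.9)) is minimised over k. Markers that
do not contribute to cluster separation are removed greedily using the
Davies-Bouldin index (lower = better-separated clustering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


def cap_extremes(matrix, tail_fraction: float = 0.01) -> np.ndarray:
    """Winsorise each column at its lower/upper tail quantiles.

    Quantiles use linear interpolation between order statistics. Constant
    columns are left unchanged (logged). ``tail_fraction`` must lie in
    (0, 0.5).
    """
    if not 0.0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    x = np.asarray(matrix, dtype=float).copy()
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) == 0:
            logger.info("column %d is constant; capping skipped", j)
            continue
        lo, hi = np.quantile(col, [tail_fraction, 1.0 - tail_fraction], method="linear")
        x[:, j] = np.clip(col, lo, hi)
    return x


def standardize(matrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale columns to zero mean and unit (population) variance.

    Returns ``(z, means, sds)`` so the transform is exactly invertible as
    ``z * sds + means``. Constant columns raise.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("standardize needs at least 2 rows")
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"constant column(s) at index {bad.tolist()}: cannot standardize")
    return (x - means) / sds, means, sds


@dataclass
class ClusterModel:
    """A fitted K-means partition. Labels are 1-based (1..k)."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    marker_subset: tuple[str, ...] = ()
    seed: int | None = None


def kmeans_fit(matrix, k: int, seed: int = 0, n_init: int = 10,
               max_iter: int = 300, marker_subset: tuple[str, ...] = ()) -> ClusterModel:
    """Best-of-``n_init`` K-means under squared Euclidean distortion.

    Deterministic given ``seed``. Empty clusters are relocated by the
    fitter to the points contributing most distortion, so every returned
    cluster is non-empty.
    """
    x = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if x.shape[0] <= k:
        raise ValueError("need more rows than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed)
    labels = km.fit_predict(x) + 1
    return ClusterModel(k=k, centroids=km.cluster_centers_, labels=labels,
                        inertia=float(km.inertia_), marker_subset=tuple(marker_subset),
                        seed=seed)


@dataclass
class ConsensusResult:
    """Per-k consensus summaries and the PAC-selected number of clusters."""

    pac: dict[int, float]
    consensus: dict[int, np.ndarray | None]
    selected_k: int
    n_subsamples: int = 0
    subsample_frac: float = 0.8
    pac_window: tuple[float, float] = (0.1, 0.9)


def consensus_cluster(matrix, k_range=range(2, 16), n_subsamples: int = 100,
                      subsample_frac: float = 0.5, seed: int = 0,
                      pac_window: tuple[float, float] = (0.1, 0.9),
                      n_init: int = 10, max_iter: int = 100,
                      keep_matrices: bool | None = None) -> ConsensusResult:
    """Subsampled consensus clustering over a range of k with PAC selection.

    For each k the same ``n_subsamples`` row subsets (fraction
    ``subsample_frac``) are clustered by K-means; the consensus value of a
    pair is its co-assignment frequency among subsamples in which both cells
    were drawn. PAC is the fraction of off-diagonal pair entries strictly
    inside ``pac_window``; the selected k minimises PAC (ties to smaller k).

    Subsampling at 50% of rows is the perturbation source: strong enough
    that a k below the true cluster count has to re-choose which groups to
    merge from subsample to subsample (raising its PAC), while each
    subsample is clustered with multi-restart K-means so local-minimum
    noise does not inflate PAC at the true k.

    ``keep_matrices=None`` retains full consensus matrices only for
    n <= 4000 rows (they are O(n^2) memory); PAC is always computed.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    k_range = list(k_range)
    if n_subsamples < 2:
        raise ValueError("n_subsamples must be >= 2")
    m_sub = int(round(subsample_frac * n))
    if m_sub <= max(k_range):
        raise ValueError("subsample too small for the largest k")
    if keep_matrices is None:
        keep_matrices = n <= 4000

    rng = np.random.default_rng(seed)
    subsets = [rng.choice(n, size=m_sub, replace=False) for _ in range(n_subsamples)]

    # Co-sampling counts are shared across k.
    count_both = np.zeros((n, n), dtype=np.int32)
    for idx in subsets:
        count_both[np.ix_(idx, idx)] += 1

    tri = np.triu_indices(n, k=1)
    pair_counts = count_both[tri]
    valid = pair_counts > 0

    pac: dict[int, float] = {}
    consensus: dict[int, np.ndarray | None] = {}
    lo, hi = pac_window
    for k in k_range:
        co = np.zeros((n, n), dtype=np.int32)
        for r, idx in enumerate(subsets):
            km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                        random_state=seed + 1000 * k + r)
            labels = km.fit_predict(x[idx])
            for c in range(k):
                members = idx[labels == c]
                co[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = co[tri][valid] / pair_counts[valid]
        pac[k] = float(np.mean((vals > lo) & (vals < hi)))
        if keep_matrices:
            cons = np.zeros((n, n), dtype=np.float32)
            nz = count_both > 0
            cons[nz] = co[nz] / count_both[nz]
            np.fill_diagonal(cons, 1.0)
            consensus[k] = cons
        else:
            consensus[k] = None

    selected = min(k_range, key=lambda k: (pac[k], k))
    return ConsensusResult(pac=pac, consensus=consensus, selected_k=selected,
                           n_subsamples=n_subsamples, subsample_frac=subsample_frac,
                           pac_window=pac_window)


def davies_bouldin_index(matrix, labels) -> float:
    """Davies-Bouldin cluster-validity index (lower is better).

    Mean over clusters i of max_{j != i} (S_i + S_j) / M_ij, where S_i is
    the mean Euclidean distance of cluster members to their centroid and
    M_ij the distance between centroids.
    """
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if ids.size < 2:
        raise ValueError("need at least 2 clusters")
    centroids = np.stack([x[labels == c].mean(axis=0) for c in ids])
    scatter = np.array([
        np.linalg.norm(x[labels == c] - centroids[i], axis=1).mean()
        for i, c in enumerate(ids)
    ])
    sep = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    ratios = np.full_like(sep, -np.inf)
    for i in range(ids.size):
        for j in range(ids.size):
            if i != j:
                if sep[i, j] == 0:
                    raise ValueError("coincident centroids: index undefined")
                ratios[i, j] = (scatter[i] + scatter[j]) / sep[i, j]
    return float(np.mean(ratios.max(axis=1)))


def down_select_markers(matrix, marker_names, k: int, seed: int = 0,
                        rel_tol: float = 0.01, n_init: int = 4) -> tuple[str, ...]:
    """Greedy leave-one-marker-out pruning by Davies-Bouldin improvement.

    At each step the marker whose removal lowers the DB index the most is
    dropped, provided the relative improvement is at least ``rel_tol``;
    iteration stops when no removal helps. Output preserves input order.
    Deterministic given ``seed``.
    """
    x = np.asarray(matrix, dtype=float)
    names = list(marker_names)
    if len(names) < 3:
        raise ValueError("need at least 3 markers to down-select")
    if x.shape[1] != len(names):
        raise ValueError("matrix width must match marker_names")

    def db_for(cols: list[int]) -> float:
        sub = x[:, cols]
        model = kmeans_fit(sub, k=k, seed=seed, n_init=n_init)
        return davies_bouldin_index(sub, model.labels)

    current = list(range(len(names)))
    db_base = db_for(current)
    while len(current) > 2:
        best_j, best_db = None, db_base
        for j in current:
            trial = [c for c in current if c != j]
            db_trial = db_for(trial)
            if db_trial < best_db:
                best_j, best_db = j, db_trial
        if best_j is None or (db_base - best_db) / db_base < rel_tol:
            break
        logger.info("dropping marker %s (DB %.4f -> %.4f)", names[best_j], db_base, best_db)
        current = [c for c in current if c != best_j]
        db_base = best_db
    if not current:
        raise ValueError("all markers dropped: degenerate data")
    return tuple(names[c] for c in current)


def patient_cluster_profile(labels, patient_ids, cluster_ids=None) -> pd.DataFrame:
    """Per-patient cluster proportions, pooling cells across cores.

    Returns a DataFrame indexed by patient_id with one ``cluster_<i>``
    column per cluster (absent clusters get 0) and a ``dominant_cluster``
    column. Fractions sum to 1 per patient.
    """
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    if labels.shape != patient_ids.shape:
        raise ValueError("labels and patient_ids must be equal-length")
    if cluster_ids is None:
        cluster_ids = np.unique(labels)
    counts = pd.crosstab(pd.Series(patient_ids, name="patient_id"),
                         pd.Series(labels, name="cluster"))
    counts = counts.reindex(columns=cluster_ids, fill_value=0)
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [f"cluster_{c}" for c in cluster_ids]
    props["dominant_cluster"] = [
        cluster_ids[i] for i in props[[f"cluster_{c}" for c in cluster_ids]]
        .to_numpy().argmax(axis=1)]
    return props
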