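"""Connectivity-state clustering and temporal statistics.

Windowed connectivity matrices from all subjects are concatenated as
upper-triangle edge vectors and clustered with squared-Euclidean k-means
(k-means++ initialization, many restarts, best inertia kept).  The number
of states is chosen by the mean silhouette criterion over a candidate
range.  Per subject, the label sequence yields the reoccurrence fraction,
mean dwell time and total transition count of each state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .containers import WindowStack, unvec_upper

__all__ = [
    "StateModel",
    "StateMetrics",
    "fit_kmeans",
    "cluster_states",
    "select_k",
    "state_metrics",
    "cohort_state_metrics",
    "match_states",
]


@dataclass
class StateModel:
    """Fitted k-means state model over all subjects' windows.

    ``centroids`` is (k, E) in Fisher-z edge-vector space; ``labels`` maps
    subject id to that subject's per-window state sequence.
    """

    k: int
    centroids: np.ndarray
    labels: dict[str, np.ndarray]
    inertia: float
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")
        for sid, lab in self.labels.items():
            lab = np.asarray(lab)
            if lab.size and (lab.min() < 0 or lab.max() >= self.k):
                raise ValueError(f"labels for {sid} outside [0, k)")

    def centroid_matrix(self, state: int, n_components: int) -> np.ndarray:
        """State centroid reshaped to a symmetric C x C matrix."""
        return unvec_upper(self.centroids[state], n_components)


@dataclass
class StateMetrics:
    """Per-subject temporal statistics of the state sequence.

    ``fraction``: proportion of windows in each state (sums to 1).
    ``mean_dwell``: mean consecutive run length per state, in windows
    (states never visited are NaN and excluded from group statistics);
    multiply by TR x step for seconds.
    ``n_transitions``: number of state changes = total runs - 1.
    """

    subject_id: str
    fraction: np.ndarray
    mean_dwell: np.ndarray
    n_transitions: int
    n_windows: int


def _stack_windows(
    stacks: list[WindowStack],
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    mats = [s.edge_matrix() for s in stacks]
    spans = [(s.subject_id, m.shape[0]) for s, m in zip(stacks, mats)]
    return np.vstack(mats), spans


def fit_kmeans(
    x: np.ndarray, k: int, max_iter: int = 500, n_replicates: int = 150,
    seed: int | None = None,
) -> KMeans:
    """Squared-Euclidean k-means, best of ``n_replicates`` k-means++ starts.

    Allows k = 1 (degenerate case used internally; centroid is the grand
    mean).  scikit-learn relocates empty clusters internally, so every
    returned model has k non-empty clusters.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_replicates,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=np.random.default_rng(seed).integers(2**31 - 1),
    )
    km.fit(x)
    return km


def cluster_states(
    stacks: list[WindowStack],
    k: int,
    max_iter: int = 500,
    n_replicates: int = 150,
    seed: int | None = None,
) -> StateModel:
    """Cluster all subjects' windows into ``k`` connectivity states."""
    if k < 2:
        raise ValueError("k must be >= 2")
    x, spans = _stack_windows(stacks)
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError("need at least k distinct window vectors")
    km = fit_kmeans(x, k, max_iter=max_iter, n_replicates=n_replicates, seed=seed)
    labels: dict[str, np.ndarray] = {}
    pos = 0
    for sid, n in spans:
        labels[sid] = km.labels_[pos:pos + n].copy()
        pos += n
    return StateModel(
        k=k,
        centroids=km.cluster_centers_.copy(),
        labels=labels,
        inertia=float(km.inertia_),
    )


def select_k(
    stacks: list[WindowStack],
    k_range: range | tuple[int, ...] = range(2, 9),
    max_iter: int = 500,
    n_replicates: int = 150,
    seed: int | None = None,
    max_silhouette_windows: int = 20_000,
) -> tuple[int, dict[int, float]]:
    """Choose the state count by the mean silhouette criterion.

    For each candidate k the full window set is clustered, then the mean
    Euclidean silhouette is evaluated on a deterministic subsample of at
    most ``max_silhouette_windows`` windows.  Returns the argmax k (ties go
    to the smaller k) and the full silhouette table.
    """
    x, _ = _stack_windows(stacks)
    rng = np.random.default_rng(seed)
    kmeans_seeds = {k: int(rng.integers(2**31 - 1)) for k in k_range}
    if x.shape[0] > max_silhouette_windows:
        sub = rng.choice(x.shape[0], size=max_silhouette_windows, replace=False)
        sub.sort()
    else:
        sub = np.arange(x.shape[0])
    silhouettes: dict[int, float] = {}
    for k in k_range:
        if k < 2 or k >= x.shape[0]:
            raise ValueError(f"infeasible cluster count {k}")
        km = fit_kmeans(
            x, k, max_iter=max_iter, n_replicates=n_replicates,
            seed=kmeans_seeds[k],
        )
        silhouettes[k] = float(
            silhouette_score(x[sub], km.labels_[sub], metric="euclidean")
        )
    best = max(sorted(silhouettes), key=lambda k: silhouettes[k])
    return best, silhouettes


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant segments as (state, length) pairs."""
    runs = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            runs.append((int(labels[start]), i - start))
            start = i
    return runs


def state_metrics(
    labels: np.ndarray,
    n_states: int,
    subject_id: str = "",
) -> StateMetrics:
    """Temporal statistics of one subject's window label sequence."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("label sequence must be non-empty")
    if labels.min() < 0 or labels.max() >= n_states:
        raise ValueError("labels outside [0, n_states)")
    w = labels.size
    fraction = np.bincount(labels, minlength=n_states) / w
    runs = _runs(labels)
    mean_dwell = np.full(n_states, np.nan)
    for s in range(n_states):
        lengths = [ln for st, ln in runs if st == s]
        if lengths:
            mean_dwell[s] = float(np.mean(lengths))
    return StateMetrics(
        subject_id=subject_id,
        fraction=fraction,
        mean_dwell=mean_dwell,
        n_transitions=len(runs) - 1,
        n_windows=w,
    )


def cohort_state_metrics(
    model: StateModel, tr_seconds: float = 2.0, step: int = 1
) -> pd.DataFrame:
    """Tidy per-subject table of fractions, dwell times and transitions.

    Dwell times are reported in windows and in seconds
    (windows x TR x step).
    """
    rows = []
    for sid, labels in model.labels.items():
        m = state_metrics(labels, model.k, subject_id=sid)
        row = {"subject_id": sid, "n_transitions": m.n_transitions,
               "n_windows": m.n_windows}
        for s in range(model.k):
            row[f"fraction_state{s + 1}"] = m.fraction[s]
            row[f"mean_dwell_state{s + 1}"] = m.mean_dwell[s]
            row[f"mean_dwell_state{s + 1}_seconds"] = (
                m.mean_dwell[s] * tr_seconds * step
            )
        rows.append(row)
    return pd.DataFrame(rows)


def match_states(
    centroids: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Map each centroid to the reference row it correlates with most.

    Used to align estimated state identities with generator truth (all
    downstream metrics are invariant to state relabeling).  Greedy maximum
    correlation assignment; returns ``perm`` with
    ``centroids[i] ~ reference[perm[i]]``.
    """
    k = centroids.shape[0]
    corr = np.corrcoef(centroids, reference)[:k, k:]
    perm = np.full(k, -1)
    used: set[int] = set()
    order = np.argsort(corr.max(axis=1))[::-1]
    for i in order:
        choices = np.argsort(corr[i])[::-1]
        for j in choices:
            if int(j) not in used:
                perm[i] = int(j)
                used.add(int(j))
                break
    return perm
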