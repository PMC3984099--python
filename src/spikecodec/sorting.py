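"""Spike sorting: PCA features, K-means clustering, and accuracy scoring.

Sorting runs at the external unit, so computational cost is not a concern
here; the first three principal-component weights of the (reconstructed)
spike waveforms are clustered with K-means given the true number of units.
Accuracy is the fraction of spikes assigned to the correct neuron under the
best cluster-to-neuron correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .detection import SpikeMatrix


@dataclass
class SortResult:
    features: np.ndarray  # N x n_components
    assigned_labels: np.ndarray
    matched_labels: np.ndarray
    accuracy: float


def pca_features(Xhat: np.ndarray | SpikeMatrix, n_components: int = 3) -> np.ndarray:
    """Project mean-centred spikes onto the top principal components.

    Returns an N x n_components feature matrix; component signs follow the
    same largest-element-positive convention as the compression bases.
    """
    A = Xhat.waveforms if isinstance(Xhat, SpikeMatrix) else np.asarray(Xhat, float)
    n = A.shape[1]
    if n < n_components:
        raise ValueError(f"need at least {n_components} spikes, got {n}")
    pca = PCA(n_components=n_components, svd_solver="full")
    feats = pca.fit_transform(A.T)
    comps = pca.components_  # n_components x M
    idx = np.argmax(np.abs(comps), axis=1)
    signs = np.sign(comps[np.arange(n_components), idx])
    signs[signs == 0] = 1.0
    return feats * signs


def kmeans_cluster(features: np.ndarray, K: int = 4, seed: int | None = 0, restarts: int = 10) -> np.ndarray:
    """Best-of-``restarts`` K-means labels (k-means++ seeding)."""
    features = np.asarray(features, float)
    if K > features.shape[0]:
        raise ValueError("K exceeds the number of spikes")
    km = KMeans(
        n_clusters=K, n_init=restarts, init="k-means++",
        tol=1e-6, max_iter=300, random_state=seed,
    )
    return km.fit_predict(features)


def match_clusters(assigned: np.ndarray, true_ids: np.ndarray) -> dict[int, int]:
    """Best injective cluster -> neuron mapping (maximises matches).

    Exhaustive over permutations for up to 6 labels on each side; Hungarian
    assignment on the contingency table otherwise (the two agree; the small
    case doubles as an internal cross-check for tests).
    """
    clusters = np.unique(assigned)
    neurons = np.unique(true_ids)
    cont = np.zeros((clusters.size, neurons.size), dtype=int)
    for i, c in enumerate(clusters):
        for j, g in enumerate(neurons):
            cont[i, j] = int(np.sum((assigned == c) & (true_ids == g)))
    if max(clusters.size, neurons.size) <= 6:
        best, best_map = -1, {}
        k = min(clusters.size, neurons.size)
        if clusters.size <= neurons.size:
            for perm in permutations(range(neurons.size), k):
                total = sum(cont[i, perm[i]] for i in range(k))
                if total > best:
                    best = total
                    best_map = {int(clusters[i]): int(neurons[perm[i]]) for i in range(k)}
        else:
            for perm in permutations(range(clusters.size), k):
                total = sum(cont[perm[j], j] for j in range(k))
                if total > best:
                    best = total
                    best_map = {int(clusters[perm[j]]): int(neurons[j]) for j in range(k)}
        return best_map
    rows, cols = linear_sum_assignment(-cont)
    return {int(clusters[r]): int(neurons[c]) for r, c in zip(rows, cols)}


def sorting_accuracy(assigned: np.ndarray, true_ids: np.ndarray) -> float:
    """Fraction of spikes identified correctly under optimal matching."""
    assigned = np.asarray(assigned)
    true_ids = np.asarray(true_ids)
    if assigned.shape != true_ids.shape:
        raise ValueError("label arrays must have equal length")
    if assigned.size == 0:
        raise ValueError("no spikes to score")
    mapping = match_clusters(assigned, true_ids)
    matched = np.array([mapping.get(int(a), -1) for a in assigned])
    return float(np.mean(matched == true_ids))


def sort_spikes(Xhat: np.ndarray | SpikeMatrix, true_ids: np.ndarray, K: int = 4,
                seed: int | None = 0, restarts: int = 10) -> SortResult:
    """PCA + K-means + optimal-matching accuracy in one call."""
    feats = pca_features(Xhat)
    labels = kmeans_cluster(feats, K=K, seed=seed, restarts=restarts)
    mapping = match_clusters(labels, true_ids)
    matched = np.array([mapping.get(int(a), -1) for a in labels])
    acc = float(np.mean(matched == np.asarray(true_ids)))
    return SortResult(feats, labels, matched, acc)
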