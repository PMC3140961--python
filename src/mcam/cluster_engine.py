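"""Combinatorial clustering-parameter grid and partition generation.

An ensemble run expands the Cartesian product transform × distance ×
algorithm × K under algorithm-specific constraints:

* affinity propagation (AP) takes no K argument — K is emergent;
* the self-organizing map (SOM) only uses the Euclidean metric;
* Kmeans squares the Euclidean distance and rejects Chebychev;
* normalized-cut (Ncut) and average-linkage hierarchical take the full grid.

Each valid configuration yields one complete partition (a *clusterset*); the
ordered collection of all clustersets plus provenance is the MCA (Multiple
Clustering Analysis). Non-deterministic algorithms (Kmeans, SOM) carry a
stored seed so any clusterset can be reproduced bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import AffinityPropagation, SpectralClustering

from .dataio import QuantDataset, RunManifest
from .transforms import (
    DegenerateTransform,
    DistanceSpec,
    TransformSpec,
    pairwise_distances,
    transform_matrix,
)

ALGORITHMS = ("Ncut", "AP", "SOM", "Kmeans", "Hierarchical")


@dataclass(frozen=True)
class ClusterConfig:
    """One grid point: transform, distance, algorithm, K and (optionally) seed."""

    transform: str
    distance: str
    algorithm: str
    K: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        TransformSpec(self.transform)
        DistanceSpec(self.distance)
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm: {self.algorithm!r}")
        if self.algorithm == "AP":
            if self.K is not None:
                raise ValueError("AP does not accept a K argument")
        elif self.K is None:
            raise ValueError(f"{self.algorithm} requires K")
        if self.algorithm == "SOM" and self.distance != "euclidean":
            raise ValueError("SOM only supports the euclidean metric")
        if self.algorithm == "Kmeans" and self.distance == "chebychev":
            raise ValueError("Kmeans does not accept the chebychev metric")

    @property
    def key(self) -> str:
        k = "-" if self.K is None else str(self.K)
        return f"{self.algorithm}|{self.transform}|{self.distance}|K={k}"


@dataclass
class ClusterSet:
    """One complete partition of the dataset from a single configuration.

    ``assignment`` holds a cluster index in 1..k_eff per peptide (dataset row
    order); indices are contiguous and every non-empty cluster appears.
    """

    config: ClusterConfig
    assignment: np.ndarray
    k_eff: int = 0

    def __post_init__(self) -> None:
        self.assignment = _relabel(np.asarray(self.assignment, dtype=int))
        self.k_eff = int(self.assignment.max())

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster)


@dataclass
class MCA:
    """An ordered ensemble of clustersets plus run provenance."""

    cluster_sets: list[ClusterSet]
    manifest: RunManifest = field(default_factory=RunManifest)

    def __len__(self) -> int:
        return len(self.cluster_sets)

    def __iter__(self):
        return iter(self.cluster_sets)

    def __getitem__(self, i: int) -> ClusterSet:
        return self.cluster_sets[i]

    def configs(self) -> list[ClusterConfig]:
        return [cs.config for cs in self.cluster_sets]

    def subset(self, indices) -> "MCA":
        return MCA([self.cluster_sets[i] for i in indices], self.manifest)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to contiguous 1..k preserving order of first use."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def default_k_grid(n_peptides: int, per_cluster: int = 5) -> list[int]:
    """Even K values 2..Kmax, Kmax the largest even K with n/K >= per_cluster.

    With 77 peptides and ~5 per cluster this gives {2, 4, ..., 14}.
    """
    if n_peptides < 2 * per_cluster:
        raise ValueError(
            f"{n_peptides} peptides is too small for K=2 at {per_cluster} per cluster"
        )
    kmax = (n_peptides // per_cluster) // 2 * 2
    return list(range(2, kmax + 1, 2))


def expand_grid(
    transforms,
    distances,
    algorithms,
    k_grid,
    seed: int = 0,
) -> list[ClusterConfig]:
    """Cartesian product of the parameter vocabularies with constraints applied.

    AP contributes |transforms| x |distances| configs (no K); SOM contributes
    |k_grid| x |transforms| (euclidean only); Kmeans drops chebychev; Ncut and
    Hierarchical take the full product. Fresh seeds are drawn for the
    non-deterministic algorithms (Kmeans, SOM) from *seed*.
    """
    transforms = list(transforms)
    distances = list(distances)
    algorithms = list(algorithms)
    k_grid = list(k_grid)
    if not transforms or not distances or not algorithms:
        raise ValueError("empty parameter vocabulary")
    rng = np.random.default_rng(seed)

    def fresh_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    configs: list[ClusterConfig] = []
    for alg in algorithms:
        if alg == "AP":
            for t in transforms:
                for d in distances:
                    configs.append(ClusterConfig(t, d, "AP"))
        elif alg == "SOM":
            for t in transforms:
                for k in k_grid:
                    configs.append(ClusterConfig(t, "euclidean", "SOM", k, fresh_seed()))
        elif alg == "Kmeans":
            for t in transforms:
                for d in distances:
                    if d == "chebychev":
                        continue
                    for k in k_grid:
                        configs.append(ClusterConfig(t, d, "Kmeans", k, fresh_seed()))
        else:  # Ncut, Hierarchical — full product, deterministic
            for t in transforms:
                for d in distances:
                    for k in k_grid:
                        configs.append(ClusterConfig(t, d, alg, k))
    if not configs:
        raise ValueError("no configurations after applying constraints")
    return configs


# --- algorithm back-ends ---------------------------------------------------


def _kmeans(X: np.ndarray, K: int, dist: DistanceSpec, seed: int) -> np.ndarray:
    """Lloyd iterations under an arbitrary metric with metric-matched updates.

    Centroids: mean for squared Euclidean, per-dimension median for
    cityblock, mean of members for correlation/cosine (the metric itself is
    scale/offset invariant). Seeding is k-means++ under the chosen metric;
    empty clusters are repaired by reassigning the point farthest from its
    current centroid.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    metric = {
        "euclidean": "sqeuclidean",
        "cityblock": "cityblock",
        "correlation": "correlation",
        "cosine": "cosine",
    }[dist.name]
    # k-means++ seeding: next center drawn with probability proportional to
    # distance from the nearest center already chosen
    chosen = [int(rng.integers(n))]
    with np.errstate(invalid="ignore", divide="ignore"):
        while len(chosen) < K:
            D0 = cdist(X, X[chosen], metric=metric)
            D0[~np.isfinite(D0)] = 0.0
            d_near = D0.min(axis=1)
            d_near[chosen] = 0.0
            total = d_near.sum()
            if total == 0:  # duplicate points: fall back to uniform choice
                remaining = np.setdiff1d(np.arange(n), chosen)
                chosen.append(int(rng.choice(remaining)))
            else:
                chosen.append(int(rng.choice(n, p=d_near / total)))
    centroids = X[chosen].copy()
    labels = np.full(n, -1)
    for _ in range(300):
        with np.errstate(invalid="ignore", divide="ignore"):
            D = cdist(X, centroids, metric=metric)
        D[~np.isfinite(D)] = 1e300  # constant centroid under correlation
        new = D.argmin(axis=1)
        # repair empty clusters with the globally worst-fit point
        for k in range(K):
            if not np.any(new == k):
                far = D[np.arange(n), new].argmax()
                new[far] = k
                D[far, :] = 0  # pin so it is not moved again this pass
        if np.array_equal(new, labels):
            break
        labels = new
        for k in range(K):
            members = X[labels == k]
            if metric == "cityblock":
                centroids[k] = np.median(members, axis=0)
            else:
                centroids[k] = members.mean(axis=0)
    return labels + 1


def _som_1d(X: np.ndarray, K: int, seed: int, n_epochs: int = 40) -> np.ndarray:
    """Batch-trained 1xK line SOM on the Euclidean metric.

    Gaussian neighborhood on the line with width decaying from K/2 to 0.5;
    unit best-matching memberships at convergence are the clusters.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    codebook = X[rng.choice(n, size=K, replace=False)].astype(float).copy()
    units = np.arange(K, dtype=float)
    sigma0, sigma_end = max(K / 2.0, 1.0), 0.5
    for epoch in range(n_epochs):
        sigma = sigma0 * (sigma_end / sigma0) ** (epoch / max(n_epochs - 1, 1))
        bmu = cdist(X, codebook, metric="euclidean").argmin(axis=1)
        h = np.exp(-((units[None, :] - bmu[:, None]) ** 2) / (2 * sigma**2))
        weights = h.sum(axis=0)
        nonzero = weights > 1e-12
        codebook[nonzero] = (h.T @ X)[nonzero] / weights[nonzero, None]
    return cdist(X, codebook, metric="euclidean").argmin(axis=1) + 1


def _ncut(D: np.ndarray, K: int) -> np.ndarray:
    """Normalized-cut spectral partition on exp(-d^2/sigma^2) affinity.

    sigma is the median off-diagonal pairwise distance (self-tuning,
    scale-free bandwidth).
    """
    off = D[np.triu_indices_from(D, k=1)]
    sigma = np.median(off)
    if sigma == 0:
        sigma = 1.0
    S = np.exp(-(D**2) / sigma**2)
    model = SpectralClustering(
        n_clusters=K,
        affinity="precomputed",
        assign_labels="discretize",
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit_predict(S) + 1


def _ap(D: np.ndarray) -> np.ndarray:
    """Affinity propagation on negated distances, median-similarity preference."""
    S = -D
    pref = np.median(S[np.triu_indices_from(S, k=1)])
    model = AffinityPropagation(
        affinity="precomputed",
        damping=0.9,
        max_iter=1000,
        preference=pref,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = model.fit_predict(S)
    if np.any(labels < 0):  # no convergence: fall back to a single cluster
        labels = np.zeros(D.shape[0], dtype=int)
    return labels + 1


def run_clustering(dataset: QuantDataset, config: ClusterConfig) -> ClusterSet:
    """Produce the partition for one configuration.

    Raises :class:`~mcam.transforms.DegenerateTransform` when the transform is
    undefined for some row of the dataset (the caller skips such configs), and
    ``ValueError`` when K exceeds the number of peptides.
    """
    X = transform_matrix(dataset.values, config.transform)
    n = X.shape[0]
    if config.K is not None and config.K > n:
        raise ValueError(f"K={config.K} exceeds {n} peptides")
    alg = config.algorithm
    if alg == "Kmeans":
        dist = DistanceSpec(config.distance, squared=config.distance == "euclidean")
        labels = _kmeans(X, config.K, dist, config.seed)
    elif alg == "SOM":
        labels = _som_1d(X, config.K, config.seed)
    else:
        D = pairwise_distances(X, config.distance)
        if alg == "Hierarchical":
            Z = linkage(squareform(D, checks=False), method="average")
            labels = fcluster(Z, t=config.K, criterion="maxclust")
        elif alg == "Ncut":
            labels = _ncut(D, config.K)
        elif alg == "AP":
            labels = _ap(D)
        else:  # pragma: no cover
            raise ValueError(alg)
    return ClusterSet(config=config, assignment=labels)


def build_mca(dataset: QuantDataset, configs, version: str = "") -> MCA:
    """Run every non-degenerate configuration and assemble the ensemble.

    Degenerate configs (transform undefined on this dataset) are skipped and
    recorded in the manifest; seeds of non-deterministic configs are recorded
    for exact reproduction.
    """
    sets: list[ClusterSet] = []
    manifest = RunManifest(software_version=version)
    for config in configs:
        try:
            sets.append(run_clustering(dataset, config))
        except DegenerateTransform as exc:
            manifest.skipped_configs.append(config.key)
            warnings.warn(f"skipping degenerate config {config.key}: {exc}", stacklevel=2)
            continue
        if config.seed is not None:
            manifest.seeds[config.key] = config.seed
    if not sets:
        raise ValueError("all configurations degenerate; empty ensemble")
    return MCA(cluster_sets=sets, manifest=manifest)
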