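"""Hypergeometric label enrichment with per-set, per-category FDR control.

Every cluster of every clusterset is tested for overrepresentation of each
categorical label it contains, against the full-dataset background: with N
dataset peptides, K_label of them carrying the label, and a cluster of n
peptides containing k carriers, the p-value is the hypergeometric upper tail
P(X >= k). Benjamini–Hochberg correction is applied per (clusterset,
category) family — all tests within a category across the clusters of one
set are accumulated into a single family, at alpha 0.05 by default.

Besides externally supplied biological annotations, four *dynamic* metrics
computed from the untransformed data (minimum value, maximum value, maximum
consecutive increase, maximum consecutive decrease) are discretized into
dataset-wide quartile bins and enriched like any other category, acting as
markers for the temporal features that drove a clustering outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cluster_engine import MCA, ClusterSet
from .dataio import AnnotationTable, QuantDataset

DYNAMIC_METRICS = ("MinValue", "MaxValue", "MaxPosChange", "MaxNegChange")

ENRICHMENT_COLUMNS = [
    "set_id",
    "category",
    "cluster",
    "label",
    "k",
    "n",
    "K",
    "N",
    "p",
    "significant",
]


def hypergeom_tail(N: int, K_label: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K_label, n)."""
    if not (0 <= K_label <= N):
        raise ValueError("require 0 <= K_label <= N")
    if not (0 <= k <= n <= N):
        raise ValueError("require 0 <= k <= n <= N")
    if k > K_label:
        raise ValueError("k cannot exceed the number of label carriers")
    return float(hypergeom.sf(k - 1, N, K_label, n))


def bh_fdr(pvalues, alpha: float = 0.05, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags (Bonferroni via method flag)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method=method)
    return reject


@dataclass
class DynamicLabeling:
    """Quartile-binned dynamic statistics per peptide, as enrichable labels."""

    stats: pd.DataFrame  # one column per metric, indexed by peptide_id
    labels: pd.DataFrame  # long form: peptide_id, category, label


def _quantile_bin(series: pd.Series, n_bins: int) -> pd.Series:
    try:
        binned = pd.qcut(series, q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        binned = pd.Series(np.zeros(len(series), dtype=int), index=series.index)
    binned = binned.fillna(0)  # constant series: qcut collapses to no bins
    if binned.nunique() < n_bins:
        warnings.warn(
            f"degenerate quantiles for {series.name}: {binned.nunique()} bin(s) "
            f"instead of {n_bins}",
            stacklevel=3,
        )
    return binned.astype(int) + 1


def dynamic_labels(dataset: QuantDataset, n_bins: int = 4) -> DynamicLabeling:
    """Compute the four dynamic metrics and bin them into dataset-wide quantiles.

    MaxPosChange is the largest consecutive increase along the condition axis
    (0 if the row never increases); MaxNegChange the largest-magnitude
    consecutive decrease (0 if it never decreases). Bins are labeled
    ``<Metric>:Q<i>``.
    """
    V = dataset.values
    steps = np.diff(V, axis=1)
    stats = pd.DataFrame(
        {
            "MinValue": V.min(axis=1),
            "MaxValue": V.max(axis=1),
            "MaxPosChange": np.maximum(steps, 0).max(axis=1),
            "MaxNegChange": np.maximum(-steps, 0).max(axis=1),
        },
        index=pd.Index(dataset.peptide_ids, name="peptide_id"),
    )
    rows = []
    for metric in DYNAMIC_METRICS:
        bins = _quantile_bin(stats[metric], n_bins)
        for pid, b in bins.items():
            rows.append((pid, metric, f"{metric}:Q{b}"))
    labels = pd.DataFrame(rows, columns=["peptide_id", "category", "label"])
    return DynamicLabeling(stats=stats, labels=labels)


def _category_label_map(
    annotations: AnnotationTable | None, dynamics: DynamicLabeling | None
) -> dict[str, dict[str, set[str]]]:
    """category -> label -> peptide-id set, merging annotations and dynamics."""
    out: dict[str, dict[str, set[str]]] = {}
    frames = []
    if annotations is not None:
        frames.append(annotations.records[["peptide_id", "category", "label"]])
    if dynamics is not None:
        frames.append(dynamics.labels)
    if not frames:
        raise ValueError("no annotations to enrich")
    combined = pd.concat(frames, ignore_index=True)
    for (cat, lab), g in combined.groupby(["category", "label"], sort=True):
        out.setdefault(cat, {})[lab] = set(g["peptide_id"])
    return out


def enrich_set(
    cluster_set: ClusterSet,
    dataset: QuantDataset,
    annotations: AnnotationTable | None = None,
    dynamics: DynamicLabeling | None = None,
    alpha: float = 0.05,
    set_id: int = 0,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Enrichment records for every (cluster, category, observed label).

    Only labels with k >= 1 in a cluster are recorded, but the BH family size
    m counts all such tests accumulated within the (set, category) family
    across the whole clusterset. Background N is all dataset peptides.
    """
    label_map = _category_label_map(annotations, dynamics)
    N = dataset.n_peptides
    pid = np.asarray(dataset.peptide_ids)
    rows = []
    for category, labels in label_map.items():
        for cluster in range(1, cluster_set.k_eff + 1):
            members = set(pid[cluster_set.members(cluster)])
            n = len(members)
            for label, carriers in labels.items():
                k = len(members & carriers)
                if k == 0:
                    continue
                p = hypergeom_tail(N, len(carriers), n, k)
                rows.append((set_id, category, cluster, label, k, n, len(carriers), N, p))
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if df.empty:
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["significant"] = False
    for _, idx in df.groupby("category").groups.items():
        df.loc[idx, "significant"] = bh_fdr(df.loc[idx, "p"], alpha=alpha, method=method)
    return df


def enrich_mca(
    mca: MCA,
    dataset: QuantDataset,
    annotations: AnnotationTable | None = None,
    dynamics: DynamicLabeling | None = None,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Concatenated enrichment records for every clusterset in the ensemble.

    FDR families remain per (set, category); ``set_id`` is the position of the
    clusterset within the MCA.
    """
    if len(mca) == 0:
        raise ValueError("empty MCA")
    tables = [
        enrich_set(cs, dataset, annotations, dynamics, alpha=alpha, set_id=i, method=method)
        for i, cs in enumerate(mca)
    ]
    return pd.concat(tables, ignore_index=True)


def enrich_group(
    group: set[str],
    dataset: QuantDataset,
    annotations: AnnotationTable | None = None,
    dynamics: DynamicLabeling | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-test one peptide group (e.g. a robust cluster) against the dataset.

    The group is treated as a single cluster; BH families are per category.
    """
    unknown = group - set(dataset.peptide_ids)
    if unknown:
        raise ValueError(f"group peptides absent from dataset: {sorted(unknown)}")
    label_map = _category_label_map(annotations, dynamics)
    N = dataset.n_peptides
    n = len(group)
    rows = []
    for category, labels in label_map.items():
        for label, carriers in labels.items():
            k = len(group & carriers)
            if k == 0:
                continue
            p = hypergeom_tail(N, len(carriers), n, k)
            rows.append((0, category, 1, label, k, n, len(carriers), N, p))
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if df.empty:
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["significant"] = False
    for _, idx in df.groupby("category").groups.items():
        df.loc[idx, "significant"] = bh_fdr(df.loc[idx, "p"], alpha=alpha)
    return df


def significant_counts(enrichment: pd.DataFrame, by_category: bool = False) -> pd.Series:
    """Number of significant labels per set (optionally per set × category)."""
    sig = enrichment[enrichment["significant"]]
    if by_category:
        return sig.groupby(["set_id", "category"]).size()
    return sig.groupby("set_id").size()
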