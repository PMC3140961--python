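"""Mining the clustering ensemble: partition agreement, parameter–metric
relationships, consensus co-occurrence and cross-dataset comparison.

Partitions are compared by mutual information computed from their joint
cluster-membership distribution (in nats). The consensus view of the
ensemble is the co-occurrence matrix — for every pair of peptides, the
number of clustersets in which they share a cluster. Robust peptide groups
are extracted either label-centrically (peptides that repeatedly sit in a
cluster enriched for a chosen label) or peptide-centrically (everything that
co-clusters with a chosen peptide at least half the time), and two ensembles
built on overlapping measurements are compared through the correlation of
their co-occurrence frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cluster_engine import MCA, ClusterConfig
from .dataio import QuantDataset
from .enrichment import bh_fdr, hypergeom_tail
from .refinement import _parameter_values, _sets_with

# --- mutual information ----------------------------------------------------


def partition_entropy(assignment) -> float:
    """Shannon entropy (nats) of a partition's cluster-size distribution."""
    _, counts = np.unique(np.asarray(assignment), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(part_a, part_b) -> float:
    """I(X;Y) in nats between two partitions of the same peptides.

    Probabilities are co-membership frequencies over the n peptides;
    0·ln(0) = 0 by convention.
    """
    a = np.asarray(part_a)
    b = np.asarray(part_b)
    if a.shape != b.shape:
        raise ValueError("partitions index different peptides")
    n = a.size
    joint = pd.crosstab(a, b).to_numpy() / n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


@dataclass
class MIMatrix:
    """Symmetric pairwise mutual-information matrix over an ensemble."""

    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values)


def mi_matrix(mca: MCA) -> MIMatrix:
    """Pairwise MI between every pair of clustersets (diagonal = entropy)."""
    if len(mca) < 2:
        raise ValueError("MI matrix needs at least 2 sets")
    m = len(mca)
    M = np.zeros((m, m))
    for i in range(m):
        M[i, i] = partition_entropy(mca[i].assignment)
        for j in range(i + 1, m):
            M[i, j] = M[j, i] = mutual_information(mca[i].assignment, mca[j].assignment)
    return MIMatrix(values=M)


def subset_mean_mi(mca: MCA, mi: MIMatrix, axis: str, value) -> float:
    """Mean off-diagonal MI among the sets sharing one parameter value."""
    idx = _sets_with(mca.configs(), axis, value)
    if len(idx) < 2:
        raise ValueError(f"fewer than 2 sets share {axis}={value!r}")
    sub = mi.values[np.ix_(idx, idx)]
    off = sub[np.triu_indices_from(sub, k=1)]
    return float(off.mean())


# --- parameter–metric quartile analysis ------------------------------------


def rank_sets(enrichment: pd.DataFrame, category: str) -> list[int]:
    """Set ids ordered by decreasing significant-label count in *category*.

    Sets with zero significant labels in the category are included at the
    bottom; ties break by set id for determinism.
    """
    all_sets = sorted(enrichment["set_id"].unique())
    if category not in set(enrichment["category"]):
        raise ValueError(f"category {category!r} absent from enrichment table")
    sig = enrichment[enrichment["significant"] & (enrichment["category"] == category)]
    counts = sig.groupby("set_id").size().reindex(all_sets, fill_value=0)
    order = sorted(all_sets, key=lambda s: (-counts[s], s))
    return order


def quartile_size(m: int) -> int:
    return math.ceil(m / 4)


def quartile_parameter_enrichment(
    ranked: list[int],
    configs: list[ClusterConfig],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Overrepresentation of each clustering parameter in the top/bottom quartile.

    Population = all M sets; successes = the sets carrying the parameter;
    sample = the ceil(M/4) sets of the quartile; hypergeometric upper tail,
    BH-corrected across all (parameter, quartile) tests of the metric.
    """
    if len(ranked) < 4:
        raise ValueError("need at least 4 sets for quartile analysis")
    M = len(ranked)
    q = quartile_size(M)
    quartiles = {"top": set(ranked[:q]), "bottom": set(ranked[-q:])}
    rows = []
    for axis, value in _parameter_values(configs):
        carriers = set(_sets_with(configs, axis, value))
        for which, members in quartiles.items():
            k = len(carriers & members)
            p = hypergeom_tail(M, len(carriers), q, k)
            rows.append(
                {
                    "axis": axis,
                    "value": value,
                    "quartile": which,
                    "k": k,
                    "q": q,
                    "carriers": len(carriers),
                    "M": M,
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    df["significant"] = bh_fdr(df["p"], alpha=alpha)
    return df


def metric_overlap_bootstrap(
    rank_a: list[int],
    rank_b: list[int],
    quartile: str = "top",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Compare the quartile overlap of two metric rankings to a bootstrap null.

    Draws ``n_boot`` pairs of random same-size subsets from the common set
    universe to form a normal null for the overlap; classifies the observed
    overlap as ``pos_sig`` / ``neg_sig`` / ``ns`` two-sided at *alpha*.
    """
    if set(rank_a) != set(rank_b):
        raise ValueError("rankings must cover the same set universe")
    universe = np.asarray(sorted(rank_a))
    M = universe.size
    q = quartile_size(M)
    if q < 1:
        raise ValueError("quartile size < 1")
    if quartile == "top":
        sub_a, sub_b = set(rank_a[:q]), set(rank_b[:q])
    elif quartile == "bottom":
        sub_a, sub_b = set(rank_a[-q:]), set(rank_b[-q:])
    else:
        raise ValueError("quartile must be 'top' or 'bottom'")
    observed = len(sub_a & sub_b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for i in range(n_boot):
        x = set(rng.choice(M, size=q, replace=False))
        y = set(rng.choice(M, size=q, replace=False))
        null[i] = len(x & y)
    mean, sd = null.mean(), null.std(ddof=1)
    if sd == 0:
        p = 1.0 if observed == mean else 0.0
    else:
        p = 2 * norm.sf(abs(observed - mean) / sd)
    if p <= alpha:
        verdict = "pos_sig" if observed > mean else "neg_sig"
    else:
        verdict = "ns"
    return {
        "observed": observed,
        "null_mean": float(mean),
        "null_sd": float(sd),
        "p": float(min(p, 1.0)),
        "verdict": verdict,
    }


# --- co-occurrence ---------------------------------------------------------


@dataclass
class CoOccurrenceMatrix:
    """Pairwise co-clustering counts over an ensemble of M clustersets."""

    counts: np.ndarray
    M: int
    peptide_ids: list[str]

    @property
    def freq(self) -> np.ndarray:
        return self.counts / self.M

    def heatmap_values(self) -> np.ndarray:
        """log10 of frequencies with zeros replaced by the 0.5/M pseudo-count."""
        f = self.freq.copy()
        f[f == 0] = 0.5 / self.M
        return np.log10(f)

    def index_of(self, peptide_id: str) -> int:
        try:
            return self.peptide_ids.index(peptide_id)
        except ValueError:
            raise KeyError(f"unknown peptide: {peptide_id}") from None


def co_occurrence(mca: MCA, dataset: QuantDataset) -> CoOccurrenceMatrix:
    """Count, for every peptide pair, the sets in which they share a cluster."""
    if len(mca) == 0:
        raise ValueError("empty MCA")
    n = dataset.n_peptides
    counts = np.zeros((n, n), dtype=int)
    for cs in mca:
        same = cs.assignment[:, None] == cs.assignment[None, :]
        counts += same
    return CoOccurrenceMatrix(counts=counts, M=len(mca), peptide_ids=list(dataset.peptide_ids))


def co_occurrence_summary(co: CoOccurrenceMatrix) -> dict:
    """Pair-level summary: never-co-clustering and majority pairs.

    With 77 peptides there are 2,926 unordered pairs; majority pairs are
    those co-clustering in more than half the sets. Percentages are rounded
    to one decimal.
    """
    iu = np.triu_indices_from(co.counts, k=1)
    counts = co.counts[iu]
    freq = co.freq[iu]
    n_pairs = counts.size
    n_never = int((counts == 0).sum())
    n_majority = int((freq > 0.5).sum())
    return {
        "n_pairs": int(n_pairs),
        "n_never": n_never,
        "pct_never": round(100.0 * n_never / n_pairs, 1),
        "n_majority": n_majority,
        "pct_majority": round(100.0 * n_majority / n_pairs, 1),
        "median_count": float(np.median(counts)),
    }


# --- robust groups ---------------------------------------------------------


def robust_cluster_by_label(
    mca: MCA,
    enrichment: pd.DataFrame,
    dataset: QuantDataset,
    category: str,
    label: str,
    threshold: float = 0.5,
) -> set[str]:
    """Peptides sitting in a *label*-enriched cluster in >= threshold of the
    sets where the label is enriched at all.

    The denominator is the number of clustersets in which the label reaches
    significance in some cluster, not the whole ensemble.
    """
    sig = enrichment[
        enrichment["significant"]
        & (enrichment["category"] == category)
        & (enrichment["label"] == label)
    ]
    if sig.empty:
        raise ValueError(f"label {label!r} is never enriched in category {category!r}")
    enriched_sets = sig.groupby("set_id")["cluster"].apply(set)
    pid = np.asarray(dataset.peptide_ids)
    participation = pd.Series(0, index=dataset.peptide_ids, dtype=int)
    for set_id, clusters in enriched_sets.items():
        cs = mca[set_id]
        in_enriched = np.isin(cs.assignment, list(clusters))
        participation[pid[in_enriched]] += 1
    frac = participation / len(enriched_sets)
    return set(frac.index[frac >= threshold])


def peptide_centric_cluster(
    co: CoOccurrenceMatrix, peptide_id: str, threshold: float = 0.5
) -> set[str]:
    """All peptides co-clustering with *peptide_id* at least *threshold* of the
    time, plus the seed peptide itself."""
    i = co.index_of(peptide_id)
    f = co.freq[i]
    group = {co.peptide_ids[j] for j in np.flatnonzero(f >= threshold) if j != i}
    group.add(peptide_id)
    return group


# --- cross-dataset comparison ----------------------------------------------


def _shared_triangle(
    co_a: CoOccurrenceMatrix, co_b: CoOccurrenceMatrix, shared: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    ia = [co_a.index_of(p) for p in shared]
    ib = [co_b.index_of(p) for p in shared]
    fa = co_a.freq[np.ix_(ia, ia)]
    fb = co_b.freq[np.ix_(ib, ib)]
    iu = np.triu_indices(len(shared), k=1)
    return fa[iu], fb[iu]


def compare_co_occurrence(
    co_a: CoOccurrenceMatrix, co_b: CoOccurrenceMatrix, shared: list[str]
) -> float:
    """Pearson correlation of co-occurrence frequencies over shared peptides."""
    if len(shared) < 3:
        raise ValueError("need at least 3 shared peptides")
    fa, fb = _shared_triangle(co_a, co_b, shared)
    if fa.std() == 0 or fb.std() == 0:
        raise ValueError("zero variance in co-occurrence frequencies")
    return float(np.corrcoef(fa, fb)[0, 1])


def extreme_differences(
    co_a: CoOccurrenceMatrix,
    co_b: CoOccurrenceMatrix,
    shared: list[str],
    hi: float = 0.75,
    lo: float = 0.25,
) -> pd.DataFrame:
    """Peptide pairs swapping from robust co-clustering in one ensemble
    (freq >= hi) to rare co-clustering in the other (freq < lo), both ways."""
    if len(shared) < 2:
        raise ValueError("need at least 2 shared peptides")
    fa, fb = _shared_triangle(co_a, co_b, shared)
    iu = np.triu_indices(len(shared), k=1)
    rows = []
    for idx in range(fa.size):
        i, j = iu[0][idx], iu[1][idx]
        if fa[idx] >= hi and fb[idx] < lo:
            rows.append((shared[i], shared[j], fa[idx], fb[idx], "a_to_b"))
        elif fb[idx] >= hi and fa[idx] < lo:
            rows.append((shared[i], shared[j], fa[idx], fb[idx], "b_to_a"))
    return pd.DataFrame(rows, columns=["peptide_1", "peptide_2", "freq_a", "freq_b", "direction"])
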