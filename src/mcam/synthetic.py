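"""Synthetic phosphoproteomic datasets with planted structure, and the two
randomization controls used to measure the empirical false-positive rate.

The generator emulates the shape of a tyrosine-phosphorylation time course
study: positive relative phosphorylation values, a handful of temporal
archetypes (transient, sustained, late-rising, ...), multiplicative
log-normal noise, and annotation categories whose labels are preferentially
co-assigned within each planted group on top of uniform background labels.

The controls destroy structure two ways: reshuffling the data matrix
globally (breaking both temporal and peptide structure) or permuting the
peptide-to-annotation mapping. Enrichment on controls measures Type I error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_engine import MCA, build_mca
from .dataio import AnnotationTable, QuantDataset
from .enrichment import dynamic_labels, enrich_mca

DEFAULT_TEMPLATES = {
    # relative phosphorylation archetypes over a 0/5/10/30-minute course
    "transient": [1.0, 4.0, 2.0, 1.0],
    "sustained": [1.0, 3.0, 3.5, 3.0],
    "late": [1.0, 1.2, 2.0, 4.0],
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror a 77-peptide, 4-timepoint tyrosine phosphorylation
    course with three temporal groups, ~10% multiplicative noise, and three
    annotation categories with strong within-group label sharing.
    """

    n_peptides: int = 77
    n_conditions: int = 4
    n_groups: int = 3
    templates: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_TEMPLATES.items()}
    )
    noise_sd: float = 0.1
    categories: tuple[str, ...] = ("F", "P", "Pfam")
    within_prob: float = 0.8
    background_prob: float = 0.05
    n_background_labels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups > self.n_peptides:
            raise ValueError("more groups than peptides")
        if len(self.templates) < self.n_groups:
            raise ValueError("need one template per group")
        for name, t in self.templates.items():
            t = np.asarray(t, dtype=float)
            if t.size != self.n_conditions:
                raise ValueError(f"template {name!r} length != n_conditions")
            if np.any(t <= 0):
                raise ValueError(f"template {name!r} must be positive")
        for p in (self.within_prob, self.background_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def generate_dataset(spec: SyntheticSpec) -> tuple[QuantDataset, np.ndarray]:
    """Planted-group dataset: row i = template(group i) × exp(Normal(0, sd²)).

    Groups are balanced up to remainder; returns the dataset and the planted
    group index per peptide. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    template_names = list(spec.templates)[: spec.n_groups]
    groups = np.arange(spec.n_peptides) % spec.n_groups
    T = np.vstack([spec.templates[template_names[g]] for g in groups])
    noise = np.exp(rng.normal(0.0, spec.noise_sd, size=T.shape))
    values = T * noise
    dataset = QuantDataset(
        peptide_ids=[f"pep{i:03d}" for i in range(spec.n_peptides)],
        protein_accs=[f"PROT{groups[i]}{i:03d}" for i in range(spec.n_peptides)],
        site_labels=[f"Y{100 + i}" for i in range(spec.n_peptides)],
        conditions=[f"t{t}" for t in (0, 5, 10, 30)][: spec.n_conditions]
        if spec.n_conditions <= 4
        else [f"t{i}" for i in range(spec.n_conditions)],
        values=values,
    )
    return dataset, groups


def generate_annotations(
    dataset: QuantDataset, groups: np.ndarray, spec: SyntheticSpec
) -> AnnotationTable:
    """Annotation table with one planted label per (group, category).

    Group-g peptides receive the planted label of their group with
    probability ``within_prob``; every peptide receives each of the
    background labels with probability ``background_prob``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for cat in spec.categories:
        for g in range(spec.n_groups):
            label = f"{cat}:planted{g}"
            for i, pid in enumerate(dataset.peptide_ids):
                if groups[i] == g and rng.random() < spec.within_prob:
                    rows.append((pid, cat, label))
        for b in range(spec.n_background_labels):
            label = f"{cat}:bg{b}"
            for pid in dataset.peptide_ids:
                if rng.random() < spec.background_prob:
                    rows.append((pid, cat, label))
    if not rows:
        raise ValueError("annotation generation produced no records")
    df = pd.DataFrame(rows, columns=["peptide_id", "category", "label"])
    df = df.drop_duplicates(subset=["peptide_id", "category", "label"])
    return AnnotationTable(records=df)


def shuffle_matrix(dataset: QuantDataset, seed: int, within_columns: bool = False) -> QuantDataset:
    """Randomization control 1: permute the data matrix, ids unchanged.

    Default permutes all n×T values globally (the stronger null, destroying
    temporal and peptide structure alike); ``within_columns=True`` permutes
    each condition column independently instead.
    """
    rng = np.random.default_rng(seed)
    values = dataset.values.copy()
    if within_columns:
        for j in range(values.shape[1]):
            values[:, j] = rng.permutation(values[:, j])
    else:
        flat = rng.permutation(values.ravel())
        values = flat.reshape(values.shape)
    return QuantDataset(
        peptide_ids=list(dataset.peptide_ids),
        protein_accs=list(dataset.protein_accs),
        site_labels=list(dataset.site_labels),
        conditions=list(dataset.conditions),
        values=values,
    )


def shuffle_labels(
    dataset: QuantDataset, annotations: AnnotationTable, seed: int
) -> AnnotationTable:
    """Randomization control 2: permute the peptide→annotation mapping.

    A uniform random bijection over the dataset's peptide ids is applied to
    the annotation table's peptide column; label multisets per category are
    preserved exactly.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(dataset.peptide_ids)
    mapping = dict(zip(ids, rng.permutation(ids)))
    df = annotations.records.copy()
    df["peptide_id"] = df["peptide_id"].map(mapping)
    return AnnotationTable(records=df)


def empirical_fpr(control_tables: list[pd.DataFrame]) -> pd.Series:
    """Per-category rejection rate pooled over control repetitions and sets.

    Every test on randomized data that reaches significance is a false
    positive; the rate is (significant tests)/(all tests) per category.
    """
    if not control_tables:
        raise ValueError("no control enrichment tables")
    combined = pd.concat(control_tables, ignore_index=True)
    if combined.empty:
        raise ValueError("control enrichment tables are empty")
    totals = combined.groupby("category").size()
    rejected = combined.groupby("category")["significant"].sum()
    return (rejected / totals).astype(float)


def reduced_control_grid(seed: int = 0):
    """A reduced but algorithm-complete grid for control experiments.

    4 transforms × 3 distances × all 5 algorithms × K in {2, 4, 6} under the
    usual constraints → 132 configurations, a tractable stand-in for the full
    1,320-set grid that still exercises every algorithm family.
    """
    from .cluster_engine import expand_grid

    return expand_grid(
        ["raw", "center", "zscore", "normMax"],
        ["euclidean", "cityblock", "correlation"],
        ["Ncut", "AP", "SOM", "Kmeans", "Hierarchical"],
        [2, 4, 6],
        seed=seed,
    )


def null_rejection_rates(
    configs,
    n_reps: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    spec: SyntheticSpec | None = None,
    include_dynamics: bool = True,
) -> pd.Series:
    """Full randomized-control experiment: per-category empirical FPR.

    For each repetition, generates a no-signal synthetic dataset (random
    annotations: within-group probability equal to background), applies the
    matrix-shuffle control, clusters the shuffled data with *configs*, runs
    enrichment at BH alpha, and pools rejection rates per category.
    """
    if spec is None:
        spec = SyntheticSpec()
    tables = []
    for rep in range(n_reps):
        rep_seed = (seed + 1000 * rep) % (2**31 - 1)
        rep_spec = SyntheticSpec(
            n_peptides=spec.n_peptides,
            n_conditions=spec.n_conditions,
            n_groups=spec.n_groups,
            templates=spec.templates,
            noise_sd=spec.noise_sd,
            categories=spec.categories,
            within_prob=spec.background_prob,  # no signal
            background_prob=spec.background_prob,
            n_background_labels=spec.n_background_labels,
            seed=rep_seed,
        )
        dataset, groups = generate_dataset(rep_spec)
        annotations = generate_annotations(dataset, groups, rep_spec)
        # dynamic bins come from the original data; the shuffle then breaks
        # any association between those labels and the clustered structure
        dynamics = dynamic_labels(dataset) if include_dynamics else None
        shuffled = shuffle_matrix(dataset, seed=rep_seed + 1)
        mca = build_mca(shuffled, configs)
        tables.append(enrich_mca(mca, shuffled, annotations, dynamics, alpha=alpha))
    return empirical_fpr(tables)
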