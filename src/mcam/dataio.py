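"""Input/output for quantitative datasets, annotation tables and run manifests.

The quantitative dataset is a wide TSV — one row per phosphopeptide with
identity columns (``peptide_id``, ``protein_acc``, ``site``) followed by one
numeric column per condition/timepoint. Annotations travel in a long TSV of
``peptide_id  category  label  [score]`` records, one row per assignment of a
categorical label (GO term, Pfam domain, predicted kinase, sequence motif,
...) to a peptide. Scored categories (Scansite predictions, domain p-values)
can be filtered by stringency before enrichment.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ID_COLUMNS = ("peptide_id", "protein_acc", "site")


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass
class QuantDataset:
    """A peptide × condition matrix with peptide identity metadata.

    Row order defines the peptide index used by every downstream module:
    partitions, co-occurrence matrices and enrichment records all refer to
    peptides by their position here.
    """

    peptide_ids: list[str]
    protein_accs: list[str]
    site_labels: list[str]
    conditions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.peptide_ids)
        if len(set(self.peptide_ids)) != n:
            dupes = sorted({p for p in self.peptide_ids if self.peptide_ids.count(p) > 1})
            raise DataError(f"duplicate peptide id: {dupes}")
        if self.values.shape != (n, len(self.conditions)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{n} peptides x {len(self.conditions)} conditions"
            )
        if len(self.conditions) < 2:
            raise DataError("at least 2 conditions are required")
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite value in data matrix")

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def index_of(self, peptide_id: str) -> int:
        try:
            return self.peptide_ids.index(peptide_id)
        except ValueError:
            raise KeyError(f"unknown peptide: {peptide_id}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.conditions)
        df.insert(0, "site", self.site_labels)
        df.insert(0, "protein_acc", self.protein_accs)
        df.insert(0, "peptide_id", self.peptide_ids)
        return df


@dataclass
class AnnotationTable:
    """Long-form categorical annotations: (peptide_id, category, label[, score]).

    ``records`` is a DataFrame with columns peptide_id/category/label/score
    (score is NaN where absent). Triples are unique.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["peptide_id", "category", "label"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise DataError(f"annotation table missing columns: {missing}")
        if "score" not in self.records.columns:
            self.records = self.records.assign(score=np.nan)
        self.records = self.records[required + ["score"]].reset_index(drop=True)
        scores = self.records["score"]
        if np.any(np.isinf(scores.to_numpy(dtype=float, na_value=np.nan))):
            raise DataError("infinite annotation score")

    @property
    def categories(self) -> list[str]:
        return sorted(self.records["category"].unique())

    def labels_for(self, category: str) -> dict[str, set[str]]:
        """Map each label in *category* to the set of peptide ids carrying it."""
        sub = self.records[self.records["category"] == category]
        return {lab: set(g["peptide_id"]) for lab, g in sub.groupby("label", sort=True)}

    def peptides_with(self, category: str, label: str) -> set[str]:
        mask = (self.records["category"] == category) & (self.records["label"] == label)
        return set(self.records.loc[mask, "peptide_id"])


@dataclass
class RunManifest:
    """Provenance of one ensemble run: seeds, config digest, input checksums.

    Every non-deterministic clusterset records its seed so the run can be
    reproduced exactly.
    """

    config_digest: str = ""
    software_version: str = ""
    seeds: dict[str, int] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    skipped_configs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def file_checksum(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def read_dataset(path) -> QuantDataset:
    """Read a wide TSV into a :class:`QuantDataset`.

    Expected columns: ``peptide_id  protein_acc  site  <cond1> ... <condT>``.
    Condition order is preserved. Raises :class:`DataError` on duplicate
    peptide ids, non-numeric values or fewer than two condition columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise DataError(f"dataset missing required column {col!r}")
    cond_cols = [c for c in df.columns if c not in ID_COLUMNS]
    if len(cond_cols) < 2:
        raise DataError("dataset needs at least 2 condition columns")
    try:
        values = df[cond_cols].astype(float).to_numpy()
    except ValueError as exc:
        raise DataError(f"non-numeric cell in value block: {exc}") from exc
    return QuantDataset(
        peptide_ids=df["peptide_id"].tolist(),
        protein_accs=df["protein_acc"].tolist(),
        site_labels=df["site"].tolist(),
        conditions=cond_cols,
        values=values,
    )


def write_dataset(dataset: QuantDataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_annotations(path, dataset: QuantDataset) -> AnnotationTable:
    """Read a long annotation TSV, restricted to peptides in *dataset*.

    Records naming peptides absent from the dataset are dropped with a
    warning; duplicate (peptide, category, label) triples are deduplicated.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "category": str, "label": str})
    if df.empty:
        raise DataError("empty annotation table")
    return _build_annotations(df, dataset)


def _build_annotations(df: pd.DataFrame, dataset: QuantDataset) -> AnnotationTable:
    known = set(dataset.peptide_ids)
    unknown = ~df["peptide_id"].isin(known)
    if unknown.any():
        warnings.warn(
            f"dropping {int(unknown.sum())} annotation record(s) for peptides "
            "absent from the dataset",
            stacklevel=3,
        )
        df = df[~unknown]
    before = len(df)
    df = df.drop_duplicates(subset=["peptide_id", "category", "label"])
    if len(df) < before:
        warnings.warn(f"deduplicated {before - len(df)} annotation record(s)", stacklevel=3)
    if df.empty:
        raise DataError("annotation table empty after filtering to dataset peptides")
    return AnnotationTable(records=df.reset_index(drop=True))


def write_annotations(table: AnnotationTable, path) -> None:
    df = table.records.copy()
    if df["score"].isna().all():
        df = df.drop(columns=["score"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def filter_annotations(
    table: AnnotationTable, category: str, threshold: float, direction: str = "le"
) -> AnnotationTable:
    """Keep only records of *category* whose score passes the stringency cut.

    Scansite-style levels are "three and better", i.e. score <= 3
    (``direction="le"``); Pfam domain p-values use the same direction with
    threshold 1e-5. Records in other categories pass through untouched.
    """
    if direction not in ("le", "ge"):
        raise ValueError("direction must be 'le' or 'ge'")
    recs = table.records
    if category not in set(recs["category"]):
        raise DataError(f"unknown annotation category: {category}")
    in_cat = recs["category"] == category
    scores = recs.loc[in_cat, "score"]
    if scores.isna().all():
        raise DataError(f"category {category!r} carries no scores to filter on")
    if direction == "le":
        keep_cat = in_cat & (recs["score"] <= threshold)
    else:
        keep_cat = in_cat & (recs["score"] >= threshold)
    if not keep_cat.any():
        warnings.warn(f"score filter left category {category!r} empty", stacklevel=2)
    kept = recs[keep_cat | ~in_cat].reset_index(drop=True)
    return AnnotationTable(records=kept)


def normalize_to_reference(dataset: QuantDataset, ref_condition: str) -> QuantDataset:
    """Divide each row by its value at *ref_condition* (which becomes 1)."""
    if ref_condition not in dataset.conditions:
        raise DataError(f"unknown condition: {ref_condition}")
    j = dataset.conditions.index(ref_condition)
    ref = dataset.values[:, j]
    if np.any(ref == 0):
        bad = [dataset.peptide_ids[i] for i in np.flatnonzero(ref == 0)]
        raise DataError(f"zero at reference condition for peptide(s): {bad}")
    return QuantDataset(
        peptide_ids=list(dataset.peptide_ids),
        protein_accs=list(dataset.protein_accs),
        site_labels=list(dataset.site_labels),
        conditions=list(dataset.conditions),
        values=dataset.values / ref[:, None],
    )
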