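"""Parameter pruning by biological-information yield.

For every individual parameter value in the grid (each transform, distance,
algorithm and K), the ensemble is re-scored with all clustersets carrying
that parameter removed. A parameter is pruned when its removal improves
total enrichment across all categories by at least 2% (relative) without
decreasing the enrichment of any single category by more than 10%.

"Total enrichment" is normalized per set — the mean number of significant
labels per clusterset — since removing sets necessarily shrinks raw totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cluster_engine import MCA, ClusterConfig


@dataclass
class PruneReport:
    """Per-parameter removal deltas and the resulting prune decisions."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    pruned_parameters: list[tuple[str, object]] = field(default_factory=list)
    aborted: bool = False


def _set_category_counts(mca: MCA, enrichment: pd.DataFrame) -> pd.DataFrame:
    """Significant-label counts, one row per set, one column per category."""
    sig = enrichment[enrichment["significant"]]
    counts = sig.groupby(["set_id", "category"]).size().unstack(fill_value=0)
    return counts.reindex(range(len(mca)), fill_value=0).fillna(0)


def enrichment_score(
    set_ids,
    enrichment: pd.DataFrame,
    category: str | None = None,
) -> float:
    """Mean significant labels per set over *set_ids*, optionally one category."""
    set_ids = list(set_ids)
    if not set_ids:
        raise ValueError("empty set subset")
    sig = enrichment[enrichment["significant"] & enrichment["set_id"].isin(set_ids)]
    if category is not None:
        sig = sig[sig["category"] == category]
    return len(sig) / len(set_ids)


def _parameter_values(configs: list[ClusterConfig]):
    """Distinct (axis, value) pairs present in the grid."""
    seen: list[tuple[str, object]] = []
    for axis in ("transform", "distance", "algorithm", "K"):
        for c in configs:
            v = getattr(c, axis)
            if v is None:
                continue
            if (axis, v) not in seen:
                seen.append((axis, v))
    return seen


def _sets_with(configs: list[ClusterConfig], axis: str, value) -> list[int]:
    return [i for i, c in enumerate(configs) if getattr(c, axis) == value]


def evaluate_removal(
    mca: MCA,
    enrichment: pd.DataFrame,
    axis: str,
    value,
) -> tuple[float, dict[str, float]]:
    """Relative enrichment changes when all sets carrying a parameter are removed.

    Returns (overall relative delta, per-category relative deltas); positive
    means removal *improves* the per-set mean. A category scoring zero both
    before and after contributes delta 0.
    """
    configs = mca.configs()
    carriers = set(_sets_with(configs, axis, value))
    if not carriers:
        raise ValueError(f"parameter {axis}={value!r} not present in any config")
    keep = [i for i in range(len(mca)) if i not in carriers]
    if not keep:
        raise ValueError(f"removing {axis}={value!r} would empty the MCA")
    counts = _set_category_counts(mca, enrichment)

    def rel_delta(before: float, after: float) -> float:
        if before == 0:
            return 0.0 if after == 0 else float("inf")
        return (after - before) / before

    before_overall = counts.sum(axis=1).mean()
    after_overall = counts.loc[keep].sum(axis=1).mean()
    overall = rel_delta(before_overall, after_overall)
    per_category = {
        cat: rel_delta(counts[cat].mean(), counts.loc[keep, cat].mean())
        for cat in counts.columns
    }
    return overall, per_category


def prune(
    mca: MCA,
    enrichment: pd.DataFrame,
    improve_threshold: float = 0.02,
    degrade_threshold: float = 0.10,
    iterative: bool = False,
) -> tuple[MCA, PruneReport]:
    """Remove every parameter whose removal passes the improvement rule.

    Default single pass: each parameter is evaluated against the full MCA and
    all qualifying parameters are removed jointly. ``iterative=True`` repeats
    the pass on the surviving ensemble until no parameter qualifies. If the
    joint removal would empty the ensemble, pruning aborts and the original
    MCA is returned with ``report.aborted`` set.
    """
    report_rows = []
    pruned: list[tuple[str, object]] = []
    current = mca
    current_enrichment = enrichment
    while True:
        configs = current.configs()
        qualifying: list[tuple[str, object]] = []
        for axis, value in _parameter_values(configs):
            carriers = _sets_with(configs, axis, value)
            if len(carriers) == len(configs):
                continue  # removal would empty the ensemble
            overall, per_cat = evaluate_removal(current, current_enrichment, axis, value)
            worst = min(per_cat.values()) if per_cat else 0.0
            qualifies = overall >= improve_threshold and worst >= -degrade_threshold
            report_rows.append(
                {
                    "axis": axis,
                    "value": value,
                    "n_sets": len(carriers),
                    "overall_delta": overall,
                    "worst_category_delta": worst,
                    "pruned": qualifies,
                }
            )
            if qualifies:
                qualifying.append((axis, value))
        if not qualifying:
            break
        drop = set()
        for axis, value in qualifying:
            drop.update(_sets_with(configs, axis, value))
        keep = [i for i in range(len(current)) if i not in drop]
        if not keep:
            report = PruneReport(
                table=pd.DataFrame(report_rows), pruned_parameters=pruned, aborted=True
            )
            return mca, report
        pruned.extend(qualifying)
        remap = {old: new for new, old in enumerate(keep)}
        current = current.subset(keep)
        current_enrichment = current_enrichment[
            current_enrichment["set_id"].isin(keep)
        ].assign(set_id=lambda d: d["set_id"].map(remap))
        if not iterative:
            break
    report = PruneReport(table=pd.DataFrame(report_rows), pruned_parameters=pruned)
    return current, report
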