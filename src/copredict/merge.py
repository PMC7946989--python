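"""Cross-cohort integration of rule models.

Per-cohort decision tables are stacked with each cohort discretized by its
own equal-frequency cuts (levels comparable by rank, not absolute value);
rules identical in conditions and decision are unified, their supports and
support sets summed, and every statistic is then recalculated against the
merged cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Mapping, Sequence

import pandas as pd

from .preprocess import DecisionTable, discretize
from .rules import Rule, RuleModel, compute_stats
from .synthetic import ExpressionMatrix

__all__ = ["combine_tables", "aggregate_rules", "merge_models"]


def combine_tables(
    matrices: Sequence[ExpressionMatrix],
    features: Sequence[str],
    n_bins: int = 3,
    id_maps: Sequence[Mapping[str, str] | None] | None = None,
) -> DecisionTable:
    """Discretize each cohort on its own cuts and stack into one table.

    Features absent from a cohort are marked absent (NaN) for its samples;
    rules conditioning on them cannot fire there.  ``id_maps`` optionally
    translates cohort-local feature ids into the shared space.
    """
    if id_maps is None:
        id_maps = [None] * len(matrices)
    blocks: list[pd.DataFrame] = []
    decisions: list[pd.Series] = []
    for matrix, id_map in zip(matrices, id_maps):
        frame = matrix.values
        if id_map:
            renamed = frame.rename(columns=dict(id_map))
            if renamed.columns.duplicated().any():
                raise ValueError("id_map collision: two source features map to one target")
            frame = renamed
        present = [f for f in features if f in frame.columns]
        sub = frame[present]
        labels = pd.Series(
            matrix.sample_meta["class"].to_numpy(), index=frame.index, name="decision"
        )
        table, _ = discretize(sub, labels, n_bins)
        block = table.values.reindex(columns=features)  # absent features become NaN
        blocks.append(block)
        decisions.append(table.decision)
    stacked = pd.concat(blocks, axis=0)
    if stacked.index.duplicated().any():
        raise ValueError("sample ids must be globally unique across cohorts")
    return DecisionTable(values=stacked, decision=pd.concat(decisions))


def aggregate_rules(models: Sequence[RuleModel]) -> list[Rule]:
    """Unify rules identical in conditions and decision: supports summed,
    support sets unioned, provenance concatenated.  No recalculation."""
    merged: dict[tuple, Rule] = {}
    for model in models:
        for rule in model.rules:
            key = rule.key()
            if key not in merged:
                merged[key] = rule
            else:
                prev = merged[key]
                merged[key] = replace(
                    prev,
                    rs_lhs=prev.rs_lhs + rule.rs_lhs,
                    rs_rhs=prev.rs_rhs + rule.rs_rhs,
                    support_set=prev.support_set | rule.support_set,
                    provenance=tuple(dict.fromkeys(prev.provenance + rule.provenance)),
                )
    return list(merged.values())


def merge_models(models: Sequence[RuleModel], merged_table: DecisionTable) -> RuleModel:
    """Aggregate rules across cohorts and recalculate RA, RC and p on the
    merged cohort's class totals."""
    if not models:
        raise ValueError("no models to merge")
    aggregated = aggregate_rules(models)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        recalculated = compute_stats(aggregated, merged_table)
    provenance = tuple(dict.fromkeys(p for m in models for p in m.provenance))
    counts = merged_table.decision.value_counts()
    return RuleModel(
        rules=recalculated,
        class_totals=merged_table.class_totals(),
        provenance=provenance,
        majority_class=str(counts.idxmax()),
    )
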