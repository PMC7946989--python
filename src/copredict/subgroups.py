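"""Subgroup dissimilarity from subnetwork topology.

Rules are mapped to clinical subgroups through their support sets; per
subgroup a co-predictive subnetwork is built and pairs of subgroups are
compared by the Euclidean distance between their betweenness-centrality
vectors on the union node set, averaged over balanced rule resamples, with a
label-permutation null.  A Kendall tau-b distance matrix over node
connection profiles supports clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from statsmodels.stats.multitest import multipletests

from .network import CoPredNetwork, build_network
from .rules import Rule, RuleModel

__all__ = [
    "DistanceResult",
    "assign_rules_to_subgroups",
    "subtype_support_distribution",
    "betweenness_distance",
    "balanced_distance",
    "permutation_test",
    "kendall_distance_matrix",
]


@dataclass(frozen=True)
class DistanceResult:
    subgroup_a: str
    subgroup_b: str
    observed_distance: float
    permutation_p: float
    p_adjusted: float | None
    n_permutations: int
    n_balance_resamples: int
    seed: int


def _subtype_of(sample_meta: pd.DataFrame) -> pd.Series:
    meta = sample_meta.set_index("sample_id") if "sample_id" in sample_meta.columns else sample_meta
    return meta["subtype"]


def assign_rules_to_subgroups(
    model: RuleModel,
    sample_meta: pd.DataFrame,
    mode: str = "membership",
    min_share: float = 0.3,
) -> dict[str, list[Rule]]:
    """Map rules to clinical subgroups through their support sets.

    ``mode="membership"`` (default): a rule belongs to subgroup g iff its
    support set contains at least one sample of subtype g; rules may belong
    to several subgroups.  ``mode="proportional"``: the per-subtype support
    counts are normalized by subtype cohort sizes and a rule is assigned to
    the subgroups holding at least ``min_share`` of its per-capita support —
    a stricter mapping that suppresses incidental single-sample overlap.
    """
    if mode not in ("membership", "proportional"):
        raise ValueError("mode must be 'membership' or 'proportional'")
    subtype = _subtype_of(sample_meta)
    totals = subtype.value_counts()
    missing_any = False
    out: dict[str, list[Rule]] = {}
    for rule in model.rules:
        counts: dict[str, int] = {}
        for sid in rule.support_set:
            if sid not in subtype.index or pd.isna(subtype.at[sid]):
                missing_any = True
                continue
            g = str(subtype.at[sid])
            counts[g] = counts.get(g, 0) + 1
        if mode == "membership":
            chosen = list(counts)
        else:
            percap = {g: c / totals[g] for g, c in counts.items()}
            z = sum(percap.values())
            chosen = [g for g, v in percap.items() if z and v / z >= min_share]
        for g in chosen:
            out.setdefault(g, []).append(rule)
    if missing_any:
        warnings.warn("samples with missing subtype excluded from assignment", stacklevel=2)
    return out


def subtype_support_distribution(rule: Rule, sample_meta: pd.DataFrame) -> dict[str, float]:
    """Percent of each subtype's cohort total found in the rule's support set."""
    subtype = _subtype_of(sample_meta)
    totals = subtype.value_counts()
    support_subtypes = subtype.loc[[s for s in rule.support_set if s in subtype.index]]
    counts = support_subtypes.value_counts()
    return {
        str(g): 100.0 * counts.get(g, 0) / totals[g]
        for g in totals.index
        if totals[g] > 0
    }


def betweenness_distance(net_a: CoPredNetwork, net_b: CoPredNetwork) -> float:
    """Euclidean norm of the difference of unnormalized shortest-path
    betweenness vectors aligned on the union node set (absent nodes count 0)."""
    if net_a.is_empty() and net_b.is_empty():
        warnings.warn("both networks empty: distance 0", stacklevel=2)
        return 0.0
    union = sorted(set(net_a.graph.nodes) | set(net_b.graph.nodes))
    vecs = []
    for net in (net_a, net_b):
        bc = nx.betweenness_centrality(net.graph, normalized=False)
        vecs.append(np.array([bc.get(node, 0.0) for node in union]))
    return float(np.linalg.norm(vecs[0] - vecs[1]))


def balanced_distance(
    rules_a: Sequence[Rule],
    rules_b: Sequence[Rule],
    n_balance: int = 20,
    seed: int = 0,
) -> float:
    """Mean betweenness distance over ``n_balance`` equal-size rule resamples.

    m = min(|A|, |B|) rules are drawn without replacement from each side per
    resample; with equal sizes the draw is exhaustive.
    """
    if not rules_a or not rules_b:
        raise ValueError("both rule lists must be non-empty")
    rng = np.random.default_rng(seed)
    m = min(len(rules_a), len(rules_b))
    total = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_balance):
            sub_a = [rules_a[i] for i in rng.choice(len(rules_a), size=m, replace=False)]
            sub_b = [rules_b[i] for i in rng.choice(len(rules_b), size=m, replace=False)]
            total += betweenness_distance(build_network(sub_a), build_network(sub_b))
    return total / n_balance


def permutation_test(
    model: RuleModel,
    sample_meta: pd.DataFrame,
    subgroups: Sequence[str] | None = None,
    n_perm: int = 500,
    n_balance: int = 20,
    seed: int = 0,
    assignment: Mapping[str, Sequence[Rule]] | None = None,
) -> list[DistanceResult]:
    """Pairwise balanced distances with a permutation null.

    The null shuffles subgroup labels across the pooled rule-to-subgroup
    assignments, preserving per-subgroup rule counts; p uses the add-one
    estimator on the count of null distances >= the observed (random networks
    are expected not to exceed the originals).
    """
    if assignment is None:
        assignment = assign_rules_to_subgroups(model, sample_meta)
    groups = list(subgroups) if subgroups is not None else sorted(assignment)
    usable = []
    for g in groups:
        if len(assignment.get(g, [])) < 2:
            warnings.warn(f"subgroup {g!r} has < 2 rules: excluded", stacklevel=2)
        else:
            usable.append(g)
    if len(usable) < 2:
        raise ValueError("need at least two subgroups with >= 2 rules")

    rng = np.random.default_rng(seed)
    pairs = list(combinations(usable, 2))
    observed = {
        pair: balanced_distance(
            assignment[pair[0]], assignment[pair[1]], n_balance, int(rng.integers(2**31 - 1))
        )
        for pair in pairs
    }
    pooled = [(g, rule) for g in usable for rule in assignment[g]]
    labels = np.array([g for g, _ in pooled], dtype=object)
    exceed = {pair: 0 for pair in pairs}
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(len(labels))]
        shuffled: dict[str, list[Rule]] = {g: [] for g in usable}
        for lab, (_, rule) in zip(perm_labels, pooled):
            shuffled[lab].append(rule)
        for pair in pairs:
            d = balanced_distance(
                shuffled[pair[0]], shuffled[pair[1]], n_balance, int(rng.integers(2**31 - 1))
            )
            if d >= observed[pair]:
                exceed[pair] += 1
    raw_p = [(1 + exceed[pair]) / (1 + n_perm) for pair in pairs]
    _, p_adj, _, _ = multipletests(raw_p, method="fdr_bh")
    return [
        DistanceResult(
            subgroup_a=a,
            subgroup_b=b,
            observed_distance=observed[(a, b)],
            permutation_p=p,
            p_adjusted=float(q),
            n_permutations=n_perm,
            n_balance_resamples=n_balance,
            seed=seed,
        )
        for (a, b), p, q in zip(pairs, raw_p, p_adj)
    ]


def kendall_distance_matrix(connection_table: pd.DataFrame) -> pd.DataFrame:
    """1 - Kendall tau-b distances between subgroup connection profiles.

    ``connection_table`` is subgroups x nodes (0 where a node is absent);
    each subgroup's vector is min-max scaled to [0, 1] first.  A constant
    vector makes tau undefined: the distance is set to 1 with a warning.
    """
    if connection_table.shape[0] < 2:
        raise ValueError("need at least two subgroups")
    scaled = {}
    for g in connection_table.index:
        v = connection_table.loc[g].to_numpy(dtype=float)
        lo, hi = v.min(), v.max()
        scaled[g] = (v - lo) / (hi - lo) if hi > lo else v
    groups = list(connection_table.index)
    out = pd.DataFrame(0.0, index=groups, columns=groups)
    for a, b in combinations(groups, 2):
        va, vb = scaled[a], scaled[b]
        if np.all(va == va[0]) or np.all(vb == vb[0]):
            warnings.warn(f"constant connection vector for {a!r} or {b!r}: distance 1", stacklevel=2)
            d = 1.0
        else:
            tau = kendalltau(va, vb).statistic
            d = 1.0 - float(tau)
        out.at[a, b] = out.at[b, a] = d
    return out
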