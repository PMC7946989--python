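"""Rough-set rule induction and classification.

Object-related Johnson reducts (greedy covering of per-object discernibility
clauses, modulo decision), IF-THEN rule induction with support / accuracy /
coverage / hypergeometric p statistics, support-weighted standard voting,
stratified 10-fold cross-validation with per-fold undersampling and
discretization, and joint Benjamini-Hochberg filtering of rules.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .preprocess import DecisionTable, DiscretizationScheme, discretize, undersample

__all__ = [
    "Rule",
    "RuleModel",
    "johnson_reducts",
    "induce_rules",
    "rule_stats",
    "compute_stats",
    "classify",
    "fit_rules",
    "crossvalidate",
    "fdr_filter",
]

Condition = tuple[str, int]


@dataclass(frozen=True)
class Rule:
    """An IF-THEN rule over discrete attribute levels.

    ``rs_lhs`` counts objects matching every condition, ``rs_rhs`` those that
    additionally carry the rule's decision; ``ra = rs_rhs / rs_lhs`` and
    ``rc_rhs = rs_rhs / n_d`` with ``n_d`` the decision-class total.
    """

    conditions: frozenset[Condition]
    decision: str
    rs_lhs: int = 0
    rs_rhs: int = 0
    ra: float = 0.0
    rc_rhs: float = 0.0
    p_value: float = 1.0
    p_adjusted: float | None = None
    support_set: frozenset[str] = frozenset()
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("rule conditions must be non-empty")
        if self.rs_rhs > self.rs_lhs:
            raise ValueError("RS_RHS cannot exceed RS_LHS")

    def key(self) -> tuple[frozenset[Condition], str]:
        return (self.conditions, self.decision)

    def sorted_conditions(self) -> list[Condition]:
        return sorted(self.conditions)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ifpart = " AND ".join(f"{a}={v}" for a, v in self.sorted_conditions())
        return f"IF {ifpart} THEN {self.decision}"


@dataclass
class RuleModel:
    """A set of rules with class totals, CV quality and cohort provenance."""

    rules: list[Rule]
    class_totals: dict[str, int]
    accuracy: float | None = None  # percent of correctly classified CV test objects
    auc: float | None = None
    provenance: tuple[str, ...] = ()
    majority_class: str | None = None
    fold_schemes: list[DiscretizationScheme] = field(default_factory=list)
    n_unclassified: int = 0

    def to_json_lines(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.rules:
                fh.write(json.dumps(_rule_to_dict(r)) + "\n")

    def summary(self) -> dict:
        return {
            "n_rules": len(self.rules),
            "class_totals": self.class_totals,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "provenance": list(self.provenance),
            "majority_class": self.majority_class,
            "n_unclassified": self.n_unclassified,
        }

    @classmethod
    def from_json_lines(cls, rules_path: str | Path, summary_path: str | Path | None = None) -> "RuleModel":
        rules = []
        with open(rules_path) as fh:
            for line in fh:
                rules.append(_rule_from_dict(json.loads(line)))
        meta = {}
        if summary_path is not None:
            meta = json.loads(Path(summary_path).read_text())
        return cls(
            rules=rules,
            class_totals=meta.get("class_totals", {}),
            accuracy=meta.get("accuracy"),
            auc=meta.get("auc"),
            provenance=tuple(meta.get("provenance", ())),
            majority_class=meta.get("majority_class"),
        )


def _rule_to_dict(r: Rule) -> dict:
    return {
        "conditions": r.sorted_conditions(),
        "decision": r.decision,
        "rs_lhs": r.rs_lhs,
        "rs_rhs": r.rs_rhs,
        "ra": r.ra,
        "rc_rhs": r.rc_rhs,
        "p_value": r.p_value,
        "p_adjusted": r.p_adjusted,
        "support_set": sorted(r.support_set),
        "provenance": list(r.provenance),
    }


def _rule_from_dict(d: dict) -> Rule:
    return Rule(
        conditions=frozenset((a, int(v)) for a, v in d["conditions"]),
        decision=d["decision"],
        rs_lhs=d["rs_lhs"],
        rs_rhs=d["rs_rhs"],
        ra=d["ra"],
        rc_rhs=d["rc_rhs"],
        p_value=d["p_value"],
        p_adjusted=d.get("p_adjusted"),
        support_set=frozenset(d.get("support_set", ())),
        provenance=tuple(d.get("provenance", ())),
    )


# ---------------------------------------------------------------------------
# Johnson reducts

def johnson_reducts(table: DecisionTable) -> tuple[list[tuple[str, ...]], list[str]]:
    """Greedy object-related reducts modulo decision.

    For each object, the discernibility clauses are the attribute sets that
    discern it from every object of a different class.  The cover is built by
    repeatedly taking the attribute present in the most uncovered clauses
    (ties broken to the lexicographically smallest attribute id).  Objects
    indiscernible from an object of another class produce an empty clause and
    are flagged inconsistent (their reduct covers the non-empty clauses only).
    """
    attrs = table.attributes
    V = table.values.to_numpy(dtype=float)
    dec = table.decision.to_numpy()
    n = V.shape[0]
    reducts: list[tuple[str, ...]] = []
    inconsistent: list[str] = []
    for i in range(n):
        other = np.flatnonzero(dec != dec[i])
        # attribute discerns iff both values present and different
        diff = (V[other] != V[i]) & ~np.isnan(V[other]) & ~np.isnan(V[i])
        clauses = {frozenset(np.flatnonzero(row)) for row in diff}
        if frozenset() in clauses:
            inconsistent.append(table.objects[i])
            clauses.discard(frozenset())
        chosen: list[int] = []
        uncovered = list(clauses)
        while uncovered:
            counts: dict[int, int] = {}
            for clause in uncovered:
                for a in clause:
                    counts[a] = counts.get(a, 0) + 1
            best = min(counts, key=lambda a: (-counts[a], attrs[a]))
            chosen.append(best)
            uncovered = [c for c in uncovered if best not in c]
        reducts.append(tuple(sorted((attrs[a] for a in chosen))))
    return reducts, inconsistent


def induce_rules(table: DecisionTable, reducts: Sequence[tuple[str, ...]] | None = None) -> list[Rule]:
    """One rule per object x reduct; duplicates collapsed; statistics filled on ``table``."""
    if reducts is None:
        reducts, _ = johnson_reducts(table)
    seen: dict[tuple[frozenset[Condition], str], Rule] = {}
    for obj, reduct in zip(table.objects, reducts):
        if not reduct:
            continue
        conds = frozenset((a, int(table.values.at[obj, a])) for a in reduct)
        rule = Rule(conditions=conds, decision=str(table.decision.at[obj]))
        seen.setdefault(rule.key(), rule)
    return compute_stats(list(seen.values()), table)


# ---------------------------------------------------------------------------
# rule statistics

def compute_stats(
    rules: Iterable[Rule],
    table: DecisionTable,
    class_totals: Mapping[str, int] | None = None,
) -> list[Rule]:
    """Recount supports on ``table`` and fill RA, RC_RHS, the hypergeometric
    upper-tail p-value and the support set for every rule.

    Rules whose conditions match no object are discarded with a warning.
    """
    totals = dict(class_totals) if class_totals is not None else table.class_totals()
    n_total = int(table.values.shape[0])
    V = table.values
    dec = table.decision
    obj_index = np.asarray(table.objects, dtype=object)
    out: list[Rule] = []
    for rule in rules:
        mask = np.ones(n_total, dtype=bool)
        for attr, level in rule.conditions:
            if attr in V.columns:
                col = V[attr].to_numpy(dtype=float)
                mask &= col == level  # NaN (absent) never matches
            else:
                mask[:] = False
        rs_lhs = int(mask.sum())
        if rs_lhs == 0:
            warnings.warn(f"rule with empty LHS support discarded: {rule}", stacklevel=2)
            continue
        rhs_mask = mask & (dec.to_numpy() == rule.decision)
        rs_rhs = int(rhs_mask.sum())
        n_d = int(totals.get(rule.decision, 0))
        p = float(hypergeom.sf(rs_rhs - 1, n_total, n_d, rs_lhs))
        out.append(
            replace(
                rule,
                rs_lhs=rs_lhs,
                rs_rhs=rs_rhs,
                ra=rs_rhs / rs_lhs,
                rc_rhs=rs_rhs / n_d if n_d else 0.0,
                p_value=min(p, 1.0),
                support_set=frozenset(obj_index[rhs_mask]),
            )
        )
    return out


def rule_stats(rule: Rule, table: DecisionTable, class_totals: Mapping[str, int] | None = None) -> Rule:
    """Single-rule convenience wrapper around :func:`compute_stats`."""
    filled = compute_stats([rule], table, class_totals)
    if not filled:
        raise ValueError("rule matches no object (RS_LHS = 0)")
    return filled[0]


# ---------------------------------------------------------------------------
# classification

def classify(
    rules: Sequence[Rule],
    obj: Mapping[str, int],
    fallback_class: str | None = None,
) -> tuple[str, dict[str, float]]:
    """Standard voting: each firing rule casts ``rs_rhs`` votes for its decision.

    Votes are normalized to fractions; the argmax class wins (ties broken
    lexicographically).  If no rule fires the fallback (training majority)
    class is returned with empty votes.
    """
    if not rules:
        raise ValueError("empty rule list")
    votes: dict[str, float] = {}
    for rule in rules:
        if all(obj.get(attr) == level for attr, level in rule.conditions):
            votes[rule.decision] = votes.get(rule.decision, 0.0) + rule.rs_rhs
    total = sum(votes.values())
    if total == 0:
        if fallback_class is None:
            raise ValueError("no rule fires and no fallback class given")
        return fallback_class, {}
    fractions = {c: v / total for c, v in votes.items()}
    winner = min(fractions, key=lambda c: (-fractions[c], c))
    return winner, fractions


# ---------------------------------------------------------------------------
# model fitting and cross-validation

def fit_rules(
    frame: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    n_bins: int = 3,
) -> tuple[list[Rule], DecisionTable, DiscretizationScheme]:
    """Undersample, discretize on the balanced data, induce rules and
    recalculate their statistics on the full (union) table."""
    full_table, scheme = _fit_table(frame, labels, seed, n_bins)
    sampled_ids = full_table.attrs_sampled  # type: ignore[attr-defined]
    sampled = full_table.subset(sampled_ids)
    reducts, _ = johnson_reducts(sampled)
    rules = induce_rules(sampled, reducts)
    rules = compute_stats(rules, full_table)
    return rules, full_table, scheme


def _fit_table(frame, labels, seed, n_bins):
    probe_table = DecisionTable(values=frame, decision=labels)  # continuous, only for sampling
    us = undersample(probe_table, seed)
    balanced_frame = frame.loc[us.sampled.objects]
    _, scheme = discretize(balanced_frame, labels.loc[us.sampled.objects], n_bins)
    full_table, _ = discretize(frame, labels, n_bins, scheme=scheme)
    full_table.attrs_sampled = us.sampled.objects  # type: ignore[attr-defined]
    return full_table, scheme


def crossvalidate(
    frame: pd.DataFrame,
    labels: pd.Series,
    folds: int = 10,
    seed: int = 0,
    n_bins: int = 3,
    positive_class: str = "case",
    provenance: tuple[str, ...] = (),
) -> RuleModel:
    """Stratified k-fold CV with per-fold undersampling and discretization.

    Accuracy is the percentage of correctly classified test objects pooled
    over folds; AUC is computed from the positive-class vote fraction.  The
    returned model's rules are refit on the full data.
    """
    labels = labels.reindex(frame.index)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} objects < {folds} folds; lower folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y = labels.to_numpy()
    correct = 0
    total = 0
    n_unclassified = 0
    scores: list[float] = []
    truth: list[str] = []
    fold_schemes: list[DiscretizationScheme] = []
    rng = np.random.default_rng(seed)
    for train_idx, test_idx in skf.split(frame.to_numpy(), y):
        fold_seed = int(rng.integers(2**31 - 1))
        train_frame = frame.iloc[train_idx]
        train_labels = labels.iloc[train_idx]
        full_train, scheme = _fit_table(train_frame, train_labels, fold_seed, n_bins)
        fold_schemes.append(scheme)
        sampled = full_train.subset(full_train.attrs_sampled)  # type: ignore[attr-defined]
        reducts, _ = johnson_reducts(sampled)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rules = compute_stats(induce_rules(sampled, reducts), full_train)
        majority = train_labels.value_counts().idxmax()
        test_table, _ = discretize(frame.iloc[test_idx], labels.iloc[test_idx], n_bins, scheme=scheme)
        for obj in test_table.objects:
            row = {a: int(v) for a, v in test_table.values.loc[obj].items() if not np.isnan(v)}
            pred, fractions = classify(rules, row, fallback_class=majority)
            if not fractions:
                n_unclassified += 1
            correct += pred == test_table.decision.at[obj]
            total += 1
            scores.append(fractions.get(positive_class, 0.5 if not fractions else 0.0))
            truth.append(str(test_table.decision.at[obj]))
    accuracy = 100.0 * correct / total
    auc = float(roc_auc_score([t == positive_class for t in truth], scores))
    final_rules, full_table, _ = fit_rules(frame, labels, seed=seed, n_bins=n_bins)
    return RuleModel(
        rules=final_rules,
        class_totals=full_table.class_totals(),
        accuracy=accuracy,
        auc=auc,
        provenance=provenance,
        majority_class=str(labels.value_counts().idxmax()),
        fold_schemes=fold_schemes,
        n_unclassified=n_unclassified,
    )


def fdr_filter(rules: Sequence[Rule], alpha: float = 0.05) -> list[Rule]:
    """Benjamini-Hochberg over all rules jointly; keep adjusted p <= alpha."""
    if not rules:
        return []
    pvals = np.array([r.p_value for r in rules])
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [
        replace(r, p_adjusted=float(q))
        for r, q, keep in zip(rules, p_adj, reject)
        if keep
    ]
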