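"""Monte Carlo feature selection.

Features are ranked by relative importance (RI) aggregated over many decision
trees trained on random attribute subsets and random 2/3 splits; a knee-point
(critical angle) threshold picks the top of the ranking, which is then
adjusted by scanning rule-model quality, and per-cohort rankings are merged
on a rescaled RI scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FeatureRanking",
    "mcfs_rank",
    "critical_angle_threshold",
    "adjust_fr",
    "merge_rankings",
]


@dataclass(frozen=True)
class FeatureRanking:
    """(feature_id, RI) pairs sorted by decreasing RI."""

    entries: tuple[tuple[str, float], ...]
    provenance: str = "unknown"
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ris = [ri for _, ri in self.entries]
        if any(b > a for a, b in zip(ris, ris[1:])):
            raise ValueError("RI must be non-increasing")
        ids = [f for f, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in ranking")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.entries]

    def top(self, k: int) -> "FeatureRanking":
        return FeatureRanking(self.entries[:k], self.provenance, self.params)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("feature_id\tRI\n")
            for f, ri in self.entries:
                fh.write(f"{f}\t{ri!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "file") -> "FeatureRanking":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(zip(df["feature_id"].astype(str), df["RI"].astype(float))), provenance)


def mcfs_rank(
    frame: pd.DataFrame,
    labels: pd.Series,
    s: int = 100,
    t: int = 5,
    m: int | None = None,
    u: float = 1.0,
    v: float = 1.0,
    seed: int = 0,
    provenance: str = "unknown",
) -> FeatureRanking:
    """Rank features by Monte Carlo relative importance.

    For each of ``s`` random attribute subsets of size ``m`` (default
    ceil(sqrt(n_features))), ``t`` entropy decision trees are trained on
    random 2/3 splits.  Each node where feature ``g`` splits contributes
    ``wAcc^u * IG * (n_node / n_root)^v`` to RI(g), where ``wAcc`` is the
    tree's class-balanced accuracy on the held-out third and ``IG`` the
    information gain of the node.
    """
    labels = labels.reindex(frame.index)
    if labels.nunique() < 2:
        raise ValueError("need at least two classes")
    n, p = frame.shape
    if m is None:
        m = math.ceil(math.sqrt(p))
    if m > p:
        raise ValueError(f"m={m} exceeds the number of features ({p})")
    rng = np.random.default_rng(seed)
    X = frame.to_numpy(dtype=float)
    y = labels.to_numpy()
    ri = np.zeros(p)
    n_train = max(int(round(n * 2 / 3)), 2)
    for _ in range(s):
        feats = rng.choice(p, size=m, replace=False)
        for _ in range(t):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            tree = DecisionTreeClassifier(
                criterion="entropy", random_state=int(rng.integers(2**31 - 1))
            )
            tree.fit(X[np.ix_(train, feats)], y[train])
            if test.size:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    wacc = balanced_accuracy_score(y[test], tree.predict(X[np.ix_(test, feats)]))
            else:
                wacc = 0.0
            if wacc == 0.0:
                continue
            tr = tree.tree_
            n_root = tr.n_node_samples[0]
            for node in range(tr.node_count):
                left, right = tr.children_left[node], tr.children_right[node]
                if left == -1:
                    continue
                n_node = tr.n_node_samples[node]
                ig = tr.impurity[node] - (
                    tr.n_node_samples[left] * tr.impurity[left]
                    + tr.n_node_samples[right] * tr.impurity[right]
                ) / n_node
                ri[feats[tr.feature[node]]] += (wacc**u) * ig * ((n_node / n_root) ** v)
    order = sorted(range(p), key=lambda j: (-ri[j], frame.columns[j]))
    entries = tuple((str(frame.columns[j]), float(ri[j])) for j in order)
    return FeatureRanking(entries, provenance, {"s": s, "t": t, "m": m, "u": u, "v": v})


def critical_angle_threshold(ranking: FeatureRanking) -> int:
    """Knee of the RI curve: with ranks and RI min-max scaled to [0, 1], the
    interior rank maximizing the exterior angle between adjacent segments.
    Returns the number of features kept; ties break to the smallest count."""
    L = len(ranking)
    if L < 3:
        raise ValueError("ranking must have at least 3 entries")
    ri = np.array([v for _, v in ranking.entries])
    if ri.max() == ri.min():
        warnings.warn("flat RI curve: keeping all features", stacklevel=2)
        return L
    x = np.linspace(0.0, 1.0, L)
    yv = (ri - ri.min()) / (ri.max() - ri.min())
    angles = np.zeros(L)
    steepens = np.zeros(L, dtype=bool)
    for i in range(1, L - 1):
        a = np.array([x[i] - x[i - 1], yv[i] - yv[i - 1]])
        b = np.array([x[i + 1] - x[i], yv[i + 1] - yv[i]])
        cosang = np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1.0, 1.0)
        angles[i] = float(np.arccos(cosang))
        steepens[i] = b[1] < a[1] - 1e-12  # the curve turns downward at i
    # the knee sits where the ranking turns from shallow to steep (the top of
    # the drop, not its bottom); on curves with no such turn, e.g. a straight
    # line, fall back to all interior points with ties to the smallest k
    candidates = np.flatnonzero(steepens) if steepens.any() else np.arange(1, L - 1)
    top = angles[candidates].max()
    best_candidates = [i for i in candidates if angles[i] >= top - 1e-6]
    return int(min(best_candidates)) + 1


def adjust_fr(
    ranking: FeatureRanking,
    quality_fn: Callable[[int], float],
    k0: int,
    k_max: int = 50,
) -> int:
    """Scan k = k0..k_max adding features by decreasing RI and return the k of
    the local quality maximum nearest to k0 (scanning upward).

    ``quality_fn(k)`` evaluates a CV rule model on the top-k features; the
    conventional composite is (accuracy-fraction + AUC) / 2.  A plateau counts
    as a maximum at its smallest k; a monotone increase yields ``k_max``.
    """
    if k0 > len(ranking):
        raise ValueError("k0 exceeds ranking length")
    k_max = min(k_max, len(ranking))
    if k0 > k_max:
        raise ValueError("k0 exceeds k_max")
    ks = list(range(k0, k_max + 1))
    q = [quality_fn(k) for k in ks]
    for idx, k in enumerate(ks):
        rises = idx == 0 or q[idx] > q[idx - 1]
        if not rises:
            continue
        nxt = next((j for j in range(idx + 1, len(ks)) if q[j] != q[idx]), None)
        if nxt is None or q[nxt] < q[idx]:
            return k
    return k_max


def cv_quality(accuracy_percent: float, auc: float) -> float:
    """Composite model quality: mean of the accuracy fraction and the AUC."""
    return (accuracy_percent / 100.0 + auc) / 2.0


def merge_rankings(
    rankings: Sequence[FeatureRanking],
    id_map: Mapping[str, str] | None = None,
) -> FeatureRanking:
    """Union per-cohort rankings on a comparable RI scale.

    Each ranking's RI is rescaled so its maximum is 1; feature ids are
    translated through ``id_map`` when given; a feature appearing in several
    rankings keeps its maximum rescaled RI.
    """
    merged: dict[str, float] = {}
    for ranking in rankings:
        if not ranking.entries:
            continue
        top = ranking.entries[0][1]
        scale = 1.0 / top if top > 0 else 0.0
        for fid, ri in ranking.entries:
            target = id_map.get(fid, fid) if id_map else fid
            value = ri * scale
            merged[target] = max(merged.get(target, 0.0), value)
    entries = tuple(sorted(merged.items(), key=lambda kv: (-kv[1], kv[0])))
    return FeatureRanking(entries, provenance="merged")
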