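"""Discretization and class balancing.

Continuous expression is converted into three-level decision tables by
equal-frequency binning learned on training data only; classes are balanced
by undersampling to the minority-class size, keeping the sampled-out objects
so rule statistics can later be recalculated on the full table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiscretizationScheme",
    "DecisionTable",
    "equal_frequency_cuts",
    "apply_cuts",
    "discretize",
    "undersample",
]

LEVEL_LABELS = {1: "low", 2: "medium", 3: "high"}


@dataclass(frozen=True)
class DiscretizationScheme:
    """Per-attribute ordered cut points; level i = 1 + #cuts strictly below."""

    cuts: Mapping[str, tuple[float, ...]]
    n_levels: int = 3

    def __post_init__(self) -> None:
        for attr, c in self.cuts.items():
            if list(c) != sorted(set(c)):
                raise ValueError(f"cuts for {attr!r} must be strictly increasing")
            if len(c) > self.n_levels - 1:
                raise ValueError(f"too many cuts for {attr!r}")

    def to_json(self, path: str | Path) -> None:
        payload = {"n_levels": self.n_levels, "cuts": {a: list(c) for a, c in self.cuts.items()}}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscretizationScheme":
        payload = json.loads(Path(path).read_text())
        return cls(
            cuts={a: tuple(c) for a, c in payload["cuts"].items()},
            n_levels=payload["n_levels"],
        )


@dataclass
class DecisionTable:
    """Discrete-valued objects x attributes with a decision column.

    ``values`` holds integer levels as floats; NaN marks an attribute absent
    for an object (a cohort lacking the feature) — conditions on absent
    attributes never match.
    """

    values: pd.DataFrame  # index: object ids, columns: attribute ids
    decision: pd.Series  # index-aligned class labels

    def __post_init__(self) -> None:
        self.decision = self.decision.reindex(self.values.index)
        if self.decision.isna().any():
            raise ValueError("decision missing for some objects")

    @property
    def objects(self) -> list[str]:
        return list(self.values.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def classes(self) -> list[str]:
        return sorted(self.decision.unique())

    def class_totals(self) -> dict[str, int]:
        return self.decision.value_counts().to_dict()

    def subset(self, object_ids: Sequence[str]) -> "DecisionTable":
        ids = list(object_ids)
        return DecisionTable(values=self.values.loc[ids], decision=self.decision.loc[ids])

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out["decision"] = self.decision
        out.to_csv(path, index_label="object_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DecisionTable":
        df = pd.read_csv(path, index_col="object_id")
        df.index.name = None
        decision = df.pop("decision")
        return cls(values=df.astype(float), decision=decision.astype(str))


def equal_frequency_cuts(values: Sequence[float], n_bins: int = 3) -> tuple[float, ...]:
    """Equal-frequency cut points at midpoints between consecutive sorted values.

    With all-distinct values the bin occupancies differ by at most one.  A cut
    never splits tied values: a boundary falling inside a run of ties shifts to
    the nearest midpoint between distinct values.  Ties may therefore collapse
    cuts, yielding fewer effective bins (a constant vector yields no cuts).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty value vector")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if v[0] == v[-1]:
        warnings.warn("constant vector: no cuts, single level", stacklevel=2)
        return ()
    # candidate boundaries: indices b where v[b-1] < v[b]
    distinct = np.flatnonzero(v[1:] > v[:-1]) + 1
    cuts: list[float] = []
    for j in range(1, n_bins):
        target = round(j * n / n_bins)
        target = min(max(target, 1), n - 1)
        if v[target - 1] < v[target]:
            b = target
        else:
            # shift to the nearest boundary between distinct values
            b = int(distinct[np.argmin(np.abs(distinct - target))])
        cuts.append((v[b - 1] + v[b]) / 2.0)
    return tuple(sorted(set(cuts)))


def apply_cuts(values: Sequence[float], cuts: Sequence[float]) -> np.ndarray:
    """Map values to levels: level = 1 + number of cuts strictly below the value."""
    c = np.asarray(cuts, dtype=float)
    if c.size and not np.all(np.diff(c) > 0):
        raise ValueError("cuts must be strictly increasing")
    return np.searchsorted(c, np.asarray(values, dtype=float), side="left") + 1


def discretize(
    frame: pd.DataFrame,
    decision: pd.Series,
    n_bins: int = 3,
    scheme: DiscretizationScheme | None = None,
) -> tuple[DecisionTable, DiscretizationScheme]:
    """Discretize a continuous samples x features frame into a decision table.

    Without ``scheme``, cuts are learned per attribute from ``frame`` itself
    (the training convention); with ``scheme``, its cuts are applied as-is
    (the test convention).
    """
    if scheme is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scheme = DiscretizationScheme(
                cuts={a: equal_frequency_cuts(frame[a].to_numpy(), n_bins) for a in frame.columns},
                n_levels=n_bins,
            )
    levels = {}
    for a in frame.columns:
        col = frame[a].to_numpy(dtype=float)
        out = apply_cuts(col, scheme.cuts.get(a, ())).astype(float)
        out[np.isnan(col)] = np.nan
        levels[a] = out
    table = DecisionTable(
        values=pd.DataFrame(levels, index=frame.index),
        decision=decision,
    )
    return table, scheme


@dataclass
class UndersampleResult:
    sampled: DecisionTable
    removed_ids: list[str] = field(default_factory=list)


def undersample(table: DecisionTable, seed: int) -> UndersampleResult:
    """Downsample every class without replacement to the minority-class size."""
    totals = table.class_totals()
    if len(totals) < 2:
        raise ValueError("undersampling requires at least two classes")
    m = min(totals.values())
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for cls in table.classes:
        ids = [o for o, d in table.decision.items() if d == cls]
        chosen = ids if len(ids) == m else sorted(rng.choice(ids, size=m, replace=False))
        keep.extend(chosen)
    keep_set = set(keep)
    removed = [o for o in table.objects if o not in keep_set]
    keep_ordered = [o for o in table.objects if o in keep_set]
    return UndersampleResult(sampled=table.subset(keep_ordered), removed_ids=removed)
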