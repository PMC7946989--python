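import numpy as np
import pandas as pd
import pytest

from copredict.preprocess import DecisionTable
from copredict.rules import Rule
from copredict.synthetic import PlantedPair, SyntheticSpec, generate_cohorts


@pytest.fixture
def toy_table() -> DecisionTable:
    """Three objects, three binary attributes; o1's minimal reduct is {a}."""
    values = pd.DataFrame(
        {"a": [1.0, 0.0, 1.0], "b": [0.0, 1.0, 1.0], "c": [0.0, 0.0, 1.0]},
        index=["o1", "o2", "o3"],
    )
    decision = pd.Series(["+", "-", "+"], index=values.index)
    return DecisionTable(values=values, decision=decision)


def make_table(values: np.ndarray, decisions, prefix: str = "o") -> DecisionTable:
    ids = [f"{prefix}{i}" for i in range(len(decisions))]
    frame = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=ids,
        columns=[f"x{j}" for j in range(np.asarray(values).shape[1])],
    )
    return DecisionTable(values=frame, decision=pd.Series(list(decisions), index=ids))


def random_table(rng: np.random.Generator, n_obj: int, n_attr: int, n_levels: int = 3) -> DecisionTable:
    vals = rng.integers(1, n_levels + 1, size=(n_obj, n_attr))
    dec = rng.choice(["a", "b"], size=n_obj)
    dec[0], dec[1] = "a", "b"  # guarantee two classes
    return make_table(vals, dec)


def make_rule(conds, decision="case", rs_lhs=10, rs_rhs=8, support=(), prov=()) -> Rule:
    return Rule(
        conditions=frozenset(conds),
        decision=decision,
        rs_lhs=rs_lhs,
        rs_rhs=rs_rhs,
        ra=rs_rhs / rs_lhs,
        support_set=frozenset(support),
        provenance=tuple(prov),
    )


def random_rules(rng: np.random.Generator, n_rules: int, n_feats: int = 6) -> list[Rule]:
    rules = []
    for _ in range(n_rules):
        k = int(rng.integers(1, 4))
        feats = rng.choice(n_feats, size=k, replace=False)
        conds = [(f"g{f}", int(rng.integers(1, 4))) for f in feats]
        rs_lhs = int(rng.integers(2, 30))
        rs_rhs = int(rng.integers(1, rs_lhs + 1))
        rules.append(
            make_rule(conds, decision=str(rng.choice(["case", "control"])), rs_lhs=rs_lhs, rs_rhs=rs_rhs)
        )
    return rules


@pytest.fixture
def separable_matrix():
    """One feature with disjoint class ranges, n=60.

    Values are tied within three clusters so equal-frequency cuts (which never
    split ties) land exactly between the classes in every CV fold.
    """
    values = np.array([1.0] * 30 + [5.0] * 15 + [9.0] * 15)[:, None]
    ids = [f"s{i}" for i in range(60)]
    frame = pd.DataFrame(values, index=ids, columns=["gene"])
    labels = pd.Series(["control"] * 30 + ["case"] * 30, index=ids)
    return frame, labels


@pytest.fixture
def small_cohorts():
    spec = SyntheticSpec(
        n_cohorts=2,
        n_genes=12,
        samples_per_subgroup={"control": 25, "AS": 8, "PDD-NOS": 8, "autism": 9},
        planted_pairs=(PlantedPair(0, 1, 0.9, 0.0),),
        shift_genes={
            0: {"AS": 1.0, "PDD-NOS": 1.4, "autism": 1.8},
            1: {"AS": 1.0, "PDD-NOS": 1.4, "autism": 1.8},
            2: {"AS": 0.8, "PDD-NOS": 1.2, "autism": 1.6},
        },
        seed=11,
    )
    return generate_cohorts(spec)
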