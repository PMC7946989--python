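"""Synthetic multi-cohort expression data with planted structure.

Generates case/control cohorts with graded case subtypes, per-subtype mean
shifts on selected genes, gene pairs that are correlated in cases but not in
controls, per-cohort additive offsets and i.i.d. Gaussian noise everywhere
else.  Everything is deterministic under the SyntheticSpec seed so the downstream
stages can be tested without external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "ExpressionMatrix",
    "PlantedPair",
    "generate_cohorts",
    "generate_term_db",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_term_db_tsv",
    "read_term_db_tsv",
]

CONTROL_LABEL = "control"


@dataclass(frozen=True)
class PlantedPair:
    """A gene pair with class-dependent correlation."""

    gene_i: int
    gene_j: int
    rho_case: float
    rho_control: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generative model.

    ``samples_per_subgroup`` maps each subtype label (including the control
    label) to its per-cohort sample count.  ``shift_genes`` maps a gene index
    to a per-subtype mean shift expressed in multiples of ``noise_sd``.
    """

    n_cohorts: int = 1
    n_genes: int = 50
    samples_per_subgroup: Mapping[str, int] = field(
        default_factory=lambda: {"control": 30, "AS": 10, "PDD-NOS": 10, "autism": 10}
    )
    subtype_labels: Sequence[str] = ("control", "AS", "PDD-NOS", "autism")
    severity_scores: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.0, "AS": 1.0, "PDD-NOS": 2.0, "autism": 3.0}
    )
    planted_pairs: Sequence[PlantedPair] = ()
    shift_genes: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    cohort_offset_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not self.samples_per_subgroup:
            raise ValueError("samples_per_subgroup must be non-empty")
        for label, count in self.samples_per_subgroup.items():
            if count < 1:
                raise ValueError(f"empty subgroup {label!r}")
            if label not in self.subtype_labels:
                raise ValueError(f"subgroup {label!r} not among subtype_labels")
        for pair in self.planted_pairs:
            for g in (pair.gene_i, pair.gene_j):
                if not 0 <= g < self.n_genes:
                    raise ValueError(f"planted gene index {g} out of range")
            for rho in (pair.rho_case, pair.rho_control):
                if not abs(rho) < 1:
                    raise ValueError(f"|rho| must be < 1, got {rho}")
        scores = [self.severity_scores[s] for s in self.subtype_labels if s in self.severity_scores]
        if scores != sorted(scores):
            raise ValueError("severity scores must be monotone over the subtype order")
        for g in self.shift_genes:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"shift gene index {g} out of range")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.cohort_offset_sd < 0:
            raise ValueError("cohort_offset_sd must be non-negative")


@dataclass
class ExpressionMatrix:
    """A samples x genes continuous expression matrix with sample metadata.

    ``sample_meta`` has one row per sample with columns ``sample_id``,
    ``cohort_id``, ``class`` (case/control), ``subtype``, ``sex``, ``age``.
    """

    values: pd.DataFrame  # index: sample_id, columns: gene ids
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate gene ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def _gene_name(i: int) -> str:
    return f"g{i:04d}"


def generate_cohorts(spec: SyntheticSpec) -> list[ExpressionMatrix]:
    """Draw one :class:`ExpressionMatrix` per cohort under ``spec``.

    All genes start as N(0, noise_sd) plus a per-cohort gene-wise offset
    N(0, cohort_offset_sd).  Planted pairs are redrawn from a bivariate
    normal whose correlation is ``rho_case`` for case samples and
    ``rho_control`` for controls.  Shift genes then receive their per-subtype
    mean shift (in multiples of ``noise_sd``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gene_ids = [_gene_name(i) for i in range(spec.n_genes)]
    cohorts: list[ExpressionMatrix] = []
    for c in range(spec.n_cohorts):
        cohort_id = f"cohort{c + 1}"
        subtypes: list[str] = []
        for label in spec.subtype_labels:
            count = spec.samples_per_subgroup.get(label, 0)
            subtypes.extend([label] * count)
        n = len(subtypes)
        values = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_genes))
        if spec.cohort_offset_sd > 0:
            values += rng.normal(0.0, spec.cohort_offset_sd, size=spec.n_genes)

        is_case = np.array([s != CONTROL_LABEL for s in subtypes])
        for pair in spec.planted_pairs:
            draw = np.empty((n, 2))
            for mask, rho in ((is_case, pair.rho_case), (~is_case, pair.rho_control)):
                k = int(mask.sum())
                if k == 0:
                    continue
                cov = spec.noise_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
                draw[mask] = rng.multivariate_normal([0.0, 0.0], cov, size=k)
            values[:, pair.gene_i] = draw[:, 0]
            values[:, pair.gene_j] = draw[:, 1]

        for g, shifts in spec.shift_genes.items():
            for j, subtype in enumerate(subtypes):
                shift = shifts.get(subtype, 0.0)
                if shift:
                    values[j, g] += shift * spec.noise_sd

        meta = pd.DataFrame(
            {
                "sample_id": [f"{cohort_id}_s{j:04d}" for j in range(n)],
                "cohort_id": cohort_id,
                "class": np.where(is_case, "case", "control"),
                "subtype": subtypes,
                "sex": rng.choice(["F", "M"], size=n),
                "age": np.round(rng.uniform(2.0, 18.0, size=n), 1),
            }
        )
        frame = pd.DataFrame(values, index=pd.Index(meta["sample_id"], name="sample_id"), columns=gene_ids)
        cohorts.append(ExpressionMatrix(values=frame, sample_meta=meta))
    return cohorts


def generate_term_db(
    gene_ids: Sequence[str], n_terms: int, genes_per_term: int, seed: int
) -> dict[str, set[str]]:
    """Sample ``n_terms`` gene sets of size ``genes_per_term`` (no replacement within a term)."""
    if genes_per_term > len(gene_ids):
        raise ValueError("genes_per_term exceeds the number of genes")
    if n_terms < 0:
        raise ValueError("n_terms must be non-negative")
    rng = np.random.default_rng(seed)
    genes = np.asarray(gene_ids, dtype=object)
    return {
        f"term{k:03d}": set(rng.choice(genes, size=genes_per_term, replace=False))
        for k in range(n_terms)
    }


# ---------------------------------------------------------------------------
# plain-text I/O

def write_expression_tsv(matrix: ExpressionMatrix, values_path: str | Path, meta_path: str | Path) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    matrix.sample_meta.to_csv(meta_path, sep="\t", index=False)


def read_expression_tsv(values_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    return ExpressionMatrix(values=values, sample_meta=meta)


def write_term_db_tsv(terms: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tgene_id\n")
        for term in sorted(terms):
            for gene in sorted(terms[term]):
                fh.write(f"{term}\t{gene}\n")


def read_term_db_tsv(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for term, group in df.groupby("term_id"):
        out[str(term)] = set(group["gene_id"])
    return out


def spec_from_dict(cfg: Mapping) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a plain (e.g. YAML) mapping."""
    cfg = dict(cfg)
    pairs = [
        PlantedPair(int(p[0]), int(p[1]), float(p[2]), float(p[3]))
        if not isinstance(p, Mapping)
        else PlantedPair(int(p["gene_i"]), int(p["gene_j"]), float(p["rho_case"]), float(p["rho_control"]))
        for p in cfg.pop("planted_pairs", [])
    ]
    shift = {int(g): {str(s): float(v) for s, v in m.items()} for g, m in cfg.pop("shift_genes", {}).items()}
    allowed = {f.name for f in dataclasses.fields(SyntheticSpec)}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown synthetic spec keys: {sorted(unknown)}")
    return SyntheticSpec(planted_pairs=tuple(pairs), shift_genes=shift, **cfg)
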