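"""Synthetic descriptor datasets and the curated fixture-molecule set.

The numeric generators emulate what the CP ANN actually consumes — a
normalized descriptor table with class (or alert-group) structure — without
any chemistry: two (or ten) Gaussian clouds in descriptor space whose mean
separation is expressed in units of the within-class standard deviation.
The fixture molecules are the chemical test surface: a small curated set of
real structures with hand-derived expected alert matches, group labels and
fragment counts.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .alerts import N_GROUPS
from .records import DescriptorMatrix, MoleculeRecord
from .scaling import apply_normalization, fit_normalization


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for the two-class Gaussian generator."""

    n_per_class: int = 100
    p: int = 12
    separation: float = 4.0  # Euclidean distance between class means, in within-class SDs
    covariance: str = "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.p < 1:
            raise ValueError("need p >= 1 dimensions")


def generate_gaussian_classes(spec: SyntheticSpec) -> tuple[DescriptorMatrix, np.ndarray]:
    """Two Gaussian clouds at the stated separation, min-max normalized.

    Labels follow the carcinogenicity coding: class 1 and class 2.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_per_class, spec.p
    offset = spec.separation / np.sqrt(p)  # per-dimension shift giving ||mu2-mu1|| = separation
    x1 = rng.standard_normal((n, p))
    x2 = rng.standard_normal((n, p)) + offset
    values = np.vstack([x1, x2])
    labels = np.concatenate([np.ones(n, dtype=int), np.full(n, 2, dtype=int)])
    matrix = DescriptorMatrix(
        values=values,
        row_ids=[f"syn_{i}" for i in range(2 * n)],
        column_names=[f"d{j + 1}" for j in range(p)],
    )
    params = fit_normalization(matrix)
    return apply_normalization(matrix, params), labels


@dataclass(frozen=True)
class SAGroupSpec:
    """Conditions for the ten-group (structural-alert) generator.

    The ten clusters mirror the SA-group coding of the alert model.  The two
    combination groups sit midway between their parent single-alert
    clusters: group 4 (SA_13+SA_27) between groups 3 and 6, group 7
    (SA_27+SA_28) between groups 6 and 8.
    """

    n_per_group: int = 20
    p: int = 12
    separation: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 10:
            raise ValueError("the 10-group generator needs p >= 10")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


def generate_sa_group_dataset(spec: SAGroupSpec) -> tuple[DescriptorMatrix, np.ndarray]:
    """Ten Gaussian clusters labelled 1..10, min-max normalized."""
    rng = np.random.default_rng(spec.seed)
    s = spec.separation
    means = np.zeros((N_GROUPS + 1, spec.p))  # index by group number, row 0 unused
    base_groups = [1, 2, 3, 5, 6, 8, 9, 10]
    for axis, g in enumerate(base_groups):
        means[g, axis] = s
    means[4] = (means[3] + means[6]) / 2.0
    means[7] = (means[6] + means[8]) / 2.0

    blocks, labels = [], []
    for g in range(1, N_GROUPS + 1):
        blocks.append(rng.standard_normal((spec.n_per_group, spec.p)) + means[g])
        labels.extend([g] * spec.n_per_group)
    values = np.vstack(blocks)
    matrix = DescriptorMatrix(
        values=values,
        row_ids=[f"sa_{i}" for i in range(len(values))],
        column_names=[f"d{j + 1}" for j in range(spec.p)],
    )
    params = fit_normalization(matrix)
    return apply_normalization(matrix, params), np.asarray(labels)


@dataclass(frozen=True)
class FixtureExpectation:
    """Hand-derived ground truth for one fixture molecule."""

    alerts: frozenset[str]
    group: int
    fragment_counts: dict[str, int]


def fixture_molecules() -> list[tuple[MoleculeRecord, FixtureExpectation]]:
    """The curated fixture set with expected annotations.

    Every alert in the packaged rulebase has at least one positive example
    here or in the rulebase's own example field; the set also covers the
    named anchors (Chlordecone -> SA_20, the SA_13+SA_27 and SA_27+SA_28
    combination groups, an unalerted alkane).
    """
    text = resources.files("cpqsar.data").joinpath("fixture_molecules.csv").read_text()
    out: list[tuple[MoleculeRecord, FixtureExpectation]] = []
    for row in csv.DictReader(text.splitlines()):
        expected_alerts = frozenset(a for a in row["expected_alerts"].split(";") if a)
        record = MoleculeRecord(
            id=row["id"],
            name=row["name"],
            casrn=row["casrn"] or None,
            smiles=row["smiles"],
            class_label=int(row["class_label"]) if row["class_label"] else None,
        )
        expectation = FixtureExpectation(
            alerts=expected_alerts,
            group=int(row["expected_group"]),
            fragment_counts={
                k: int(row[k]) for k in ("nRNNOx", "nPO4", "N-067", "N-078")
            },
        )
        out.append((record, expectation))
    return out
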