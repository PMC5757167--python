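"""Similar-class partitioning of the training set and subdictionary assembly.

The training rasters are divided into m + 1 groups against m representative
"typical shape" images t_1..t_m: sample x_i joins the group of its most
similar representative provided that similarity clears a threshold T;
samples similar to no representative fall into the overflow group m + 1.
Each group's rasters, flattened column-wise, form one subdictionary A_j —
the small dictionary a routed test sample is sparsely coded on.

At test time a sample is routed to the group of its most similar
representative (threshold T1, typically looser than T), or to the overflow
group when nothing is similar enough.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging import ContourRaster
from .similarity import cross_distances

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "RepresentativeSet",
    "SimilarClassPartition",
    "Subdictionary",
    "assign_groups",
    "build_subdictionaries",
    "route_test",
    "similarity_to_reps",
]


@dataclass
class TrainingSet:
    """n labelled contour rasters spanning C species."""

    rasters: list
    species: list

    def __post_init__(self):
        if len(self.rasters) != len(self.species):
            raise ValueError("rasters and species must have equal length")
        if len(self.rasters) == 0:
            raise ValueError("training set is empty")

    def __len__(self) -> int:
        return len(self.rasters)

    @property
    def n_species(self) -> int:
        return len(set(self.species))


@dataclass
class RepresentativeSet:
    """The m typical-shape prototype rasters t_j, one per shape family."""

    rasters: list
    names: list

    def __post_init__(self):
        if len(self.rasters) != len(self.names):
            raise ValueError("rasters and names must have equal length")
        if len(self.rasters) == 0:
            raise ValueError("need at least one representative")

    def __len__(self) -> int:
        return len(self.rasters)


@dataclass
class SimilarClassPartition:
    """Group index (1..m+1) for every training sample; m+1 is the overflow."""

    group_of: np.ndarray
    threshold_T: float
    beta: float
    n_reps: int

    def __post_init__(self):
        self.group_of = np.asarray(self.group_of, dtype=int)
        if self.group_of.min() < 1 or self.group_of.max() > self.n_reps + 1:
            raise ValueError("group indices must lie in 1..m+1")

    @property
    def overflow_size(self) -> int:
        return int(np.sum(self.group_of == self.n_reps + 1))

    def to_json(self, path: str | Path, sample_ids: Sequence[str] | None = None) -> None:
        ids = list(sample_ids) if sample_ids is not None else [
            str(i) for i in range(len(self.group_of))
        ]
        payload = {
            "threshold_T": self.threshold_T,
            "beta": self.beta,
            "n_reps": self.n_reps,
            "group_of": dict(zip(ids, (int(g) for g in self.group_of))),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class Subdictionary:
    """Column matrix A_j (d x n_j) of one similar class, with per-column labels."""

    atoms: np.ndarray
    species_of_col: list
    group_id: int
    source_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a 2-D matrix")
        if self.atoms.shape[1] != len(self.species_of_col):
            raise ValueError("column count must equal label count")
        if self.atoms.shape[1] == 0:
            raise ValueError("subdictionary must have at least one column")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def species(self) -> list:
        return sorted(set(self.species_of_col))

    def class_counts(self) -> dict:
        """n_c: number of columns per species in this group."""
        counts: dict = {}
        for s in self.species_of_col:
            counts[s] = counts.get(s, 0) + 1
        return counts


def similarity_to_reps(rasters: Sequence, reps: RepresentativeSet, beta: float) -> np.ndarray:
    """(len(rasters), m) matrix of Gaussian similarities to the representatives."""
    d = cross_distances(rasters, reps.rasters)
    return np.exp(-(d * d) / (2.0 * beta * beta))


def assign_groups(
    train: TrainingSet, reps: RepresentativeSet, T: float, beta: float
) -> SimilarClassPartition:
    """Partition the training set into m + 1 similar classes.

    Sample x_i goes to argmax_j s(x_i, t_j) among representatives with
    s >= T (exact ties to the lowest group index, via argmax); when no
    representative passes the threshold it goes to the overflow group m + 1.
    """
    if not (0 < T < 1):
        raise ValueError(f"threshold T must lie in (0, 1), got {T}")
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    s = similarity_to_reps(train.rasters, reps, beta)
    best = np.argmax(s, axis=1)
    passed = s[np.arange(len(train)), best] >= T
    groups = np.where(passed, best + 1, len(reps) + 1)
    part = SimilarClassPartition(groups, threshold_T=T, beta=beta, n_reps=len(reps))
    logger.info(
        "partitioned %d samples into %d named groups (+%d overflow)",
        len(train),
        len(np.unique(groups[groups <= len(reps)])),
        part.overflow_size,
    )
    return part


def build_subdictionaries(
    train: TrainingSet, part: SimilarClassPartition
) -> list[Subdictionary]:
    """One subdictionary per nonempty group; empty groups are dropped with a
    warning.  Column k of A_j is the row-major flattening of the k-th member
    raster, so every column is traceable to its training index and species."""
    if len(part.group_of) != len(train):
        raise ValueError("partition length does not match training set")
    dicts = []
    for j in range(1, part.n_reps + 2):
        idx = np.flatnonzero(part.group_of == j)
        if idx.size == 0:
            logger.warning("similar class %d is empty; skipped", j)
            continue
        atoms = np.stack(
            [np.asarray(train.rasters[i].pixels).ravel() for i in idx], axis=1
        )
        dicts.append(
            Subdictionary(
                atoms=atoms,
                species_of_col=[train.species[i] for i in idx],
                group_id=j,
                source_ids=[
                    getattr(train.rasters[i], "source_id", str(i)) or str(i)
                    for i in idx
                ],
            )
        )
    return dicts


def route_test(
    y: ContourRaster,
    reps: RepresentativeSet,
    T1: float,
    beta: float,
    dicts: Sequence[Subdictionary],
) -> Subdictionary:
    """Pick the candidate subdictionary for a test raster.

    Returns the group of the most similar representative when that
    similarity reaches T1, else the overflow subdictionary.  A routed-to
    group with no dictionary (it was empty at training time) falls back to
    the overflow; if the overflow is missing too, routing fails.
    """
    if not (0 < T1 < 1):
        raise ValueError(f"threshold T1 must lie in (0, 1), got {T1}")
    by_group = {d.group_id: d for d in dicts}
    m = len(reps)
    s = similarity_to_reps([y], reps, beta)[0]
    j = int(np.argmax(s)) + 1
    target = j if s[j - 1] >= T1 else m + 1
    if target in by_group:
        return by_group[target]
    if target != m + 1:
        logger.warning("routed group %d has no dictionary; using overflow", target)
        if m + 1 in by_group:
            return by_group[m + 1]
    raise ValueError(
        f"cannot route test sample: group {target} and overflow are both empty"
    )
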