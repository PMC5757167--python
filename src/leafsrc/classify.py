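"""End-to-end sparse-representation classifiers and the evaluation harness.

Three classifiers share one machinery:

* SRC  — sparse-code the test vector on the global dictionary of all
  training atoms (uniform l1 weights); label by the class with minimum
  reconstruction residual ||y - A a^c||.
* WSRC — same global dictionary, but the l1 penalty carries per-atom
  weights from the thresholded-similarity scheme, so the code prefers
  atoms near the test sample.
* DWSRC — two stages.  The training set is pre-partitioned into shape-
  similar groups against representative leaves; the test sample is routed
  to the most similar group and coded only on that group's subdictionary
  with distance-penalizing Gaussian weights (width set per test sample by
  the midrange rule).  The label is the class with minimum size-normalized
  residual m_c(y) = ||y - A_r a^c|| / n_c, which corrects for groups in
  which species contribute different numbers of atoms.

The evaluation harness provides the two hold-out protocols used for leaf
databases (k images per species, or k images overall) with repeated random
splits and reports accuracy, per-class accuracy, a confusion table, and the
mean sparse-code support size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .imaging import ContourRaster, PreprocessConfig, preprocess
from .partition import (
    RepresentativeSet,
    SimilarClassPartition,
    Subdictionary,
    TrainingSet,
    assign_groups,
    build_subdictionaries,
    route_test,
)
from .similarity import auto_width
from .sparse import (
    SolverConfig,
    SparseCode,
    solve_weighted_l1,
    weights_gaussian,
    weights_similarity,
    weights_uniform,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DwsrcConfig",
    "DwsrcModel",
    "ClassificationResult",
    "EvalReport",
    "build_model",
    "class_errors",
    "classify_dwsrc",
    "classify_wsrc",
    "classify_src",
    "evaluate",
    "evaluate_repeated",
    "holdout_split",
    "global_dictionary",
]


@dataclass
class DwsrcConfig:
    """Classifier settings.

    T       partition threshold: training similarity to a representative
            needed to join its group
    T1      routing threshold for test samples (looser than T by default)
    mu      l1 regularizer of the sparse coder
    beta    partition/routing kernel width; None = midrange rule over all
            (training, representative) pairs
    beta1   atom-weight kernel width; None = midrange rule per test sample
    weight_scheme  'gaussian_distance' (distance-penalizing, DWSRC default),
            'thresholded_similarity' (thresholded similarity, WSRC convention) or
            'uniform'
    decision  'normalized' divides each class residual by its atom count
            (DWSRC convention); 'plain' uses the raw residual (SRC/WSRC
            convention)
    """

    T: float = 0.5
    T1: float = 0.1
    mu: float = 0.001
    beta: Optional[float] = None
    beta1: Optional[float] = None
    weight_scheme: str = "gaussian_distance"
    decision: str = "normalized"
    max_iter: int = 10_000
    tol: float = 1e-8
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def solver(self) -> SolverConfig:
        return SolverConfig(mu=self.mu, max_iter=self.max_iter, tol=self.tol)


@dataclass
class DwsrcModel:
    """A trained DWSRC model: representatives, partition, subdictionaries."""

    reps: RepresentativeSet
    partition: SimilarClassPartition
    dicts: list
    config: DwsrcConfig

    @property
    def beta(self) -> float:
        return self.partition.beta


@dataclass
class ClassificationResult:
    predicted: str
    errors: dict
    group_used: int
    code: Optional[SparseCode] = None

    def top_errors(self, k: int = 3) -> list:
        return sorted(self.errors.items(), key=lambda kv: (kv[1], kv[0]))[:k]


@dataclass
class EvalReport:
    accuracy: float
    per_class_accuracy: dict
    n_test: int
    mean_nnz: float
    confusion: pd.DataFrame

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 100.0):
            raise ValueError("accuracy must be a percentage in [0, 100]")


def build_model(
    train: TrainingSet, reps: RepresentativeSet, config: Optional[DwsrcConfig] = None
) -> DwsrcModel:
    """Partition the training set against the representatives and assemble
    the per-group subdictionaries."""
    config = config or DwsrcConfig()
    beta = config.beta if config.beta is not None else auto_width(
        train.rasters, reps.rasters
    )
    part = assign_groups(train, reps, config.T, beta)
    dicts = build_subdictionaries(train, part)
    return DwsrcModel(reps=reps, partition=part, dicts=dicts, config=config)


def class_errors(
    y, dict_: Subdictionary, code: SparseCode, normalized: bool = True
) -> dict:
    """Per-species reconstruction error of the sparse code.

    For each species c present in the subdictionary the code is restricted
    to that species' columns and the l2 residual ||y - A a^c|| computed;
    with normalized=True it is divided by n_c, the species' atom count in
    the group."""
    yv = np.asarray(getattr(y, "pixels", y), dtype=float).ravel()
    if code.a.size != dict_.n_atoms:
        raise ValueError("code length does not match dictionary column count")
    labels = np.asarray(dict_.species_of_col)
    errors: dict = {}
    for c in dict_.species:
        mask = labels == c
        resid = yv - dict_.atoms[:, mask] @ code.a[mask]
        err = float(np.linalg.norm(resid))
        if normalized:
            err /= int(mask.sum())
        errors[c] = err
    return errors


def _argmin_label(errors: dict) -> str:
    # ties broken by lexicographically smallest label
    return min(errors, key=lambda c: (errors[c], c))


def _as_raster(y, cfg: PreprocessConfig) -> ContourRaster:
    if isinstance(y, ContourRaster):
        return y
    return preprocess(np.asarray(y), cfg)


def _exact_match_result(y, dict_: Subdictionary) -> ClassificationResult:
    """Degenerate case: every candidate atom equals y; classify by identity."""
    errors = {c: 0.0 for c in dict_.species}
    return ClassificationResult(
        predicted=_argmin_label(errors),
        errors=errors,
        group_used=dict_.group_id,
        code=None,
    )


def classify_dwsrc(y, model: DwsrcModel) -> ClassificationResult:
    """Route -> weight -> sparse-code -> size-normalized residual -> argmin."""
    cfg = model.config
    raster = _as_raster(y, cfg.preprocess)
    cand = route_test(raster, model.reps, cfg.T1, model.beta, model.dicts)

    yv = raster.vector
    d = np.linalg.norm(cand.atoms - yv[:, None], axis=0)
    if d.max() == 0.0:
        return _exact_match_result(raster, cand)

    if cfg.weight_scheme == "gaussian_distance":
        beta1 = cfg.beta1 if cfg.beta1 is not None else 0.5 * (d.max() + d.min())
        w = weights_gaussian(raster, cand, beta1)
    elif cfg.weight_scheme == "thresholded_similarity":
        beta1 = cfg.beta1 if cfg.beta1 is not None else 0.5 * (d.max() + d.min())
        w = weights_similarity(raster, cand, beta1, cfg.T)
    elif cfg.weight_scheme == "uniform":
        w = weights_uniform(cand.n_atoms)
    else:
        raise ValueError(f"unknown weight scheme {cfg.weight_scheme!r}")

    code = solve_weighted_l1(yv, cand.atoms, w, cfg.solver())
    errors = class_errors(yv, cand, code, normalized=(cfg.decision == "normalized"))
    return ClassificationResult(
        predicted=_argmin_label(errors),
        errors=errors,
        group_used=cand.group_id,
        code=code,
    )


def global_dictionary(train: TrainingSet) -> Subdictionary:
    """All n training atoms stacked as one dictionary (SRC/WSRC baseline)."""
    atoms = np.stack([np.asarray(r.pixels).ravel() for r in train.rasters], axis=1)
    return Subdictionary(
        atoms=atoms, species_of_col=list(train.species), group_id=0
    )


def _classify_global(
    y, train: TrainingSet, config: DwsrcConfig, weighted: bool
) -> ClassificationResult:
    raster = _as_raster(y, config.preprocess)
    dict_ = global_dictionary(train)
    yv = raster.vector
    d = np.linalg.norm(dict_.atoms - yv[:, None], axis=0)
    if d.max() == 0.0:
        return _exact_match_result(raster, dict_)
    if weighted:
        beta1 = config.beta1 if config.beta1 is not None else 0.5 * (d.max() + d.min())
        w = weights_similarity(raster, dict_, beta1, config.T)
    else:
        w = weights_uniform(dict_.n_atoms)
    code = solve_weighted_l1(yv, dict_.atoms, w, config.solver())
    errors = class_errors(yv, dict_, code, normalized=(config.decision == "normalized"))
    return ClassificationResult(
        predicted=_argmin_label(errors),
        errors=errors,
        group_used=0,
        code=code,
    )


def classify_wsrc(
    y, train: TrainingSet, config: Optional[DwsrcConfig] = None
) -> ClassificationResult:
    """Weighted SRC on the global dictionary with thresholded-similarity
    weights; decision by minimum raw residual."""
    config = config or DwsrcConfig(weight_scheme="thresholded_similarity", decision="plain")
    return _classify_global(y, train, config, weighted=True)


def classify_src(
    y, train: TrainingSet, config: Optional[DwsrcConfig] = None
) -> ClassificationResult:
    """Plain SRC on the global dictionary; decision by minimum raw residual."""
    config = config or DwsrcConfig(weight_scheme="uniform", decision="plain")
    return _classify_global(y, train, config, weighted=False)


def _default_config(method: str) -> DwsrcConfig:
    if method == "dwsrc":
        return DwsrcConfig()
    return DwsrcConfig(
        weight_scheme="thresholded_similarity" if method == "wsrc" else "uniform",
        decision="plain",
    )


def evaluate(
    train: TrainingSet,
    test: TrainingSet,
    reps: Optional[RepresentativeSet] = None,
    method: str = "dwsrc",
    config: Optional[DwsrcConfig] = None,
) -> EvalReport:
    """Classify every test raster against the training set and summarize.

    Species present in the test set but absent from training are counted as
    errors and logged.  The run is fully deterministic."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    if method not in ("dwsrc", "wsrc", "src"):
        raise ValueError(f"unknown method {method!r}")
    config = config or _default_config(method)
    if method == "dwsrc":
        if reps is None:
            raise ValueError("DWSRC evaluation needs a representative set")
        model = build_model(train, reps, config)

    train_species = set(train.species)
    species_all = sorted(train_species | set(test.species))
    confusion = pd.DataFrame(
        0, index=species_all, columns=species_all, dtype=int
    )
    nnz_values = []
    correct = 0
    for raster, truth in zip(test.rasters, test.species):
        if method == "dwsrc":
            res = classify_dwsrc(raster, model)
        elif method == "wsrc":
            res = classify_wsrc(raster, train, config)
        else:
            res = classify_src(raster, train, config)
        if truth not in train_species:
            logger.warning("test species %r absent from training set", truth)
        confusion.loc[truth, res.predicted] += 1
        if res.code is not None:
            nnz_values.append(res.code.nnz)
        if res.predicted == truth:
            correct += 1

    per_class = {}
    for c in sorted(set(test.species)):
        row = confusion.loc[c]
        total = int(row.sum())
        per_class[c] = 100.0 * int(row.get(c, 0)) / total if total else float("nan")
    return EvalReport(
        accuracy=100.0 * correct / len(test),
        per_class_accuracy=per_class,
        n_test=len(test),
        mean_nnz=float(np.mean(nnz_values)) if nnz_values else 0.0,
        confusion=confusion,
    )


def holdout_split(
    data: TrainingSet,
    per_species: Optional[int] = None,
    n_random: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[TrainingSet, TrainingSet]:
    """Random train/test split by one of the two standard protocols:
    hold out `per_species` images from every species, or `n_random` images
    overall."""
    if (per_species is None) == (n_random is None):
        raise ValueError("specify exactly one of per_species / n_random")
    rng = rng or np.random.default_rng()
    n = len(data)
    if per_species is not None:
        test_idx: list = []
        labels = np.asarray(data.species)
        for c in sorted(set(data.species)):
            members = np.flatnonzero(labels == c)
            if members.size <= per_species:
                raise ValueError(
                    f"species {c!r} has only {members.size} samples; cannot hold out {per_species}"
                )
            test_idx.extend(rng.choice(members, size=per_species, replace=False))
        test_idx = np.sort(np.asarray(test_idx))
    else:
        if n_random >= n:
            raise ValueError("cannot hold out the whole dataset")
        test_idx = np.sort(rng.choice(n, size=n_random, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    tr = TrainingSet(
        [data.rasters[i] for i in range(n) if not mask[i]],
        [data.species[i] for i in range(n) if not mask[i]],
    )
    te = TrainingSet(
        [data.rasters[i] for i in range(n) if mask[i]],
        [data.species[i] for i in range(n) if mask[i]],
    )
    return tr, te


def evaluate_repeated(
    data: TrainingSet,
    reps: Optional[RepresentativeSet] = None,
    method: str = "dwsrc",
    config: Optional[DwsrcConfig] = None,
    per_species: Optional[int] = 5,
    n_random: Optional[int] = None,
    repeats: int = 10,
    seed: int = 0,
) -> dict:
    """Repeat a random hold-out split `repeats` times; report the accuracy
    mean and standard deviation plus the individual reports."""
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(repeats):
        tr, te = holdout_split(data, per_species=per_species, n_random=n_random, rng=rng)
        reports.append(evaluate(tr, te, reps=reps, method=method, config=config))
    acc = np.array([r.accuracy for r in reports])
    return {
        "mean_accuracy": float(acc.mean()),
        "sd_accuracy": float(acc.std(ddof=1)) if repeats > 1 else 0.0,
        "mean_nnz": float(np.mean([r.mean_nnz for r in reports])),
        "reports": reports,
    }
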