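"""Serialization of trained models to a plain-text directory layout.

A model directory contains:

    config.json        classifier settings (schema-versioned)
    partition.json     sample-id -> group-id map, plus T, beta, m
    reps/<name>.csv    representative rasters, one CSV matrix each
    dicts/group_<j>.csv         subdictionary atoms (d x n_j)
    dicts/group_<j>.meta.json   group id, per-column species and source ids

Everything is CSV/JSON so models diff cleanly and survive text-only
transport.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .classify import DwsrcConfig, DwsrcModel
from .imaging import ContourRaster, PreprocessConfig
from .partition import RepresentativeSet, SimilarClassPartition, Subdictionary

__all__ = ["save_model", "load_model"]

SCHEMA_VERSION = 1


def save_model(model: DwsrcModel, path: str | Path) -> None:
    path = Path(path)
    (path / "reps").mkdir(parents=True, exist_ok=True)
    (path / "dicts").mkdir(exist_ok=True)

    cfg = asdict(model.config)
    cfg["schema_version"] = SCHEMA_VERSION
    (path / "config.json").write_text(json.dumps(cfg, indent=2))

    model.partition.to_json(path / "partition.json")

    for raster, name in zip(model.reps.rasters, model.reps.names):
        np.savetxt(path / "reps" / f"{name}.csv", raster.pixels, delimiter=",", fmt="%.8g")
    (path / "reps" / "names.json").write_text(json.dumps(list(model.reps.names)))

    for d in model.dicts:
        np.savetxt(
            path / "dicts" / f"group_{d.group_id}.csv", d.atoms, delimiter=",", fmt="%.8g"
        )
        meta = {
            "group_id": d.group_id,
            "species_of_col": list(d.species_of_col),
            "source_ids": list(d.source_ids),
        }
        (path / "dicts" / f"group_{d.group_id}.meta.json").write_text(
            json.dumps(meta, indent=2)
        )


def load_model(path: str | Path) -> DwsrcModel:
    path = Path(path)
    cfg = json.loads((path / "config.json").read_text())
    version = cfg.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r}")
    pre = cfg.pop("preprocess", None)
    config = DwsrcConfig(**cfg)
    if pre is not None:
        config.preprocess = PreprocessConfig(**pre)

    part_raw = json.loads((path / "partition.json").read_text())
    partition = SimilarClassPartition(
        group_of=np.array(list(part_raw["group_of"].values()), dtype=int),
        threshold_T=part_raw["threshold_T"],
        beta=part_raw["beta"],
        n_reps=part_raw["n_reps"],
    )

    names = json.loads((path / "reps" / "names.json").read_text())
    reps = RepresentativeSet(
        rasters=[
            ContourRaster(np.loadtxt(path / "reps" / f"{n}.csv", delimiter=","), source_id=n)
            for n in names
        ],
        names=names,
    )

    dicts = []
    for meta_file in sorted((path / "dicts").glob("group_*.meta.json")):
        meta = json.loads(meta_file.read_text())
        atoms = np.loadtxt(
            meta_file.with_name(f"group_{meta['group_id']}.csv"), delimiter=","
        )
        if atoms.ndim == 1:  # single-column dictionary
            atoms = atoms[:, None]
        dicts.append(
            Subdictionary(
                atoms=atoms,
                species_of_col=meta["species_of_col"],
                group_id=meta["group_id"],
                source_ids=meta["source_ids"],
            )
        )
    dicts.sort(key=lambda d: d.group_id)
    return DwsrcModel(reps=reps, partition=partition, dicts=dicts, config=config)
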