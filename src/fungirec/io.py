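"""Readers and writers for the tabular interchange formats.

* posterior matrices — CSV, header row = species ids, first column =
  observation id;
* priors — JSON mapping species id -> probability;
* metadata — CSV with columns ``observation_id,habitat,substrate,month``
  (empty cell = missing);
* labels — CSV with columns ``observation_id,species_id``;
* frequency models, crop specs, reports — JSON.

Numeric output uses 9 significant digits: below the validation
tolerance, above the test tolerances, so round-trips are lossless at the
precision the pipeline cares about.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LabelSpace, MetadataTable, PosteriorMatrix, PriorVector
from .errors import ParseError
from .metadata_fusion import FrequencyModel
from .tta import CropSpec

FLOAT_FMT = "{:.9g}"


def _fmt(x: float) -> str:
    return FLOAT_FMT.format(float(x))


# -- posterior matrices ----------------------------------------------------

def write_posteriors(matrix: PosteriorMatrix, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["observation_id", *matrix.space.species_ids])
        for obs, row in zip(matrix.observation_ids, matrix.values):
            w.writerow([obs, *(_fmt(x) for x in row)])


def read_posteriors(path, space: LabelSpace | None = None) -> PosteriorMatrix:
    """Read a posterior CSV; the header defines (or must match) the space."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty posterior file", path) from None
        if not header or header[0] != "observation_id":
            raise ParseError("first column must be 'observation_id'", path, 1)
        species = header[1:]
        if len(set(species)) != len(species):
            dupes = sorted({s for s in species if species.count(s) > 1})
            raise ParseError(f"duplicated species columns {dupes}", path, 1)
        file_space = LabelSpace(tuple(species))
        if space is not None and space.species_ids != file_space.species_ids:
            raise ParseError("species columns do not match the expected label space", path, 1)
        obs_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise ParseError(
                    f"expected {len(header)} cells, found {len(rec)}", path, lineno
                )
            obs_ids.append(rec[0])
            try:
                rows.append([float(x) for x in rec[1:]])
            except ValueError:
                raise ParseError("non-numeric probability cell", path, lineno) from None
    if not rows:
        raise ParseError("posterior file has no data rows", path)
    try:
        return PosteriorMatrix(np.array(rows), tuple(obs_ids), file_space)
    except ValueError as exc:
        raise ParseError(f"invalid posteriors: {exc}", path) from exc


# -- priors ----------------------------------------------------------------

def write_prior(prior: PriorVector, space: LabelSpace, path) -> None:
    payload = {s: float(p) for s, p in zip(space.species_ids, prior.values)}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_prior(path, space: LabelSpace) -> PriorVector:
    path = Path(path)
    payload = json.loads(path.read_text())
    missing = [s for s in space.species_ids if s not in payload]
    if missing:
        raise ParseError(f"prior lacks species {missing[:5]}", path)
    extra = [s for s in payload if s not in space]
    if extra:
        raise ParseError(f"prior has unknown species {extra[:5]}", path)
    return PriorVector(np.array([payload[s] for s in space.species_ids], dtype=float))


# -- metadata and labels ---------------------------------------------------

def write_metadata(metadata: MetadataTable, path) -> None:
    df = metadata.frame.copy()
    df.insert(0, "observation_id", df.index)
    df.to_csv(path, index=False)


def read_metadata(path) -> MetadataTable:
    path = Path(path)
    df = pd.read_csv(path, dtype={"habitat": "string", "substrate": "string"})
    if "observation_id" not in df.columns:
        raise ParseError("metadata needs an 'observation_id' column", path, 1)
    df = df.set_index("observation_id")
    if "month" in df.columns:
        month = pd.to_numeric(df["month"], errors="coerce")
        bad = month.notna() & ((month < 1) | (month > 12) | (month % 1 != 0))
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(f"month out of range 1-12 for observation {row!r}", path)
    try:
        return MetadataTable(df)
    except ValueError as exc:
        raise ParseError(str(exc), path) from exc


def write_labels(observation_ids, labels, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["observation_id", "species_id"])
        for obs, sp in zip(observation_ids, labels):
            w.writerow([obs, sp])


def read_labels(path) -> tuple[list[str], list[str]]:
    """Return aligned (observation_ids, species_labels)."""
    path = Path(path)
    obs, labs = [], []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[:2] != ["observation_id", "species_id"]:
            raise ParseError("labels need columns observation_id,species_id", path, 1)
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) < 2:
                raise ParseError("short label row", path, lineno)
            obs.append(rec[0])
            labs.append(rec[1])
    return obs, labs


# -- misc structured text --------------------------------------------------

def write_frequency_model(model: FrequencyModel, path) -> None:
    Path(path).write_text(model.to_json())


def read_frequency_model(path) -> FrequencyModel:
    return FrequencyModel.from_json(Path(path).read_text())


def write_crop_specs(specs: list[CropSpec], path) -> None:
    payload = [
        {"box": list(s.box), "mirrored": s.mirrored} for s in specs
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_crop_specs(path) -> list[CropSpec]:
    payload = json.loads(Path(path).read_text())
    return [CropSpec(tuple(e["box"]), bool(e["mirrored"])) for e in payload]


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
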