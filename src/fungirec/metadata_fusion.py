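"""Bayesian fusion of image posteriors with categorical observation metadata.

The model: for metadata value ``d`` of a given type, the conditional
``p(s|d)`` is estimated as the (optionally smoothed) relative frequency of
species ``s`` among training observations carrying ``d``. Assuming the
visual appearance of a species is conditionally independent of the
metadata given the species, the fused posterior for observation ``i`` with
selected, non-missing metadata values ``d_1..d_m`` is

    p(s | i, d_1..d_m)  ∝  p(s|i) * Π_j p(s|d_j) / p(s)^m

renormalized per row. Observations missing a selected type simply skip
that factor (``m`` shrinks); with all factors missing the visual
posterior passes through unchanged.

Products are taken in log space — three factors over ~1600 classes
underflow in linear space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    METADATA_TYPES,
    LabelSpace,
    MetadataTable,
    PosteriorMatrix,
    PriorVector,
    check_prior_supports,
)
from .errors import AlignmentError, DegenerateRowError, ShapeError


def _check_month(value) -> int:
    m = int(value)
    if not 1 <= m <= 12:
        raise ValueError(f"month must be in 1..12, got {m}")
    return m


def _norm_value(mtype: str, value) -> str:
    """Canonical string key for a metadata value (months validated)."""
    if mtype == "month":
        return str(_check_month(value))
    return str(value)


@dataclass
class FrequencyModel:
    """Smoothed species-given-metadata frequency tables plus fallback prior.

    ``tables[type][value]`` is a length-K probability vector ``p(s|value)``.
    Lookups of values never seen in training fall back to ``train_prior``.
    Optional joint tables over type pairs (``joint_tables[(t1, t2)]``)
    hold directly-estimated ``p(s | d1, d2)`` for pairs with enough
    training support.
    """

    space: LabelSpace
    train_prior: PriorVector
    tables: dict[str, dict[str, np.ndarray]]
    alpha: dict[str, float]
    joint_tables: dict[tuple[str, str], dict[tuple[str, str], np.ndarray]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        if self.train_prior.k != self.space.k:
            raise ShapeError("train prior does not match label space")
        for mtype, table in self.tables.items():
            if mtype not in METADATA_TYPES:
                raise KeyError(f"unknown metadata type {mtype!r}")
            for value, vec in table.items():
                vec = np.asarray(vec, dtype=float)
                if vec.shape != (self.space.k,):
                    raise ShapeError(f"table {mtype}={value!r} has shape {vec.shape}")
                if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"table {mtype}={value!r} is not a distribution"
                    )
                table[value] = vec

    def to_json(self) -> str:
        payload = {
            "species": list(self.space.species_ids),
            "train_prior": {
                s: p for s, p in zip(self.space.species_ids, self.train_prior.values)
            },
            "alpha": self.alpha,
            "tables": {
                mtype: {
                    value: {
                        s: float(p)
                        for s, p in zip(self.space.species_ids, vec)
                    }
                    for value, vec in table.items()
                }
                for mtype, table in self.tables.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FrequencyModel":
        payload = json.loads(text)
        space = LabelSpace(tuple(payload["species"]))
        prior = PriorVector(
            np.array([payload["train_prior"][s] for s in space.species_ids])
        )
        tables = {
            mtype: {
                value: np.array([entry[s] for s in space.species_ids])
                for value, entry in table.items()
            }
            for mtype, table in payload["tables"].items()
        }
        return cls(space, prior, tables, {k: float(v) for k, v in payload["alpha"].items()})


def fit_frequency_model(
    labels: Sequence[str],
    metadata: MetadataTable,
    space: LabelSpace,
    alpha: float | Mapping[str, float] = 0.0,
    joint_types: tuple[str, str] | None = None,
    min_joint_count: int = 10,
) -> FrequencyModel:
    """Fit ``p(s|d)`` tables by (smoothed) relative frequency.

    For each metadata type and each value ``d`` occurring at least once,
    ``p(s|d) = (count(s, d) + alpha) / (count(d) + K * alpha)``;
    observations with missing ``d`` are excluded from that type's counts.

    Parameters
    ----------
    labels, metadata
        Training species labels and metadata, aligned by position.
    alpha
        Pseudocount, either one number for all types or per-type mapping.
    joint_types
        Optional pair of types for which ``p(s|d1,d2)`` is additionally
        estimated directly from joint counts; only pairs observed at
        least ``min_joint_count`` times are stored. Off by default — the
        baseline combines types under the independence assumption.
    """
    labels = list(labels)
    if len(labels) != len(metadata):
        raise AlignmentError(
            f"{len(labels)} labels for {len(metadata)} metadata records"
        )
    if isinstance(alpha, Mapping):
        alphas = {t: float(alpha.get(t, 0.0)) for t in METADATA_TYPES}
    else:
        alphas = {t: float(alpha) for t in METADATA_TYPES}
    if any(a < 0 for a in alphas.values()):
        raise ValueError("alpha must be non-negative")

    label_idx = space.indices_of(labels)
    k = space.k

    tables: dict[str, dict[str, np.ndarray]] = {}
    for mtype in METADATA_TYPES:
        col = metadata.column(mtype)
        a = alphas[mtype]
        table: dict[str, np.ndarray] = {}
        present = ~col.isna().to_numpy()
        values = col.to_numpy(dtype=object)
        groups: dict[str, np.ndarray] = {}
        for i in np.flatnonzero(present):
            key = _norm_value(mtype, values[i])
            groups.setdefault(key, []).append(label_idx[i])
        for key, members in groups.items():
            counts = np.bincount(members, minlength=k).astype(float)
            table[key] = (counts + a) / (counts.sum() + k * a)
        tables[mtype] = table

    train_prior = PriorVector(
        np.bincount(label_idx, minlength=k).astype(float) / len(labels)
    )
    model = FrequencyModel(space, train_prior, tables, alphas)

    if joint_types is not None:
        t1, t2 = joint_types
        c1, c2 = metadata.column(t1), metadata.column(t2)
        ok = (~c1.isna() & ~c2.isna()).to_numpy()
        joint: dict[tuple[str, str], np.ndarray] = {}
        groups = {}
        v1 = c1.to_numpy(dtype=object)
        v2 = c2.to_numpy(dtype=object)
        for i in np.flatnonzero(ok):
            key = (_norm_value(t1, v1[i]), _norm_value(t2, v2[i]))
            groups.setdefault(key, []).append(label_idx[i])
        a = 0.5 * (alphas[t1] + alphas[t2])
        for key, members in groups.items():
            if len(members) < min_joint_count:
                continue
            counts = np.bincount(members, minlength=k).astype(float)
            joint[key] = (counts + a) / (counts.sum() + k * a)
        model.joint_tables[(t1, t2)] = joint
    return model


def species_given_metadata(model: FrequencyModel, mtype: str, value) -> np.ndarray:
    """Return ``p(s|value)`` for one metadata value, or the train prior.

    Values never observed in training fall back to the model's training
    prior (an uninformative factor under the fusion rule). Unknown
    metadata types and out-of-range months raise.
    """
    if mtype not in METADATA_TYPES:
        raise KeyError(f"unknown metadata type {mtype!r}; expected {METADATA_TYPES}")
    key = _norm_value(mtype, value)
    table = model.tables.get(mtype, {})
    if key in table:
        return table[key]
    return model.train_prior.values.copy()


def fuse(
    post: PosteriorMatrix,
    metadata: MetadataTable,
    model: FrequencyModel,
    types: Sequence[str] = METADATA_TYPES,
    use_joint: bool = False,
) -> PosteriorMatrix:
    """Combine image posteriors with metadata frequency factors.

    Row ``i`` becomes ``p(s|i) * Π p(s|d) / p(s)^m`` over the selected,
    non-missing types, renormalized. Rows with every selected type
    missing are returned unchanged. With ``use_joint=True``, pairs of
    types covered by a fitted joint table use the directly-estimated
    ``p(s|d1,d2)`` (one division by ``p(s)``) when the pair was seen
    often enough in training, falling back to independence otherwise.
    """
    types = list(types)
    unknown = [t for t in types if t not in METADATA_TYPES]
    if unknown:
        raise KeyError(f"unknown metadata types {unknown}")
    if len(set(types)) != len(types):
        raise ValueError("duplicate metadata types selected")
    metadata.check_aligned(post.observation_ids)
    if model.space.species_ids != post.space.species_ids:
        raise ShapeError("frequency model fitted on a different label space")
    check_prior_supports(model.train_prior, post.values, post.space)
    if not types:
        return post

    prior = model.train_prior.values
    live = prior > 0
    with np.errstate(divide="ignore"):
        log_prior = np.where(live, np.log(np.where(live, prior, 1.0)), -np.inf)
        log_post = np.log(post.values)

    out = np.empty_like(post.values)
    for i, obs in enumerate(post.observation_ids):
        factors: list[np.ndarray] = []
        remaining = []
        for t in types:
            v = metadata.value(obs, t)
            if v is not None:
                remaining.append((t, v))
        if use_joint:
            for (t1, t2), table in model.joint_tables.items():
                have = dict(remaining)
                if t1 in have and t2 in have:
                    key = (_norm_value(t1, have[t1]), _norm_value(t2, have[t2]))
                    if key in table:
                        factors.append(table[key])
                        remaining = [(t, v) for t, v in remaining if t not in (t1, t2)]
        for t, v in remaining:
            factors.append(species_given_metadata(model, t, v))
        if not factors:
            out[i] = post.values[i]
            continue
        m = len(factors)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_row = log_post[i] - m * log_prior
            for f in factors:
                log_row = log_row + np.log(f)
        log_row[post.values[i] == 0] = -np.inf
        log_row[~live] = -np.inf
        peak = log_row.max()
        if peak == -np.inf:
            raise DegenerateRowError([i])
        row = np.exp(log_row - peak)
        out[i] = row / row.sum()
    return post.replace_values(out)
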