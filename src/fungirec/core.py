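"""Shared probability containers, validation and normalization.

Every other module exchanges data through the types defined here:

* :class:`LabelSpace` — the ordered species list; column ``j`` of every
  matrix in a run refers to ``species_ids[j]``.
* :class:`PriorVector` — a categorical distribution over the species list.
* :class:`PosteriorMatrix` — per-observation species probabilities
  (rows = observations, columns = species).
* :class:`MetadataTable` — per-observation categorical metadata
  (habitat, substrate, month) with explicit missing values.

Probabilities are stored in linear space; modules that multiply many
factors work in log space internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateRowError, ShapeError

#: Row sums within this tolerance of 1 are renormalized silently; larger
#: drift is treated as a bug in the producing code and rejected.
ROW_SUM_TOL = 1e-6

#: Tolerance for prior vectors, which are short enough to stay near-exact.
PRIOR_SUM_TOL = 1e-9

METADATA_TYPES = ("habitat", "substrate", "month")


def normalize_rows(scores) -> np.ndarray:
    """Scale each row of a non-negative score matrix to sum to one.

    Parameters
    ----------
    scores
        ``(N, K)`` array-like of non-negative scores. A 1-D input is
        treated as a single row.

    Returns
    -------
    numpy.ndarray
        Array of the same shape whose rows each sum to 1.

    Raises
    ------
    DegenerateRowError
        If any row has zero total mass (empty support).
    ValueError
        If any entry is negative or non-finite.
    """
    arr = np.asarray(scores, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    if np.any(arr < 0):
        raise ValueError("scores must be non-negative")
    sums = arr.sum(axis=1)
    dead = np.flatnonzero(sums == 0)
    if dead.size:
        raise DegenerateRowError(dead.tolist())
    out = arr / sums[:, None]
    return out[0] if squeeze else out


@dataclass(frozen=True)
class LabelSpace:
    """Ordered, immutable list of species identifiers."""

    species_ids: tuple[str, ...]

    def __post_init__(self):
        ids = tuple(str(s) for s in self.species_ids)
        object.__setattr__(self, "species_ids", ids)
        if len(ids) < 2:
            raise ValueError("a label space needs at least two species")
        if any(not s for s in ids):
            raise ValueError("species identifiers must be non-empty")
        if len(set(ids)) != len(ids):
            raise ValueError("species identifiers must be unique")
        object.__setattr__(self, "_index", {s: j for j, s in enumerate(ids)})

    @property
    def k(self) -> int:
        return len(self.species_ids)

    def index_of(self, species: str) -> int:
        try:
            return self._index[species]
        except KeyError:
            from .errors import UnknownSpeciesError

            raise UnknownSpeciesError([species]) from None

    def indices_of(self, labels: Sequence[str]) -> np.ndarray:
        """Vectorized label -> column lookup; rejects unknown species."""
        from .errors import UnknownSpeciesError

        idx = self._index
        unknown = [s for s in labels if s not in idx]
        if unknown:
            raise UnknownSpeciesError(unknown)
        return np.fromiter((idx[s] for s in labels), dtype=np.intp, count=len(labels))

    def __len__(self) -> int:
        return self.k

    def __contains__(self, species) -> bool:
        return species in self._index


@dataclass(frozen=True)
class PriorVector:
    """A categorical distribution over a label space (length-K)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ShapeError(f"prior must be 1-D, got shape {v.shape}")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("prior entries must be finite and non-negative")
        total = v.sum()
        if abs(total - 1.0) > PRIOR_SUM_TOL:
            raise ValueError(f"prior sums to {total!r}, not 1 within {PRIOR_SUM_TOL}")
        v = v / total
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @classmethod
    def uniform(cls, k: int) -> "PriorVector":
        return cls(np.full(k, 1.0 / k))

    @classmethod
    def from_weights(cls, weights) -> "PriorVector":
        """Build a prior from unnormalized non-negative weights."""
        return cls(normalize_rows(np.asarray(weights, dtype=float)))

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.k


@dataclass(frozen=True)
class PosteriorMatrix:
    """N×K matrix of per-observation species probabilities.

    Rows whose sums drift from 1 by less than :data:`ROW_SUM_TOL` are
    silently renormalized on construction; larger drift raises.
    """

    values: np.ndarray
    observation_ids: tuple[str, ...]
    space: LabelSpace

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ShapeError(f"posteriors must be 2-D, got shape {v.shape}")
        if v.shape[0] < 1:
            raise ShapeError("posterior matrix needs at least one row")
        if v.shape[1] != self.space.k:
            raise ShapeError(
                f"matrix width {v.shape[1]} != label-space size {self.space.k}"
            )
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("posterior entries must be finite and non-negative")
        sums = v.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)
        if bad.size:
            raise ValueError(
                f"rows {bad.tolist()} sum to {sums[bad].tolist()}; "
                f"drift exceeds {ROW_SUM_TOL}"
            )
        v = v / sums[:, None]
        v.setflags(write=False)
        ids = tuple(str(i) for i in self.observation_ids)
        if len(ids) != v.shape[0]:
            raise AlignmentError(
                f"{len(ids)} observation ids for {v.shape[0]} rows"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("observation ids must be unique")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "observation_ids", ids)

    @classmethod
    def from_scores(cls, scores, observation_ids, space: LabelSpace) -> "PosteriorMatrix":
        """Normalize raw non-negative scores into a posterior matrix."""
        return cls(np.atleast_2d(normalize_rows(scores)), tuple(observation_ids), space)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def replace_values(self, values: np.ndarray) -> "PosteriorMatrix":
        return PosteriorMatrix(values, self.observation_ids, self.space)

    def argmax_labels(self) -> list[str]:
        """Top-1 species per row (ties -> earliest species in order)."""
        ids = self.space.species_ids
        return [ids[j] for j in np.argmax(self.values, axis=1)]


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate`."""

    kind: str  # "negative" | "row_sum" | "shape"
    detail: str
    row: int | None = None


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def validate(values, space: LabelSpace, tol: float = ROW_SUM_TOL) -> ValidationReport:
    """Check a raw probability matrix against the posterior invariants.

    Unlike the :class:`PosteriorMatrix` constructor this never raises; it
    returns a report listing every violation (negative entries, row-sum
    drift beyond ``tol``, width != K). The report is empty iff all
    invariants hold.
    """
    report = ValidationReport()
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[1] != space.k:
        report.violations.append(
            Violation("shape", f"width {arr.shape[1]} != K={space.k}")
        )
        return report
    for i in np.flatnonzero(np.any(arr < 0, axis=1)):
        report.violations.append(Violation("negative", "negative entry", row=int(i)))
    sums = arr.sum(axis=1)
    for i in np.flatnonzero(np.abs(sums - 1.0) > tol):
        report.violations.append(
            Violation("row_sum", f"row sums to {sums[i]!r}", row=int(i))
        )
    return report


class MetadataTable:
    """Per-observation categorical metadata with explicit missing values.

    Wraps a :class:`pandas.DataFrame` indexed by observation id with the
    columns ``habitat``, ``substrate`` (strings) and ``month`` (nullable
    integer 1–12). Missing cells are ``pd.NA``.
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        for col in METADATA_TYPES:
            if col not in df.columns:
                df[col] = pd.NA
        df = df[list(METADATA_TYPES)]
        for col in ("habitat", "substrate"):
            df[col] = df[col].astype("string")
            df.loc[df[col].isin(["", "nan", "None"]), col] = pd.NA
        month = pd.to_numeric(df["month"], errors="coerce").astype("Int64")
        bad = month.dropna()
        bad = bad[(bad < 1) | (bad > 12)]
        if len(bad):
            raise ValueError(
                f"month out of range 1-12 for observations {list(bad.index[:5])}"
            )
        df["month"] = month
        df.index = df.index.map(str)
        self._df = df

    @classmethod
    def from_records(
        cls,
        observation_ids: Sequence[str],
        habitat: Sequence | None = None,
        substrate: Sequence | None = None,
        month: Sequence | None = None,
    ) -> "MetadataTable":
        data: dict = {}
        n = len(observation_ids)
        for name, col in (("habitat", habitat), ("substrate", substrate), ("month", month)):
            if col is not None:
                if len(col) != n:
                    raise AlignmentError(f"{name} column length {len(col)} != {n}")
                data[name] = [pd.NA if v is None else v for v in col]
        return cls(pd.DataFrame(data, index=pd.Index(observation_ids, dtype=str)))

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def observation_ids(self) -> tuple[str, ...]:
        return tuple(self._df.index)

    def __len__(self) -> int:
        return len(self._df)

    def column(self, mtype: str) -> pd.Series:
        if mtype not in METADATA_TYPES:
            raise KeyError(f"unknown metadata type {mtype!r}; expected {METADATA_TYPES}")
        return self._df[mtype]

    def value(self, observation_id: str, mtype: str):
        """Metadata value for one observation, or None when missing."""
        v = self.column(mtype).loc[str(observation_id)]
        return None if pd.isna(v) else (int(v) if mtype == "month" else str(v))

    def check_aligned(self, observation_ids: Sequence[str]) -> None:
        theirs = tuple(str(i) for i in observation_ids)
        if theirs != self.observation_ids:
            raise AlignmentError(
                "metadata records do not match the observation set "
                f"({len(theirs)} vs {len(self)} records or different order)"
            )


def check_prior_supports(prior: PriorVector, posterior_values: np.ndarray, space: LabelSpace) -> None:
    """Raise UnsupportedClassError where the prior is 0 but posteriors > 0."""
    from .errors import UnsupportedClassError

    mass = np.asarray(posterior_values).max(axis=0) if posterior_values.ndim == 2 else posterior_values
    bad = np.flatnonzero((prior.values == 0) & (mass > 0))
    if bad.size:
        raise UnsupportedClassError([space.species_ids[j] for j in bad])
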