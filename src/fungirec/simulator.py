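"""Synthetic citizen-science dataset generator with exact-Bayes oracles.

The generative model is fully discrete so that posterior probabilities
can be computed exactly by enumeration:

* species ``s`` ~ a long-tailed categorical prior (train or test);
* a visual token ``v`` ~ a per-species categorical over ``V`` tokens
  (a stand-in for the image; no pixels involved);
* each metadata field (habitat, substrate, month) ~ its own per-species
  categorical, drawn independently of the visual token given the
  species — conditional independence holds by construction.

The simulated classifier returns the exact posterior ``p(s|v)`` under
the *training* prior (a model trained to convergence by cross-entropy
estimates exactly this), optionally sharpened/flattened by a temperature
to emulate mis-calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import (
    METADATA_TYPES,
    LabelSpace,
    MetadataTable,
    PosteriorMatrix,
    PriorVector,
    normalize_rows,
)
from .errors import ShapeError
from .metadata_fusion import FrequencyModel


def longtail_priors(k: int, exponent: float) -> PriorVector:
    """Power-law prior over rank order: ``values[j] ∝ (j+1)^(-exponent)``.

    Small exponents approach the uniform distribution; larger ones
    produce the heavy head / long tail typical of citizen-science
    species records.
    """
    if k < 2:
        raise ValueError("need at least two species")
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    weights = np.arange(1, k + 1, dtype=float) ** (-exponent)
    return PriorVector.from_weights(weights)


@dataclass(frozen=True)
class GenerativeModel:
    """Fully-specified discrete observation model.

    ``visual_channel`` is ``(K, V)``: row ``s`` is the distribution of
    visual tokens for species ``s``. ``metadata_channels[type]`` is
    ``(K, C_type)`` over that type's category indices. Categories are
    surfaced as strings (``h0..``, ``s0..``) except month, which uses
    integers 1..12.
    """

    space: LabelSpace
    train_prior: PriorVector
    test_prior: PriorVector
    visual_channel: np.ndarray
    metadata_channels: dict[str, np.ndarray]
    metadata_categories: dict[str, list] = field(default_factory=dict)

    def __post_init__(self):
        k = self.space.k
        vc = np.asarray(self.visual_channel, dtype=float)
        if vc.ndim != 2 or vc.shape[0] != k:
            raise ShapeError(f"visual channel must be (K, V); got {vc.shape}")
        _check_rows(vc, "visual channel")
        object.__setattr__(self, "visual_channel", vc)
        channels = {}
        cats = dict(self.metadata_categories)
        for mtype, ch in self.metadata_channels.items():
            if mtype not in METADATA_TYPES:
                raise KeyError(f"unknown metadata type {mtype!r}")
            ch = np.asarray(ch, dtype=float)
            if ch.ndim != 2 or ch.shape[0] != k:
                raise ShapeError(f"{mtype} channel must be (K, C); got {ch.shape}")
            if mtype == "month" and ch.shape[1] != 12:
                raise ShapeError("month channel must have 12 categories")
            _check_rows(ch, f"{mtype} channel")
            channels[mtype] = ch
            if mtype not in cats:
                if mtype == "month":
                    cats[mtype] = list(range(1, 13))
                else:
                    cats[mtype] = [f"{mtype[0]}{i}" for i in range(ch.shape[1])]
            if len(cats[mtype]) != ch.shape[1]:
                raise ShapeError(f"{mtype}: {len(cats[mtype])} labels for {ch.shape[1]} categories")
        object.__setattr__(self, "metadata_channels", channels)
        object.__setattr__(self, "metadata_categories", cats)
        if self.train_prior.k != k or self.test_prior.k != k:
            raise ShapeError("priors must match the label space")

    @property
    def v(self) -> int:
        return self.visual_channel.shape[1]

    def prior(self, which: str) -> PriorVector:
        if which not in ("train", "test"):
            raise ValueError("prior must be 'train' or 'test'")
        return self.train_prior if which == "train" else self.test_prior

    def category_index(self, mtype: str, value) -> int:
        cats = self.metadata_categories[mtype]
        try:
            return cats.index(int(value) if mtype == "month" else value)
        except ValueError:
            raise ValueError(f"unknown {mtype} category {value!r}") from None

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "species": list(self.space.species_ids),
                "train_prior": self.train_prior.values.tolist(),
                "test_prior": self.test_prior.values.tolist(),
                "visual_channel": self.visual_channel.tolist(),
                "metadata_channels": {
                    t: ch.tolist() for t, ch in self.metadata_channels.items()
                },
                "metadata_categories": self.metadata_categories,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GenerativeModel":
        import json

        p = json.loads(text)
        return cls(
            LabelSpace(tuple(p["species"])),
            PriorVector(np.array(p["train_prior"])),
            PriorVector(np.array(p["test_prior"])),
            np.array(p["visual_channel"]),
            {t: np.array(ch) for t, ch in p["metadata_channels"].items()},
            {t: list(c) for t, c in p["metadata_categories"].items()},
        )


def _check_rows(arr: np.ndarray, what: str) -> None:
    if np.any(arr < 0) or np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError(f"{what} rows must be probability distributions")


def build_model(
    k: int,
    v: int,
    metadata_cardinalities: Mapping[str, int] | None = None,
    concentrations: Mapping[str, float] | float = 0.1,
    train_exponent: float = 1.0,
    test_exponent: float | None = None,
    seed: int = 0,
) -> GenerativeModel:
    """Draw a random generative model from symmetric Dirichlet channels.

    Low concentration makes a channel informative (each species puts its
    mass on few categories); high concentration drives it towards
    uniform / uninformative. ``test_exponent=None`` reuses the training
    prior (no shift).
    """
    if k < 2 or v < 2:
        raise ValueError("need k >= 2 species and v >= 2 visual tokens")
    cards = {"habitat": 10, "substrate": 8, "month": 12}
    if metadata_cardinalities is not None:
        cards.update({t: int(c) for t, c in metadata_cardinalities.items()})
    for t, c in cards.items():
        if c < 2:
            raise ValueError(f"{t} cardinality must be >= 2")
    if cards["month"] != 12:
        raise ValueError("month always has 12 categories")
    if not isinstance(concentrations, Mapping):
        concentrations = {t: float(concentrations) for t in ("visual", *METADATA_TYPES)}
    conc = {t: float(concentrations.get(t, 0.1)) for t in ("visual", *METADATA_TYPES)}
    if any(c <= 0 for c in conc.values()):
        raise ValueError("concentrations must be positive")

    rng = np.random.default_rng(seed)
    space = LabelSpace(tuple(f"sp{j:04d}" for j in range(k)))
    visual = rng.dirichlet(np.full(v, conc["visual"]), size=k)
    channels = {
        t: rng.dirichlet(np.full(cards[t], conc[t]), size=k) for t in METADATA_TYPES
    }
    train_prior = longtail_priors(k, train_exponent)
    if test_exponent is None:
        test_prior = train_prior
    else:
        test_prior = longtail_priors(k, test_exponent)
    return GenerativeModel(space, train_prior, test_prior, visual, channels)


def exact_posterior_visual(
    model: GenerativeModel, token: int, prior: str = "train"
) -> np.ndarray:
    """Exact ``p(s|v=token)`` by direct enumeration over species."""
    if not 0 <= token < model.v:
        raise ValueError(f"token {token} outside 0..{model.v - 1}")
    weights = model.prior(prior).values * model.visual_channel[:, token]
    total = weights.sum()
    if total == 0:
        from .errors import DegenerateRowError

        raise DegenerateRowError([token])
    return weights / total


def exact_posterior_full(
    model: GenerativeModel,
    token: int,
    metadata_values: Mapping[str, object],
    prior: str = "train",
) -> np.ndarray:
    """Exact ``p(s | v, d_1..d_m)`` including any subset of metadata fields."""
    if not 0 <= token < model.v:
        raise ValueError(f"token {token} outside 0..{model.v - 1}")
    weights = model.prior(prior).values * model.visual_channel[:, token]
    for mtype, value in metadata_values.items():
        if mtype not in model.metadata_channels:
            raise KeyError(f"model has no {mtype!r} channel")
        ci = model.category_index(mtype, value)
        weights = weights * model.metadata_channels[mtype][:, ci]
    total = weights.sum()
    if total == 0:
        from .errors import DegenerateRowError

        raise DegenerateRowError([token])
    return weights / total


def implied_conditionals(model: GenerativeModel, mtype: str, prior: str = "train") -> np.ndarray:
    """True ``p(s|d)`` table ``(C, K)`` implied by the model via Bayes.

    ``p(s|d) ∝ prior(s) * channel[s, d]`` — what an infinitely large
    training sample's relative frequencies would converge to.
    """
    ch = model.metadata_channels[mtype]  # (K, C)
    joint = model.prior(prior).values[:, None] * ch  # (K, C)
    return normalize_rows(joint.T)  # (C, K)


def true_frequency_model(model: GenerativeModel) -> FrequencyModel:
    """FrequencyModel holding the model's exact conditionals.

    Fusing the exact visual posterior with these tables must reproduce
    :func:`exact_posterior_full` — the central correctness oracle.
    """
    tables: dict[str, dict[str, np.ndarray]] = {}
    for mtype in model.metadata_channels:
        cond = implied_conditionals(model, mtype)
        cats = model.metadata_categories[mtype]
        tables[mtype] = {str(c): cond[i] for i, c in enumerate(cats)}
    return FrequencyModel(
        model.space,
        model.train_prior,
        tables,
        {t: 0.0 for t in METADATA_TYPES},
    )


@dataclass(frozen=True)
class SyntheticDataset:
    """One sampled batch: labels, tokens, metadata, simulated posteriors."""

    labels: tuple[str, ...]
    visual_tokens: np.ndarray
    metadata: MetadataTable
    posteriors: PosteriorMatrix
    model: GenerativeModel
    seed: int

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def observation_ids(self) -> tuple[str, ...]:
        return self.posteriors.observation_ids


def _sample_rows(rng: np.random.Generator, table: np.ndarray, row_idx: np.ndarray) -> np.ndarray:
    """Draw one category per observation from ``table[row_idx[i]]`` (vectorized)."""
    cum = np.cumsum(table, axis=1)
    cum[:, -1] = 1.0  # guard against float drift at the top end
    u = rng.random(row_idx.size)
    return (u[:, None] >= cum[row_idx]).sum(axis=1)


def sample_dataset(
    model: GenerativeModel,
    n: int,
    which_prior: str = "train",
    seed: int = 0,
    temperature: float = 1.0,
    missing_rate: float = 0.0,
) -> SyntheticDataset:
    """Draw a dataset and the simulated classifier's posteriors.

    The classifier output for observation ``i`` is the exact posterior
    ``p(s | v_i)`` under the *train* prior regardless of which prior the
    sample was drawn from (that is what a converged classifier trained
    on the training distribution emits). ``temperature != 1`` raises the
    exact rows to ``1/temperature`` and renormalizes, emulating over-
    (<1) or under- (>1) confidence. ``missing_rate`` blanks each
    metadata cell independently with that probability.
    """
    if n < 1:
        raise ValueError("need at least one observation")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    k = model.space.k
    prior = model.prior(which_prior).values

    species_idx = rng.choice(k, size=n, p=prior)
    tokens = _sample_rows(rng, model.visual_channel, species_idx)
    meta_cols: dict[str, list] = {}
    for mtype, ch in model.metadata_channels.items():
        cat_idx = _sample_rows(rng, ch, species_idx)
        cats = model.metadata_categories[mtype]
        col = [cats[ci] for ci in cat_idx]
        if missing_rate:
            blank = rng.random(n) < missing_rate
            col = [None if b else v for v, b in zip(col, blank)]
        meta_cols[mtype] = col

    # classifier: exact train-distribution posterior per distinct token
    post_by_token = np.stack(
        [exact_posterior_visual(model, t, "train") for t in range(model.v)]
    )
    rows = post_by_token[tokens]
    if temperature != 1.0:
        rows = normalize_rows(np.power(rows, 1.0 / temperature))

    obs_ids = tuple(f"obs{i:06d}" for i in range(n))
    labels = tuple(model.space.species_ids[s] for s in species_idx)
    metadata = MetadataTable.from_records(
        obs_ids,
        habitat=meta_cols.get("habitat"),
        substrate=meta_cols.get("substrate"),
        month=meta_cols.get("month"),
    )
    posteriors = PosteriorMatrix(rows, obs_ids, model.space)
    return SyntheticDataset(labels, tokens, metadata, posteriors, model, seed)
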