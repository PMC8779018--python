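"""Class-prior-shift (label-shift) correction of classifier posteriors.

A probabilistic classifier trained on data with class priors ``p(k)``
estimates posteriors under those priors. When the deployment-time priors
``q(k)`` differ while the class-conditional appearance stays fixed, the
deployment posterior is proportional to ``post[i,k] * q(k) / p(k)``,
renormalized per row. The common special case is a uniform deployment
prior, where the update reduces to dividing by ``p(k)``.

Ratios are computed in log space: with ~1600 species the per-class
factors can underflow in linear space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    LabelSpace,
    PosteriorMatrix,
    PriorVector,
    check_prior_supports,
)
from .errors import ShapeError, UnknownSpeciesError


@dataclass(frozen=True)
class PriorShiftSpec:
    """Pair of priors defining a shift: train ``p(k)`` -> target ``q(k)``."""

    train_prior: PriorVector
    target_prior: PriorVector

    def __post_init__(self):
        if self.train_prior.k != self.target_prior.k:
            raise ShapeError(
                f"train prior length {self.train_prior.k} != "
                f"target prior length {self.target_prior.k}"
            )


def _reweight_rows(values: np.ndarray, log_ratio: np.ndarray, zero_mask: np.ndarray) -> np.ndarray:
    # exp(log post + log ratio), with exact zeros preserved through the mask
    with np.errstate(divide="ignore"):
        log_post = np.log(values)
    out = np.exp(log_post + log_ratio[None, :])
    out[:, zero_mask] = 0.0
    sums = out.sum(axis=1)
    dead = np.flatnonzero(sums == 0)
    if dead.size:
        from .errors import DegenerateRowError

        raise DegenerateRowError(dead.tolist())
    return out / sums[:, None]


def adjust_posteriors(post: PosteriorMatrix, spec: PriorShiftSpec) -> PosteriorMatrix:
    """Re-express posteriors under the target prior of ``spec``.

    Each output row is proportional to
    ``post[i, k] * target_prior[k] / train_prior[k]`` and sums to one.

    Raises
    ------
    UnsupportedClassError
        If ``train_prior[k] == 0`` for some ``k`` with positive posterior
        mass anywhere (the ratio is undefined; clamping would hide a
        data/model mismatch). A class with zero prior *and* zero posterior
        mass everywhere is dropped consistently.
    ShapeError
        If the priors do not match the matrix width.
    """
    if spec.train_prior.k != post.k:
        raise ShapeError(f"prior length {spec.train_prior.k} != matrix width {post.k}")
    check_prior_supports(spec.train_prior, post.values, post.space)

    p = spec.train_prior.values
    q = spec.target_prior.values
    live = p > 0
    log_ratio = np.full(post.k, -np.inf)
    with np.errstate(divide="ignore"):
        log_ratio[live] = np.log(q[live]) - np.log(p[live])
    zero_mask = ~live | (q == 0)
    return post.replace_values(_reweight_rows(post.values, log_ratio, zero_mask))


def adjust_to_uniform(post: PosteriorMatrix, train_prior: PriorVector) -> PosteriorMatrix:
    """Shift posteriors to a uniform deployment prior (divide by ``p(k)``)."""
    return adjust_posteriors(
        post, PriorShiftSpec(train_prior, PriorVector.uniform(train_prior.k))
    )


def estimate_class_priors(
    labels, space: LabelSpace, pseudocount: float = 0.0
) -> PriorVector:
    """Empirical class prior from training labels, optionally smoothed.

    ``values[k] = (count_k + pseudocount) / (N + K * pseudocount)``.
    The default ``pseudocount=0`` is the plain relative frequency.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("cannot estimate priors from an empty label list")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    idx = space.indices_of(labels)
    counts = np.bincount(idx, minlength=space.k).astype(float)
    return PriorVector((counts + pseudocount) / (len(labels) + space.k * pseudocount))
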