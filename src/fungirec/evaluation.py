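"""Metrics and split utilities for long-tailed species recognition.

Accuracies are reported in percent. The rank of the true species in a
row is ``1 + #(species with strictly higher probability)``, with ties
broken by species order; top-k and rank-share statistics both derive
from this single rank definition, so ``rank-1 share * 100 == top-1``
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import LabelSpace, PosteriorMatrix


def true_ranks(post: PosteriorMatrix, truth: Sequence[str]) -> np.ndarray:
    """Rank (1-based) of the true species in each row.

    Ties with the true species' probability count against it when they
    sit earlier in species order — the deterministic worst-case-free rule
    used throughout this module.
    """
    truth = list(truth)
    if len(truth) != post.n:
        from .errors import AlignmentError

        raise AlignmentError(f"{len(truth)} truth labels for {post.n} rows")
    tidx = post.space.indices_of(truth)
    v = post.values
    ptrue = v[np.arange(post.n), tidx]
    higher = (v > ptrue[:, None]).sum(axis=1)
    cols = np.arange(post.k)
    earlier_ties = ((v == ptrue[:, None]) & (cols[None, :] < tidx[:, None])).sum(axis=1)
    return 1 + higher + earlier_ties


def topk_accuracy(post: PosteriorMatrix, truth: Sequence[str], k: int = 1) -> float:
    """Percent of rows whose true species ranks within the top ``k``."""
    if not 1 <= k <= post.k:
        raise ValueError(f"k must be in 1..{post.k}")
    return float((true_ranks(post, truth) <= k).mean() * 100.0)


def mean_class_accuracy(post: PosteriorMatrix, truth: Sequence[str]) -> float:
    """Unweighted mean of per-species top-1 accuracy, in percent.

    Species absent from ``truth`` are excluded (not scored as zero), so
    the metric covers observed records only. Robust to long-tailed class
    imbalance, unlike the plain pooled accuracy.
    """
    truth = list(truth)
    if not truth:
        raise ValueError("truth must not be empty")
    hits = true_ranks(post, truth) == 1
    tidx = post.space.indices_of(truth)
    per_class = []
    for j in np.unique(tidx):
        sel = tidx == j
        per_class.append(hits[sel].mean())
    return float(np.mean(per_class) * 100.0)


DEFAULT_RANK_BINS: tuple[tuple[int, float], ...] = ((1, 1), (2, 2), (3, 5), (6, math.inf))


def rank_shares(
    post: PosteriorMatrix,
    truth: Sequence[str],
    bins: Sequence[tuple[int, float]] = DEFAULT_RANK_BINS,
) -> list[float]:
    """Fraction of observations whose true-species rank falls in each bin.

    ``bins`` are inclusive rank intervals (``math.inf`` for an open upper
    end); they must not overlap. Shares over bins covering all ranks sum
    to one.
    """
    bins = [tuple(b) for b in bins]
    for (lo, hi) in bins:
        if lo > hi or lo < 1:
            raise ValueError(f"invalid rank bin [{lo}, {hi}]")
    for a in range(len(bins)):
        for b in range(a + 1, len(bins)):
            lo1, hi1 = bins[a]
            lo2, hi2 = bins[b]
            if lo1 <= hi2 and lo2 <= hi1:
                raise ValueError(f"overlapping rank bins {bins[a]} and {bins[b]}")
    ranks = true_ranks(post, truth)
    return [float(((ranks >= lo) & (ranks <= hi)).mean()) for lo, hi in bins]


@dataclass
class EvalReport:
    """Bundle of the reporting metrics for one posterior matrix."""

    topk: dict[int, float]
    mean_class_accuracy: float
    rank_shares: list[float]
    rank_bins: list[tuple[int, float]]
    n: int

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "topk": {str(k): round(v, 2) for k, v in self.topk.items()},
            "mean_class_accuracy": round(self.mean_class_accuracy, 2),
            "rank_shares": {
                f"[{lo},{'inf' if math.isinf(hi) else int(hi)}]": share
                for (lo, hi), share in zip(self.rank_bins, self.rank_shares)
            },
        }


def evaluate(
    post: PosteriorMatrix,
    truth: Sequence[str],
    ks: Sequence[int] = (1, 3, 5),
    bins: Sequence[tuple[int, float]] = DEFAULT_RANK_BINS,
) -> EvalReport:
    """Compute the full metric bundle (top-k, mean per-class, rank shares)."""
    ranks = true_ranks(post, truth)
    topk = {int(k): float((ranks <= k).mean() * 100.0) for k in ks}
    return EvalReport(
        topk=topk,
        mean_class_accuracy=mean_class_accuracy(post, truth),
        rank_shares=rank_shares(post, truth, bins),
        rank_bins=[tuple(b) for b in bins],
        n=post.n,
    )


def species_split(
    truth: Sequence[str], train_fraction: float = 0.9, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-species stratified split: ``ceil(fraction * n)`` of each species
    goes to train, the remainder to test, chosen uniformly at random.

    Note a species with few observations can land entirely in train
    (e.g. n=5 at fraction 0.9 gives ceil(4.5)=5 train, 0 test) — hence
    benchmark builds usually restrict to species above a minimum count.

    Returns
    -------
    (train_indices, test_indices)
        Sorted integer positions into ``truth``; disjoint and exhaustive.
    """
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    truth = np.asarray(list(truth), dtype=object)
    if truth.size == 0:
        raise ValueError("truth must not be empty")
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for sp in sorted(set(truth.tolist())):
        idx = np.flatnonzero(truth == sp)
        n_train = math.ceil(train_fraction * idx.size)
        perm = rng.permutation(idx)
        train.extend(perm[:n_train].tolist())
        test.extend(perm[n_train:].tolist())
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def error_rate(accuracy_percent: float) -> float:
    """Error in percent for an accuracy in percent."""
    return 100.0 - accuracy_percent


def relative_error_reduction(acc_old: float, acc_new: float) -> float:
    """Relative reduction of the error rate, in percent.

    ``100 * (e_old - e_new) / e_old`` with ``e = 100 - accuracy``; the
    standard way headline "error lowered by X%" figures are derived from
    a pair of accuracies.
    """
    e_old, e_new = error_rate(acc_old), error_rate(acc_new)
    if e_old <= 0:
        raise ValueError("old system has zero error; reduction undefined")
    return 100.0 * (e_old - e_new) / e_old
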