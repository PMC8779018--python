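"""Test-time augmentation geometry and prediction pooling.

The 14-view scheme: the full image; a central crop covering 80% of the
width and height; a central 60% crop; four 60% crops anchored flush to
the corners; and the horizontal mirror of each of those seven views.
Pooling across views (or across ensemble members) is either by averaging
probabilities (``sum``) or by majority over top-1 votes (``mode``).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import PosteriorMatrix, normalize_rows
from .errors import DegenerateCropError, ShapeError


@dataclass(frozen=True)
class CropSpec:
    """One deterministic view: fractional crop box plus mirror flag.

    ``box`` is ``(x0, y0, x1, y1)`` as fractions of image width/height,
    within the unit square with ``x0 < x1`` and ``y0 < y1``. ``mirrored``
    means a horizontal (left-right) flip applied after cropping.
    """

    box: tuple[float, float, float, float]
    mirrored: bool = False

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (0 <= x0 < x1 <= 1 and 0 <= y0 < y1 <= 1):
            raise ValueError(f"crop box {self.box} outside the unit square")


def tta_crop_specs() -> list[CropSpec]:
    """The 14 test-time views (7 geometric views x {plain, mirrored})."""
    boxes = [
        (0.0, 0.0, 1.0, 1.0),  # full image
        (0.1, 0.1, 0.9, 0.9),  # central 80%
        (0.2, 0.2, 0.8, 0.8),  # central 60%
        (0.0, 0.0, 0.6, 0.6),  # 60% corners, anchored flush
        (0.4, 0.0, 1.0, 0.6),
        (0.0, 0.4, 0.6, 1.0),
        (0.4, 0.4, 1.0, 1.0),
    ]
    return [CropSpec(b, mirrored=m) for m in (False, True) for b in boxes]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def crop_pixels(spec: CropSpec, width: int, height: int) -> tuple[int, int, int, int]:
    """Realize a fractional crop box on a concrete image size.

    Returns a half-open integer rectangle ``(left, top, right, bottom)``
    with edges rounded half-away-from-zero (symmetric for centered
    crops). Raises :class:`DegenerateCropError` if the rectangle would be
    empty (tiny images).
    """
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be >= 1 pixel")
    x0, y0, x1, y1 = spec.box
    left, right = _round_half_away(x0 * width), _round_half_away(x1 * width)
    top, bottom = _round_half_away(y0 * height), _round_half_away(y1 * height)
    if right <= left or bottom <= top:
        raise DegenerateCropError(
            f"crop {spec.box} collapses on a {width}x{height} image"
        )
    return left, top, right, bottom


def apply_crop(image: np.ndarray, spec: CropSpec) -> np.ndarray:
    """Apply a crop spec to an ``(H, W[, C])`` pixel array.

    Cropping and mirroring only; any resizing/interpolation is up to the
    caller.
    """
    arr = np.asarray(image)
    if arr.ndim not in (2, 3):
        raise ValueError("expected an (H, W) or (H, W, C) array")
    h, w = arr.shape[:2]
    left, top, right, bottom = crop_pixels(spec, w, h)
    out = arr[top:bottom, left:right]
    if spec.mirrored:
        out = out[:, ::-1]
    return out


class PredictionStack:
    """Aligned posterior matrices from several views and/or models."""

    def __init__(self, members: Sequence[PosteriorMatrix], tags: Sequence[str] | None = None):
        members = list(members)
        if not members:
            raise ValueError("prediction stack must not be empty")
        first = members[0]
        for m in members[1:]:
            if m.values.shape != first.values.shape:
                raise ShapeError("stack members differ in shape")
            if m.observation_ids != first.observation_ids:
                raise ShapeError("stack members differ in observation order")
            if m.space.species_ids != first.space.species_ids:
                raise ShapeError("stack members use different label spaces")
        if tags is not None and len(tags) != len(members):
            raise ValueError("one tag per stack member required")
        self.members = members
        self.tags = list(tags) if tags is not None else [str(i) for i in range(len(members))]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def array(self) -> np.ndarray:
        """(M, N, K) view of the stack."""
        return np.stack([m.values for m in self.members])


def pool_sum(stack: PredictionStack) -> PosteriorMatrix:
    """Average probabilities across stack members (then renormalize)."""
    mean = stack.array.mean(axis=0)
    first = stack.members[0]
    return PosteriorMatrix(normalize_rows(mean), first.observation_ids, first.space)


def pool_mode(stack: PredictionStack) -> tuple[list[str], list[Counter]]:
    """Majority vote over per-member top-1 predictions.

    Each member votes its arg-max species per observation. Ties on vote
    count are broken by the larger probability summed over the whole
    stack, then by species order. Returns the winning species per
    observation and the per-observation vote tallies.
    """
    arr = stack.array  # (M, N, K)
    first = stack.members[0]
    species = first.space.species_ids
    votes = np.argmax(arr, axis=2)  # (M, N)
    summed = arr.sum(axis=0)  # (N, K)
    winners: list[str] = []
    tallies: list[Counter] = []
    for i in range(arr.shape[1]):
        tally = Counter(int(j) for j in votes[:, i])
        best = max(tally.items(), key=lambda kv: (kv[1], summed[i, kv[0]], -kv[0]))[0]
        winners.append(species[best])
        tallies.append(Counter({species[j]: c for j, c in tally.items()}))
    return winners, tallies
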