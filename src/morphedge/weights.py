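"""Gray-difference direction features and 8-direction element weights.

The 3x3 neighborhood of a pixel is labelled

    d8 d1 d2
    d7 d0 d3
    d6 d5 d4

with ``d0`` the center.  Accumulating squared center-neighbor differences
over the image interior yields, per opposite-neighbor axis, the four
features ``h1..h4`` and, per single neighbor, the eight "gray mutation"
features ``l1..l8``.  Normalizing the axis features gives the four axis
weights ``vQ1..vQ4``; each axis weight is then split between two fine
directions in proportion to a pair of ``l`` features:

    v1 = l5/(l5+l6) * vQ3    v5 = vQ3 - v1
    v2 = l7/(l7+l8) * vQ4    v6 = vQ4 - v2
    v3 = l1/(l1+l2) * vQ1    v7 = vQ1 - v3
    v4 = l3/(l3+l4) * vQ2    v8 = vQ2 - v4

(The fourth line's published form repeats ``l3`` in its denominator; the
``l3/(l3+l4)`` pattern used here is the consistent extension of the first
three lines.)  The eight weights are nonnegative, sum to one, and satisfy
the paired sums v1+v5=vQ3, v2+v6=vQ4, v3+v7=vQ1, v4+v8=vQ2 by construction.
On a flat image every feature is zero and the weights fall back to uniform.

The weighted directional edge response applies the combined anti-noise
operator Q with a half-line element in each of the eight compass directions
and mixes the responses with these weights, so directions along which the
image actually varies dominate the edge map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .image import as_pixel_array
from .morphology import EdgeResponse, OperatorParams, combined_Q, make_structuring_element

__all__ = [
    "NEIGHBOR_OFFSETS",
    "AXIS_PAIRS",
    "FINE_DIRECTION_LABELS",
    "DirectionWeights",
    "axis_features",
    "axis_weights",
    "fine_features",
    "fine_weights",
    "direction_weights",
    "weighted_directional_response",
]

#: Offset (row, col) of neighbor d_x relative to the center d0, x = 1..8.
#: d1 sits above the center and the labels run clockwise.
NEIGHBOR_OFFSETS: dict[int, tuple[int, int]] = {
    1: (-1, 0),   # N
    2: (-1, 1),   # NE
    3: (0, 1),    # E
    4: (1, 1),    # SE
    5: (1, 0),    # S
    6: (1, -1),   # SW
    7: (0, -1),   # W
    8: (-1, -1),  # NW
}

#: Opposite-neighbor pairs per axis index m = 1..4.
AXIS_PAIRS: dict[int, tuple[int, int]] = {1: (1, 5), 2: (2, 6), 3: (3, 7), 4: (4, 8)}

#: Compass label of the structuring element used for fine direction x.
FINE_DIRECTION_LABELS: dict[int, str] = {
    1: "N", 2: "NE", 3: "E", 4: "SE", 5: "S", 6: "SW", 7: "W", 8: "NW",
}

#: (numerator l index, denominator partner l index, axis index) per fine
#: direction v1..v4; v5..v8 are the axis complements.
_SPLIT_RULE: dict[int, tuple[int, int, int]] = {
    1: (5, 6, 3),
    2: (7, 8, 4),
    3: (1, 2, 1),
    4: (3, 4, 2),
}


@dataclass(frozen=True)
class DirectionWeights:
    """Axis weights vQ1..vQ4 and fine weights v1..v8 (each set sums to 1)."""

    axis_weights: tuple[float, float, float, float]
    fine_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        vq = tuple(float(v) for v in self.axis_weights)
        v = tuple(float(x) for x in self.fine_weights)
        if len(vq) != 4 or len(v) != 8:
            raise ValidationError("expected 4 axis weights and 8 fine weights")
        if any(x < -1e-12 or x > 1 + 1e-12 for x in vq + v):
            raise ValidationError("weights must lie in [0, 1]")
        if abs(sum(vq) - 1.0) > 1e-9 or abs(sum(v) - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")
        object.__setattr__(self, "axis_weights", vq)
        object.__setattr__(self, "fine_weights", v)


def _interior_diffs(image) -> dict[int, np.ndarray]:
    """Center-minus-neighbor differences on the interior, per neighbor label."""
    arr = as_pixel_array(image)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValidationError(f"image must be at least 3x3, got {arr.shape}")
    center = arr[1:-1, 1:-1]
    diffs = {}
    for x, (dr, dc) in NEIGHBOR_OFFSETS.items():
        neighbor = arr[1 + dr : arr.shape[0] - 1 + dr, 1 + dc : arr.shape[1] - 1 + dc]
        diffs[x] = center - neighbor
    return diffs


def fine_features(image) -> tuple[float, ...]:
    """l1..l8: summed squared center-neighbor differences per direction."""
    diffs = _interior_diffs(image)
    return tuple(float((diffs[x] ** 2).sum()) for x in range(1, 9))


def axis_features(image) -> tuple[float, float, float, float]:
    """h1..h4: summed squared differences per opposite-neighbor axis."""
    l = fine_features(image)
    return tuple(l[a - 1] + l[b - 1] for a, b in AXIS_PAIRS.values())  # type: ignore[return-value]


def axis_weights(h) -> tuple[float, float, float, float]:
    """vQm = hm / sum(h); uniform 1/4 on a flat image (all h zero)."""
    h = tuple(float(x) for x in h)
    if len(h) != 4:
        raise ValidationError(f"expected 4 axis features, got {len(h)}")
    if any(x < 0 for x in h):
        raise ValidationError("axis features must be nonnegative")
    total = sum(h)
    if total == 0.0:
        return (0.25, 0.25, 0.25, 0.25)
    return tuple(x / total for x in h)  # type: ignore[return-value]


def fine_weights(l, vq) -> DirectionWeights:
    """Split each axis weight between its two fine directions.

    ``l`` are the eight gray-mutation features, ``vq`` the four axis
    weights.  A zero-sum feature pair splits its axis weight 50/50.
    """
    l = tuple(float(x) for x in l)
    vq = tuple(float(x) for x in vq)
    if len(l) != 8 or len(vq) != 4:
        raise ValidationError("expected 8 fine features and 4 axis weights")
    if any(x < 0 for x in l):
        raise ValidationError("fine features must be nonnegative")
    v = [0.0] * 9  # 1-based
    for x, (num, den_partner, axis) in _SPLIT_RULE.items():
        la, lb = l[num - 1], l[den_partner - 1]
        frac = 0.5 if la + lb == 0 else la / (la + lb)
        v[x] = frac * vq[axis - 1]
        v[x + 4] = vq[axis - 1] - v[x]
    return DirectionWeights(axis_weights=vq, fine_weights=tuple(v[1:]))


def direction_weights(image) -> DirectionWeights:
    """All weights of an image in one call (features -> axis -> fine)."""
    l = fine_features(image)
    vq = axis_weights(axis_features(image))
    return fine_weights(l, vq)


def weighted_directional_response(
    image,
    scale: int,
    params: OperatorParams | None = None,
    border: str = "replicate",
    weights: DirectionWeights | None = None,
) -> EdgeResponse:
    """Weight-mixed combined-Q response over the 8 compass directions.

    The weights are computed once per image (the features sum over the
    whole interior); pass ``weights`` to reuse a precomputed set.
    """
    params = params or OperatorParams()
    w = weights or direction_weights(image)
    arr = as_pixel_array(image)
    out = np.zeros_like(arr)
    for x in range(1, 9):
        se = make_structuring_element(scale, FINE_DIRECTION_LABELS[x])
        out += w.fine_weights[x - 1] * combined_Q(arr, se, params, border).values
    return EdgeResponse(values=out, operator_tag="Qw")
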