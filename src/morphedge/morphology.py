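"""Flat grayscale morphology and the anti-noise gradient operator family.

For an image ``g`` and a flat structuring element ``J`` the basic transforms
obey the pixelwise ordering

    dilate(g) >= close(g) >= g >= open(g) >= erode(g)

(for structuring elements that contain their anchor).  Differences between
members of this chain form the classical morphological gradients ``p1..p6``.
Cascading opening and closing before differencing yields the anti-noise
gradients ``q1``/``q2``: the pre-filtering removes bright ("salt") and dark
("pepper") impulses so they do not register as edges.  Their pixelwise
max/min blend ``Q = kappa*qmax + lambda*qmin`` trades noise suppression
against edge sharpness.

Conventions (fixed so that the duality ``dilate(x, J) = 255 - erode(255 - x,
reflect(J))`` holds exactly):

* erosion takes the minimum of ``x[i + s]`` over the support offsets ``s``
  as listed;
* dilation takes the maximum of ``x[i - s]``, i.e. uses the support
  reflected through the anchor;
* image borders are replicate-padded by default (``border="replicate"``),
  with reflect padding available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .exceptions import ValidationError
from .image import GrayImage, as_pixel_array

__all__ = [
    "DIRECTIONS",
    "StructuringElement",
    "OperatorParams",
    "EdgeResponse",
    "make_structuring_element",
    "erode",
    "dilate",
    "open_",
    "close_",
    "gradient_p",
    "gradient_q",
    "combined_Q",
]

logger = logging.getLogger(__name__)

#: Compass step (row, col) per direction label; rows grow downward.
DIRECTIONS: dict[str, tuple[int, int]] = {
    "E": (0, 1),
    "NE": (-1, 1),
    "N": (-1, 0),
    "NW": (-1, -1),
    "W": (0, -1),
    "SW": (1, -1),
    "S": (1, 0),
    "SE": (1, 1),
}

_BORDER_MODES = {"replicate": "nearest", "reflect": "mirror"}


@dataclass(frozen=True)
class StructuringElement:
    """A flat (binary-support) neighborhood with anchor at offset (0, 0).

    ``scale`` is the side of the bounding box; the eight directional
    elements are half-lines of ``ceil(scale/2)`` pixels from the anchor,
    the isotropic element is the full ``scale x scale`` square.
    """

    support: tuple[tuple[int, int], ...]
    scale: int
    direction: str

    def __post_init__(self) -> None:
        offsets = tuple(sorted((int(r), int(c)) for r, c in self.support))
        if (0, 0) not in offsets:
            raise ValidationError("structuring element must contain its anchor (0, 0)")
        half = self.scale // 2
        if any(abs(r) > half or abs(c) > half for r, c in offsets):
            raise ValidationError(
                f"support offsets exceed the scale-{self.scale} bounding box"
            )
        object.__setattr__(self, "support", offsets)

    def footprint(self) -> np.ndarray:
        """Boolean scale x scale mask with the anchor at the center."""
        half = self.scale // 2
        fp = np.zeros((self.scale, self.scale), dtype=bool)
        for r, c in self.support:
            fp[half + r, half + c] = True
        return fp

    def reflected(self) -> "StructuringElement":
        """The element reflected through its anchor."""
        return StructuringElement(
            support=tuple((-r, -c) for r, c in self.support),
            scale=self.scale,
            direction=self.direction,
        )


@dataclass(frozen=True)
class OperatorParams:
    """Blend parameters of the combined operator Q = kappa*qmax + lambda*qmin.

    ``kappa`` weights the dark-noise-suppressing pixelwise maximum, ``lam``
    the bright-noise-suppressing minimum; they must sum to 1.
    """

    kappa: float = 0.5
    lam: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= 1.0 and 0.0 <= self.lam <= 1.0):
            raise ValidationError("kappa and lam must lie in [0, 1]")
        if abs(self.kappa + self.lam - 1.0) > 1e-12:
            raise ValidationError(
                f"kappa + lam must equal 1, got {self.kappa + self.lam!r}"
            )


@dataclass(frozen=True)
class EdgeResponse:
    """Per-pixel nonnegative gradient magnitude map."""

    values: np.ndarray
    operator_tag: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise ValidationError("edge response must be 2-D")
        if vals.min() < 0:
            raise ValidationError("edge response values must be nonnegative")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]


def make_structuring_element(scale: int, direction: str = "isotropic") -> StructuringElement:
    """Build a directional half-line or isotropic square element.

    Examples
    --------
    >>> make_structuring_element(3, "E").support
    ((0, 0), (0, 1))
    >>> make_structuring_element(5, "N").support
    ((-2, 0), (-1, 0), (0, 0))
    """
    if scale < 3 or scale % 2 == 0:
        raise ValidationError(f"scale must be an odd integer >= 3, got {scale}")
    if direction == "isotropic":
        half = scale // 2
        support = tuple(
            (r, c) for r in range(-half, half + 1) for c in range(-half, half + 1)
        )
        return StructuringElement(support=support, scale=scale, direction=direction)
    if direction not in DIRECTIONS:
        raise ValidationError(
            f"unknown direction {direction!r}; expected one of "
            f"{sorted(DIRECTIONS)} or 'isotropic'"
        )
    dr, dc = DIRECTIONS[direction]
    npix = (scale + 1) // 2  # half-line from the anchor, inclusive
    support = tuple((k * dr, k * dc) for k in range(npix))
    return StructuringElement(support=support, scale=scale, direction=direction)


def _mode(border: str) -> str:
    try:
        return _BORDER_MODES[border]
    except KeyError:
        raise ValidationError(
            f"unknown border mode {border!r}; expected one of {sorted(_BORDER_MODES)}"
        ) from None


def _wrap_like(image, values: np.ndarray):
    if isinstance(image, GrayImage):
        return GrayImage(values.astype(np.uint8))
    return values


def erode(image, se: StructuringElement, border: str = "replicate"):
    """Per-pixel minimum over the support (as listed)."""
    arr = as_pixel_array(image)
    out = ndi.grey_erosion(arr, footprint=se.footprint(), mode=_mode(border))
    return _wrap_like(image, out)


def dilate(image, se: StructuringElement, border: str = "replicate"):
    """Per-pixel maximum over the support reflected through the anchor."""
    arr = as_pixel_array(image)
    out = ndi.grey_dilation(arr, footprint=se.footprint(), mode=_mode(border))
    return _wrap_like(image, out)


def open_(image, se: StructuringElement, border: str = "replicate"):
    """Opening: erosion followed by dilation (removes bright specks)."""
    return dilate(erode(image, se, border), se, border)


def close_(image, se: StructuringElement, border: str = "replicate"):
    """Closing: dilation followed by erosion (removes dark specks)."""
    return erode(dilate(image, se, border), se, border)


def gradient_p(image, se: StructuringElement, which: int, border: str = "replicate") -> EdgeResponse:
    """Classical morphological gradients p1..p6.

    p1 = dilate - g, p2 = g - erode, p3 = dilate - erode, p4 = g - open,
    p5 = close - g, p6 = close - open.  All are nonnegative in the image
    interior by the ordering chain; border padding can break the
    opening/closing side of the chain inside a ring of width scale-1 for
    one-sided (directional) elements, so p4/p5/p6 are clamped at zero
    there (logged at debug level).
    """
    arr = as_pixel_array(image)
    d = as_pixel_array(dilate(arr, se, border))
    e = as_pixel_array(erode(arr, se, border))
    if which == 1:
        vals = d - arr
    elif which == 2:
        vals = arr - e
    elif which == 3:
        vals = d - e
    elif which == 4:
        vals = arr - as_pixel_array(dilate(e, se, border))
    elif which == 5:
        vals = as_pixel_array(erode(d, se, border)) - arr
    elif which == 6:
        vals = as_pixel_array(erode(d, se, border)) - as_pixel_array(dilate(e, se, border))
    else:
        raise ValidationError(f"gradient_p selector must be 1..6, got {which}")
    if which >= 4:
        vals = _clamp_negative(vals, f"p{which}", se)
    return EdgeResponse(values=vals, operator_tag=f"p{which}")


def _clamp_negative(vals: np.ndarray, tag: str, se: StructuringElement) -> np.ndarray:
    negative = vals < 0
    if negative.any():
        logger.debug(
            "%s clamped %d negative pixels (min %.3f) for %s SE at scale %d",
            tag,
            int(negative.sum()),
            float(vals.min()),
            se.direction,
            se.scale,
        )
        vals = np.maximum(vals, 0.0)
    return vals


def gradient_q(image, se: StructuringElement, which: int, border: str = "replicate") -> EdgeResponse:
    """Cascaded anti-noise gradients.

    q1 = open(close(g)) - erode(close(g)): the closing removes dark
    impulses before the gradient is formed.  q2 = dilate(open(g)) -
    close(open(g)): the opening removes bright impulses first.  For
    directional (non-symmetric) elements the raw differences are not
    guaranteed nonnegative, so they are clamped at zero; clamping is
    logged at debug level.
    """
    arr = as_pixel_array(image)
    if which == 1:
        base = as_pixel_array(close_(arr, se, border))
        vals = as_pixel_array(open_(base, se, border)) - as_pixel_array(
            erode(base, se, border)
        )
    elif which == 2:
        base = as_pixel_array(open_(arr, se, border))
        vals = as_pixel_array(dilate(base, se, border)) - as_pixel_array(
            close_(base, se, border)
        )
    else:
        raise ValidationError(f"gradient_q selector must be 1 or 2, got {which}")
    vals = _clamp_negative(vals, f"q{which}", se)
    return EdgeResponse(values=vals, operator_tag=f"q{which}")


def combined_Q(
    image,
    se: StructuringElement,
    params: OperatorParams | None = None,
    border: str = "replicate",
) -> EdgeResponse:
    """Blend of the two cascades: Q = kappa*max(q1,q2) + lambda*min(q1,q2)."""
    params = params or OperatorParams()
    q1 = gradient_q(image, se, 1, border).values
    q2 = gradient_q(image, se, 2, border).values
    vals = params.kappa * np.maximum(q1, q2) + params.lam * np.minimum(q1, q2)
    return EdgeResponse(values=vals, operator_tag="Q")
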