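"""Full-reference image quality indicators and classification concordance.

MSE is the mean squared pixel difference between a processed image E and a
reference R.  PSNR comes in two dialects: the ``paper`` dialect uses
256*256 = 65536 as the peak-power numerator, the ``standard`` dialect uses
255**2; they differ by a constant 10*log10(65536/65025) ~ 0.034 dB.  SSIM
is the standard stabilized luminance-contrast-structure product with
C1 = (0.01*255)**2 and C2 = (0.03*255)**2, either as a single window over
the whole image (``global``) or averaged over 8x8 sliding windows
(``windowed``).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .image import as_pixel_array

__all__ = [
    "C1",
    "C2",
    "QualityReport",
    "ConfusionTable",
    "mse",
    "psnr",
    "ssim",
    "accuracy",
    "evaluate_pair",
]

C1 = (0.01 * 255) ** 2
C2 = (0.03 * 255) ** 2

_PEAK_POWER = {"paper": 256.0 * 256.0, "standard": 255.0**2}


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = as_pixel_array(a), as_pixel_array(b)
    if a.shape != b.shape:
        raise ValidationError(f"image dimensions differ: {a.shape} vs {b.shape}")
    return a, b


def mse(a, b) -> float:
    """Mean squared pixel difference (symmetric in its arguments)."""
    a, b = _pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a, b, dialect: str = "paper") -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    try:
        peak = _PEAK_POWER[dialect]
    except KeyError:
        raise ValidationError(
            f"unknown PSNR dialect {dialect!r}; expected 'paper' or 'standard'"
        ) from None
    err = mse(a, b)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(peak / err)


def _ssim_terms(ma, mb, va, vb, cov):
    return ((2 * ma * mb + C1) * (2 * cov + C2)) / (
        (ma**2 + mb**2 + C1) * (va + vb + C2)
    )


def ssim(a, b, mode: str = "global", window: int = 8) -> float:
    """Structural similarity; 1.0 for identical images.

    ``global`` evaluates a single window spanning the whole image;
    ``windowed`` averages over all dense ``window x window`` patches.
    """
    a, b = _pair(a, b)
    if mode == "global":
        cov = float(np.mean((a - a.mean()) * (b - b.mean())))
        return float(_ssim_terms(a.mean(), b.mean(), a.var(), b.var(), cov))
    if mode != "windowed":
        raise ValidationError(f"unknown SSIM mode {mode!r}")
    if a.shape[0] < window or a.shape[1] < window:
        raise ValidationError(f"image smaller than the {window}x{window} SSIM window")
    wa = np.lib.stride_tricks.sliding_window_view(a, (window, window))
    wb = np.lib.stride_tricks.sliding_window_view(b, (window, window))
    ma = wa.mean(axis=(2, 3))
    mb = wb.mean(axis=(2, 3))
    va = wa.var(axis=(2, 3))
    vb = wb.var(axis=(2, 3))
    cov = (wa * wb).mean(axis=(2, 3)) - ma * mb
    return float(np.mean(_ssim_terms(ma, mb, va, vb, cov)))


@dataclass(frozen=True)
class QualityReport:
    """MSE/PSNR/SSIM for one processed/reference pair; elapsed is informational."""

    mse: float
    psnr: float
    ssim: float
    elapsed: float = 0.0

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValidationError("mse must be nonnegative")
        if (self.mse == 0.0) != math.isinf(self.psnr):
            raise ValidationError("psnr must be +inf exactly when mse is 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "mse": self.mse,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "elapsed_s": self.elapsed,
        }


def evaluate_pair(processed, reference, dialect: str = "paper", mode: str = "global") -> QualityReport:
    """Compute all three indicators for a processed/reference pair."""
    t0 = time.perf_counter()
    err = mse(processed, reference)
    report = QualityReport(
        mse=err,
        psnr=psnr(processed, reference, dialect),
        ssim=ssim(processed, reference, mode),
        elapsed=time.perf_counter() - t0,
    )
    return report


@dataclass(frozen=True)
class ConfusionTable:
    """Square table of case counts; rows = reference class, cols = assigned."""

    counts: np.ndarray
    labels: tuple[str, ...] = ("complete", "partial", "marginal")

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValidationError("confusion table must be square")
        if counts.min() < 0:
            raise ValidationError("case counts must be nonnegative")
        if counts.sum() == 0:
            raise ValidationError("confusion table must contain at least one case")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def accuracy(table: ConfusionTable) -> float:
    """Percentage of cases on the diagonal: 100 * trace / total."""
    return 100.0 * float(np.trace(table.counts)) / table.total
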