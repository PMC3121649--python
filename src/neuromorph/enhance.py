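"""Image enhancement: zero the background, keep signal pixels untouched.

The enhancement classifies a pixel as background when it is *both*
low-contrast and low-intensity, and sets those pixels to zero:

1. Edge/contrast branch: the image minus its Gaussian-blurred copy
   (clamped at 0) is thresholded into ``[0, lowc]`` — pixels with low local
   contrast.
2. Intensity branch: the image is flattened with rolling-ball background
   subtraction (ball radius ``ball_radius``) and thresholded into
   ``[0, lowi]`` — pixels with low intensity above local background.
3. Background = low-contrast AND low-intensity; those pixels are zeroed,
   all others keep their original gray level exactly.

MASK POLARITY.  The AND combination is deliberate: a *dim but sharp*
neurite fails the low-contrast test (its local contrast exceeds ``lowc``)
and therefore survives even when its intensity is below ``lowi``; a
*flat but bright* soma interior fails the low-intensity test and survives
even though its local contrast is near zero.  Treating the union of the two
"low" masks as background would delete both.  (Under an inverted-mask
convention the same rule can be written as OR of the two masks followed by
a multiply, which is De Morgan-equivalent.)

Both branches read the *original* image, not a chained result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imops import (
    GrayImage,
    gaussian_blur,
    mask_multiply_gray,
    subtract_background,
    subtract_clamped,
    threshold_range,
)

__all__ = ["EnhanceParams", "enhance", "enhance_intermediates"]


@dataclass(frozen=True)
class EnhanceParams:
    """Thresholds and scales for the background-zeroing enhancement.

    Parameters
    ----------
    lowc
        Local-contrast threshold (gray levels): pixels whose blur-subtracted
        value is <= lowc count as low-contrast.
    lowi
        Intensity threshold (gray levels) applied to the background-flattened
        image: pixels <= lowi count as low-intensity.
    ball_radius
        Rolling-ball radius in pixels for background flattening (default 50).
    blur_sigma
        Gaussian sigma in pixels for the contrast branch (default 2.0).
    """

    lowc: int
    lowi: int
    ball_radius: float = 50.0
    blur_sigma: float = 2.0

    def validate(self, gmax: int) -> None:
        if not (0 <= self.lowc <= gmax):
            raise ValueError(f"lowc must be in [0, {gmax}], got {self.lowc}")
        if not (0 <= self.lowi <= gmax):
            raise ValueError(f"lowi must be in [0, {gmax}], got {self.lowi}")
        if self.ball_radius < 1:
            raise ValueError(f"ball_radius must be >= 1, got {self.ball_radius}")
        if self.blur_sigma <= 0:
            raise ValueError(f"blur_sigma must be positive, got {self.blur_sigma}")


def enhance_intermediates(img: GrayImage, params: EnhanceParams) -> dict:
    """Run the enhancement and return every intermediate product.

    Returns a dict with keys ``blur``, ``sub_blurred``, ``low_contrast``,
    ``flatten``, ``low_intensity``, ``background``, ``enhanced``.  Gray
    products are :class:`GrayImage`, masks are boolean arrays.
    """
    params.validate(img.gmax)
    blur = gaussian_blur(img, params.blur_sigma)
    sub_blurred = subtract_clamped(img, blur)
    low_contrast = threshold_range(sub_blurred, 0, params.lowc)
    flatten = subtract_background(img, params.ball_radius)
    low_intensity = threshold_range(flatten, 0, params.lowi)
    background = low_contrast & low_intensity
    enhanced = mask_multiply_gray(img, ~background)
    return {
        "blur": blur,
        "sub_blurred": sub_blurred,
        "low_contrast": low_contrast,
        "flatten": flatten,
        "low_intensity": low_intensity,
        "background": background,
        "enhanced": enhanced,
    }


def enhance(img: GrayImage, params: EnhanceParams) -> GrayImage:
    """Return the image with background pixels set to zero.

    Every output pixel is either 0 or the unchanged input value, so the
    output never exceeds the input pointwise and the fraction of
    exactly-zero pixels can only grow.
    """
    return enhance_intermediates(img, params)["enhanced"]


def histogram_table(original: GrayImage, enhanced: GrayImage) -> np.ndarray:
    """Two-series histogram (gray level, original count, enhanced count).

    Used by the interactive workflow to pick ``lowc``/``lowi``: after
    enhancement the background mass collapses onto gray level zero.
    """
    bins = np.arange(original.gmax + 2)
    h0, _ = np.histogram(original.pixels, bins=bins)
    h1, _ = np.histogram(enhanced.pixels, bins=bins)
    return np.column_stack([bins[:-1], h0, h1])
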