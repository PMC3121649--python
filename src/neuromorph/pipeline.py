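"""The per-image quantification pipeline.

Given an enhanced image (background zeroed) the pipeline extracts, in order:

* **somata** — grayscale opening with a disk of radius ``nwidth`` (the width
  of the thickest neurite) removes everything thinner than a cell body,
  including debris; thresholding the opened image at ``th1 = 1`` gives the
  soma mask, quantified by particle analysis;
* **neurites** — the enhanced image is binarized at ``th2 = 1``, components
  smaller than ``psize`` are removed, the result is skeletonized to 1-px
  centerlines and the soma mask is subtracted; neurite length is the number
  of remaining foreground pixels;
* **attachment points** — tips of the skeleton fragments that lie inside the
  1-px-dilated soma but not in the soma itself (where neurites join somata);
* **ending points** — tips of the neurite skeleton (pixels stripped by a
  count-7 erosion) that do not touch the dilated soma.

``th1``/``th2`` default to 1 because the enhancement has already set every
background pixel to zero, so any positive pixel is signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .enhance import EnhanceParams, enhance
from .imops import (
    GrayImage,
    Particle,
    analyze_particles,
    binary_dilate,
    binary_erode,
    count_particles,
    filter_particles,
    grayscale_open,
    mask_and,
    mask_subtract,
    skeletonize,
    threshold_range,
)

__all__ = [
    "PipelineParams",
    "MorphologyResult",
    "extract_soma",
    "extract_neurites",
    "detect_attachment_points",
    "detect_ending_points",
    "quantify_image",
    "robustness_sweep",
]


@dataclass(frozen=True)
class PipelineParams:
    """All user parameters of the pipeline.

    ``nwidth`` is the opening radius and should equal the width of the
    thickest neurite in pixels; ``psize`` is the smallest particle area kept
    when cleaning the binarized image.  ``th1``/``th2`` are fixed at 1 by
    construction of the enhancement and should not normally be changed.
    """

    enhance: EnhanceParams
    nwidth: int = 3
    psize: int = 20
    th1: int = 1
    th2: int = 1

    def validate(self, gmax: int) -> None:
        self.enhance.validate(gmax)
        if self.nwidth < 1:
            raise ValueError(f"nwidth must be >= 1, got {self.nwidth}")
        if self.psize < 0:
            raise ValueError(f"psize must be >= 0, got {self.psize}")


@dataclass(frozen=True)
class MorphologyResult:
    """Per-image quantification record.

    Derived ratios are ``None`` (not zero) when their denominator is zero:
    ``mean_neurite_length_per_soma`` needs at least one soma and
    ``branching_ratio`` (ending points per attachment point) at least one
    attachment point.
    """

    soma_count: int
    soma_areas: list[int] = field(default_factory=list)
    soma_total_area: int = 0
    neurite_length: int = 0
    attachment_count: int = 0
    ending_count: int = 0

    @property
    def mean_soma_area(self) -> float | None:
        return self.soma_total_area / self.soma_count if self.soma_count else None

    @property
    def mean_neurite_length_per_soma(self) -> float | None:
        return self.neurite_length / self.soma_count if self.soma_count else None

    @property
    def branching_ratio(self) -> float | None:
        if self.attachment_count:
            return self.ending_count / self.attachment_count
        return None

    def as_dict(self) -> dict:
        return {
            "soma_count": self.soma_count,
            "soma_total_area": self.soma_total_area,
            "mean_soma_area": self.mean_soma_area,
            "neurite_length": self.neurite_length,
            "attachment_count": self.attachment_count,
            "ending_count": self.ending_count,
            "mean_neurite_length_per_soma": self.mean_neurite_length_per_soma,
            "branching_ratio": self.branching_ratio,
        }


def extract_soma(
    i_new: GrayImage, params: PipelineParams
) -> tuple[np.ndarray, list[Particle]]:
    """Soma mask and particles from the enhanced image.

    Opening with a disk of radius ``nwidth`` erases neurites (width at most
    ``nwidth`` px, thinner than the 2*nwidth+1 px disk) and small debris
    while leaving cell bodies intact; the opened image is binarized at
    ``[th1, gmax]``.
    """
    opened = grayscale_open(i_new, params.nwidth)
    soma = threshold_range(opened, params.th1, i_new.gmax)
    return soma, analyze_particles(soma, 1, np.inf)


def extract_neurites(
    i_new: GrayImage, soma: np.ndarray, params: PipelineParams
) -> tuple[np.ndarray, np.ndarray, int]:
    """Skeleton, soma-free neurite mask, and total neurite length in pixels.

    Returns ``(neuritesoma_skeleton, neurite_length_mask, length)`` where the
    skeleton still runs through the somata (needed for attachment-point
    detection) and the length mask has the soma mask subtracted.  Length is a
    raw pixel count of the length mask; no diagonal sqrt(2) correction.
    """
    neuritesoma = threshold_range(i_new, params.th2, i_new.gmax)
    cleaned = filter_particles(neuritesoma, min_size=params.psize)
    skeleton = skeletonize(cleaned)
    neurite_length_mask = mask_subtract(skeleton, soma)
    return skeleton, neurite_length_mask, int(neurite_length_mask.sum())


def detect_attachment_points(
    soma: np.ndarray, neuritesoma_skeleton: np.ndarray
) -> tuple[np.ndarray, int]:
    """Points where neurites join somata.

    The soma is dilated by one pixel (count 1) and intersected with the
    skeleton, yielding 1-px-wide "stem" fragments around and inside the
    soma.  A count-7 erosion strips exactly the tip pixels of those
    fragments; the stripped tips that fall outside the soma proper are the
    attachment points, counted as 8-connected components.
    """
    soma_dilate = binary_dilate(soma, iterations=1, count=1)
    stem = mask_and(soma_dilate, neuritesoma_skeleton)
    stem_erode = binary_erode(stem, iterations=1, count=7)
    stem_points = mask_subtract(stem, stem_erode)
    points = mask_subtract(stem_points, soma)
    return points, count_particles(points)


def detect_ending_points(
    neurite_length_mask: np.ndarray, soma: np.ndarray
) -> tuple[np.ndarray, int]:
    """Terminal tips of neurites.

    A count-7 erosion removes exactly one pixel from each tip of a 1-px
    filament; subtracting the eroded mask from the original isolates the
    tips, and tips touching the dilated soma (cut ends at the soma border)
    are discarded.  A closed loop has no pixel with 7 background neighbors
    and therefore contributes no ending point.
    """
    neurite_erode = binary_erode(neurite_length_mask, iterations=1, count=7)
    tips = mask_subtract(neurite_length_mask, neurite_erode)
    points = mask_subtract(tips, binary_dilate(soma, iterations=1, count=1))
    return points, count_particles(points)


def quantify_image(img: GrayImage, params: PipelineParams) -> MorphologyResult:
    """Run the full pipeline on one image; fully deterministic."""
    params.validate(img.gmax)
    i_new = enhance(img, params.enhance)
    soma, particles = extract_soma(i_new, params)
    skeleton, neurite_mask, length = extract_neurites(i_new, soma, params)
    _, attachment_count = detect_attachment_points(soma, skeleton)
    _, ending_count = detect_ending_points(neurite_mask, soma)
    areas = [p.area for p in particles]
    return MorphologyResult(
        soma_count=len(particles),
        soma_areas=areas,
        soma_total_area=int(sum(areas)),
        neurite_length=length,
        attachment_count=attachment_count,
        ending_count=ending_count,
    )


# outputs compared by the parameter-robustness sweep
_SWEEP_OUTPUTS = (
    "soma_count",
    "soma_total_area",
    "neurite_length",
    "attachment_count",
    "ending_count",
)


def _with_perturbed(params: PipelineParams, name: str, frac: float) -> PipelineParams:
    """Perturb one user parameter by a relative fraction (rounded to int)."""
    if name == "lowc":
        value = max(0, int(round(params.enhance.lowc * (1 + frac))))
        return replace(params, enhance=replace(params.enhance, lowc=value))
    if name == "lowi":
        value = max(0, int(round(params.enhance.lowi * (1 + frac))))
        return replace(params, enhance=replace(params.enhance, lowi=value))
    if name == "psize":
        value = max(0, int(round(params.psize * (1 + frac))))
        return replace(params, psize=value)
    raise ValueError(f"unknown sweep parameter {name!r}")


def robustness_sweep(
    img: GrayImage,
    params: PipelineParams,
    perturb_fracs: tuple[float, ...] = (-0.3, -0.2, -0.1, 0.0, 0.1, 0.2, 0.3),
    parameters: tuple[str, ...] = ("lowc", "lowi", "psize"),
) -> pd.DataFrame:
    """Perturb each user parameter individually and report output deviations.

    For every parameter and perturbation fraction the image is requantified
    with the other parameters held at baseline, and each output's relative
    deviation from the 0%-perturbation value is reported.  Rows:
    ``parameter``, ``perturbation``, one ``<output>_dev`` column per output
    (relative deviation; 0 when the baseline output is 0 and unchanged,
    NaN when the baseline is 0 and the perturbed value is not).
    """
    baseline = quantify_image(img, params).as_dict()
    rows = []
    for name in parameters:
        for frac in perturb_fracs:
            res = (
                baseline
                if frac == 0.0
                else quantify_image(img, _with_perturbed(params, name, frac)).as_dict()
            )
            row: dict = {"parameter": name, "perturbation": frac}
            for out in _SWEEP_OUTPUTS:
                base, val = baseline[out], res[out]
                if base:
                    dev = (val - base) / base
                else:
                    dev = 0.0 if val == base else np.nan
                row[f"{out}_dev"] = dev
            rows.append(row)
    return pd.DataFrame(rows)
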