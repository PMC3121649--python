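"""File formats, configuration, batch driver, and the explore workflow.

The batch contract: images in a folder are processed one at a time in
lexicographic filename order, each producing one CSV row; a failure on one
image is logged and does not abort the batch; per-image memory is released
after each image, so peak memory is bounded by a single image.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .enhance import enhance_intermediates, histogram_table
from .imops import GrayImage
from .pipeline import (
    MorphologyResult,
    PipelineParams,
    detect_attachment_points,
    detect_ending_points,
    extract_neurites,
    extract_soma,
    quantify_image,
)

__all__ = [
    "RunConfig",
    "BatchSummary",
    "read_image",
    "write_image",
    "run_batch",
    "explore",
    "write_truth_sidecar",
    "INTERMEDIATE_NAMES",
]

log = logging.getLogger("neuromorph")

#: intermediate products written by :func:`explore`, in pipeline order
INTERMEDIATE_NAMES = (
    "I-blur",
    "I-sub_blurred",
    "I-low_contrast",
    "I-flatten",
    "I-low_intensity",
    "I-new",
    "I-soma",
    "I-neuritesoma",
    "I-neurite_length",
    "I-stem",
    "I-attachmentpoints",
    "I-end_points",
)

CSV_COLUMNS = (
    "filename",
    "soma_count",
    "soma_total_area",
    "mean_soma_area",
    "neurite_length",
    "attachment_count",
    "ending_count",
    "mean_neurite_length_per_soma",
    "branching_ratio",
)


@dataclass
class RunConfig:
    """Configuration for a batch run."""

    inputs: list[Path]
    output_csv: Path
    params: PipelineParams
    overlay_output: bool = False
    overlay_dir: Path | None = None
    pixel_size_um: float | None = None
    log_level: str = "INFO"


@dataclass
class BatchSummary:
    processed: int = 0
    failed: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)


def read_image(path: str | Path) -> GrayImage:
    """Read a single-channel 8/16-bit TIFF.

    The maximum gray level is inferred from the data: 8-bit containers get
    gmax = 255; 16-bit containers holding 12-bit data (max value <= 4095)
    get gmax = 4095, otherwise 65535.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2D image, got shape {data.shape}; "
            "split the channels and pass the neurite-marker channel only"
        )
    if data.dtype == np.uint8:
        gmax = 255
    elif data.dtype == np.uint16:
        gmax = 4095 if data.max() <= 4095 else 65535
    else:
        raise ValueError(f"{path}: unsupported dtype {data.dtype}; need uint8 or uint16")
    return GrayImage(data, gmax)


def write_image(path: str | Path, img: GrayImage | np.ndarray) -> None:
    """Write a gray image or a binary mask (as 0/255) to TIFF."""
    if isinstance(img, GrayImage):
        data = img.pixels
    else:
        data = np.asarray(img)
        if data.dtype == bool:
            data = data.astype(np.uint8) * 255
    tifffile.imwrite(str(path), data)


def _overlay(img: GrayImage, params: PipelineParams) -> np.ndarray:
    """RGB overlay: neurites red, attachment points blue, ending points green."""
    from .enhance import enhance

    i_new = enhance(img, params.enhance)
    soma, _ = extract_soma(i_new, params)
    skeleton, neurite_mask, _ = extract_neurites(i_new, soma, params)
    ap, _ = detect_attachment_points(soma, skeleton)
    ep, _ = detect_ending_points(neurite_mask, soma)
    base = (img.pixels.astype(np.float64) / img.gmax * 160).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    rgb[neurite_mask] = (255, 0, 0)
    rgb[soma] = (64, 64, 255)
    rgb[ep] = (0, 255, 0)
    rgb[ap] = (0, 128, 255)
    return rgb


def _result_row(filename: str, result: MorphologyResult,
                pixel_size_um: float | None) -> dict:
    row = {"filename": filename, **result.as_dict()}
    if pixel_size_um is not None:
        row["neurite_length_um"] = result.neurite_length * pixel_size_um
        row["soma_total_area_um2"] = result.soma_total_area * pixel_size_um**2
    return row


def run_batch(config: RunConfig) -> BatchSummary:
    """Process all configured images, one CSV row per image.

    The CSV starts with comment lines echoing every parameter value for
    provenance.  Images are processed in lexicographic order; per-image
    failures are logged and counted but never abort the batch.
    """
    logging.basicConfig(level=config.log_level)
    files = sorted(Path(p) for p in config.inputs)
    if not files:
        raise ValueError("no input images given")
    columns = list(CSV_COLUMNS)
    if config.pixel_size_um is not None:
        columns += ["neurite_length_um", "soma_total_area_um2"]
    summary = BatchSummary()
    config.output_csv.parent.mkdir(parents=True, exist_ok=True)
    with open(config.output_csv, "w", newline="") as fh:
        p, e = config.params, config.params.enhance
        fh.write(
            f"# lowc={e.lowc} lowi={e.lowi} ball_radius={e.ball_radius} "
            f"blur_sigma={e.blur_sigma} nwidth={p.nwidth} psize={p.psize} "
            f"th1={p.th1} th2={p.th2} pixel_size_um={config.pixel_size_um}\n"
        )
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for path in files:
            try:
                img = read_image(path)
                result = quantify_image(img, config.params)
                writer.writerow(_result_row(path.name, result, config.pixel_size_um))
                summary.processed += 1
                log.info("%s: %s", path.name, result.as_dict())
                if config.overlay_output:
                    outdir = config.overlay_dir or config.output_csv.parent
                    outdir.mkdir(parents=True, exist_ok=True)
                    tifffile.imwrite(
                        str(outdir / f"{path.stem}_overlay.tif"),
                        _overlay(img, config.params),
                    )
            except Exception as exc:  # noqa: BLE001 - per-image error policy
                summary.failed += 1
                summary.failures.append((path.name, str(exc)))
                log.error("%s: failed: %s", path.name, exc)
    return summary


def explore(path: str | Path, params: PipelineParams, outdir: str | Path) -> dict:
    """Single-image interactive analogue: write every intermediate product.

    Writes the 12 named intermediates (:data:`INTERMEDIATE_NAMES`), a
    before/after histogram table for threshold selection, and the
    quantification row.  Returns the quantification result as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img = read_image(path)
    params.validate(img.gmax)
    inter = enhance_intermediates(img, params.enhance)
    i_new = inter["enhanced"]
    soma, _ = extract_soma(i_new, params)
    from .imops import filter_particles, threshold_range

    neuritesoma = filter_particles(
        threshold_range(i_new, params.th2, i_new.gmax), min_size=params.psize
    )
    skeleton, neurite_mask, _ = extract_neurites(i_new, soma, params)
    ap_mask, _ = detect_attachment_points(soma, skeleton)
    ep_mask, _ = detect_ending_points(neurite_mask, soma)
    from .imops import binary_dilate, mask_and

    stem = mask_and(binary_dilate(soma, 1, 1), skeleton)
    products = {
        "I-blur": inter["blur"],
        "I-sub_blurred": inter["sub_blurred"],
        "I-low_contrast": inter["low_contrast"],
        "I-flatten": inter["flatten"],
        "I-low_intensity": inter["low_intensity"],
        "I-new": i_new,
        "I-soma": soma,
        "I-neuritesoma": neuritesoma,
        "I-neurite_length": neurite_mask,
        "I-stem": stem,
        "I-attachmentpoints": ap_mask,
        "I-end_points": ep_mask,
    }
    for name in INTERMEDIATE_NAMES:
        write_image(outdir / f"{name}.tif", products[name])
    hist = histogram_table(img, i_new)
    with open(outdir / "histogram.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gray_level", "count_original", "count_enhanced"])
        writer.writerows(hist.tolist())
    result = quantify_image(img, params)
    with open(outdir / "quantification.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        writer.writerow(_result_row(Path(path).name, result, None))
    return result.as_dict()


def write_truth_sidecar(path: str | Path, truth) -> None:
    """Write a scene's ground truth as a JSON sidecar next to its TIFF."""
    payload = {
        "soma_centers": truth.soma_centers,
        "soma_radii": truth.soma_radii,
        "soma_count": truth.soma_count,
        "attachment_points": truth.attachment_points,
        "ending_points": truth.ending_points,
        "total_neurite_path_length": truth.total_neurite_path_length,
        "total_neurite_pixel_length": truth.total_neurite_pixel_length,
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=float))
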