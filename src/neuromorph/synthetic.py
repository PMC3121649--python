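"""Ground-truth scene generator for validating the quantification pipeline.

Emulates the imaging regime of low-magnification (~10x) fluorescence images
of neurite-marker-stained neurons: bright, flat-topped, disk-like somata;
curvilinear neurites 1-3 px wide emanating from soma boundaries, optionally
with a single level of branching; uneven background illumination; additive
Gaussian noise; and small bright debris particles.  Every scene carries an
analytic :class:`GroundTruth` (soma centers, attachment points, ending
points, polylines, and both the Euclidean and the rasterized-pixel neurite
length) computed from the construction itself, never from the image.

Design notes
------------
* One pseudo-random stream per scene, keyed by ``seed``; the same seed
  yields a bit-identical image and truth.
* Candidate neurites whose rasterization would touch another neurite or a
  foreign soma are re-drawn (bounded retries), so truth point counts remain
  exact; truth is always built from the accepted polylines only.
* Soma interiors are flat (near-zero local contrast) and bright, and the
  soma edge falls off over a narrow Gaussian skirt — this exercises the
  intensity branch of the enhancement, while thin dim neurites exercise the
  contrast branch.
* Debris blobs are always smaller than ``debris_area_max`` and are placed
  away from the signal, so the particle remover's effect is observable by
  construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.draw import line as _draw_line

from .enhance import EnhanceParams
from .imops import GrayImage
from .pipeline import PipelineParams, quantify_image

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "render_fig_suite",
    "render_dose_series",
    "default_params",
]

# soft-edge scale of the soma skirt (pixels)
_SOMA_EDGE_SIGMA = 1.2
# random-walk step length (pixels) and per-step heading jitter (radians)
_STEP = 2.5
_JITTER = 0.10


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults describe the standard validation condition: a 384x384 8-bit
    field with 4 somata, moderate uneven illumination (gradient amplitude
    20 gray levels), additive noise of 5 gray levels, and debris well below
    the particle-removal size used in analysis.
    """

    shape: tuple[int, int] = (384, 384)
    n_somata: int = 4
    soma_radius_range: tuple[int, int] = (9, 14)
    neurites_per_soma_range: tuple[int, int] = (2, 4)
    neurite_width_range: tuple[int, int] = (1, 3)
    neurite_length_range: tuple[float, float] = (40.0, 110.0)
    branch_prob: float = 0.25
    background_gradient_amp: float = 20.0
    noise_sigma: float = 5.0
    n_debris: int = 8
    debris_area_max: int = 12
    seed: int = 0
    # rendering intensities (gray levels)
    soma_amplitude: float = 180.0
    neurite_amp_range: tuple[float, float] = (80.0, 160.0)
    tip_amp_frac: float = 0.55
    base_level: float = 8.0
    gmax: int = 255


@dataclass(frozen=True)
class GroundTruth:
    """Analytic ground truth recorded while constructing a scene."""

    soma_centers: list[tuple[float, float]] = field(default_factory=list)
    soma_radii: list[float] = field(default_factory=list)
    attachment_points: list[tuple[float, float]] = field(default_factory=list)
    ending_points: list[tuple[float, float]] = field(default_factory=list)
    neurite_polylines: list[list[tuple[float, float]]] = field(default_factory=list)
    total_neurite_path_length: float = 0.0
    total_neurite_pixel_length: int = 0

    @property
    def soma_count(self) -> int:
        return len(self.soma_centers)


def default_params(gmax: int = 255) -> PipelineParams:
    """Analysis parameters matched to the generator's standard condition.

    ``lowc = 15`` sits at ~3x the default noise scale (5 gray levels), so
    essentially all background pixels count as low-contrast while even the
    dimmest tapered neurite tip (~45 gray levels at 1-3 px width) keeps a
    local contrast well above it.  ``lowi = 40`` clears the background band
    (base + gradient + flattening residue, < ~30) yet stays below soma and
    neurite intensities.  ``nwidth = 3`` equals the thickest generated
    neurite; ``psize = 20`` exceeds the largest debris (12 px).
    """
    return PipelineParams(
        enhance=EnhanceParams(lowc=15, lowi=40, ball_radius=50.0, blur_sigma=2.0),
        nwidth=3,
        psize=20,
    )


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

_WIDTH_OFFSETS = {
    1: [(0, 0)],
    2: [(0, 0), (1, 0), (0, 1), (1, 1)],
    3: [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)],
}


def _polyline_pixels(vertices: np.ndarray) -> list[tuple[int, int]]:
    """8-connected 1-px rasterization of a polyline (ordered, deduplicated)."""
    pts: list[tuple[int, int]] = []
    vi = np.rint(vertices).astype(int)
    for (r0, c0), (r1, c1) in zip(vi[:-1], vi[1:]):
        rr, cc = _draw_line(r0, c0, r1, c1)
        for p in zip(rr.tolist(), cc.tolist()):
            if not pts or pts[-1] != p:
                pts.append(p)
    seen: set[tuple[int, int]] = set()
    out = []
    for p in pts:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def _stamp(canvas: np.ndarray, pixels: list[tuple[int, int]], values: np.ndarray,
           width: int) -> None:
    """Max-blend a widened polyline into a float canvas."""
    h, w = canvas.shape
    for (r, c), v in zip(pixels, values):
        for dr, dc in _WIDTH_OFFSETS[width]:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                if canvas[rr, cc] < v:
                    canvas[rr, cc] = v


def _stamp_mask(mask: np.ndarray, pixels: list[tuple[int, int]], width: int) -> None:
    h, w = mask.shape
    for r, c in pixels:
        for dr, dc in _WIDTH_OFFSETS[width]:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                mask[rr, cc] = True


def _render_soma(canvas: np.ndarray, center: tuple[float, float], radius: float,
                 amplitude: float) -> None:
    """Flat-topped disk with a Gaussian skirt, max-blended into the canvas."""
    h, w = canvas.shape
    pad = int(math.ceil(radius + 5 * _SOMA_EDGE_SIGMA))
    r0 = max(0, int(center[0]) - pad)
    r1 = min(h, int(center[0]) + pad + 1)
    c0 = max(0, int(center[1]) - pad)
    c1 = min(w, int(center[1]) + pad + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - center[0], cc - center[1])
    prof = np.where(
        d <= radius,
        amplitude,
        amplitude * np.exp(-((d - radius) ** 2) / (2 * _SOMA_EDGE_SIGMA**2)),
    )
    np.maximum(canvas[r0:r1, c0:c1], prof, out=canvas[r0:r1, c0:c1])


def _walk(rng: np.random.Generator, start: np.ndarray, heading: float,
          length: float, shape: tuple[int, int], margin: float = 6.0) -> np.ndarray:
    """Smooth random-walk polyline, steered to stay inside the image."""
    center = np.array(shape, dtype=float) / 2.0
    pts = [start.copy()]
    pos = start.copy()
    traveled = 0.0
    while traveled < length:
        placed = False
        h = heading
        for _ in range(12):
            nxt = pos + _STEP * np.array([math.cos(h), math.sin(h)])
            if (margin <= nxt[0] < shape[0] - margin
                    and margin <= nxt[1] < shape[1] - margin):
                placed = True
                break
            to_center = math.atan2(center[1] - pos[1], center[0] - pos[0])
            delta = (to_center - h + math.pi) % (2 * math.pi) - math.pi
            h += math.copysign(0.45, delta)
        if not placed:
            break  # cornered: truncate; truth follows the actual polyline
        heading = h + rng.normal(0.0, _JITTER)
        pos = nxt
        pts.append(pos.copy())
        traveled += _STEP
    return np.array(pts)


def _path_length(vertices: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(vertices, axis=0), axis=1)))


def _taper(amp: float, tip_frac: float, n: int, start_frac: float = 0.0,
           end_frac: float = 1.0) -> np.ndarray:
    """Per-vertex intensity tapering linearly from soma toward the tip."""
    f = np.linspace(start_frac, end_frac, n)
    return amp * (1.0 - (1.0 - tip_frac) * f)


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------


def _place_somata(rng: np.random.Generator, spec: SceneSpec,
                  max_tries: int = 4000) -> tuple[list[tuple[float, float]], list[float]]:
    h, w = spec.shape
    reach = spec.neurite_length_range[1]
    margin = spec.soma_radius_range[1] + min(reach * 0.35 + 10, min(h, w) * 0.2)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(max_tries):
        if len(centers) == spec.n_somata:
            break
        r = float(rng.uniform(*spec.soma_radius_range))
        cr = float(rng.uniform(margin, h - margin))
        cc = float(rng.uniform(margin, w - margin))
        if all(
            math.hypot(cr - pr, cc - pc) >= r + pr2 + 55
            for (pr, pc), pr2 in zip(centers, radii)
        ):
            centers.append((cr, cc))
            radii.append(r)
    if len(centers) < spec.n_somata:
        raise RuntimeError(
            f"could not place {spec.n_somata} non-overlapping somata in "
            f"{spec.shape} after {max_tries} tries; reduce n_somata or enlarge the image"
        )
    return centers, radii


def render_scene(spec: SceneSpec) -> tuple[GrayImage, GroundTruth]:
    """Render one scene and its exact ground truth (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    canvas = np.zeros(spec.shape, dtype=np.float64)

    soma_centers, soma_radii = _place_somata(rng, spec)
    for center, radius in zip(soma_centers, soma_radii):
        _render_soma(canvas, center, radius, spec.soma_amplitude)

    soma_block = np.zeros(spec.shape, dtype=bool)  # forbidden zone of foreign somata
    for center, radius in zip(soma_centers, soma_radii):
        rr, cc = np.mgrid[0:h, 0:w]
        soma_block |= np.hypot(rr - center[0], cc - center[1]) <= radius + 4

    occupied = np.zeros(spec.shape, dtype=bool)  # cumulative neurite stamps
    polylines: list[list[tuple[float, float]]] = []
    attachment_points: list[tuple[float, float]] = []
    ending_points: list[tuple[float, float]] = []
    centerline: set[tuple[int, int]] = set()
    path_length = 0.0

    for s_idx, (center, radius) in enumerate(zip(soma_centers, soma_radii)):
        n_neur = int(rng.integers(spec.neurites_per_soma_range[0],
                                  spec.neurites_per_soma_range[1] + 1))
        base = rng.uniform(0, 2 * math.pi)
        own_disk = np.zeros(spec.shape, dtype=bool)
        rr, cc = np.mgrid[0:h, 0:w]
        own_disk = np.hypot(rr - center[0], cc - center[1]) <= radius + 4
        for k in range(n_neur):
            accepted = None
            for attempt in range(40):
                theta = base + 2 * math.pi * k / n_neur + rng.uniform(-0.35, 0.35)
                start = np.array(
                    [center[0] + radius * math.cos(theta),
                     center[1] + radius * math.sin(theta)]
                )
                length = float(rng.uniform(*spec.neurite_length_range))
                main = _walk(rng, start, theta + rng.uniform(-0.2, 0.2), length, spec.shape)
                if _path_length(main) < 12:
                    continue
                branch = None
                if rng.random() < spec.branch_prob and len(main) >= 9:
                    j = int(rng.integers(len(main) // 3, 2 * len(main) // 3))
                    seg = main[j + 1] - main[j - 1]
                    bdir = math.atan2(seg[1], seg[0]) + rng.choice([-1, 1]) * rng.uniform(0.6, 1.0)
                    blen = float(rng.uniform(0.35, 0.6)) * _path_length(main[j:])
                    if blen >= 10:
                        branch = (j, _walk(rng, main[j].copy(), bdir, blen, spec.shape))
                width = int(rng.integers(spec.neurite_width_range[0],
                                         spec.neurite_width_range[1] + 1))
                # candidate stamp for the overlap test
                cand = np.zeros(spec.shape, dtype=bool)
                px_main = _polyline_pixels(main)
                _stamp_mask(cand, px_main, width)
                px_branch: list[tuple[int, int]] = []
                if branch is not None:
                    px_branch = _polyline_pixels(branch[1])
                    _stamp_mask(cand, px_branch, width)
                clash = cand & (occupied | (soma_block & ~own_disk))
                if not clash.any():
                    accepted = (main, branch, width, px_main, px_branch)
                    break
            if accepted is None:
                continue  # overcrowded direction: soma simply grows fewer neurites
            main, branch, width, px_main, px_branch = accepted
            amp = float(rng.uniform(*spec.neurite_amp_range))
            vals_main = _taper(amp, spec.tip_amp_frac, len(px_main))
            _stamp(canvas, px_main, vals_main, width)
            keep = np.zeros(spec.shape, dtype=bool)
            _stamp_mask(keep, px_main, width)
            if branch is not None:
                j, bverts = branch
                frac0 = j / max(len(main) - 1, 1)
                vals_b = _taper(amp, spec.tip_amp_frac, len(px_branch), frac0, 1.0)
                _stamp(canvas, px_branch, vals_b, width)
                _stamp_mask(keep, px_branch, width)
            # book-keeping: truth + occupancy (with a 2-px moat around stamps)
            occupied |= ndi.binary_dilation(keep, structure=np.ones((5, 5), dtype=bool))
            polylines.append([tuple(p) for p in main])
            attachment_points.append(tuple(main[0]))
            ending_points.append(tuple(main[-1]))
            centerline.update(px_main)
            path_length += _path_length(main)
            if branch is not None:
                polylines.append([tuple(p) for p in branch[1]])
                ending_points.append(tuple(branch[1][-1]))
                centerline.update(px_branch)
                path_length += _path_length(branch[1])

    # debris: small bright blobs away from the signal
    free = ~(occupied | soma_block)
    free[: 8, :] = False
    free[-8:, :] = False
    free[:, : 8] = False
    free[:, -8:] = False
    free_idx = np.flatnonzero(free)
    for _ in range(spec.n_debris):
        if free_idx.size == 0:
            break
        pos = int(free_idx[rng.integers(free_idx.size)])
        r0, c0 = divmod(pos, w)
        n_px = int(rng.integers(3, max(4, spec.debris_area_max + 1)))
        amp = float(rng.uniform(60, 150))
        blob = {(r0, c0)}
        rr, cc = r0, c0
        while len(blob) < n_px:
            rr = min(max(rr + int(rng.integers(-1, 2)), 0), h - 1)
            cc = min(max(cc + int(rng.integers(-1, 2)), 0), w - 1)
            blob.add((rr, cc))
        blob_list = [p for p in blob if free[p]]
        for p in blob_list:
            canvas[p] = max(canvas[p], amp)
        # keep debris blobs from merging with each other
        moat = np.zeros(spec.shape, dtype=bool)
        _stamp_mask(moat, blob_list, 1)
        free &= ~ndi.binary_dilation(moat, structure=np.ones((9, 9), dtype=bool))
        free_idx = np.flatnonzero(free)

    # background: pedestal + low-frequency gradient, then noise
    img = canvas + spec.base_level
    if spec.background_gradient_amp > 0:
        phi = rng.uniform(0, 2 * math.pi)
        rr, cc = np.mgrid[0:h, 0:w]
        proj = (rr * math.cos(phi) + cc * math.sin(phi)).astype(np.float64)
        proj -= proj.min()
        if proj.max() > 0:
            proj /= proj.max()
        img = img + spec.background_gradient_amp * proj
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    pixels = np.clip(np.rint(img), 0, spec.gmax)
    dtype = np.uint8 if spec.gmax <= 255 else np.uint16
    gray = GrayImage(pixels.astype(dtype), spec.gmax)

    # truth pixel length: centerline pixels outside the soma disks proper
    def _inside_soma(p: tuple[int, int]) -> bool:
        return any(
            math.hypot(p[0] - sc[0], p[1] - sc[1]) <= sr
            for sc, sr in zip(soma_centers, soma_radii)
        )

    pixel_length = sum(1 for p in centerline if not _inside_soma(p))

    truth = GroundTruth(
        soma_centers=soma_centers,
        soma_radii=soma_radii,
        attachment_points=attachment_points,
        ending_points=ending_points,
        neurite_polylines=polylines,
        total_neurite_path_length=path_length,
        total_neurite_pixel_length=int(pixel_length),
    )
    return gray, truth


# ---------------------------------------------------------------------------
# canonical complexity suite
# ---------------------------------------------------------------------------


def _canonical_neuron(
    rays: list[list[tuple[float, float]]],
    roots: int,
    junction_stems: frozenset[int] = frozenset(),
    shape: tuple[int, int] = (256, 256),
    soma_radius: float = 12.0,
) -> tuple[GrayImage, GroundTruth]:
    """Deterministic neuron: a soma at the center plus explicit 1-px rays.

    ``rays`` lists vertex chains; the first ``roots`` chains start on the
    soma boundary (their first vertex is an attachment point), the rest are
    branches whose first vertex lies on a parent ray.  Chains listed in
    ``junction_stems`` end at a branch junction, so their last vertex is not
    an ending point.
    """
    center = (shape[0] / 2.0, shape[1] / 2.0)
    canvas = np.zeros(shape, dtype=np.float64)
    _render_soma(canvas, center, soma_radius, 200.0)
    centerline: set[tuple[int, int]] = set()
    attachment, ending = [], []
    path_length = 0.0
    for i, chain in enumerate(rays):
        verts = np.array(chain, dtype=float)
        px = _polyline_pixels(verts)
        _stamp(canvas, px, np.full(len(px), 150.0), 1)
        centerline.update(px)
        path_length += _path_length(verts)
        if i < roots:
            attachment.append(tuple(verts[0]))
        if i not in junction_stems:
            ending.append(tuple(verts[-1]))
    pixel_length = sum(
        1 for p in centerline
        if math.hypot(p[0] - center[0], p[1] - center[1]) > soma_radius
    )
    img = GrayImage(np.clip(np.rint(canvas), 0, 255).astype(np.uint8), 255)
    truth = GroundTruth(
        soma_centers=[center],
        soma_radii=[soma_radius],
        attachment_points=attachment,
        ending_points=ending,
        neurite_polylines=[list(map(tuple, r)) for r in rays],
        total_neurite_path_length=path_length,
        total_neurite_pixel_length=int(pixel_length),
    )
    return img, truth


def render_fig_suite() -> list[tuple[GrayImage, GroundTruth]]:
    """Four canonical neurons A-D with graded morphological complexity.

    The suite realizes the textbook ordering used to motivate the three
    readouts: total neurite length NL separates A from B (NL_A < NL_B while
    NL_B = NL_C = NL_D); attachment points AP separate B from C (AP_B <
    AP_C = AP_D); ending points EP separate C from D (EP_C < EP_D).  All
    rays are axis-aligned (branches diagonal) so the rasterized pixel
    lengths match by construction.
    """
    cr, cc = 128.0, 128.0
    R = 12.0

    def ray(direction: tuple[int, int], start: tuple[float, float], n: int):
        return [start, (start[0] + direction[0] * n, start[1] + direction[1] * n)]

    up, down, left, right = (-1, 0), (1, 0), (0, -1), (0, 1)
    b_up = (cr - R, cc)
    b_down = (cr + R, cc)
    b_left = (cr, cc - R)
    b_right = (cr, cc + R)

    # A: two short neurites        B: the same two, four times longer
    a_rays = [ray(up, b_up, 25), ray(down, b_down, 25)]
    b_rays = [ray(up, b_up, 100), ray(down, b_down, 100)]
    # C: four medium neurites, same total pixel length as B
    c_rays = [ray(up, b_up, 50), ray(down, b_down, 50),
              ray(left, b_left, 50), ray(right, b_right, 50)]
    # D: as C, but the left and right neurites split into two branches each
    # (stem 30 px + two 10-step diagonal branches = 50 px per neurite)
    lj = (cr, cc - R - 30)
    rj = (cr, cc + R + 30)
    d_rays = [
        ray(up, b_up, 50),
        ray(down, b_down, 50),
        ray(left, b_left, 30),
        ray(right, b_right, 30),
        ray((-1, -1), lj, 10),
        ray((1, -1), lj, 10),
        ray((-1, 1), rj, 10),
        ray((1, 1), rj, 10),
    ]
    return [
        _canonical_neuron(a_rays, roots=2),
        _canonical_neuron(b_rays, roots=2),
        _canonical_neuron(c_rays, roots=4),
        _canonical_neuron(d_rays, roots=4, junction_stems=frozenset({2, 3})),
    ]


# ---------------------------------------------------------------------------
# dose-response series
# ---------------------------------------------------------------------------

# expected ratio of chebyshev pixel count to euclidean path length for a
# uniformly random direction: E[max(|cos|,|sin|)] = (4/pi) sin(pi/4)
_CHEBYSHEV_FACTOR = 0.9003


def render_dose_series(
    ic50: float,
    hill: float,
    doses: list[float],
    replicates: int = 3,
    seed: int = 0,
    noise_frac: float = 0.0,
    top: float = 600.0,
    bottom: float = 100.0,
    measure: str = "truth",
    params: PipelineParams | None = None,
    shape: tuple[int, int] = (256, 256),
) -> pd.DataFrame:
    """Scenes whose total drawn neurite length follows a 4PL inhibition curve.

    For each dose and replicate a scene is generated whose target total
    neurite length is ``bottom + (top - bottom) / (1 + (dose/ic50)**hill)``,
    optionally perturbed by multiplicative Gaussian noise of relative scale
    ``noise_frac``.  ``measure`` selects what is tabulated: ``"truth"``
    (the rasterized ground-truth pixel length, fast) or ``"pipeline"``
    (the length recovered by running the full quantification).

    Returns a DataFrame with columns ``dose``, ``replicate``,
    ``neurite_length``.
    """
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive")
    if measure not in ("truth", "pipeline"):
        raise ValueError(f"measure must be 'truth' or 'pipeline', got {measure!r}")
    rng = np.random.default_rng(seed)
    if params is None:
        params = default_params()
    n_somata, per_soma = 3, 3
    rows = []
    for dose in doses:
        target = bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)
        for rep in range(replicates):
            t = target
            if noise_frac > 0:
                t = max(bottom * 0.3, target * (1.0 + rng.normal(0.0, noise_frac)))
            per_len = t / (n_somata * per_soma) / _CHEBYSHEV_FACTOR
            # individual walks truncate at borders, get rejected on overlap,
            # and rasterization is biased for short segments, so calibrate
            # the requested length against the measured drawn length
            best: tuple[float, GrayImage, GroundTruth] | None = None
            for _ in range(20):
                per_len = float(np.clip(per_len, 6.0, min(shape) / 3.0))
                spec = SceneSpec(
                    shape=shape,
                    n_somata=n_somata,
                    neurites_per_soma_range=(per_soma, per_soma),
                    neurite_width_range=(2, 2),
                    neurite_length_range=(per_len * 0.97, per_len * 1.03),
                    branch_prob=0.0,
                    background_gradient_amp=0.0,
                    noise_sigma=0.0,
                    n_debris=0,
                    seed=int(rng.integers(2**31 - 1)),
                )
                img, truth = render_scene(spec)
                drawn = truth.total_neurite_pixel_length
                rel = abs(drawn - t) / t
                if best is None or rel < best[0]:
                    best = (rel, img, truth)
                if rel <= 0.004:
                    break
                per_len *= t / max(drawn, 1)
            _, img, truth = best
            if measure == "truth":
                length = truth.total_neurite_pixel_length
            else:
                length = quantify_image(img, params).neurite_length
            rows.append({"dose": dose, "replicate": rep, "neurite_length": length})
    return pd.DataFrame(rows)
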