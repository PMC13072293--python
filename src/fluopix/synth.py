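"""Synthetic fluorescence scenes with per-pixel ground truth.

Two kinds of scene are rendered, emulating the two image sources of the
study design:

* **sample scenes** — dark blue-cast backgrounds with circular liquid-sample
  wells whose red-channel signal rises monotonically with a nominal PPIX
  concentration drawn from the dilution ladder
  {5, 2, 1, 0.5, 0.2, 0.1, 0.05, 0.025, 0.01, 0} ug/mL;
* **surgical frames** — full-resolution operating-field images with
  low-frequency tissue texture in dark blue/violet tones, Gaussian-profile
  fluorescent blobs, near-saturated specular reflection discs, an
  exactly-black border outside the circular optical field, and (optionally)
  JPEG-like block-quantization artifacts injected into a dark region.

Concentration maps to mean red-channel elevation through a saturating
Hill-type response ``A * c^h / (c^h + K^h)`` (``h = 1`` gives the plain
hyperbola).  The default constants (``A = 175``, ``K = 0.9`` ug/mL,
``h = 1.7``, background red 8, noise sd 3) place the ladder's visibility
boundary between 0.5 and 0.2 ug/mL: elevations at c <= 0.05 sit within
about half a noise standard deviation of the background, c in {0.2, 0.1}
sit in the detection transition zone (about 4 and 1.4 sd), and c >= 0.5 is
unambiguous (16+ sd).  Green rises at a fixed fraction of the red
response; blue is unaffected by fluorescence.

Every renderer returns the frame together with a :class:`GroundTruth`
(fluorescence mask, concentration map, artifact mask) — the oracle that
real intraoperative data lacks.  Rendering is bit-deterministic for a fixed
seed.  No optics, photobleaching or working-distance effects are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

LADDER = (5.0, 2.0, 1.0, 0.5, 0.2, 0.1, 0.05, 0.025, 0.01, 0.0)

#: concentrations below this are rendered as exactly zero (blob tails)
CONC_FLOOR = 0.005


@dataclass
class GroundTruth:
    """Per-pixel oracle emitted alongside every rendered frame."""

    fluorescence_mask: np.ndarray  # bool, true iff concentration > 0
    concentration_map: np.ndarray  # float ug/mL, >= 0
    artifact_mask: np.ndarray      # bool, injected compression-artifact pixels

    def __post_init__(self):
        cm = np.asarray(self.concentration_map, dtype=np.float64)
        if np.any(cm < 0):
            raise ValueError("concentration map must be non-negative")
        fm = np.asarray(self.fluorescence_mask, dtype=bool)
        if not np.array_equal(fm, cm > 0):
            raise ValueError("fluorescence mask must equal concentration > 0")
        self.concentration_map = cm
        self.fluorescence_mask = fm
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)


@dataclass
class SampleSceneSpec:
    """Layout and photometric constants of a sample-ladder scene."""

    concentrations: tuple = LADDER
    well_radius: int = 20
    image_size: tuple | None = None     # (height, width); None = auto grid
    illumination_gain: float = 1.0
    noise_sd: float = 3.0
    half_saturation: float = 0.9        # K, ug/mL
    amplitude: float = 175.0            # A, max red elevation
    hill: float = 1.7                   # response steepness; 1 = hyperbola
    background: tuple = (8.0, 10.0, 26.0)
    green_fraction: float = 0.15
    grid_cols: int = 5
    roi_margin: int = 5                 # ROI discs stop this far inside wells

    def __post_init__(self):
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")
        if self.well_radius < 1:
            raise ValueError("well radius must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.half_saturation <= 0:
            raise ValueError("half-saturation constant K must be > 0")

    def response(self, c):
        """Mean red-channel elevation for concentration ``c`` (ug/mL)."""
        return _hill_response(c, self.amplitude, self.half_saturation, self.hill)


@dataclass
class SurgicalSceneSpec:
    """Layout of a full-resolution intraoperative frame."""

    image_size: tuple = (1080, 1920)
    blob_centers: tuple = ()            # (row, col) pairs; () with n_blobs>0 = random
    blob_scales: tuple = ()             # Gaussian sd in pixels
    blob_peaks: tuple = ()              # peak concentrations, ug/mL
    n_blobs: int = 0
    n_reflections: int = 0
    reflection_radii: tuple = ()
    dark_fraction: float = 0.12         # area share of the dark shadow region
    inject_artifacts: bool = False
    noise_sd: float = 3.0
    half_saturation: float = 0.9
    amplitude: float = 175.0
    hill: float = 1.7
    green_fraction: float = 0.15
    fov_radius_fraction: float = 0.52   # optical-field radius / min(H, W)

    def __post_init__(self):
        if any(p < 0 for p in self.blob_peaks):
            raise ValueError("blob peak concentrations must be >= 0")
        if not 0 <= self.dark_fraction < 1:
            raise ValueError("dark_fraction must lie in [0, 1)")

    def response(self, c):
        return _hill_response(c, self.amplitude, self.half_saturation, self.hill)


def _hill_response(c, amplitude, k, hill):
    c = np.asarray(c, dtype=np.float64)
    ch = np.power(c, hill, where=c > 0, out=np.zeros_like(c, dtype=np.float64))
    return amplitude * ch / (ch + k**hill)


def _well_centres(n: int, spec: SampleSceneSpec) -> tuple[np.ndarray, tuple]:
    """Grid layout for ``n`` wells; returns centres and the image size."""
    r = spec.well_radius
    pitch = int(round(2.5 * r))
    cols = min(spec.grid_cols, n)
    rows = math.ceil(n / cols)
    if spec.image_size is None:
        # leave a dark-background band below the grid so scenes carry an
        # ample negative-class pixel pool
        size = (rows * pitch + r + max(40, 2 * r), cols * pitch + r)
    else:
        size = tuple(spec.image_size)
    centres = []
    for k in range(n):
        i, j = divmod(k, cols)
        centres.append((r + pitch // 4 + i * pitch, r + pitch // 4 + j * pitch))
    centres = np.asarray(centres, dtype=float)
    h, w = size
    if np.any(centres[:, 0] + r > h) or np.any(centres[:, 1] + r > w):
        raise ValueError("wells do not fit the requested image size")
    d2 = ((centres[:, None, :] - centres[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    if np.any(d2 < (2 * r) ** 2):
        raise ValueError("wells overlap; reduce the radius or enlarge the image")
    return centres, size


def render_sample_scene(
    spec: SampleSceneSpec, seed: int
) -> tuple[np.ndarray, GroundTruth]:
    """Render a sample-ladder scene.

    The returned :class:`GroundTruth` additionally carries ``well_masks``
    (each concentration — including the 0 reference — mapped to its full
    well disc), ``roi_masks`` (the same discs eroded by ``roi_margin``,
    emulating regions of interest drawn inside each sample and clear of
    boundary effects) and ``background_mask``, for ROI extraction in tests
    and benchmarks.
    """
    rng = np.random.default_rng(seed)
    concs = list(spec.concentrations)
    centres, (h, w) = _well_centres(len(concs), spec)

    mean = np.empty((h, w, 3), dtype=np.float64)
    mean[:] = spec.background
    conc_map = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]

    well_masks, roi_masks = {}, {}
    roi_r = max(1, spec.well_radius - spec.roi_margin)
    in_any_well = np.zeros((h, w), dtype=bool)
    for c, (cy, cx) in zip(concs, centres):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mask = d2 <= spec.well_radius**2
        well_masks[c] = mask
        roi_masks[c] = d2 <= roi_r**2
        # background ROI keeps the same margin away from well boundaries
        in_any_well |= d2 <= (spec.well_radius + spec.roi_margin) ** 2
        resp = float(spec.response(c))
        mean[mask, 0] += resp
        mean[mask, 1] += spec.green_fraction * resp
        conc_map[mask] = c

    mean *= spec.illumination_gain
    noisy = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    frame = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    gt = GroundTruth(
        fluorescence_mask=conc_map > 0,
        concentration_map=conc_map,
        artifact_mask=np.zeros((h, w), dtype=bool),
    )
    gt.well_masks = well_masks
    gt.roi_masks = roi_masks
    gt.background_mask = ~in_any_well
    return frame, gt


_BLOCK = 8          # artifact block edge, pixels
_QSTEP = 4          # artifact quantization step, intensity levels
_DARK_LIMIT = 40    # "dark region": all channels below this


def _inject_block_artifacts(
    frame: np.ndarray, dark_region: np.ndarray
) -> np.ndarray:
    """Quantize red and blue of 8x8 blocks inside the dark region.

    Each block channel collapses to a single level, a positive multiple of
    the quantization step — the histogram-spike signature the preprocessing
    stage is built to remove.  Returns the boolean artifact mask.
    """
    h, w = dark_region.shape
    mask = np.zeros((h, w), dtype=bool)
    for bi in range(0, h - _BLOCK + 1, _BLOCK):
        for bj in range(0, w - _BLOCK + 1, _BLOCK):
            sl = np.s_[bi : bi + _BLOCK, bj : bj + _BLOCK]
            if not dark_region[sl].all() or frame[sl].max() >= _DARK_LIMIT:
                continue
            for ch in (0, 2):
                m = frame[sl + (ch,)].mean()
                level = int(np.clip(_QSTEP * round(m / _QSTEP), _QSTEP, 36))
                frame[sl + (ch,)] = level
            mask[sl] = True
    return mask


def render_surgical_scene(
    spec: SurgicalSceneSpec, seed: int
) -> tuple[np.ndarray, GroundTruth]:
    """Render an intraoperative-style frame with ground truth.

    A spec with zero blobs yields a non-fluorescence-guided (negative)
    frame.  The returned ground truth additionally carries ``dark_mask``
    (the generator's own dark-region map) and ``reflection_mask``.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]

    # circular optical field; outside is exactly black
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    fov_r = spec.fov_radius_fraction * min(h, w)
    fov = (yy - cy) ** 2 + (xx - cx) ** 2 <= fov_r**2

    # low-frequency tissue texture, dark blue/violet
    t = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 10.0)
    t = (t - t.min()) / (t.max() - t.min() + 1e-12)
    mean = np.empty((h, w, 3))
    mean[..., 0] = 46.0 + 34.0 * t
    mean[..., 1] = 10.0 + 14.0 * t
    mean[..., 2] = 62.0 + 46.0 * t

    # hard-edged dark shadow region: an 8 px grid-aligned rectangle kept
    # fully inside the FOV circle, offset left of centre so it stays clear
    # of the fluorescent blobs.  The shadow occludes fluorescence: the
    # concentration field is zeroed there.
    dark_region = np.zeros((h, w), dtype=bool)
    if spec.dark_fraction > 0:
        area = spec.dark_fraction * h * w
        dh = _BLOCK * max(1, int(round(math.sqrt(area / 2) / _BLOCK)))
        dwd = _BLOCK * max(1, int(round(2 * area / dh / _BLOCK)))
        dh, dwd = min(dh, h), min(dwd, w)
        reach = fov_r**2 - (dh / 2) ** 2
        d_off = max(0.0, math.sqrt(reach) - dwd / 2) if reach > 0 else 0.0
        r0 = _BLOCK * max(0, int(round((cy - dh / 2) / _BLOCK)))
        c0 = _BLOCK * max(0, int(round((cx - d_off - dwd / 2) / _BLOCK)))
        dark_region[r0 : r0 + dh, c0 : c0 + dwd] = True
        mean[dark_region] *= 0.12

    # fluorescent blobs (Gaussian concentration profiles)
    n_blobs = max(spec.n_blobs, len(spec.blob_centers))
    centres = list(spec.blob_centers)
    scales = list(spec.blob_scales)
    peaks = list(spec.blob_peaks)
    margin = 0.25 * min(h, w)
    while len(centres) < n_blobs:
        centres.append(
            (cy + rng.uniform(-margin, margin), cx + rng.uniform(-margin, margin))
        )
    while len(scales) < n_blobs:
        scales.append(rng.uniform(0.03, 0.07) * min(h, w))
    while len(peaks) < n_blobs:
        peaks.append(float(rng.choice([2.0, 5.0])))
    conc = np.zeros((h, w))
    for (by, bx), s, p in zip(centres, scales, peaks):
        if not (0 <= by < h and 0 <= bx < w):
            raise ValueError("blob centre lies outside the image")
        conc = np.maximum(
            conc, p * np.exp(-((yy - by) ** 2 + (xx - bx) ** 2) / (2 * s**2))
        )
    conc[conc < CONC_FLOOR] = 0.0
    conc[~fov] = 0.0
    conc[dark_region] = 0.0

    resp = spec.response(conc)
    mean[..., 0] += resp
    mean[..., 1] += spec.green_fraction * resp

    # specular reflection discs: near-saturated, carry no fluorescence
    refl = np.zeros((h, w), dtype=bool)
    radii = list(spec.reflection_radii)
    while len(radii) < spec.n_reflections:
        radii.append(rng.uniform(0.004, 0.012) * min(h, w))
    for r in radii:
        for _ in range(50):  # keep reflections clear of the shadow region
            ry = cy + rng.uniform(-0.8, 0.8) * (fov_r - r) * 0.7
            rx = cx + rng.uniform(-0.8, 0.8) * (fov_r - r) * 0.7
            disc = (yy - ry) ** 2 + (xx - rx) ** 2 <= (r + 2) ** 2
            if not (disc & dark_region).any():
                break
        if not (0 <= ry < h and 0 <= rx < w):
            raise ValueError("reflection disc lies outside the image")
        refl |= (yy - ry) ** 2 + (xx - rx) ** 2 <= r**2
    mean[refl] = 250.0
    conc[refl] = 0.0

    noisy = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    frame = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    frame[~fov] = 0

    artifact = np.zeros((h, w), dtype=bool)
    if spec.inject_artifacts:
        artifact = _inject_block_artifacts(frame, dark_region & fov)

    gt = GroundTruth(
        fluorescence_mask=conc > 0,
        concentration_map=conc,
        artifact_mask=artifact,
    )
    gt.dark_mask = dark_region & fov
    gt.reflection_mask = refl
    gt.fov_mask = fov
    return frame, gt
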