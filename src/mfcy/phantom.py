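"""Synthetic ultrasound-like phantom videos with annulus ground truth.

The clinical footage this package targets — transabdominal sweeps through
the fetal chest around the four-chamber view — cannot be redistributed, so
this module provides a synthetic stand-in that reproduces the *geometry
and failure modes* the fusion methods exploit, not echo physics:

* each video is a slowly drifting, slightly elliptical bright ring (the
  wall cross-section) over a darker interior and background, corrupted by
  multiplicative speckle and optional angular shadow sectors;
* per-frame ground truth (wall / cavity / whole structure) is derived
  analytically from the ring geometry, never from the rendered image;
* ``simulate_degraded_prediction`` turns a ground-truth mask into an
  imperfect probability map whose failing areas are arc-shaped gaps along
  the mask boundary, placed independently from frame to frame — the
  discontinuous-prediction failure mode that multi-frame voting is built
  to repair;
* ``baseline_ring_segmenter`` is a deterministic classical segmenter
  (smooth, threshold, small-object removal) satisfying the
  SegmentationModel contract, so the whole pipeline runs end to end
  without any trained network.

Everything is deterministic given the config seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .label_derivation import LabelTriple
from .mask_core import Frame, VideoSequence

__all__ = [
    "PhantomConfig",
    "DegradationConfig",
    "generate_phantom_video",
    "simulate_degraded_prediction",
    "BaselineRingSegmenter",
    "baseline_ring_segmenter",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise of one synthetic sweep video.

    Defaults emulate a chest filling roughly two-thirds of a 128 px frame:
    outer ring radius 40 px, wall 9 px thick, mild ellipticity, sub-pixel
    per-frame drift (the probe sweeping through the chest) and a gentle
    periodic radius wobble (cross-section change), with moderate speckle.
    """

    height: int = 128
    width: int = 128
    n_frames: int = 21
    center_drift: float = 0.35  # px per frame, along a seeded direction
    radius_base: float = 40.0  # outer radius, px
    wall_thickness: float = 9.0  # px
    ellipticity: float = 1.15  # x/y axis ratio
    wobble_amplitude: float = 1.2  # px, sinusoidal radius modulation
    speckle_scale: float = 0.35  # multiplicative speckle SD
    shadow_sectors: int = 1
    shadow_width_deg: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8 or self.n_frames < 1:
            raise ValueError("phantom frame geometry too small")
        if not (self.radius_base > self.wall_thickness > 0):
            raise ValueError("need radius_base > wall_thickness > 0")
        # Worst-case extent: max radius, widest axis, full drift excursion.
        r_max = (self.radius_base + self.wobble_amplitude) * np.sqrt(
            max(self.ellipticity, 1.0 / self.ellipticity)
        )
        excursion = self.center_drift * self.n_frames / 2.0
        if r_max + excursion + 2 > min(self.height, self.width) / 2.0:
            raise ValueError("annulus would overflow the frame at extreme drift")


@dataclass(frozen=True)
class DegradationConfig:
    """Imperfect-prediction simulator settings.

    Each frame independently loses ``dropout_sectors`` random angular arcs
    of the mask boundary (suppressed toward ``dropout_prob_floor``), has
    its boundary jittered by a random sub-pixel shift, and receives
    additive Gaussian noise.  ``dropout_depth`` is how far (px) from the
    mask boundary the suppression reaches; at the default it severs the
    full thickness of the phantom wall, producing the arc-shaped gaps seen
    in failing CNN predictions, while only nibbling the boundary of filled
    structures such as the whole thorax.
    """

    dropout_sectors: int = 2
    dropout_width_deg: float = 40.0
    dropout_prob_floor: float = 0.05
    dropout_depth: float = 9.0
    boundary_jitter: float = 1.0  # px, uniform shift amplitude
    noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_prob_floor < 1.0):
            raise ValueError("dropout_prob_floor must be in [0, 1)")
        for name in ("dropout_width_deg", "dropout_depth", "boundary_jitter", "noise_sd"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.dropout_sectors < 0:
            raise ValueError("dropout_sectors must be >= 0")


def _ring_geometry(cfg: PhantomConfig, t: int, drift_dir: np.ndarray):
    """Center and outer radius of the ring at frame t (analytic)."""
    cy = cfg.height / 2.0 + drift_dir[0] * cfg.center_drift * (t - (cfg.n_frames - 1) / 2.0)
    cx = cfg.width / 2.0 + drift_dir[1] * cfg.center_drift * (t - (cfg.n_frames - 1) / 2.0)
    radius = cfg.radius_base + cfg.wobble_amplitude * np.sin(
        2.0 * np.pi * t / max(cfg.n_frames, 2)
    )
    return cy, cx, radius


def _elliptic_distance(cfg: PhantomConfig, cy: float, cx: float, radius: float):
    """Pixel map of elliptical distance scaled so `radius` is the outer edge."""
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    sx = np.sqrt(cfg.ellipticity)
    sy = 1.0 / sx
    r_norm = np.sqrt(((yy - cy) / (radius * sy)) ** 2 + ((xx - cx) / (radius * sx)) ** 2)
    return r_norm * radius


def generate_phantom_video(cfg: PhantomConfig) -> Tuple[VideoSequence, List[LabelTriple]]:
    """Render one phantom sweep and its analytic per-frame label triples."""
    rng = np.random.default_rng(cfg.seed)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    drift_dir = np.array([np.sin(theta), np.cos(theta)])

    frames: List[Frame] = []
    labels: List[LabelTriple] = []
    for t in range(cfg.n_frames):
        cy, cx, radius = _ring_geometry(cfg, t, drift_dir)
        dist = _elliptic_distance(cfg, cy, cx, radius)
        wall = ((dist <= radius) & (dist > radius - cfg.wall_thickness)).astype(np.uint8)
        cavity = (dist <= radius - cfg.wall_thickness).astype(np.uint8)
        thorax = (wall | cavity).astype(np.uint8)
        labels.append(LabelTriple(tw=wall, tc=cavity, wt=thorax))

        img = np.full((cfg.height, cfg.width), 0.12)
        img[cavity.astype(bool)] = 0.25
        img[wall.astype(bool)] = 0.85

        if cfg.shadow_sectors > 0 and cfg.shadow_width_deg > 0:
            ang = _pixel_angles(cfg.height, cfg.width, cy, cx)
            half = np.deg2rad(cfg.shadow_width_deg) / 2.0
            for _ in range(cfg.shadow_sectors):
                center = rng.uniform(0.0, 2.0 * np.pi)
                in_sector = _angular_band(ang, center, half)
                img = np.where(in_sector, img * 0.45, img)

        if cfg.speckle_scale > 0:
            # Gamma speckle: mean 1, variance speckle_scale^2.
            shape = 1.0 / cfg.speckle_scale**2
            img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)
        frames.append(Frame(pixels=np.clip(img, 0.0, 1.0), frame_index=t))

    video = VideoSequence(
        frames=frames, video_id=f"phantom-{cfg.seed}", case_id=f"case-{cfg.seed}"
    )
    return video, labels


def _pixel_angles(height: int, width: int, cy: float, cx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    return np.arctan2(yy - cy, xx - cx)


def _angular_band(angles: np.ndarray, center: float, half_width: float) -> np.ndarray:
    diff = np.angle(np.exp(1j * (angles - center)))
    return np.abs(diff) <= half_width


def simulate_degraded_prediction(
    gt: np.ndarray, cfg: DegradationConfig, frame_index: int
) -> np.ndarray:
    """Corrupt a ground-truth mask into a plausible imperfect probability map.

    Failing areas are angular arcs of the mask boundary (within
    ``dropout_depth`` px of it), suppressed toward ``dropout_prob_floor``;
    their placement is keyed to ``(cfg.seed, frame_index)`` so neighboring
    frames fail in independent places.  The boundary is jittered by a
    random sub-pixel shift and Gaussian noise is added; output is clipped
    to [0, 1].
    """
    mask = np.asarray(gt, dtype=float)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("ground-truth mask must be 2D and non-empty")
    rng = np.random.default_rng((cfg.seed, frame_index))
    p = mask.copy()

    if cfg.boundary_jitter > 0:
        shift = rng.uniform(-cfg.boundary_jitter, cfg.boundary_jitter, size=2)
        p = ndimage.shift(p, shift, order=1, mode="constant", cval=0.0)

    if cfg.dropout_sectors > 0 and cfg.dropout_width_deg > 0 and cfg.dropout_depth > 0:
        com = ndimage.center_of_mass(mask)
        ang = _pixel_angles(*mask.shape, com[0], com[1])
        # Boundary band of the (jittered) prediction support.
        support = p >= 0.5
        if support.any():
            interior = ndimage.binary_erosion(
                support, iterations=max(int(round(cfg.dropout_depth)), 1)
            )
            band = support & ~interior
            half = np.deg2rad(cfg.dropout_width_deg) / 2.0
            for _ in range(cfg.dropout_sectors):
                center = rng.uniform(0.0, 2.0 * np.pi)
                zone = band & _angular_band(ang, center, half)
                p[zone] *= cfg.dropout_prob_floor

    if cfg.noise_sd > 0:
        p = p + rng.normal(0.0, cfg.noise_sd, size=p.shape)
    return np.clip(p, 0.0, 1.0)


class BaselineRingSegmenter:
    """Classical bright-structure segmenter: smooth, threshold, clean up.

    Deterministic and model-contract compliant; returns a soft probability
    map whose 0.5 level set is exactly the cleaned binary segmentation
    (probabilities shade away from the boundary via distance transforms).
    """

    def __init__(
        self,
        smoothing_radius: float = 1.5,
        intensity_threshold: float = 0.5,
        min_component_size: int = 64,
        name: str = "baseline-ring",
    ):
        self.smoothing_radius = smoothing_radius
        self.intensity_threshold = intensity_threshold
        self.min_component_size = min_component_size
        self.name = name

    def predict(self, frame: Frame) -> np.ndarray:
        smoothed = filters.gaussian(frame.pixels, sigma=self.smoothing_radius)
        binary = smoothed >= self.intensity_threshold
        if self.min_component_size > 0:
            binary = morphology.remove_small_objects(
                binary, max_size=self.min_component_size - 1
            )
        if not binary.any():
            return np.zeros(frame.shape)
        d_in = ndimage.distance_transform_edt(binary)
        d_out = ndimage.distance_transform_edt(~binary)
        return np.clip(0.5 + (d_in - d_out) / 4.0, 0.0, 1.0)


def baseline_ring_segmenter(
    frame: Frame,
    smoothing_radius: float = 1.5,
    intensity_threshold: float = 0.5,
    min_component_size: int = 64,
) -> np.ndarray:
    """Functional form of :class:`BaselineRingSegmenter` for one frame."""
    seg = BaselineRingSegmenter(smoothing_radius, intensity_threshold, min_component_size)
    return seg.predict(frame)
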