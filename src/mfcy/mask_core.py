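"""Core raster types and primitive operators for mask fusion.

Everything downstream of a segmentation model is expressed in terms of three
rasters: a grayscale ``Frame`` with intensities in [0, 1], a real-valued
``ProbabilityMap`` in [0, 1] emitted by a model, and a ``BinaryMask`` over
{0, 1}.  This module also owns the element-wise step (threshold) operator
H_phi that binarizes rasters, the "normalized model" wrapper that binarizes
a model's output at a fixed threshold before any fusion, and the temporal
neighborhood index arithmetic T(a, k) = {0, ±a, ±2a, ..., ±ak} used by
multi-frame fusion.

Masks and maps are plain ``numpy.ndarray``s; the dataclasses here carry the
video/sequence structure and the tunable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Literal, Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "Frame",
    "VideoSequence",
    "NeighborhoodSpec",
    "FusionConfig",
    "SegmentationModel",
    "NormalizedModel",
    "step_threshold",
    "normalize_model",
    "neighbor_indices",
    "as_binary_mask",
    "validate_probability_map",
]

BoundaryPolicy = Literal["drop", "clamp", "mirror"]
MFSemantics = Literal["mean", "literal_sum"]


def validate_probability_map(values: np.ndarray) -> np.ndarray:
    """Validate a 2D probability map: finite, within [0, 1]."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"probability map must be 2D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(f"non-finite value at (row={bad[0]}, col={bad[1]})")
    if arr.min() < 0.0 or arr.max() > 1.0:
        bad = np.argwhere((arr < 0.0) | (arr > 1.0))[0]
        raise ValueError(
            f"probability map value out of [0, 1] at (row={bad[0]}, col={bad[1]})"
        )
    return arr


def as_binary_mask(values: np.ndarray) -> np.ndarray:
    """Coerce an array-like to a {0, 1} uint8 mask, rejecting other values."""
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    if not np.isin(arr, (0, 1)).all():
        bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
        raise ValueError(
            f"mask value {arr[tuple(bad)]!r} at (row={bad[0]}, col={bad[1]}) "
            "is not 0 or 1"
        )
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class Frame:
    """A single grayscale video frame with intensities stored in [0, 1].

    Rescaling to whatever range a particular network expects (e.g. [-1, 1])
    is the concern of that model's adapter, not of the core types.
    """

    pixels: np.ndarray
    frame_index: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"frame must be a non-empty 2D raster, got {arr.shape}")
        if not np.all(np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("frame intensities must be finite and within [0, 1]")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class VideoSequence:
    """An ordered sequence of frames from one sweep, with identifiers."""

    frames: List[Frame]
    video_id: str
    case_id: str

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a video must contain at least one frame")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError(f"all frames must share one shape, got {shapes}")
        indices = [f.frame_index for f in self.frames]
        if indices != list(range(len(self.frames))):
            raise ValueError("frame_index values must be contiguous 0..length-1")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Temporal neighborhood T(a, k): offsets {0, ±a, ±2a, ..., ±ak}.

    ``a`` is the frame interval, ``k`` the factor of the frame number; the
    full offset set has 2k+1 members. ``boundary_policy`` resolves offsets
    that fall outside the video.
    """

    a: int = 3
    k: int = 3
    boundary_policy: BoundaryPolicy = "drop"

    def __post_init__(self) -> None:
        if self.a < 1 or self.k < 0:
            raise ValueError("need frame interval a >= 1 and factor k >= 0")
        if self.boundary_policy not in ("drop", "clamp", "mirror"):
            raise ValueError(f"unknown boundary_policy {self.boundary_policy!r}")

    @property
    def offsets(self) -> List[int]:
        return [i * self.a for i in range(-self.k, self.k + 1)]


@dataclass(frozen=True)
class FusionConfig:
    """All tunable thresholds and the neighborhood for MF/CY/MFCY fusion.

    Defaults: normalization threshold phi_norm=0.5, MF threshold
    phi_mf=3/7 (with a 7-frame neighborhood under mean semantics this is
    "at least 3 votes"), cylinder thresholds (phi1, phi2)=(0.5, 0.5), and
    neighborhood T(3, 3).
    """

    phi_norm: float = 0.5
    phi_mf: float = 3.0 / 7.0
    phi1: float = 0.5
    phi2: float = 0.5
    neighborhood: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)
    mf_semantics: MFSemantics = "mean"

    def __post_init__(self) -> None:
        for name in ("phi_norm", "phi_mf", "phi1", "phi2"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.mf_semantics not in ("mean", "literal_sum"):
            raise ValueError(f"unknown mf_semantics {self.mf_semantics!r}")


@runtime_checkable
class SegmentationModel(Protocol):
    """Contract for any per-frame segmentation model.

    ``predict`` maps a Frame to a probability map of the same shape with
    values in [0, 1] and must be deterministic for a given frame (seed any
    internal randomness at construction).
    """

    name: str

    def predict(self, frame: Frame) -> np.ndarray: ...


def step_threshold(raster: np.ndarray, phi: float) -> np.ndarray:
    """Element-wise step function H_phi: 1 where value >= phi, else 0.

    The boundary is inclusive: a value exactly equal to phi maps to 1.
    Accepts any finite real-valued raster (including the {-1, 0, 1} values
    produced by mask subtraction); shape is preserved.
    """
    arr = np.asarray(raster, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"non-finite value {arr[tuple(bad)]!r} at (row={bad[0]}, col={bad[1]})"
        )
    if not np.isfinite(phi):
        raise ValueError("threshold phi must be finite")
    return (arr >= phi).astype(np.uint8)


class NormalizedModel:
    """A model whose probability output is binarized at ``phi_norm``.

    Fusion operates on normalized models only: the wrapped prediction is
    ``step_threshold(model.predict(frame), phi_norm)``, so every value it
    emits is exactly 0 or 1.
    """

    def __init__(self, model: SegmentationModel, phi_norm: float = 0.5):
        if not (0.0 < phi_norm <= 1.0):
            raise ValueError(f"phi_norm={phi_norm} outside (0, 1]")
        self._model = model
        self.phi_norm = phi_norm
        self.name = f"normalized({getattr(model, 'name', model.__class__.__name__)})"

    def predict(self, frame: Frame) -> np.ndarray:
        raw = np.asarray(self._model.predict(frame), dtype=float)
        if raw.shape != frame.shape:
            raise ValueError(
                f"model {self.name} returned shape {raw.shape} "
                f"for frame of shape {frame.shape}"
            )
        return step_threshold(raw, self.phi_norm)


def normalize_model(model: SegmentationModel, phi_norm: float = 0.5) -> NormalizedModel:
    """Wrap ``model`` so its predictions are binarized at ``phi_norm``.

    Idempotent in effect: normalizing an already-normalized model leaves its
    outputs unchanged for any phi_norm in (0, 1], because {0, 1} outputs pass
    through any such threshold.
    """
    return NormalizedModel(model, phi_norm)


def neighbor_indices(
    t0: int, spec: NeighborhoodSpec, video_length: int
) -> List[int]:
    """Resolve the temporal neighborhood of frame ``t0`` within a video.

    Offsets outside [0, video_length) are resolved by the spec's boundary
    policy: ``drop`` removes them, ``clamp`` pins them to the first/last
    frame, ``mirror`` reflects them about the video ends.  The result is
    sorted, unique, and always contains ``t0``; under ``drop`` it has
    between 1 and 2k+1 members.
    """
    if video_length < 1:
        raise ValueError("video_length must be >= 1")
    if not (0 <= t0 < video_length):
        raise ValueError(f"t0={t0} out of range for video of length {video_length}")

    raw = [t0 + d for d in spec.offsets]
    if spec.boundary_policy == "drop":
        resolved: Iterable[int] = (t for t in raw if 0 <= t < video_length)
    elif spec.boundary_policy == "clamp":
        resolved = (min(max(t, 0), video_length - 1) for t in raw)
    else:  # mirror
        resolved = (_reflect(t, video_length) for t in raw)
    return sorted(set(resolved))


def _reflect(t: int, length: int) -> int:
    # Reflect about -0.5 and length-0.5 style boundaries until in range;
    # for length 1 everything collapses to frame 0.
    if length == 1:
        return 0
    period = 2 * (length - 1)
    t = t % period
    return t if t < length else period - t
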