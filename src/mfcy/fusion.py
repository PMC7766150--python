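"""Multi-frame (MF), cylinder (CY), and combined (MFCY) prediction fusion.

All three fusions are model-agnostic: they consume only binarized
prediction rasters and thresholds.

MF fuses per-frame wall predictions over a temporal neighborhood by
thresholded voting.  Under the default ``mean`` semantics a pixel is
positive when the fraction of neighborhood frames voting for it is at
least ``phi_mf`` — with phi_mf = 3/7 and a 7-frame neighborhood that is
"at least 3 of 7 votes".  The ``literal_sum`` semantics instead thresholds
the raw vote count, which for any phi <= 1 degenerates to a union over
frames; it is kept for comparison, never as the default.

CY exploits the annulus topology: the wall can be reconstructed as

    H_phi1(wall) ∪ H_phi2(thorax − cavity)

where the subtraction is element-wise over {−1, 0, 1} and the two terms
are combined as a logical union.  MFCY applies MF to each of the three
structure stacks (with a shared threshold phi3) and then CY to the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .mask_core import (
    FusionConfig,
    MFSemantics,
    NormalizedModel,
    SegmentationModel,
    VideoSequence,
    as_binary_mask,
    neighbor_indices,
    normalize_model,
    step_threshold,
)

__all__ = [
    "PredictionStack",
    "TriplePrediction",
    "multi_frame_fuse",
    "cylinder_fuse",
    "mfcy_fuse",
    "predict_with_mfcy",
    "predict_single_frame",
]


@dataclass
class PredictionStack:
    """Normalized per-frame predictions for one structure over a neighborhood."""

    masks: List[np.ndarray]
    source_indices: List[int]

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("prediction stack must be non-empty")
        if len(self.masks) != len(self.source_indices):
            raise ValueError("one source index per mask required")
        self.masks = [as_binary_mask(m) for m in self.masks]
        shapes = {m.shape for m in self.masks}
        if len(shapes) != 1:
            raise ValueError(f"all masks must share one shape, got {shapes}")
        idx = self.source_indices
        if sorted(set(idx)) != list(idx):
            raise ValueError("source_indices must be sorted and unique")

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks[0].shape


@dataclass
class TriplePrediction:
    """One normalized prediction per structure model (wall, cavity, thorax)."""

    tw: np.ndarray
    tc: np.ndarray
    wt: np.ndarray

    def __post_init__(self) -> None:
        self.tw = as_binary_mask(self.tw)
        self.tc = as_binary_mask(self.tc)
        self.wt = as_binary_mask(self.wt)
        if not (self.tw.shape == self.tc.shape == self.wt.shape):
            raise ValueError("tw, tc, wt predictions must share one shape")


def multi_frame_fuse(
    stack: PredictionStack,
    phi_mf: float,
    semantics: MFSemantics = "mean",
) -> np.ndarray:
    """Fuse a temporal stack of binary predictions by thresholded voting.

    mean: positive where (sum of votes) / len(stack) >= phi_mf (inclusive).
    literal_sum: positive where the raw vote count >= phi_mf.

    With a partial neighborhood (frames dropped at video ends) the mean
    semantics keeps phi_mf as a fraction of the *available* frames, so the
    3-of-7 proportion degrades gracefully rather than becoming unreachable.
    """
    if not (0.0 < phi_mf <= 1.0):
        raise ValueError(f"phi_mf={phi_mf} outside (0, 1]")
    votes = np.sum(np.stack(stack.masks, axis=0), axis=0, dtype=np.int64)
    if semantics == "mean":
        return step_threshold(votes / len(stack), phi_mf)
    if semantics == "literal_sum":
        return step_threshold(votes, phi_mf)
    raise ValueError(f"unknown MF semantics {semantics!r}")


def cylinder_fuse(
    triple: TriplePrediction, phi1: float = 0.5, phi2: float = 0.5
) -> np.ndarray:
    """Reconstruct the wall from the three structure predictions.

    Output = H_phi1(tw) ∪ H_phi2(wt − tc).  The subtraction lives in
    {−1, 0, 1}; with any positive threshold only the +1 pixels (thorax but
    not cavity) survive.  The union clamps the combination to {0, 1}.
    """
    for name, v in (("phi1", phi1), ("phi2", phi2)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name}={v} outside (0, 1]")
    direct = step_threshold(triple.tw, phi1)
    ring = step_threshold(
        triple.wt.astype(np.int8) - triple.tc.astype(np.int8), phi2
    )
    return (direct | ring).astype(np.uint8)


def mfcy_fuse(
    tw_stack: PredictionStack,
    tc_stack: PredictionStack,
    wt_stack: PredictionStack,
    phi1: float = 0.5,
    phi2: float = 0.5,
    phi3: float = 3.0 / 7.0,
    semantics: MFSemantics = "mean",
) -> np.ndarray:
    """MF each structure stack at phi3, then CY at (phi1, phi2).

    The three stacks must cover the same neighborhood (identical source
    indices) and share one raster shape.
    """
    if not (
        tw_stack.source_indices == tc_stack.source_indices == wt_stack.source_indices
    ):
        raise ValueError("the three stacks must cover the same neighborhood")
    if not (tw_stack.shape == tc_stack.shape == wt_stack.shape):
        raise ValueError("the three stacks must share one raster shape")
    fused = TriplePrediction(
        tw=multi_frame_fuse(tw_stack, phi3, semantics),
        tc=multi_frame_fuse(tc_stack, phi3, semantics),
        wt=multi_frame_fuse(wt_stack, phi3, semantics),
    )
    return cylinder_fuse(fused, phi1, phi2)


def _build_stack(
    video: VideoSequence, indices: Sequence[int], model: NormalizedModel
) -> PredictionStack:
    masks = []
    for t in indices:
        try:
            masks.append(model.predict(video.frames[t]))
        except Exception as exc:  # surface the offending frame
            raise RuntimeError(
                f"model {model.name} failed on frame {t} of video "
                f"{video.video_id}: {exc}"
            ) from exc
    return PredictionStack(masks=masks, source_indices=list(indices))


def predict_single_frame(
    video: VideoSequence,
    t0: int,
    tw_model: SegmentationModel,
    config: FusionConfig | None = None,
) -> np.ndarray:
    """Baseline: the wall model's single-frame prediction, binarized."""
    config = config or FusionConfig()
    model = normalize_model(tw_model, config.phi_norm)
    return model.predict(video.frames[t0])


def predict_with_mfcy(
    video: VideoSequence,
    t0: int,
    tw_model: SegmentationModel,
    tc_model: SegmentationModel,
    wt_model: SegmentationModel,
    config: FusionConfig | None = None,
    mode: str = "mfcy",
) -> np.ndarray:
    """Run the full pipeline at frame ``t0`` of ``video``.

    ``mode`` selects the ablation row: ``baseline`` (single-frame wall
    prediction), ``mf`` (multi-frame wall fusion only), ``cy`` (cylinder
    fusion of single-frame predictions), or ``mfcy`` (both).
    """
    config = config or FusionConfig()
    if mode not in ("baseline", "mf", "cy", "mfcy"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "baseline":
        return predict_single_frame(video, t0, tw_model, config)

    tw = normalize_model(tw_model, config.phi_norm)
    if mode == "cy":
        frame = video.frames[t0]
        triple = TriplePrediction(
            tw=tw.predict(frame),
            tc=normalize_model(tc_model, config.phi_norm).predict(frame),
            wt=normalize_model(wt_model, config.phi_norm).predict(frame),
        )
        return cylinder_fuse(triple, config.phi1, config.phi2)

    indices = neighbor_indices(t0, config.neighborhood, len(video))
    tw_stack = _build_stack(video, indices, tw)
    if mode == "mf":
        return multi_frame_fuse(tw_stack, config.phi_mf, config.mf_semantics)

    tc_stack = _build_stack(video, indices, normalize_model(tc_model, config.phi_norm))
    wt_stack = _build_stack(video, indices, normalize_model(wt_model, config.phi_norm))
    return mfcy_fuse(
        tw_stack,
        tc_stack,
        wt_stack,
        config.phi1,
        config.phi2,
        config.phi_mf,
        config.mf_semantics,
    )
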