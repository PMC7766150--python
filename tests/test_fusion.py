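"""MF / CY / MFCY fusion against an independent per-pixel oracle."""

import numpy as np
import pytest

from mfcy.experiment import PrecomputedModel
from mfcy.fusion import (
    PredictionStack,
    TriplePrediction,
    cylinder_fuse,
    mfcy_fuse,
    multi_frame_fuse,
    predict_single_frame,
    predict_with_mfcy,
)
from mfcy.mask_core import FusionConfig, NeighborhoodSpec, neighbor_indices
from mfcy.phantom import DegradationConfig, PhantomConfig, generate_phantom_video, simulate_degraded_prediction


# ---- independent brute-force oracles: per-pixel, no vectorization -----------

def oracle_step(x, phi):
    return 1 if x >= phi else 0


def oracle_mf(masks, phi, semantics="mean"):
    n = len(masks)
    h, w = masks[0].shape
    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            votes = sum(int(m[i, j]) for m in masks)
            x = votes / n if semantics == "mean" else votes
            out[i, j] = oracle_step(x, phi)
    return out


def oracle_cy(tw, tc, wt, phi1, phi2):
    h, w = tw.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            direct = oracle_step(int(tw[i, j]), phi1)
            ring = oracle_step(int(wt[i, j]) - int(tc[i, j]), phi2)
            out[i, j] = min(direct + ring, 1)
    return out


def oracle_mfcy(tws, tcs, wts, phi1, phi2, phi3, semantics="mean"):
    return oracle_cy(
        oracle_mf(tws, phi3, semantics),
        oracle_mf(tcs, phi3, semantics),
        oracle_mf(wts, phi3, semantics),
        phi1,
        phi2,
    )


def _stack(masks):
    return PredictionStack(masks=list(masks), source_indices=list(range(len(masks))))


def _random_masks(r, n, shape):
    return [(r.random(shape) < 0.5).astype(np.uint8) for _ in range(n)]


class TestMultiFrame:
    def test_three_of_seven_votes_inclusive(self):
        masks = [np.full((1, 1), 1 if i < 3 else 0, dtype=np.uint8) for i in range(7)]
        assert multi_frame_fuse(_stack(masks), 3 / 7, "mean")[0, 0] == 1

    def test_two_of_seven_votes_below(self):
        masks = [np.full((1, 1), 1 if i < 2 else 0, dtype=np.uint8) for i in range(7)]
        assert multi_frame_fuse(_stack(masks), 3 / 7, "mean")[0, 0] == 0

    @pytest.mark.parametrize("semantics", ["mean", "literal_sum"])
    @pytest.mark.parametrize("phi", [1 / 7, 3 / 7, 0.5, 1.0])
    def test_idempotent_on_identical_masks(self, rng, semantics, phi):
        mask = (rng.random((6, 6)) < 0.5).astype(np.uint8)
        out = multi_frame_fuse(_stack([mask] * 7), phi, semantics)
        assert np.array_equal(out, mask)

    def test_degenerate_thresholds_union_and_intersection(self, rng):
        masks = _random_masks(rng, 5, (8, 8))
        union = np.bitwise_or.reduce(masks)
        inter = np.bitwise_and.reduce(masks)
        assert np.array_equal(multi_frame_fuse(_stack(masks), 1 / 5, "mean"), union)
        assert np.array_equal(multi_frame_fuse(_stack(masks), 1.0, "mean"), inter)

    def test_literal_sum_degenerates_to_union_below_one(self, rng):
        masks = _random_masks(rng, 7, (8, 8))
        out = multi_frame_fuse(_stack(masks), 3 / 7, "literal_sum")
        assert np.array_equal(out, np.bitwise_or.reduce(masks))

    def test_pixelwise_monotone_in_each_input(self, rng):
        for _ in range(20):
            masks = _random_masks(rng, 7, (6, 6))
            base = multi_frame_fuse(_stack(masks), 3 / 7, "mean")
            raised = [m.copy() for m in masks]
            i = int(rng.integers(7))
            raised[i] = np.ones_like(raised[i])
            up = multi_frame_fuse(_stack(raised), 3 / 7, "mean")
            assert np.all(up >= base)

    def test_rejects_empty_and_mismatched(self):
        with pytest.raises(ValueError, match="non-empty"):
            PredictionStack(masks=[], source_indices=[])
        with pytest.raises(ValueError, match="shape"):
            PredictionStack(
                masks=[np.zeros((2, 2), dtype=np.uint8), np.zeros((3, 3), dtype=np.uint8)],
                source_indices=[0, 1],
            )


class TestCylinder:
    def test_perfect_triple_reconstructs_ring(self, ring5_triple):
        tw, tc, wt = ring5_triple
        out = cylinder_fuse(TriplePrediction(tw=tw, tc=tc, wt=wt), 0.5, 0.5)
        assert np.array_equal(out, tw)

    def test_subtraction_term_alone_suffices(self, ring5_triple):
        tw, tc, wt = ring5_triple
        zero = np.zeros_like(tw)
        out = cylinder_fuse(TriplePrediction(tw=zero, tc=tc, wt=wt), 0.5, 0.5)
        assert np.array_equal(out, tw)

    def test_direct_term_alone_suffices(self, ring5_triple):
        tw, _, _ = ring5_triple
        zero = np.zeros_like(tw)
        out = cylinder_fuse(TriplePrediction(tw=tw, tc=zero, wt=zero), 0.5, 0.5)
        assert np.array_equal(out, tw)

    def test_union_dominance(self, rng):
        for _ in range(50):
            tw, tc, wt = _random_masks(rng, 3, (8, 8))
            out = cylinder_fuse(TriplePrediction(tw=tw, tc=tc, wt=wt), 0.5, 0.5)
            assert np.all(out >= tw)


class TestMFCY:
    def test_single_frame_stacks_reduce_to_cylinder(self, rng):
        tw, tc, wt = _random_masks(rng, 3, (8, 8))
        single = mfcy_fuse(_stack([tw]), _stack([tc]), _stack([wt]))
        assert np.array_equal(single, cylinder_fuse(TriplePrediction(tw, tc, wt)))

    def test_contains_mf_only_wall_output(self, rng):
        for _ in range(20):
            tws, tcs, wts = (_random_masks(rng, 7, (8, 8)) for _ in range(3))
            mf_only = multi_frame_fuse(_stack(tws), 3 / 7, "mean")
            combined = mfcy_fuse(_stack(tws), _stack(tcs), _stack(wts))
            assert np.all(combined >= mf_only)

    def test_oracle_equivalence_random_instances(self, rng):
        phis = [i / 7 for i in range(1, 8)]
        for trial in range(100):
            tws, tcs, wts = (_random_masks(rng, 7, (8, 8)) for _ in range(3))
            phi3 = phis[trial % 7]
            got = mfcy_fuse(_stack(tws), _stack(tcs), _stack(wts), 0.5, 0.5, phi3)
            assert np.array_equal(got, oracle_mfcy(tws, tcs, wts, 0.5, 0.5, phi3))

    def test_mismatched_neighborhoods_rejected(self, rng):
        tws, tcs, wts = (_random_masks(rng, 3, (4, 4)) for _ in range(3))
        shifted = PredictionStack(masks=tcs, source_indices=[0, 1, 3])
        with pytest.raises(ValueError, match="neighborhood"):
            mfcy_fuse(_stack(tws), shifted, _stack(wts))


@pytest.fixture(scope="module")
def phantom():
    video, labels = generate_phantom_video(PhantomConfig(n_frames=11, seed=7))
    return video, labels


class TestPredictWithMFCY:
    def _oracle_models(self, labels):
        return tuple(
            PrecomputedModel([getattr(t, s).astype(float) for t in labels], name=s)
            for s in ("tw", "tc", "wt")
        )

    @pytest.mark.parametrize("mode", ["baseline", "mf", "cy", "mfcy"])
    def test_perfect_models_return_ground_truth(self, phantom, mode):
        video, labels = phantom
        tw_m, tc_m, wt_m = self._oracle_models(labels)
        for t0 in range(len(video)):
            out = predict_with_mfcy(video, t0, tw_m, tc_m, wt_m, mode=mode)
            if mode in ("baseline", "cy"):
                assert np.array_equal(out, labels[t0].tw)
            else:
                # MF fuses neighboring (drifted) ground truths: votes agree
                # with the per-pixel oracle, not necessarily with frame t0.
                idx = neighbor_indices(t0, NeighborhoodSpec(), len(video))
                expected = oracle_mf([labels[t].tw for t in idx], 3 / 7)
                if mode == "mf":
                    assert np.array_equal(out, expected)
                else:
                    assert np.all(out >= expected)

    def test_degraded_models_match_equation_oracle(self, phantom):
        video, labels = phantom
        from mfcy.mask_core import step_threshold

        models = []
        for s_idx, s in enumerate(("tw", "tc", "wt")):
            cfg = DegradationConfig(seed=100 + s_idx)
            maps = [
                simulate_degraded_prediction(getattr(labels[t], s), cfg, t)
                for t in range(len(video))
            ]
            models.append(PrecomputedModel(maps, name=s))
        t0 = 5
        out = predict_with_mfcy(video, t0, *models, mode="mfcy")
        idx = neighbor_indices(t0, NeighborhoodSpec(), len(video))
        binarized = [
            [step_threshold(m._maps[t], 0.5) for t in idx] for m in models
        ]
        assert np.array_equal(out, oracle_mfcy(*binarized, 0.5, 0.5, 3 / 7))

    def test_edge_frame_uses_reduced_stack(self, phantom):
        video, labels = phantom
        tw_m, tc_m, wt_m = self._oracle_models(labels)
        out = predict_with_mfcy(video, 0, tw_m, tc_m, wt_m, mode="mf")
        idx = neighbor_indices(0, NeighborhoodSpec(), len(video))
        assert idx == [0, 3, 6, 9]
        expected = oracle_mf([labels[t].tw for t in idx], 3 / 7)
        assert np.array_equal(out, expected)

    def test_baseline_equals_single_frame_helper(self, phantom):
        video, labels = phantom
        tw_m, _, _ = self._oracle_models(labels)
        assert np.array_equal(
            predict_with_mfcy(video, 4, tw_m, tw_m, tw_m, mode="baseline"),
            predict_single_frame(video, 4, tw_m),
        )

    def test_model_failure_names_frame(self, phantom):
        video, labels = phantom

        class Broken:
            name = "broken"

            def predict(self, frame):
                raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="frame 0"):
            predict_with_mfcy(video, 0, Broken(), Broken(), Broken(), mode="mf")
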