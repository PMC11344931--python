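"""Drift estimation, accumulation, and segmentation against exhaustive
oracles and generator ground truth."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosip import (
    DriftTrace,
    IonImageStack,
    SceneConfig,
    accumulate,
    estimate_drift,
    segment_cells,
    translate,
)
from nanosip.synth import generate_scene


def oracle_drift(planes, max_shift):
    """Independent exhaustive NCC search: Pearson r via np.corrcoef on the
    overlap of every candidate shift; best r, ties to smallest magnitude
    then row-major (dy, dx)."""
    h, w = planes[0].shape
    ref = planes[0].astype(float)
    out = [(0, 0)]
    for p in range(1, len(planes)):
        mov = planes[p].astype(float)
        scored = []
        for dy in range(-max_shift, max_shift + 1):
            for dx in range(-max_shift, max_shift + 1):
                a = ref[max(0, -dy): h - max(0, dy), max(0, -dx): w - max(0, dx)]
                b = mov[max(0, dy): h - max(0, -dy), max(0, dx): w - max(0, -dx)]
                if a.std() == 0 or b.std() == 0:
                    r = -np.inf
                else:
                    r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
                scored.append((r, dy, dx))
        best_r = max(s[0] for s in scored)
        ties = [(dy, dx) for r, dy, dx in scored if r == best_r]
        ties.sort(key=lambda s: (s[0] ** 2 + s[1] ** 2, s[0], s[1]))
        out.append(ties[0])
    return out


def _inject(field, shifts, bg):
    planes = [field if s == (0, 0) else translate(field, *s, fill=bg) for s in shifts]
    return np.stack(planes)


class TestEstimateDrift:
    def test_identical_planes_give_zero_shifts(self, flat_stack):
        # constant planes carry no signal: the reference is nonzero but NCC is
        # undefined everywhere, so the smallest-magnitude candidate (0,0) wins
        trace = estimate_drift(flat_stack, ref_ion="12C14N", max_shift=3)
        assert list(trace) == [(0, 0)] * 6

    def test_known_shifts_recovered_exactly_noise_free(self):
        cfg = SceneConfig(n_cells=2, image_size=128, raster_um=12.0,
                          drift_max_px=0, seed=21)
        stack, _ = generate_scene(cfg, 0.0, expectation=True)
        field = stack.ion("12C14N")[0]
        shifts = [(0, 0), (1, 0), (2, 1), (3, 1), (3, 2), (4, 2)]
        planes = _inject(field, shifts, bg=field.min())
        s = IonImageStack(ion_labels=("12C14N",), counts=planes[None],
                          raster_um=12.0)
        trace = estimate_drift(s, ref_ion="12C14N", max_shift=5)
        assert list(trace) == shifts

    def test_matches_exhaustive_oracle_on_noise_free_scenes(self):
        rng = np.random.default_rng(77)
        for case in range(10):
            cfg = SceneConfig(n_cells=2, image_size=96, raster_um=9.0,
                              cell_length_um=(2.5, 3.5), drift_max_px=0,
                              seed=100 + case)
            stack, _ = generate_scene(cfg, 0.0, expectation=True)
            field = stack.ion("12C14N")[0]
            shifts = [(0, 0)] + [tuple(rng.integers(-3, 4, 2)) for _ in range(3)]
            planes = _inject(field, shifts, bg=field.min())
            s = IonImageStack(ion_labels=("12C14N",), counts=planes[None], raster_um=9.0)
            trace = estimate_drift(s, ref_ion="12C14N", max_shift=3)
            assert list(trace) == oracle_drift(planes, 3)
            assert list(trace) == [tuple(x) for x in shifts]

    def test_noisy_scene_recovery_rate(self):
        """Poisson scenes at >=50 counts/px: nearly every plane's drift is
        recovered exactly."""
        total = correct = 0
        for rep in range(20):
            cfg = SceneConfig(n_cells=3, image_size=128, raster_um=12.0,
                              drift_max_px=3, seed=500)
            stack, truth = generate_scene(cfg, 0.0, replicate=rep)
            trace = estimate_drift(stack, max_shift=3)
            for est, true in zip(list(trace)[1:], truth.shifts[1:]):
                total += 1
                correct += est == true
        assert correct / total >= 0.95

    def test_all_zero_reference_errors(self):
        counts = np.zeros((1, 3, 32, 32), dtype=np.int64)
        s = IonImageStack(ion_labels=("12C14N",), counts=counts, raster_um=6.0)
        with pytest.raises(ValueError, match="no signal"):
            estimate_drift(s)


class TestAccumulate:
    def test_six_ones_planes_zero_trace(self, flat_stack):
        acc = accumulate(flat_stack, DriftTrace.zero(6))
        assert acc.validity.all()
        np.testing.assert_array_equal(acc.ion("12C"), 6)

    def test_zero_drift_conserves_counts(self, small_scene):
        stack, _ = small_scene
        acc = accumulate(stack, DriftTrace.zero(stack.n_planes))
        assert acc.counts.sum() == stack.counts.sum()
        np.testing.assert_array_equal(acc.counts, stack.counts.sum(axis=1))

    def test_in_mask_counts_bounded_by_stack_total(self, small_scene):
        stack, truth = small_scene
        acc = accumulate(stack, DriftTrace(truth.shifts))
        assert acc.counts.sum() <= stack.counts.sum()

    def test_unit_shift_excludes_exactly_one_column(self):
        counts = np.ones((1, 6, 64, 64), dtype=np.int64)
        s = IonImageStack(ion_labels=("12C",), counts=counts, raster_um=6.0)
        trace = DriftTrace([(0, 0)] + [(0, 1)] * 5)
        acc = accumulate(s, trace)
        # planes drifted right by 1 px are shifted back left; their footprint
        # misses the rightmost column only
        expected = np.ones((64, 64), bool)
        expected[:, -1] = False
        np.testing.assert_array_equal(acc.validity, expected)
        assert (acc.counts[0, :, :-1] == 6).all()
        assert (acc.counts[0, :, -1] == 0).all()

    def test_composition_property_noise_free(self):
        """Accumulating a drifted scene with the recovered trace reproduces
        the undrifted accumulation on the common validity mask."""
        cfg = SceneConfig(n_cells=2, image_size=96, raster_um=9.0,
                          cell_length_um=(2.5, 3.5), drift_max_px=3, seed=31)
        drifted, truth = generate_scene(cfg, 0.0, expectation=True)
        cfg0 = dataclasses.replace(cfg, drift_max_px=0)
        still, _ = generate_scene(cfg0, 0.0, expectation=True)
        trace = estimate_drift(drifted, max_shift=3)
        assert list(trace) == truth.shifts
        acc_d = accumulate(drifted, trace)
        acc_0 = accumulate(still, DriftTrace.zero(still.n_planes))
        common = acc_d.validity & acc_0.validity
        for i in range(len(acc_d.ion_labels)):
            np.testing.assert_allclose(acc_d.counts[i][common], acc_0.counts[i][common],
                                       rtol=1e-12)

    def test_trace_length_mismatch_rejected(self, flat_stack):
        with pytest.raises(ValueError, match="planes"):
            accumulate(flat_stack, DriftTrace.zero(4))

    def test_oversize_shift_rejected(self, flat_stack):
        with pytest.raises(ValueError, match="exceeds"):
            accumulate(flat_stack, DriftTrace([(0, 0)] + [(0, 99)] * 5))


class TestTranslate:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(dy=st.integers(-5, 5), dx=st.integers(-5, 5), seed=st.integers(0, 100))
    def test_inverse_shift_restores_interior(self, dy, dx, seed):
        img = np.random.default_rng(seed).integers(0, 100, (16, 16)).astype(float)
        back = translate(translate(img, dy, dx, fill=-1.0), -dy, -dx, fill=-1.0)
        inner = back[5:11, 5:11]
        np.testing.assert_array_equal(inner, img[5:11, 5:11])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(dy=st.integers(-5, 5), dx=st.integers(-5, 5))
    def test_shift_never_creates_counts(self, dy, dx):
        img = np.full((12, 12), 3.0)
        assert translate(img, dy, dx, fill=0.0).sum() <= img.sum()


class TestSegmentCells:
    def test_background_only_scene_empty(self):
        cfg = SceneConfig(n_cells=0, image_size=64, raster_um=6.0, seed=4)
        stack, _ = generate_scene(cfg, 0.0)
        acc = accumulate(stack, DriftTrace.zero(stack.n_planes))
        assert segment_cells(acc) == []

    def test_constant_image_warns_and_returns_empty(self, flat_stack, caplog):
        acc = accumulate(flat_stack, DriftTrace.zero(6))
        with caplog.at_level("WARNING"):
            rois = segment_cells(acc, ion="12C14N")
        assert rois == []
        assert "constant" in caplog.text

    def test_rois_match_truth_masks(self, small_scene):
        stack, truth = small_scene
        trace = estimate_drift(stack, max_shift=3)
        acc = accumulate(stack, trace)
        rois = segment_cells(acc)
        assert len(rois) == truth.n_cells
        assert all(r.source == "auto" for r in rois)
        areas = [r.area_px for r in rois]
        assert areas == sorted(areas, reverse=True)
        for roi in rois:
            ious = []
            for k in range(1, truth.n_cells + 1):
                t = truth.cell_mask(k)
                ious.append((roi.mask & t).sum() / (roi.mask | t).sum())
            assert max(ious) >= 0.9

    def test_roi_count_equals_truth_over_seeded_scenes(self):
        for rep in range(15):
            cfg = SceneConfig(n_cells=3, image_size=128, raster_um=12.0, seed=900)
            stack, truth = generate_scene(cfg, 0.0, replicate=rep)
            acc = accumulate(stack, estimate_drift(stack, max_shift=3))
            assert len(segment_cells(acc)) == truth.n_cells
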