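"""Nucleus detection/tracking, equatorial sections, ring segments and HIPs."""

import numpy as np
import pytest

from thermoscreen import TimelapseSimConfig, simulate_timelapse
from thermoscreen.condensation import (
    NucleusCandidate,
    SectionError,
    condensation_statistic,
    detect_nuclei,
    equatorial_section,
    group_compare,
    hip_fractions,
    ring_segments,
    track,
)


def _spheres(shape, centers, radius=8.0):
    vol = np.zeros(shape, dtype=float)
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    for zc, yc, xc in centers:
        vol += 1.0 * (np.sqrt((zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2) < radius)
    return vol


def _disc(radius, pad=4):
    n = 2 * (radius + pad) + 1
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


class TestDetect:
    def test_detects_all_planted_nuclei(self, peripheral_sim):
        cands = detect_nuclei(peripheral_sim.stack[0, ..., 1])
        assert len(cands) == len(peripheral_sim.truth)
        truth = peripheral_sim.truth[["z", "y", "x"]].to_numpy()
        for c in cands:
            assert np.min(np.linalg.norm(truth - c.centroid, axis=1)) < 2.0

    def test_border_proximity_rejected(self):
        vol = _spheres((24, 64, 64), [(12, 5, 32)])  # 5 px from the Y edge
        assert detect_nuclei(vol, smooth_sigma=2, min_size=100, border_margin=10) == []

    def test_too_close_pair_both_rejected(self):
        vol = _spheres((24, 96, 96), [(12, 48, 30), (12, 48, 50)])
        cands = detect_nuclei(
            vol, smooth_sigma=2, min_size=100, border_margin=5, min_separation=30
        )
        assert cands == []


def _cand(z, y, x):
    return NucleusCandidate(np.array([z, y, x], dtype=float), 100)


class TestTrack:
    def test_stationary_nuclei_keep_identity(self):
        frames = [[_cand(5, 10, 10), _cand(5, 40, 40)] for _ in range(6)]
        tracks = track(frames)
        assert len(tracks) == 2
        for tr in tracks:
            assert len(tr) == 6
            assert len({tuple(c.centroid) for c in tr}) == 1

    def test_vanishing_nucleus_drops_its_track(self):
        frames = [[_cand(5, 10, 10), _cand(5, 40, 40)] for _ in range(3)]
        frames += [[_cand(5, 10, 10)] for _ in range(3)]
        tracks = track(frames)
        assert len(tracks) == 1
        assert tracks[0][0].centroid[1] == 10

    def test_candidate_order_within_frames_irrelevant(self):
        frames_a = [[_cand(5, 10, 10), _cand(5, 40, 40)], [_cand(5, 11, 10), _cand(5, 41, 40)]]
        frames_b = [list(reversed(f)) for f in frames_a]
        ta, tb = track(frames_a), track(frames_b)
        ends_a = sorted(tuple(tr[-1].centroid) for tr in ta)
        ends_b = sorted(tuple(tr[-1].centroid) for tr in tb)
        assert ends_a == ends_b

    def test_displacement_beyond_limit_starts_new_track(self):
        frames = [[_cand(5, 10, 10)], [_cand(5, 50, 50)]]
        assert track(frames, max_displacement=10.0) == []


class TestEquatorialSection:
    def test_recovers_equator_and_radius(self, peripheral_sim):
        sim = peripheral_sim
        nuc = sim.truth.iloc[0]
        sec = equatorial_section(sim.stack[0, ..., 0], nuc[["z", "y", "x"]].to_numpy())
        assert abs(sec.z_index - nuc["z"]) <= 1
        r_eff = np.sqrt(sec.interior_mask.sum() / np.pi)
        assert r_eff == pytest.approx(sim.config.nucleus_radius, abs=2.0)
        # interior area ~ pi r^2 within 10%
        r_in = sim.config.nucleus_radius - sim.config.lamina_ring_width / 2
        assert sec.interior_mask.sum() == pytest.approx(np.pi * r_in**2, rel=0.10)

    def test_contour_is_closed(self, peripheral_sim):
        nuc = peripheral_sim.truth.iloc[1]
        sec = equatorial_section(peripheral_sim.stack[0, ..., 0], nuc[["z", "y", "x"]].to_numpy())
        assert np.allclose(sec.contour[0], sec.contour[-1])

    def test_blank_lamina_is_excluded_not_crashed(self):
        with pytest.raises(SectionError):
            equatorial_section(np.zeros((10, 64, 64)), np.array([5.0, 32.0, 32.0]))


class TestRingSegments:
    def test_disc_radius_30_segment1_area_share(self):
        labels = ring_segments(_disc(30))
        areas = np.bincount(labels[labels > 0], minlength=7)[1:]
        share1 = areas[0] / areas.sum()
        assert share1 == pytest.approx((30**2 - 28**2) / 30**2, abs=0.02)

    def test_segments_partition_interior_exactly(self):
        interior = _disc(20)
        labels = ring_segments(interior)
        assert ((labels > 0) == interior).all()  # union = interior, disjoint by construction
        assert set(np.unique(labels[interior])) == {1, 2, 3, 4, 5, 6}

    def test_small_disc_populates_outer_segments_only(self):
        labels = ring_segments(_disc(6))
        present = set(np.unique(labels[labels > 0]))
        assert {1, 2, 3} <= present
        assert 6 not in present

    def test_thin_interior_warns_all_segment1(self):
        strip = np.zeros((10, 40), dtype=bool)
        strip[4:6, 5:35] = True
        with pytest.warns(UserWarning, match="thinner"):
            labels = ring_segments(strip)
        assert set(np.unique(labels[strip])) == {1}

    def test_equal_depth_mode_covers_interior(self):
        interior = _disc(25)
        labels = ring_segments(interior, mode="equal_depth")
        assert ((labels > 0) == interior).all()


class TestHipFractions:
    def test_uniform_intensities_give_area_shares(self):
        interior = _disc(30)
        labels = ring_segments(interior)
        areas = np.bincount(labels[labels > 0], minlength=7)[1:]
        shares = areas / areas.sum()
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(100):
            img = rng.uniform(size=interior.shape)
            fracs.append(hip_fractions(img, labels).fractions)
        mean_frac = np.mean(fracs, axis=0)
        se = np.std(fracs, axis=0, ddof=1) / np.sqrt(100)
        assert np.all(np.abs(mean_frac - shares) < 3 * np.maximum(se, 1e-4))

    def test_all_hips_in_segment1(self):
        interior = _disc(20)
        labels = ring_segments(interior)
        img = np.zeros(interior.shape)
        img[(labels == 1)] = 10.0
        prof = hip_fractions(img, labels)
        assert prof.fractions[0] > 0.999
        assert prof.tie_flagged  # constant-0 interior creates massive ties

    def test_fractions_sum_to_one(self):
        interior = _disc(15)
        labels = ring_segments(interior)
        rng = np.random.default_rng(1)
        prof = hip_fractions(rng.normal(size=interior.shape), labels)
        assert prof.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert prof.n_hips == pytest.approx(0.3 * prof.n_interior_pixels, rel=0.05)

    def test_tiny_interior_rejected(self):
        labels = ring_segments(_disc(3))
        with pytest.raises(ValueError, match="interior pixels"):
            hip_fractions(np.ones(labels.shape), labels)


class TestCondensationStatistic:
    def test_max_over_window_and_constant_series(self):
        series = np.full(9, 0.25)
        assert condensation_statistic(series, 8) == pytest.approx(0.25)
        series[5] = 0.6
        assert condensation_statistic(series, 8) == pytest.approx(0.6)

    def test_window_excludes_metaphase_frame_itself(self):
        series = np.full(9, 0.2)
        series[8] = 0.9  # the metaphase frame does not count
        assert condensation_statistic(series, 8) == pytest.approx(0.2)

    def test_doubled_rate_needs_16_frames(self):
        series = np.full(17, 0.3)
        assert condensation_statistic(series, 16, doubled_rate=True) == pytest.approx(0.3)
        with pytest.raises(ValueError, match="fewer"):
            condensation_statistic(np.full(9, 0.3), 8, doubled_rate=True)

    def test_missing_values_exclude_nucleus(self):
        series = np.full(9, 0.2)
        series[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            condensation_statistic(series, 8)


class TestGroupCompare:
    def test_identical_groups(self):
        g = [0.3, 0.4, 0.5]
        cmp = group_compare(g, g)
        assert cmp.t == pytest.approx(0.0)
        assert cmp.p == pytest.approx(1.0)

    def test_hand_checkable_t_test(self):
        cmp = group_compare([1, 2, 3], [4, 5, 6])
        assert cmp.t == pytest.approx(-3.6742, abs=1e-3)
        assert cmp.p == pytest.approx(0.02131, abs=5e-4)

    def test_welch_option_differs_under_unequal_variance(self):
        a = [1.0, 1.1, 0.9, 1.0, 1.05]
        b = [2.0, 4.0, 0.5, 3.0, 1.5]
        student = group_compare(a, b)
        welch = group_compare(a, b, equal_var=False)
        assert student.p != welch.p

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [2.0, 3.0])


class TestEndToEnd:
    def test_peripheral_statistic_exceeds_twice_area_share(self, peripheral_analysis):
        # segment-1 area share of the detected interior is ~0.236
        assert peripheral_analysis["max_seg1_hip_fraction"].mean() > 2 * 0.236
        assert len(peripheral_analysis) == 4

    def test_internal_statistic_near_area_share(self, internal_analysis):
        assert internal_analysis["max_seg1_hip_fraction"].mean() == pytest.approx(0.236, abs=0.05)

    def test_rotated_stack_gives_same_fractions(self, internal_sim):
        """Segment fractions are rotation invariant up to discretization."""
        sim = internal_sim
        t = 0
        nuc = sim.truth.iloc[0]
        lam, chrom = sim.stack[t, ..., 0], sim.stack[t, ..., 1]
        sec = equatorial_section(lam, nuc[["z", "y", "x"]].to_numpy())
        prof = hip_fractions(chrom[sec.z_index], ring_segments(sec.interior_mask))

        lam_r = np.rot90(lam, axes=(1, 2))
        chrom_r = np.rot90(chrom, axes=(1, 2))
        ny = lam.shape[2]
        cen_r = np.array([nuc["z"], ny - 1 - nuc["x"], nuc["y"]])
        sec_r = equatorial_section(lam_r, cen_r)
        prof_r = hip_fractions(chrom_r[sec_r.z_index], ring_segments(sec_r.interior_mask))
        np.testing.assert_allclose(prof_r.fractions, prof.fractions, atol=0.01)
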