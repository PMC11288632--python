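import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zygoquant.errors import (
    DegenerateEmbryoError,
    ExcludedPhaseError,
    NoDataError,
    NoSignalError,
)
from zygoquant.geometry import EllipsoidDims
from zygoquant.scatter import (
    DetectionParams,
    Punctum,
    detect_puncta,
    distance_to_dna,
    punctum_multiplicity,
    quantify_stack,
    scatter_profile,
)
from zygoquant.synthetic import SceneConfig, sample_puncta, simulate_zstack


class TestMultiplicity:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(2.0, 2), (1.0, 1), (3.05, 3), (0.4, 1), (2.5, 3), (1.49, 1)],
    )
    def test_rounding_half_up_with_floor_one(self, ratio, expected):
        assert punctum_multiplicity(ratio * 10.0, 10.0) == expected

    def test_negative_corrected_mean_clips_to_floor(self):
        assert punctum_multiplicity(-5.0, 10.0) == 1

    def test_degenerate_normalisation_rejected(self):
        with pytest.raises(DegenerateEmbryoError):
            punctum_multiplicity(10.0, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(mass=st.floats(0.1, 1000), avg=st.floats(0.1, 1000),
           c=st.floats(0.01, 100))
    def test_scale_invariance(self, mass, avg, c):
        assert punctum_multiplicity(mass, avg) == punctum_multiplicity(c * mass, c * avg)


class TestDistance:
    def test_in_plane_3_4_5(self):
        assert distance_to_dna((3, 4, 0), (0, 0, 0)) == 5.0

    def test_z_offset_pythagoras(self):
        # 4 µm in plane plus 3 z-steps of 1 µm
        assert distance_to_dna((4, 0, 3), (0, 0, 0)) == 5.0

    def test_random_pairs_match_formula(self, rng):
        p = rng.uniform(-50, 50, size=(1000, 3))
        q = rng.uniform(-50, 50, size=(1000, 3))
        for a, b in zip(p, q):
            direct = math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))
            assert distance_to_dna(a, b) == pytest.approx(direct, abs=1e-12)

    def test_translation_invariance(self, rng):
        p, q = rng.uniform(-10, 10, size=(2, 3))
        shift = rng.uniform(-100, 100, size=3)
        assert distance_to_dna(p + shift, q + shift) == pytest.approx(
            distance_to_dna(p, q), abs=1e-9
        )


class TestScatterProfile:
    def test_hand_worked_weighted_profile(self):
        """Distances (2, 2, 4) with multiplicities (1, 1, 2) expand to the
        weighted list (2, 2, 4, 4): mean 3, sample SD 2/sqrt(3)."""
        puncta = [
            Punctum((2, 0, 0), 10, 9, 1),
            Punctum((0, 2, 0), 10, 9, 1),
            Punctum((0, 0, 4), 30, 27, 2, is_mass=True),
        ]
        prof = scatter_profile(puncta, (0, 0, 0), "AI", "e1")
        np.testing.assert_allclose(sorted(prof.distances_um), [2, 2, 4, 4])
        assert prof.mean_um == pytest.approx(3.0)
        assert prof.sd_um == pytest.approx(2 / math.sqrt(3), abs=1e-4)

    def test_single_punctum_degenerate(self):
        prof = scatter_profile([Punctum((1, 0, 0), 5, 4, 1)], (0, 0, 0), "MII")
        assert prof.mean_um == 1.0 and prof.sd_um == 0.0 and prof.degenerate

    def test_metaphase_i_excluded(self):
        with pytest.raises(ExcludedPhaseError):
            scatter_profile([Punctum((1, 0, 0), 5, 4, 1)], (0, 0, 0), "MI")

    def test_empty_puncta_rejected(self):
        with pytest.raises(NoDataError):
            scatter_profile([], (0, 0, 0), "AI")

    @settings(derandomize=True, max_examples=50)
    @given(mults=st.lists(st.integers(1, 5), min_size=1, max_size=10))
    def test_count_conservation(self, mults):
        rng = np.random.default_rng(0)
        puncta = [Punctum(tuple(rng.uniform(-5, 5, 3)), 10, 9, m) for m in mults]
        prof = scatter_profile(puncta, (0, 0, 0), "AII")
        assert prof.distances_um.size == sum(mults)

    def test_summaries_recomputable_from_distances(self, rng):
        puncta = [Punctum(tuple(rng.uniform(-5, 5, 3)), 10, 9, int(m))
                  for m in rng.integers(1, 4, size=12)]
        prof = scatter_profile(puncta, (0, 0, 0), "AI")
        assert prof.mean_um == pytest.approx(prof.distances_um.mean())
        assert prof.sd_um == pytest.approx(prof.distances_um.std(ddof=1))


class TestDetection:
    def test_noise_free_puncta_recovered(self, small_scene):
        stack, truth = simulate_zstack(small_scene)
        pos = detect_puncta(stack.channel("mitochondria"), 0.2, 0.5,
                            DetectionParams(smooth_sigma_um=0.15, threshold_abs=10.0))
        assert len(pos) == len(truth.puncta) == 5
        gt = np.array([p.position_um for p in truth.puncta])
        for p in pos:
            errs = np.abs(gt - p)
            best = errs[np.linalg.norm(gt - p, axis=1).argmin()]
            assert best[0] <= 0.2 and best[1] <= 0.2  # within one pixel in-plane
            assert best[2] <= 0.5  # within one z-step

    def test_blank_image_has_no_signal(self):
        with pytest.raises(NoSignalError):
            detect_puncta(np.zeros((5, 20, 20)), 0.2, 0.5)

    def test_nearby_maxima_merge_to_brighter(self):
        vol = np.zeros((1, 40, 40))
        yy, xx = np.mgrid[0:40, 0:40]
        vol[0] += 100 * np.exp(-((xx - 18) ** 2 + (yy - 20) ** 2) / (2 * 1.5**2))
        vol[0] += 60 * np.exp(-((xx - 21) ** 2 + (yy - 20) ** 2) / (2 * 1.5**2))
        pos = detect_puncta(vol, 0.2, 0.5,
                            DetectionParams(smooth_sigma_um=0.1, threshold_abs=20.0,
                                            roi_diameter_um=1.2))
        assert len(pos) == 1
        assert abs(pos[0][0] - 18 * 0.2) < 2 * 0.2  # near the brighter focus


class TestQuantifyStack:
    def test_mass_tiling_and_multiplicity(self):
        """A bright extended region is classified as a mass and each of its
        tiles gets the intensity-ratio multiplicity."""
        from zygoquant.io import ImageStack

        vol = np.zeros((3, 80, 80))
        yy, xx = np.mgrid[0:80, 0:80]
        # broad puncta so the 6 px ROI samples near-peak intensity (~87)
        for cx, cy in [(15, 15), (15, 60), (60, 15)]:
            vol[1] += 100 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 4.0**2))
        # extended mass: 20x20 px plateau at ~3.5x the punctum ROI mean
        vol[1, 45:65, 45:65] += 300.0
        stack = ImageStack(vol, ("mitochondria",), 0.2, 0.5)
        q = quantify_stack(
            stack, dna_position_um=(8.0, 8.0, 0.5), phase="AI",
            params=DetectionParams(smooth_sigma_um=0.1, threshold_abs=50.0,
                                   roi_diameter_um=1.2),
        )
        masses = [p for p in q.puncta if p.is_mass]
        singles = [p for p in q.puncta if not p.is_mass]
        assert len(singles) == 3 and all(p.multiplicity == 1 for p in singles)
        assert masses and all(p.multiplicity >= 2 for p in masses)
        punctum_avg = np.mean([p.corrected_mean for p in singles])
        interior = [p for p in masses if p.corrected_mean > 0.99 * 300]
        assert interior
        for p in interior:
            assert p.multiplicity == round(300 / punctum_avg) == 3

    def test_detections_outside_embryo_mask_excluded(self, small_scene):
        stack, truth = simulate_zstack(small_scene)
        mask = np.zeros(stack.channel("mitochondria").shape, dtype=bool)
        with pytest.raises(NoDataError):
            quantify_stack(stack, truth.dna_position_um, "AI",
                           params=DetectionParams(smooth_sigma_um=0.15,
                                                  threshold_abs=10.0),
                           embryo_mask=mask)


class TestParameterRecovery:
    def test_mean_distance_tracks_cloud_sigma(self):
        """Mean punctum-DNA distance over 50 embryos recovers the closed form
        2*sigma*sqrt(2/pi) for an isotropic 3-D Gaussian cloud; the closed
        form is itself verified against a 10^6-sample Monte-Carlo oracle."""
        sigma = 1.0
        mc = np.random.default_rng(0).normal(0, sigma, size=(10**6, 3))
        mc_mean = float(np.linalg.norm(mc, axis=1).mean())
        closed = 2 * sigma * math.sqrt(2 / math.pi)
        assert mc_mean == pytest.approx(closed, rel=0.005)

        means = []
        for seed in range(50):
            cfg = SceneConfig(seed=seed, n_masses=0, n_puncta=30,
                              cloud_sigma_um=sigma)
            dna, pts = sample_puncta(cfg)
            prof = scatter_profile(
                [Punctum(tuple(p.position_um), p.true_intensity,
                         p.true_intensity, 1) for p in pts], dna, "AI")
            means.append(prof.mean_um)
        means = np.asarray(means)
        se = means.std(ddof=1) / math.sqrt(len(means))
        assert abs(means.mean() - closed) <= 3 * se
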