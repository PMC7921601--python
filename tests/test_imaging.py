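"""Image correction, focus detection, extraction and colocalization."""

import itertools

import numpy as np
import pytest
from scipy.spatial import cKDTree

from smstoich import (
    CameraModel,
    ComplexStoichiometry,
    Focus,
    FluorophorePhotophysics,
    ImageStack,
    colocalize,
    correct_stack,
    corrected_abundance,
    detect_foci,
    extract_trajectory,
    render_two_color_movie,
)


class TestCorrectStack:
    def test_identity(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 100, (3, 8, 8))
        out = correct_stack(ImageStack(frames), offset=0.0)
        assert out.frames == pytest.approx(frames)

    def test_uniform_offset_cancels(self):
        out = correct_stack(ImageStack(np.full((2, 6, 6), 77.0)), offset=77.0)
        assert np.all(out.frames == 0.0)

    def test_vignetting_round_trip(self):
        # synthetic vignetting applied then divided out
        rows, cols = np.mgrid[:16, :16]
        flat = 1.0 - 0.4 * ((rows - 8) ** 2 + (cols - 8) ** 2) / 128.0
        signal = np.full((4, 16, 16), 200.0)
        observed = 50.0 + flat * signal
        out = correct_stack(ImageStack(observed), offset=50.0, flatfield=flat)
        assert np.max(np.abs(out.frames - 200.0)) < 1e-6

    def test_inverts_camera_model_noise_free(self, small_movie):
        cam = CameraModel(offset=100.0, read_noise_sd=0.0, shape=(48, 48))
        pp = small_movie["photophysics"]
        sa, _, gt = render_two_color_movie(
            [ComplexStoichiometry(2, 1)], pp, pp, cam, 10, seed=3,
            positions=np.array([[24.0, 24.0]]),
        )
        out = correct_stack(sa, cam.offset, cam.flatfield, clip=False)
        expected = np.zeros_like(out.frames)
        from smstoich.simulate import _psf_weights

        rs, cs, w = _psf_weights((24.0, 24.0), cam.psf_sigma, (48, 48), 6)
        expected[:, rs, cs] = gt.trajectories["A"][0].intensities[
            :, None, None
        ] * w
        assert out.frames == pytest.approx(expected, abs=1e-9)

    def test_dimension_mismatch_error(self):
        with pytest.raises(ValueError, match="shape"):
            correct_stack(ImageStack(np.zeros((2, 8, 8))), 0.0,
                          flatfield=np.ones((4, 4)))


class TestDetectFoci:
    def test_blank_stack_gives_no_foci(self):
        stack = ImageStack(np.full((12, 32, 32), 5.0))
        assert detect_foci(stack) == []

    def test_single_psf_found_within_one_pixel(self):
        cam = CameraModel(offset=0.0, read_noise_sd=5.0, psf_sigma=1.2,
                          shape=(32, 32))
        pp = FluorophorePhotophysics(2000.0, 0.0, 1e-6)  # peak SNR ~ 20
        sa, _, _ = render_two_color_movie(
            [ComplexStoichiometry(1, 0)], pp, pp, cam, 12, seed=1,
            positions=np.array([[15.4, 17.2]]),
        )
        foci = detect_foci(sa)
        assert len(foci) == 1
        assert np.hypot(foci[0].row - 15.4, foci[0].col - 17.2) < 1.0

    def test_recall_and_precision_on_fifty_foci(self):
        cam = CameraModel(offset=100.0, read_noise_sd=10.0, psf_sigma=1.2,
                          shape=(200, 200))
        pp = FluorophorePhotophysics(1000.0, 100.0, 1 / 500)  # peak SNR ~ 10
        complexes = [ComplexStoichiometry(1, 0) for _ in range(50)]
        sa, _, gt = render_two_color_movie(complexes, pp, pp, cam, 12, seed=9)
        foci = detect_foci(correct_stack(sa, 100.0))
        tree = cKDTree(gt.positions)
        d, idx = tree.query([f.position for f in foci])
        hits = set(idx[d < 2.0])
        recall = len(hits) / 50
        precision = np.mean(d < 2.0) if foci else 0.0
        assert recall >= 0.95
        assert precision >= 0.95

    def test_empty_stack_error(self):
        stack = ImageStack(np.zeros((3, 16, 16)))
        with pytest.raises(ValueError):
            detect_foci(stack, detect_window=10)


class TestExtractTrajectory:
    def test_uniform_stack_gives_zero_trace(self):
        stack = ImageStack(np.full((8, 24, 24), 33.0))
        traj = extract_trajectory(stack, Focus(12.0, 12.0))
        assert traj.intensities == pytest.approx(np.zeros(8), abs=1e-9)

    def test_single_fluorophore_plateau_recovery(self):
        cam = CameraModel(offset=0.0, read_noise_sd=0.0, psf_sigma=1.2,
                          shape=(32, 32))
        pp = FluorophorePhotophysics(300.0, 0.0, 1e-6)
        sa, _, _ = render_two_color_movie(
            [ComplexStoichiometry(1, 0)], pp, pp, cam, 10, seed=1,
            positions=np.array([[16.0, 16.0]]),
        )
        traj = extract_trajectory(sa, Focus(16.0, 16.0))
        assert traj.intensities.mean() == pytest.approx(300.0, rel=0.10)

    def test_framewise_background_ramp_cancels(self):
        cam = CameraModel(offset=0.0, read_noise_sd=0.0, psf_sigma=1.2,
                          shape=(32, 32))
        pp = FluorophorePhotophysics(300.0, 0.0, 1e-6)
        sa, _, _ = render_two_color_movie(
            [ComplexStoichiometry(1, 0)], pp, pp, cam, 10, seed=1,
            positions=np.array([[16.0, 16.0]]),
        )
        clean = extract_trajectory(sa, Focus(16.0, 16.0))
        ramp = np.linspace(0, 50, 10)[:, None, None] * np.ones((1, 32, 32))
        ramped = ImageStack(sa.frames + ramp)
        traj = extract_trajectory(ramped, Focus(16.0, 16.0))
        assert traj.intensities == pytest.approx(clean.intensities, abs=1e-6)

    def test_aperture_outside_image_error(self):
        stack = ImageStack(np.zeros((3, 24, 24)))
        with pytest.raises(ValueError, match="outside"):
            extract_trajectory(stack, Focus(2.0, 12.0))


def brute_force_matching(pos_a, pos_b, radius):
    """Oracle: enumerate all pairings, pick the minimum-total-distance
    matching of maximum cardinality within the radius."""
    d = np.linalg.norm(pos_a[:, None] - pos_b[None], axis=2)
    best = None
    idx_b = list(range(len(pos_b)))
    for k in range(min(len(pos_a), len(pos_b)), -1, -1):
        for subset_a in itertools.combinations(range(len(pos_a)), k):
            for perm in itertools.permutations(idx_b, k):
                if all(d[i, j] <= radius for i, j in zip(subset_a, perm)):
                    total = sum(d[i, j] for i, j in zip(subset_a, perm))
                    if best is None or total < best[0]:
                        best = (total, set(zip(subset_a, perm)))
        if best is not None:
            return best[1]
    return set()


class TestColocalize:
    def foci(self, positions, ch):
        return [Focus(r, c, channel=ch, focus_id=f"{ch}{i}")
                for i, (r, c) in enumerate(positions)]

    def test_identical_lists_fully_paired(self):
        pos = np.array([[5.0, 5.0], [10.0, 20.0], [30.0, 7.0]])
        pairs, frac = colocalize(self.foci(pos, "A"), self.foci(pos, "B"), 2.0)
        assert len(pairs) == 3 and frac == 1.0
        assert all(p.distance == 0.0 for p in pairs)

    def test_distant_lists_unpaired(self):
        a = self.foci(np.array([[5.0, 5.0]]), "A")
        b = self.foci(np.array([[50.0, 50.0]]), "B")
        pairs, frac = colocalize(a, b, 2.0)
        assert pairs == [] and frac == 0.0

    def test_crafted_triple_matches_brute_force(self):
        # one B nearly equidistant between two A foci plus a second B
        pos_a = np.array([[10.0, 10.0], [10.0, 13.0]])
        pos_b = np.array([[10.0, 11.6], [10.0, 14.0]])
        pairs, _ = colocalize(self.foci(pos_a, "A"), self.foci(pos_b, "B"), 2.0)
        got = {
            (int(p.focus_a.focus_id[1:]), int(p.focus_b.focus_id[1:]))
            for p in pairs
        }
        assert got == brute_force_matching(pos_a, pos_b, 2.0)

    def test_random_instances_valid_and_maximal(self):
        # greedy matching yields valid pairs (within radius, each focus
        # used once) and is maximal: no unused A/B pair remains in range
        rng = np.random.default_rng(4)
        for _ in range(20):
            pos_a = rng.uniform(0, 12, (5, 2))
            pos_b = rng.uniform(0, 12, (5, 2))
            pairs, _ = colocalize(
                self.foci(pos_a, "A"), self.foci(pos_b, "B"), 3.0
            )
            used_a = [int(p.focus_a.focus_id[1:]) for p in pairs]
            used_b = [int(p.focus_b.focus_id[1:]) for p in pairs]
            assert len(set(used_a)) == len(used_a)
            assert len(set(used_b)) == len(used_b)
            assert all(p.distance <= 3.0 for p in pairs)
            d = np.linalg.norm(pos_a[:, None] - pos_b[None], axis=2)
            for i in range(5):
                for j in range(5):
                    if i not in used_a and j not in used_b:
                        assert d[i, j] > 3.0

    def test_chance_colocalization_bounded_by_permutation_oracle(self):
        # with no true complexes the measured fraction should look like a
        # random placement: compare to the permutation null of shuffled B
        rng = np.random.default_rng(8)
        pos_a = rng.uniform(0, 100, (60, 2))
        pos_b = rng.uniform(0, 100, (60, 2))
        _, frac = colocalize(self.foci(pos_a, "A"), self.foci(pos_b, "B"), 2.0)
        null = []
        for _ in range(200):
            shuffled = rng.uniform(0, 100, (60, 2))
            _, f = colocalize(
                self.foci(pos_a, "A"), self.foci(shuffled, "B"), 2.0
            )
            null.append(f)
        assert frac <= np.quantile(null, 0.99) + 1e-12


class TestCorrectedAbundance:
    def test_equal_counts_equal_efficiency(self):
        assert corrected_abundance([10, 10], [0.5, 0.5]) == pytest.approx(
            [0.5, 0.5]
        )

    def test_paper_labeling_efficiencies(self):
        # 86 and 73 counts at 86%/73% labeling -> equal true abundance
        assert corrected_abundance([86, 73], [0.86, 0.73]) == pytest.approx(
            [0.5, 0.5]
        )

    def test_unequal_efficiency(self):
        assert corrected_abundance([100, 100], [0.5, 1.0]) == pytest.approx(
            [2 / 3, 1 / 3]
        )

    def test_zero_efficiency_error(self):
        with pytest.raises(ValueError):
            corrected_abundance([1, 1], [0.0, 1.0])
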