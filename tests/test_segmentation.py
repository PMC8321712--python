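"""GrabCut tests: exhaustive energy oracle, monotone traces, phantom accuracy.

The energy oracle evaluates the Gibbs energy with explicit loops over pixels
and neighbor pairs, sharing no code with the vectorized implementation.
"""

import itertools

import numpy as np
import pytest

from petloop import segmentation as seg
from petloop.phantom import SceneSpec, make_color_scene


def brute_force_energy(image, labels, gmm, gamma, beta, connectivity):
    h, w = labels.shape
    data = 0.0
    for r in range(h):
        for c in range(w):
            cls = gmm.foreground if labels[r, c] else gmm.background
            z = image[r, c].astype(float)
            best = np.inf
            for k in range(len(cls.weights)):
                if cls.weights[k] <= 0:
                    continue
                diff = z - cls.means[k]
                cov = cls.covariances[k]
                maha = diff @ np.linalg.inv(cov) @ diff
                nll = (
                    -np.log(cls.weights[k])
                    + 0.5 * np.log(np.linalg.det(cov))
                    + 0.5 * maha
                    + 1.5 * np.log(2 * np.pi)
                )
                best = min(best, nll)
            data += best
    offsets = [(0, 1), (1, 0)] + ([(1, 1), (1, -1)] if connectivity == 8 else [])
    smooth = 0.0
    for r in range(h):
        for c in range(w):
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < h and 0 <= c2 < w):
                    continue
                if labels[r, c] != labels[r2, c2]:
                    d2 = float(((image[r, c] - image[r2, c2]) ** 2).sum())
                    smooth += gamma * np.exp(-beta * d2)
    return data + smooth


def two_blob_image(rng, shape=(24, 24)):
    """Random two-color scene with mild per-pixel noise."""
    spec = SceneSpec(
        shape=shape,
        center=(shape[0] / 2 + rng.uniform(-3, 3), shape[1] / 2 + rng.uniform(-3, 3)),
        radius=rng.uniform(4, 7),
        fg_color=tuple(rng.uniform(0.6, 0.9, 3)),
        bg_color=tuple(rng.uniform(0.05, 0.35, 3)),
        noise_sd=0.03,
        seed=int(rng.integers(2**31)),
    )
    return make_color_scene(spec)


class TestInitTrimap:
    def test_full_image_rect_is_all_foreground(self):
        trimap = seg.init_trimap(np.zeros((5, 7, 3)), (0, 0, 5, 7))
        assert trimap.labels.all()
        assert not trimap.hard.any()

    def test_outside_rect_is_hard_background(self):
        trimap = seg.init_trimap(np.zeros((6, 6, 3)), (2, 2, 5, 5))
        assert trimap.labels[0, 0] == 0 and trimap.hard[0, 0]
        assert trimap.labels[3, 3] == 1 and not trimap.hard[3, 3]

    @pytest.mark.parametrize("rect", [(2, 2, 2, 5), (0, 0, 0, 0), (4, 0, 2, 5)])
    def test_degenerate_rect_rejected(self, rect):
        with pytest.raises(ValueError):
            seg.init_trimap(np.zeros((6, 6, 3)), rect)


class TestFitGmms:
    def test_five_components_per_class(self, rng):
        img = rng.random((20, 20, 3))
        labels = np.zeros((20, 20), dtype=int)
        labels[5:15, 5:15] = 1
        gmm = seg.fit_gmms(img, labels)
        assert len(gmm.foreground.weights) == 5
        assert len(gmm.background.weights) == 5

    def test_weights_sum_to_one(self, rng):
        img = rng.random((16, 16, 3))
        labels = (rng.random((16, 16)) > 0.5).astype(int)
        labels[0, 0], labels[0, 1] = 0, 1  # both classes nonempty
        gmm = seg.fit_gmms(img, labels)
        assert gmm.foreground.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert gmm.background.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_recovers_separated_component_means(self, rng):
        """Pixels from 5 well-separated Gaussians: means found to 2 sd/sqrt(n)."""
        true_means = np.array(
            [[0.1, 0.1, 0.1], [0.9, 0.1, 0.1], [0.1, 0.9, 0.1],
             [0.1, 0.1, 0.9], [0.9, 0.9, 0.9]]
        )
        sd, per = 0.015, 400
        pixels = np.concatenate(
            [rng.normal(m, sd, (per, 3)) for m in true_means]
        )
        rng.shuffle(pixels)
        img = pixels.reshape(50, 40, 3)
        labels = np.ones((50, 40), dtype=int)
        labels[:, :2] = 0  # a slim background strip so both classes exist
        gmm = seg.fit_gmms(img, labels, seed=0)
        from scipy.spatial.distance import cdist

        pairing = cdist(true_means, gmm.foreground.means).argmin(axis=1)
        assert len(set(pairing)) == 5  # one component per true cluster
        got = gmm.foreground.means[pairing]
        # 4 SE: the max runs over 15 coordinates, so 2 SE per coordinate
        # would be exceeded by chance alone
        assert np.abs(got - true_means).max() < 4 * sd / np.sqrt(per * 0.9)

    def test_small_class_reduces_components(self, rng):
        img = rng.random((4, 4, 3))
        labels = np.zeros((4, 4), dtype=int)
        labels[0, :3] = 1  # 3 foreground pixels < 5 components
        with pytest.warns(UserWarning, match="reducing"):
            gmm = seg.fit_gmms(img, labels)
        assert len(gmm.foreground.weights) == 3

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="nonempty"):
            seg.fit_gmms(rng.random((4, 4, 3)), np.ones((4, 4), dtype=int))


class TestGibbsEnergy:
    def test_uniform_labeling_has_zero_smoothness(self, rng):
        img = rng.random((6, 6, 3))
        labels = np.ones((6, 6), dtype=int)
        labels[0, 0] = 0
        with pytest.warns(UserWarning, match="reducing"):  # 1 bg pixel < 5
            gmm = seg.fit_gmms(img, labels)
        for uniform in (np.zeros((6, 6), int), np.ones((6, 6), int)):
            e = seg.gibbs_energy(img, uniform, gmm)
            assert e.smoothness == 0.0
            assert e.total == e.data

    def test_identical_color_neighbors_cost_gamma(self, rng):
        """Two adjacent equal-color pixels with different labels pay exactly gamma."""
        img = np.full((1, 2, 3), 0.5)
        with pytest.warns(UserWarning, match="reducing"):  # 4 fg pixels < 5
            gmm = seg.fit_gmms(rng.random((4, 4, 3)), np.eye(4, dtype=int))
        cfg = seg.GrabCutConfig(gamma=17.0, beta=1.0)
        e = seg.gibbs_energy(img, np.array([[0, 1]]), gmm, cfg)
        assert e.smoothness == pytest.approx(17.0)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_exhaustive_enumeration(self, rng, connectivity):
        """All 2^9 labelings of a 3x3 image match the loop oracle, E = U + V."""
        img = rng.random((3, 3, 3))
        init = np.zeros((3, 3), dtype=int)
        init[1:, 1:] = 1
        gmm = seg.fit_gmms(img, init, n_components=2)
        beta = seg.auto_beta(img, connectivity)
        cfg = seg.GrabCutConfig(gamma=30.0, connectivity=connectivity)
        for bits in itertools.product([0, 1], repeat=9):
            labels = np.array(bits).reshape(3, 3)
            e = seg.gibbs_energy(img, labels, gmm, cfg)
            want = brute_force_energy(img, labels, gmm, 30.0, beta, connectivity)
            assert e.total == pytest.approx(want, rel=1e-9)
            assert e.total == pytest.approx(e.data + e.smoothness, rel=1e-12)


class TestGrabCut:
    def test_energy_trace_non_increasing_on_random_scenes(self):
        for i in range(5):
            rng = np.random.default_rng(100 + i)
            img, _ = two_blob_image(rng)
            _, trace = seg.grabcut(img, (3, 3, 21, 21), seed=i)
            totals = [e.total for e in trace]
            assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))

    def test_zero_noise_phantom_segmented_exactly(self, disc_scene):
        _, img, truth = disc_scene
        mask, _ = seg.grabcut(img, (8, 8, 40, 40))
        assert seg.segmentation_accuracy(mask, truth) >= 0.99

    def test_hard_background_never_foreground(self, disc_scene):
        _, img, _ = disc_scene
        rect = (10, 10, 40, 40)
        mask, _ = seg.grabcut(img, rect)
        outside = np.ones_like(mask)
        outside[rect[0]:rect[2], rect[1]:rect[3]] = False
        assert not mask[outside].any()


class TestSmoothBoundary:
    @staticmethod
    def disc_mask(shape=(40, 40), center=(20, 20), radius=11.0):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2

    def test_smooth_disc_nearly_unchanged(self):
        mask = self.disc_mask()
        out = seg.smooth_boundary(mask)
        boundary_diff = out ^ mask
        from scipy.ndimage import distance_transform_edt

        d_inside = distance_transform_edt(mask)
        d_outside = distance_transform_edt(~mask)
        assert (np.maximum(d_inside, d_outside)[boundary_diff] <= 1.5).all()

    def test_boundary_salt_removed(self, rng):
        """Single-pixel protrusions on the contour are cleaned off."""
        clean = self.disc_mask()
        noisy = clean.copy()
        yy, xx = np.mgrid[0:40, 0:40]
        ring = (np.hypot(yy - 20, xx - 20) > 11) & (np.hypot(yy - 20, xx - 20) < 13)
        salt = ring & (rng.random((40, 40)) < 0.08)
        noisy |= salt
        out = seg.smooth_boundary(noisy)
        assert (out ^ clean).sum() < salt.sum()

    def test_area_change_bounded(self, rng):
        mask = self.disc_mask() | (rng.random((40, 40)) < 0.02)
        area = mask.sum()
        out = seg.smooth_boundary(mask, max_area_change=0.05)
        assert abs(int(out.sum()) - int(area)) <= 0.05 * area

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            seg.smooth_boundary(np.zeros((8, 8), dtype=bool))
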