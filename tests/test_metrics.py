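import numpy as np
import pytest

from dbareit.metrics import (
    MetricsReport,
    TargetTruth,
    convergence_table,
    degree_of_truth,
    position_error,
    quarter_amplitude,
    rel_extremum_errors,
    resolution,
    ringing,
    shape_deformation,
)


def unit_grid(n):
    ax = np.linspace(-1, 1, n)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    return X + 1j * Y


def disk_indicator(n, center=0j, radius=0.3, value=1.0):
    pts = unit_grid(n)
    img = np.zeros((n, n))
    img[np.abs(pts - center) <= radius] = value
    return img, pts


class TestQuarterAmplitude:
    def test_disk_indicator_recovered(self):
        img, pts = disk_indicator(64, center=0.2 + 0.1j)
        q = quarter_amplitude(img, pts)
        np.testing.assert_array_equal(q.mask, img > 0)
        assert abs(q.cog - (0.2 + 0.1j)) < 0.03

    def test_single_peak_excludes_low_background(self):
        img = np.full((32, 32), 0.2)
        img[10, 20] = 1.0
        q = quarter_amplitude(img)
        assert q.A_q == 1  # 0.2 < 0.25

    def test_gaussian_blob_matches_bruteforce_threshold(self):
        pts = unit_grid(80)
        img = np.exp(-np.abs(pts - 0.1) ** 2 / 0.05)
        q = quarter_amplitude(img, pts)
        brute = int(np.sum(img >= img.max() / 4))
        assert q.A_q == brute

    def test_nonpositive_image_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            quarter_amplitude(-np.ones((8, 8)))


class TestPositionError:
    def test_arithmetic(self):
        q = quarter_amplitude(*_shifted_blob(0.25))
        truth = TargetTruth(center=0.3 + 0j, radius=0.05, sigma_t=2, sigma_r=1)
        assert position_error(q, truth) == pytest.approx(0.3 - q.r_q)

    def test_perfect_reconstruction_zero(self):
        img, pts = disk_indicator(100, center=0.4 + 0j, radius=0.05)
        q = quarter_amplitude(img, pts)
        truth = TargetTruth(center=0.4 + 0j, radius=0.05, sigma_t=2, sigma_r=1)
        assert abs(position_error(q, truth)) < 0.02

    def test_rotation_invariance(self):
        truth0 = TargetTruth(center=0.5 + 0j, radius=0.08, sigma_t=2, sigma_r=1)
        img0, pts = disk_indicator(120, center=0.5 + 0j, radius=0.08)
        pe0 = position_error(quarter_amplitude(img0, pts), truth0)
        rot = 0.5 * np.exp(1j * np.pi / 2)
        truth1 = TargetTruth(center=rot, radius=0.08, sigma_t=2, sigma_r=1)
        img1, _ = disk_indicator(120, center=rot, radius=0.08)
        pe1 = position_error(quarter_amplitude(img1, pts), truth1)
        assert pe1 == pytest.approx(pe0, abs=0.02)


class TestRinging:
    def test_no_negative_pixels_gives_zero(self):
        img, pts = disk_indicator(64, radius=0.3)
        q = quarter_amplitude(img, pts)
        assert ringing(img, q, pts) == 0.0

    def test_constructed_ring_ratio(self):
        # main lobe +1 over a disk, ring -0.5 over an equal-area annulus
        pts = unit_grid(400)
        r1 = 0.3
        r2 = r1 * np.sqrt(2)  # annulus (r1, r2) has the same area as the disk
        img = np.zeros(pts.shape)
        img[np.abs(pts) <= r1] = 1.0
        ring_px = (np.abs(pts) > r1) & (np.abs(pts) <= r2)
        img[ring_px] = -0.5
        q = quarter_amplitude(img, pts)
        rng_val = ringing(img, q, pts)
        assert rng_val == pytest.approx(0.5, rel=0.05)

    def test_monotone_in_ring_amplitude(self):
        pts = unit_grid(200)
        base = np.zeros(pts.shape)
        base[np.abs(pts) <= 0.25] = 1.0
        ring_px = (np.abs(pts) > 0.3) & (np.abs(pts) <= 0.45)
        vals = []
        for amp in (0.1, 0.3, 0.6):
            img = base.copy()
            img[ring_px] = -amp
            q = quarter_amplitude(img, pts)
            vals.append(ringing(img, q, pts))
        assert vals[0] < vals[1] < vals[2]


class TestResolution:
    def test_full_domain(self):
        img, pts = disk_indicator(64, radius=2.0)  # covers everything
        mask = np.abs(pts) <= 1.0
        img[~mask] = np.nan
        q = quarter_amplitude(img, pts)
        assert resolution(q, mask) == pytest.approx(1.0, rel=0.05)

    def test_pixel_ratio(self):
        q = QuarterDummy(A_q=10)
        mask = np.zeros(1000, dtype=bool)
        mask[:1000] = True
        assert resolution(q, mask) == pytest.approx(0.01)

    def test_monotone_in_blob_width(self):
        pts = unit_grid(120)
        mask = np.abs(pts) <= 1.0
        vals = []
        for w in (0.02, 0.05, 0.1):
            img = np.exp(-np.abs(pts) ** 2 / (2 * w))
            vals.append(resolution(quarter_amplitude(img, pts), mask))
        assert vals[0] < vals[1] < vals[2]

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            resolution(QuarterDummy(A_q=1), np.zeros(10, dtype=bool))


class TestShapeDeformation:
    def test_perfect_disk_zero(self):
        img, pts = disk_indicator(200, center=0.1 + 0.2j, radius=0.3)
        q = quarter_amplitude(img, pts)
        assert shape_deformation(q, pts) < 0.03

    def test_two_disjoint_disks_match_bruteforce(self):
        pts = unit_grid(300)
        img = np.zeros(pts.shape)
        img[np.abs(pts - 0.4) <= 0.15] = 1.0
        img[np.abs(pts + 0.4) <= 0.15] = 1.0
        q = quarter_amplitude(img, pts)
        sd = shape_deformation(q, pts)
        px = np.abs(pts[1, 0] - pts[0, 0])
        rad = np.sqrt(q.A_q * px**2 / np.pi)
        brute = np.sum(q.mask & (np.abs(pts - q.cog) > rad)) / q.A_q
        assert sd == pytest.approx(brute)
        assert sd > 0.3  # half of each disk sits outside the centered circle

    def test_bounded_by_one(self, rng):
        pts = unit_grid(50)
        img = rng.normal(size=pts.shape) + 0.5
        q = quarter_amplitude(img, pts)
        assert 0.0 <= shape_deformation(q, pts) <= 1.0


class TestConvergenceTable:
    def test_ratio_arithmetic(self):
        truth = np.zeros((32, 32))
        imgs = [truth + e for e in (0.4, 0.2, 0.1)]
        E, CR = convergence_table(imgs, truth)
        np.testing.assert_allclose(E, [0.4, 0.2, 0.1])
        np.testing.assert_allclose(CR, [2.0, 2.0])

    def test_exact_image_zero_error(self):
        truth = np.random.default_rng(0).normal(size=(16, 16))
        E, _ = convergence_table([truth, truth + 0.1], truth)
        assert E[0] == 0.0

    def test_matches_bruteforce_scan(self, rng):
        truth = rng.normal(size=(24, 24))
        img = truth + rng.normal(size=(24, 24)) * 0.1
        E, _ = convergence_table([img, img], truth, rim_exclude=0)
        ax = np.linspace(-1, 1, 24)
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        mask = np.hypot(X, Y) <= 1.0
        brute = np.abs(truth - img)[mask].max()
        assert E[0] == pytest.approx(brute)

    def test_single_image_rejected(self):
        with pytest.raises(ValueError):
            convergence_table([np.zeros((8, 8))], np.zeros((8, 8)))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            convergence_table(
                [np.zeros((8, 8)), np.zeros((9, 9))], np.zeros((8, 8))
            )


class TestDegreeOfTruth:
    def test_perfect_reconstruction(self):
        truth = np.array([[240.0, 750.0]])
        assert degree_of_truth(truth, truth) == 1.0
        assert rel_extremum_errors(truth, truth) == (0.0, 0.0)

    def test_half_range(self):
        truth = np.array([[0.0, 1.0]])
        rec = np.array([[0.25, 0.75]])
        assert degree_of_truth(rec, truth) == pytest.approx(0.5)

    def test_chest_arithmetic(self):
        # truth range (240, 750); reconstruction (247.2, 787.5)
        truth = np.array([[240.0, 750.0]])
        rec = np.array([[247.2, 787.5]])
        err_max, err_min = rel_extremum_errors(rec, truth)
        assert err_max == pytest.approx(5.0)
        assert err_min == pytest.approx(3.0)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            degree_of_truth(np.ones((4, 4)), np.ones((4, 4)))


class TestMetricsReport:
    def test_invariant_validation(self):
        with pytest.raises(ValueError, match="RES"):
            MetricsReport(AR=1, PE=0, RNG=0, RES=1.5, SD=0)
        with pytest.raises(ValueError, match="RNG"):
            MetricsReport(AR=1, PE=0, RNG=-0.1, RES=0.5, SD=0)

    def test_as_dict_roundtrip(self):
        rep = MetricsReport(AR=1.0, PE=0.1, RNG=0.2, RES=0.3, SD=0.4,
                            extra={"r_q": 0.5})
        d = rep.as_dict()
        assert d["AR"] == 1.0 and d["r_q"] == 0.5


class QuarterDummy:
    """Minimal stand-in carrying only A_q (for ratio-only operations)."""

    def __init__(self, A_q):
        self.A_q = A_q
        self.cog = 0j
        self.r_q = 0.0


def _shifted_blob(r):
    pts = unit_grid(100)
    img = np.exp(-np.abs(pts - r) ** 2 / 0.01)
    return img, pts
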