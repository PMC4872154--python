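"""POC registration, spot detection, Gaussian fitting, coincidence."""

import numpy as np
import pytest

import smtseq as s
from smtseq.imagesim import add_gaussian_spots
from smtseq.imageproc import DetectionParams


def _noisy(img, seed, background=20.0, read_noise=3.0):
    rng = np.random.default_rng(seed)
    return rng.poisson(img + background).astype(float) + rng.normal(0, read_noise, img.shape)


class TestPOC:
    def test_image_against_itself(self):
        img = np.random.default_rng(0).random((64, 64))
        shift = s.estimate_shift_poc(img, img)
        assert (shift.dx, shift.dy) == (0.0, 0.0)

    def test_circular_integer_shift_exact(self):
        img = np.random.default_rng(1).random((64, 64))
        shifted = np.roll(img, (-2, 3), axis=(0, 1))  # dy=-2, dx=3
        shift = s.estimate_shift_poc(img, shifted)
        assert (shift.dx, shift.dy) == (3.0, -2.0)

    def test_matches_skimage_oracle(self):
        from skimage.registration import phase_cross_correlation

        img = np.random.default_rng(2).random((64, 64))
        shifted = np.roll(img, (4, -5), axis=(0, 1))
        ours = s.estimate_shift_poc(img, shifted)
        # skimage reports the shift that maps the moving image back onto
        # the reference, i.e. the negated displacement
        theirs, _, _ = phase_cross_correlation(img, shifted)
        assert (ours.dy, ours.dx) == (-theirs[0], -theirs[1])

    def test_robust_to_noise_at_snr_10(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.random((64, 64))
            b = np.roll(a, (-2, 3), axis=(0, 1)) + rng.normal(0, 0.1, (64, 64))
            shift = s.estimate_shift_poc(a, b)
            hits += (shift.dx, shift.dy) == (3.0, -2.0)
        assert hits >= 99

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            s.estimate_shift_poc(np.ones((8, 8)), np.random.default_rng(0).random((8, 8)))


class TestRegisterStack:
    def test_injected_drifts_recovered_and_inverted(self, refs, noise_free_optics):
        mol = _grid_molecules(9)
        protocol = s.FlowProtocol(n_cycles=3)
        ev = s.simulate_events(mol, refs, protocol, s.ErrorModel(0, 0, 0), seed=0)
        drifts = [(0.0, 0.0), (3.0, -2.0), (5.0, 1.0)]
        stack = s.render_cycle_stack(mol, ev, noise_free_optics, seed=1, shape=(96, 96),
                                     drifts=drifts)
        registered, shifts = s.register_stack(stack)
        assert [(sh.dx, sh.dy) for sh in shifts] == drifts
        for c in range(1, 3):
            back = s.estimate_shift_poc(registered.template[0], registered.template[c])
            assert (back.dx, back.dy) == (0.0, 0.0)

    def test_zero_drift_all_zero_shifts(self, refs, noise_free_optics):
        mol = _grid_molecules(4)
        ev = s.simulate_events(mol, refs, s.FlowProtocol(n_cycles=3), s.ErrorModel(0, 0, 0), seed=0)
        stack = s.render_cycle_stack(mol, ev, noise_free_optics, seed=1, shape=(64, 64),
                                     drifts=[(0, 0)] * 3)
        _, shifts = s.register_stack(stack)
        assert all((sh.dx, sh.dy) == (0.0, 0.0) for sh in shifts)

    def test_single_cycle_identity(self, refs, noise_free_optics):
        mol = _grid_molecules(4)
        ev = s.simulate_events(mol, refs, s.FlowProtocol(n_cycles=1), s.ErrorModel(0, 0, 0), seed=0)
        stack = s.render_cycle_stack(mol, ev, noise_free_optics, seed=1, shape=(64, 64))
        registered, shifts = s.register_stack(stack)
        assert (shifts[0].dx, shifts[0].dy) == (0.0, 0.0)
        assert np.array_equal(registered.template, stack.template)


class TestDetectSpots:
    def test_pure_noise_rarely_yields_spots(self):
        with_spots = 0
        for seed in range(100):
            img = _noisy(np.zeros((64, 64)), seed)
            with_spots += len(s.detect_spots(img)) > 0
        assert with_spots <= 5

    def test_bright_spot_detected_with_subpixel_accuracy(self):
        errors = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x0, y0 = 30 + rng.uniform(-5, 5), 30 + rng.uniform(-5, 5)
            img = np.zeros((64, 64))
            add_gaussian_spots(img, np.array([x0]), np.array([y0]), np.array([400.0]), 1.0)
            spots = s.detect_spots(_noisy(img, seed))
            assert len(spots) == 1
            errors.append(np.hypot(spots[0].x - x0, spots[0].y - y0))
        rmse = float(np.sqrt(np.mean(np.square(errors))))
        assert rmse < 0.2

    def test_two_spots_ten_pixels_apart(self):
        img = np.zeros((64, 64))
        add_gaussian_spots(img, np.array([25.0, 35.0]), np.array([30.0, 30.0]),
                           np.array([400.0, 400.0]), 1.0)
        spots = s.detect_spots(_noisy(img, 5))
        assert len(spots) == 2

    def test_offset_invariance(self):
        img = np.zeros((64, 64))
        add_gaussian_spots(img, np.array([30.0]), np.array([30.0]), np.array([400.0]), 1.0)
        noisy = _noisy(img, 6)
        a = s.detect_spots(noisy)
        b = s.detect_spots(noisy + 500.0)
        assert len(a) == len(b) == 1
        assert a[0].x == pytest.approx(b[0].x, abs=1e-6)
        assert a[0].sigma == pytest.approx(b[0].sigma, abs=1e-6)

    def test_recall_and_precision_on_separated_spots(self):
        hits, total, detected = 0, 0, 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            xs = (np.arange(9) % 3) * 18.0 + 12 + rng.uniform(-2, 2, 9)
            ys = (np.arange(9) // 3) * 18.0 + 12 + rng.uniform(-2, 2, 9)
            img = np.zeros((64, 64))
            add_gaussian_spots(img, xs, ys, np.full(9, 200.0), 1.0)  # ~10x noise scale
            spots = s.detect_spots(_noisy(img, 100 + seed))
            total += 9
            detected += len(spots)
            for x, y in zip(xs, ys):
                if any(np.hypot(sp.x - x, sp.y - y) < 1.0 for sp in spots):
                    hits += 1
        assert hits / total >= 0.99       # recall
        assert hits / detected >= 0.99    # precision

    def test_cluster_filter_rejects_spread_aggregate(self):
        img = np.zeros((64, 64))
        # three emitters spread ~3 px: one blob with inflated width
        add_gaussian_spots(img, np.array([28.5, 31.8, 30.0]), np.array([30.0, 30.2, 33.0]),
                           np.full(3, 300.0), 1.0)
        spots, rejected = s.detect_spots(_noisy(img, 7), return_rejected=True)
        assert len(spots) == 0
        assert any(r.flag in ("cluster_sigma", "cluster_area") for r in rejected)


class TestFitSpot:
    def test_noiseless_subpixel_centroid(self):
        img = np.zeros((48, 48))
        add_gaussian_spots(img, np.array([10.3]), np.array([20.7]), np.array([500.0]), 1.2)
        spot = s.fit_spot(img, (slice(15, 27), slice(5, 17)))
        assert spot.ok
        assert spot.x == pytest.approx(10.3, abs=0.05)
        assert spot.y == pytest.approx(20.7, abs=0.05)
        assert spot.sigma == pytest.approx(1.2, abs=0.05)

    def test_flat_region_flagged(self):
        spot = s.fit_spot(np.full((32, 32), 7.0), (slice(10, 20), slice(10, 20)))
        assert not spot.ok

    def test_unresolved_pair_inflates_sigma(self):
        img = np.zeros((48, 48))
        add_gaussian_spots(img, np.array([23.0, 25.0]), np.array([24.0, 24.0]),
                           np.array([400.0, 400.0]), 1.0)
        spot = s.fit_spot(img, (slice(18, 31), slice(17, 31)))
        assert spot.ok
        assert spot.sigma > 1.2  # measurably wider than a single emitter


class TestCoincidence:
    def _spot(self, x, y):
        return s.Spot(x=x, y=y, amplitude=100.0, sigma=1.0, background=0.0,
                      residual=0.0, area=9)

    def test_match_within_radius(self):
        anchors = [self._spot(10, 10)]
        inc = [self._spot(10.3, 10.4)]  # 0.5 px away
        matches = s.coincidence_spots(anchors, inc, radius=1.6)
        assert len(matches) == 1 and matches[0].anchor_id == 0

    def test_discard_beyond_radius(self):
        anchors = [self._spot(10, 10)]
        inc = [self._spot(12.0, 10.0)]  # 2.0 px away
        assert s.coincidence_spots(anchors, inc, radius=1.6) == []

    def test_equidistant_tie_goes_to_lower_spot_index(self):
        anchors = [self._spot(10, 10)]
        inc = [self._spot(11.0, 10.0), self._spot(9.0, 10.0)]  # both 1.0 px
        matches = s.coincidence_spots(anchors, inc, radius=1.6)
        assert len(matches) == 1
        assert matches[0].spot is inc[0]

    def test_anchor_accepts_single_nearest_spot(self):
        anchors = [self._spot(10, 10)]
        inc = [self._spot(10.9, 10.0), self._spot(10.2, 10.0)]
        matches = s.coincidence_spots(anchors, inc, radius=1.6)
        assert len(matches) == 1
        assert matches[0].spot is inc[1]  # nearest wins


def _grid_molecules(n):
    side = int(np.ceil(np.sqrt(n)))
    xs = (np.arange(n) % side) * 20.0 + 12.0
    ys = (np.arange(n) // side) * 20.0 + 12.0
    return s.MoleculeSet(
        x=xs, y=ys,
        template_index=np.zeros(n, dtype=np.int32),
        origin=np.zeros(n, dtype=np.int8),
        site_index=np.arange(n),
        site_occupancy=np.ones(n, dtype=int),
    )
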