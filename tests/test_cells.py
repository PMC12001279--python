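"""Nuclei detection by signal curvature and clipped-box density estimation."""

import numpy as np
import pytest
from scipy import stats

from morphofold import cells, synth


def _blob_volume(centers, shape=(64, 64, 64), sigma=2.0, peak=10.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    vol = (
        rng.normal(0, noise, size=shape).astype(np.float32)
        if noise
        else np.zeros(shape, np.float32)
    )
    synth._paint_blobs(vol, np.asarray(centers, dtype=float), sigma, peak)
    return vol


class TestSignalCurvatures:
    def test_constant_volume_all_zero(self):
        sc = cells.signal_curvatures(np.full((16, 16, 16), 3.0), 2.0)
        assert np.abs(sc.k1).max() < 1e-6

    def test_sorted_descending(self):
        vol = _blob_volume([[32, 30, 34], [20, 40, 22]], noise=0.5)
        sc = cells.signal_curvatures(vol, 2.0)
        assert np.all(sc.k1 >= sc.k2 - 1e-12) and np.all(sc.k2 >= sc.k3 - 1e-12)

    def test_isolated_blob_center_curvatures_analytic(self):
        s, sig, peak = 2.0, 2.0, 10.0
        vol = _blob_volume([[32, 32, 32]], sigma=s, peak=peak)
        sc = cells.signal_curvatures(vol, sig)
        expected = peak * s**3 / (s**2 + sig**2) ** 2.5
        got = np.array([sc.k1[32, 32, 32], sc.k2[32, 32, 32], sc.k3[32, 32, 32]])
        assert np.allclose(got, expected, rtol=0.05)
        assert np.abs(got - got.mean()).max() / got.mean() < 0.05

    def test_bright_sheet_has_one_dominant_curvature(self):
        z = np.arange(48)
        vol = np.exp(-((z - 24.0) ** 2) / 8.0)[:, None, None] * np.ones((1, 32, 32))
        sc = cells.signal_curvatures(vol.astype(np.float32), 2.0)
        mid = sc.k1[24, 16, 16], sc.k2[24, 16, 16], sc.k3[24, 16, 16]
        assert mid[0] > 0.01
        assert abs(mid[1]) < 0.05 * mid[0] and abs(mid[2]) < 0.05 * mid[0]

    def test_small_sigma_rejected(self):
        with pytest.raises(ValueError):
            cells.signal_curvatures(np.zeros((16, 16, 16)), 0.3)


class TestBlobScore:
    def test_any_nonpositive_curvature_zeroes_score(self):
        k = cells.SignalCurvatures(
            k1=np.array([1.0, 2.0]), k2=np.array([1.0, 0.5]), k3=np.array([-0.1, 0.0])
        )
        assert np.allclose(cells.blob_score(k), 0.0)

    @pytest.mark.parametrize("triple, expect", [((1, 1, 1), 1.0), ((8, 1, 1), 2.0)])
    def test_geometric_mean(self, triple, expect):
        k = cells.SignalCurvatures(*(np.array([float(v)]) for v in triple))
        assert cells.blob_score(k)[0] == pytest.approx(expect)

    def test_intensity_scaling_equivariance(self):
        # exact equivariance holds in exact arithmetic; the positive-part
        # boundary (ki ~ 0) amplifies float32 rounding through the cube root,
        # so compare with a tolerance away from machine epsilon
        vol = _blob_volume([[32, 30, 34], [20, 40, 22]])
        ks1 = cells.blob_score(cells.signal_curvatures(vol, 2.0))
        ks3 = cells.blob_score(cells.signal_curvatures(3.0 * vol, 2.0))
        assert np.allclose(ks3, 3.0 * ks1, atol=5e-3 * ks1.max())


class TestDetectCells:
    def test_single_blob_detected_at_truth(self):
        vol = _blob_volume([[30.0, 34.0, 28.0]], noise=0.5, seed=1)
        det = cells.detect_cells(vol, 2.0, peak_intensity=10, blob_sigma=2)
        assert len(det) == 1
        assert np.linalg.norm(det.positions[0] - [30, 34, 28]) < 1.0

    def test_two_separated_blobs(self):
        vol = _blob_volume([[20, 20, 20], [40, 40, 40]], noise=0.5, seed=2)
        det = cells.detect_cells(vol, 2.0, peak_intensity=10, blob_sigma=2)
        assert len(det) == 2

    def test_pure_noise_detects_nothing(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(0, 1.0, size=(64, 64, 64)).astype(np.float32)
        det = cells.detect_cells(vol, 2.0, peak_intensity=10, blob_sigma=2)
        assert len(det) == 0

    def test_f1_on_separated_blobs_with_noise(self):
        """F1 >= 0.95 for blobs >= 6 sigma apart at SNR >= 5, over 5 seeds."""
        sig = 2.0
        f1s = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            # jittered grid keeps a minimum spacing of 16 > 6*sigma voxels
            base = np.stack(
                np.meshgrid(*([np.arange(12, 96, 16.0)] * 3), indexing="ij"), -1
            ).reshape(-1, 3)
            truth = base + rng.uniform(-1.5, 1.5, base.shape)
            vol = _blob_volume(truth, shape=(96, 96, 96), sigma=sig, peak=10.0,
                               noise=2.0, seed=seed)
            det = cells.detect_cells(vol, sig, peak_intensity=10, blob_sigma=sig)
            from scipy.spatial import cKDTree

            if len(det) == 0:
                f1s.append(0.0)
                continue
            d, _ = cKDTree(det.positions).query(truth)
            tp = int((d < 3.0).sum())
            prec = tp / len(det)
            rec = tp / len(truth)
            f1s.append(2 * prec * rec / (prec + rec))
        assert min(f1s) >= 0.95


class TestLayerDensity:
    def test_homogeneous_field_unbiased(self):
        """Mean clipped-box estimate falls in the 95% CI of the true density."""
        rho = 3e-4
        shape = (120, 120, 120)
        labels = np.ones(shape, dtype=np.uint8)
        rng = np.random.default_rng(5)
        n = rng.poisson(rho * np.prod(shape))
        pos = rng.uniform(0, shape[0], size=(n, 3))
        det = cells.CellCentroids(positions=pos, sizes=np.ones(n, dtype=int))
        est = cells.layer_density(det, labels, 1, box_edge=80)
        se = np.sqrt(n) / np.prod(shape)
        assert abs(est.mean - rho) < 2.5 * se

    def test_flat_boundary_density_unbiased(self):
        rho = 5e-4
        shape = (80, 80, 80)
        labels = np.ones(shape, dtype=np.uint8)
        labels[40:] = 2
        rng = np.random.default_rng(8)
        n = rng.poisson(rho * 40 * 80 * 80)
        pos = rng.uniform([0, 0, 0], [40, 80, 80], size=(n, 3))
        det = cells.CellCentroids(positions=pos, sizes=np.ones(n, dtype=int))
        # sampling point right on the boundary: count and volume both halve
        est = cells.layer_density(
            det, labels, 1, sampling_points=np.array([[39, 40, 40]]), box_edge=40
        )
        se = np.sqrt(rho * 40 * 40 * 20) / (40 * 40 * 20)
        assert abs(est.density[0] - rho) < 3 * se

    def test_no_cells_zero_density(self):
        labels = np.ones((32, 32, 32), dtype=np.uint8)
        det = cells.CellCentroids(positions=np.empty((0, 3)), sizes=np.empty(0, int))
        est = cells.layer_density(det, labels, 1, box_edge=16)
        assert est.mean == 0.0

    def test_bias_below_two_percent_over_seeds(self):
        """Relative bias of the lattice estimate < 2% when rho*box^3 >= 50."""
        rho = 1e-3
        shape = (96, 96, 96)
        labels = np.ones(shape, dtype=np.uint8)
        ratio = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            n = rng.poisson(rho * np.prod(shape))
            pos = rng.uniform(0, 96, size=(n, 3))
            det = cells.CellCentroids(positions=pos, sizes=np.ones(n, int))
            est = cells.layer_density(det, labels, 1, box_edge=64)
            ratio.append(est.mean / rho)
        assert abs(np.mean(ratio) - 1.0) < 0.02


class TestDensityContrast:
    def _est(self, vals):
        return cells.DensityEstimate(
            points=np.zeros((len(vals), 3), int),
            density=np.asarray(vals, float),
            layer=1,
            box_edge=80,
        )

    @pytest.mark.parametrize(
        "epi, derm, expect",
        [([2.0, 2.0], [2.0], 0.0), ([1.23], [1.0], 23.0), ([0.5], [1.0], -50.0)],
    )
    def test_examples(self, epi, derm, expect):
        assert cells.density_contrast(self._est(epi), self._est(derm)) == pytest.approx(
            expect
        )

    def test_zero_dermal_mean_rejected(self):
        with pytest.raises(ValueError):
            cells.density_contrast(self._est([1.0]), self._est([0.0]))

    def test_empty_estimate_rejected(self):
        with pytest.raises(ValueError):
            cells.density_contrast(self._est([]), self._est([1.0]))


class TestEndToEndContrast:
    def test_generator_ratio_recovered_small_scale(self):
        """Detection + clipped boxes recover the generator's layer ratio.

        Small volumes, pooled over seeds; tolerance set by Poisson counting.
        """
        spec_kwargs = dict(
            grid_shape=(128, 160, 160),
            epidermis_band_thickness=48,
            dermal_density=2e-4,
            epidermal_to_dermal_ratio=1.5,
        )
        epi_means, derm_means = [], []
        for seed in range(3):
            spec = synth.EduVolumeSpec(**spec_kwargs, seed=seed)
            vol, labels, _ = synth.make_edu_volume(spec)
            det = cells.detect_cells(
                vol, 2.0, peak_intensity=spec.peak_intensity, blob_sigma=spec.blob_sigma
            )
            epi_means.append(cells.layer_density(det, labels, 1, box_edge=80).mean)
            derm_means.append(cells.layer_density(det, labels, 2, box_edge=80).mean)
        got = np.mean(epi_means) / np.mean(derm_means)
        # ~1200 epi / ~3300 derm nuclei per seed, 3 seeds
        assert got == pytest.approx(1.5, rel=0.08)
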