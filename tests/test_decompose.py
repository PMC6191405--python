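"""Maximum-likelihood decomposition: recovery, statistics and oracles."""

import numpy as np
import pytest

from spcct.beam import BinCountModel, expected_bin_counts, generate_spectrum
from spcct.decompose import (
    DecomposedSinogram,
    _nll,
    choose_basis,
    decompose_sinogram,
    ml_decompose_ray,
    validate_basis,
    water_equivalent_thickness,
)
from spcct.phantom import DesignTable, PhantomSpec, TubeFill
from spcct.scan import CountSinogram, ScanProtocol, forward_project_phantom, simulate_counts


class TestBasis:
    @pytest.mark.parametrize(
        "study, expected",
        [
            ("IGd_mix", ["water", "iodine", "gadolinium"]),
            ("AuGd_mix", ["water", "iodine", "gadolinium", "gold"]),
            ("I_only", ["water", "iodine"]),
            ("Gd_only", ["water", "iodine", "gadolinium"]),
            ("Au_only", ["water", "iodine", "gold"]),
        ],
    )
    def test_choose_basis(self, study, expected):
        assert choose_basis(study) == expected

    def test_unknown_study(self):
        with pytest.raises(KeyError):
            choose_basis("Bi_only")

    def test_kedge_below_noise_threshold_rejected(self):
        from spcct.beam import DetectorModel

        det = DetectorModel((35, 51, 64, 72, 85), upper_limit=120.0)
        with pytest.raises(ValueError):
            validate_basis(["water", "iodine"], det)

    def test_basis_size_limits(self, detector_gd):
        with pytest.raises(ValueError):
            validate_basis(["water"], detector_gd)
        with pytest.raises(ValueError):
            validate_basis(["iodine", "water"], detector_gd)


class TestSingleRay:
    def test_noiseless_recovery(self, spectrum_hi, detector_augd):
        """Rounded noiseless counts invert to the generating densities."""
        truth = {"water": 10.0, "iodine": 0.05}
        m = np.round(expected_bin_counts(spectrum_hi, detector_augd, truth))
        basis = ["water", "iodine"]
        a, diag = ml_decompose_ray(m, spectrum_hi, detector_augd, basis)
        assert diag["converged"]
        assert a["water"] == pytest.approx(10.0, rel=0.01)
        assert a["iodine"] == pytest.approx(0.05, rel=0.01)

    def test_four_material_noiseless_recovery(self, spectrum_hi, detector_augd):
        truth = {"water": 9.0, "iodine": 0.004, "gadolinium": 0.006, "gold": 0.01}
        m = expected_bin_counts(spectrum_hi, detector_augd, truth)
        basis = choose_basis("AuGd_mix")
        a, diag = ml_decompose_ray(m, spectrum_hi, detector_augd, basis)
        assert diag["converged"]
        for mat, val in truth.items():
            assert a[mat] == pytest.approx(val, rel=1e-4)

    def test_all_zero_counts_flagged(self, spectrum_hi, detector_gd):
        a, diag = ml_decompose_ray(
            np.zeros(5), spectrum_hi, detector_gd, ["water", "iodine"]
        )
        assert not diag["converged"]
        assert a == {"water": 0.0, "iodine": 0.0}

    def test_invalid_counts(self, spectrum_hi, detector_gd):
        with pytest.raises(ValueError):
            ml_decompose_ray(
                np.array([1.0, 2, 3, -4, 5]), spectrum_hi, detector_gd,
                ["water", "iodine"],
            )
        with pytest.raises(ValueError):
            ml_decompose_ray(
                np.array([1.0, 2, 3, np.nan, 5]), spectrum_hi, detector_gd,
                ["water", "iodine"],
            )


class TestWaterEquivalent:
    def test_pure_water_identity(self, spectrum_hi, detector_gd):
        m = expected_bin_counts(spectrum_hi, detector_gd, {"water": 10.0})
        t = water_equivalent_thickness(m, spectrum_hi, detector_gd)
        assert t == pytest.approx(10.0, abs=1e-4)

    def test_decreasing_in_total_counts(self, spectrum_hi, detector_gd):
        m = expected_bin_counts(spectrum_hi, detector_gd, {"water": 10.0})
        t1 = water_equivalent_thickness(m, spectrum_hi, detector_gd)
        t2 = water_equivalent_thickness(0.8 * m, spectrum_hi, detector_gd)
        assert t2 > t1

    def test_contrast_exceeds_geometric_water(self, spectrum_hi, detector_gd):
        m = expected_bin_counts(
            spectrum_hi, detector_gd, {"water": 10.0, "gadolinium": 0.01}
        )
        t = water_equivalent_thickness(m, spectrum_hi, detector_gd)
        assert t > 10.0


class TestEstimatorStatistics:
    def test_asymptotic_unbiasedness(self, detector_gd):
        """Mean over 1000 Poisson replicates is within 3 SE of truth."""
        spectrum = generate_spectrum(120.0, 1e6)
        basis = ["water", "iodine", "gadolinium"]
        truth = np.array([10.0, 0.004, 0.005])
        lam = expected_bin_counts(
            spectrum, detector_gd, dict(zip(basis, truth))
        )
        rng = np.random.default_rng(42)
        M = rng.poisson(lam, size=(1000, 5)).astype(float)
        model = BinCountModel(spectrum, detector_gd, basis)
        from spcct.decompose import _newton_poisson, _water_equivalent

        model_w = BinCountModel(spectrum, detector_gd, ["water"])
        a0 = np.zeros((1000, 3))
        a0[:, 0] = _water_equivalent(model_w, M)
        A, conv, _, _ = _newton_poisson(model, M, a0)
        assert conv.mean() > 0.99
        se = A.std(axis=0, ddof=1) / np.sqrt(len(A))
        assert np.all(np.abs(A.mean(axis=0) - truth) < 3 * se)

    def test_bias_shrinks_with_exposure(self, detector_gd):
        """|bias| decreases from N0=1e4 to N0=1e6 (estimator consistency)."""
        basis = ["water", "iodine", "gadolinium"]
        truth = np.array([10.0, 0.004, 0.005])
        biases = []
        for n0, seed in ((1e4, 1), (1e6, 2)):
            spectrum = generate_spectrum(120.0, n0)
            lam = expected_bin_counts(spectrum, detector_gd, dict(zip(basis, truth)))
            rng = np.random.default_rng(seed)
            M = rng.poisson(lam, size=(2000, 5)).astype(float)
            model = BinCountModel(spectrum, detector_gd, basis)
            from spcct.decompose import _newton_poisson, _water_equivalent

            model_w = BinCountModel(spectrum, detector_gd, ["water"])
            a0 = np.zeros((M.shape[0], 3))
            a0[:, 0] = _water_equivalent(model_w, M)
            A, _, _, _ = _newton_poisson(model, M, a0)
            biases.append(np.abs(A.mean(axis=0) - truth) / truth)
        assert np.all(biases[1] <= biases[0] + 1e-3)

    def test_four_material_basis_increases_gd_variance(self, detector_augd):
        """Adding gold to the basis inflates the gadolinium variance on
        gold-free rays (the documented mixed-study noise penalty)."""
        spectrum = generate_spectrum(120.0, 1e6)
        truth3 = {"water": 10.0, "iodine": 0.004, "gadolinium": 0.005}
        lam = expected_bin_counts(spectrum, detector_augd, truth3)
        rng = np.random.default_rng(3)
        M = rng.poisson(lam, size=(1500, 5)).astype(float)
        from spcct.decompose import _newton_poisson, _water_equivalent

        model_w = BinCountModel(spectrum, detector_augd, ["water"])
        sds = {}
        for basis in (
            ["water", "iodine", "gadolinium"],
            ["water", "iodine", "gadolinium", "gold"],
        ):
            model = BinCountModel(spectrum, detector_augd, basis)
            a0 = np.zeros((M.shape[0], len(basis)))
            a0[:, 0] = _water_equivalent(model_w, M)
            A, _, _, _ = _newton_poisson(model, M, a0)
            sds[len(basis)] = A[:, 2].std(ddof=1)
        assert sds[4] > sds[3]

    def test_likelihood_ascent(self, detector_gd):
        """The reported optimum never falls below the initialiser's
        log-likelihood."""
        spectrum = generate_spectrum(120.0, 1e5)
        basis = ["water", "iodine", "gadolinium"]
        lam = expected_bin_counts(
            spectrum, detector_gd, {"water": 8.0, "iodine": 0.002, "gadolinium": 0.004}
        )
        rng = np.random.default_rng(5)
        M = rng.poisson(lam, size=(200, 5)).astype(float)
        model = BinCountModel(spectrum, detector_gd, basis)
        from spcct.decompose import _newton_poisson, _water_equivalent

        model_w = BinCountModel(spectrum, detector_gd, ["water"])
        a0 = np.zeros((200, 3))
        a0[:, 0] = _water_equivalent(model_w, M)
        nll0 = _nll(model.expected(a0), M)
        A, _, _, nll1 = _newton_poisson(model, M, a0)
        assert np.all(nll1 <= nll0 + 1e-9)

    def test_grid_search_oracle(self, detector_gd):
        """On 100 random rays the optimiser's objective matches or beats a
        brute-force grid search around the truth."""
        spectrum = generate_spectrum(120.0, 1e5)
        basis = ["water", "iodine", "gadolinium"]
        truth = np.array([9.0, 0.003, 0.005])
        lam = expected_bin_counts(spectrum, detector_gd, dict(zip(basis, truth)))
        rng = np.random.default_rng(17)
        M = rng.poisson(lam, size=(100, 5)).astype(float)
        model = BinCountModel(spectrum, detector_gd, basis)
        from spcct.decompose import _newton_poisson, _water_equivalent

        model_w = BinCountModel(spectrum, detector_gd, ["water"])
        a0 = np.zeros((100, 3))
        a0[:, 0] = _water_equivalent(model_w, M)
        A, _, _, nll_opt = _newton_poisson(model, M, a0)
        # coarse grid: 11^3 points spanning ±6 noise SDs around the truth
        spans = [0.3, 0.006, 0.012]
        axes = [t + np.linspace(-s, s, 11) for t, s in zip(truth, spans)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        lam_grid = model.expected(grid)  # (n_grid, 5)
        for i in range(100):
            with np.errstate(divide="ignore", invalid="ignore"):
                nll_grid = np.sum(
                    lam_grid
                    - np.where(M[i] > 0, M[i] * np.log(np.maximum(lam_grid, 1e-12)), 0.0),
                    axis=1,
                )
            assert nll_opt[i] <= nll_grid.min() + 1e-6


def _tiny_phantom_scan(noise=False):
    """Water-body phantom (basis spans the object) at a coarse protocol."""
    spec = PhantomSpec(body_material="water")
    fills = [TubeFill(t, {"iodine": 0.5 * t}) for t in range(1, 12)]
    fills.append(TubeFill(12, {}))
    design = DesignTable("I_only", tuple(fills))
    proto = ScanProtocol(n_views=64, n_detectors=128, n0=1e5, slice_averaging=1)
    spectrum = generate_spectrum(120.0, proto.exposure)
    from spcct.beam import DetectorModel

    det = DetectorModel((30, 51, 64, 72, 85), upper_limit=120.0)
    sinos = forward_project_phantom(spec, design, proto)
    # body material is water here: merge into the water sinogram
    counts = simulate_counts(sinos, spectrum, det, proto, noiseless=not noise)
    return sinos, counts, spectrum, det, proto


class TestSinogramDecomposition:
    def test_noiseless_round_trip(self):
        """Noiseless counts of a basis-spanned phantom decompose back to the
        forward-projected sinograms within 1 % RMS."""
        sinos, counts, spectrum, det, proto = _tiny_phantom_scan()
        dec = decompose_sinogram(counts, spectrum, det, ["water", "iodine"])
        support = sinos["water"] > 0.1
        for mat in ("water", "iodine"):
            truth = sinos[mat]
            err = np.sqrt(np.mean((dec.materials[mat][support] - truth[support]) ** 2))
            assert err < 0.01 * max(np.abs(truth[support]).max(), 1e-6)

    def test_ray_order_invariance(self):
        """Permuting the ray evaluation order leaves results bit-identical."""
        sinos, counts, spectrum, det, proto = _tiny_phantom_scan(noise=True)
        dec1 = decompose_sinogram(counts, spectrum, det, ["water", "iodine"])
        # feed the rays in a shuffled order via a view permutation
        rng = np.random.default_rng(0)
        perm = rng.permutation(proto.n_views)
        shuffled = CountSinogram(counts.counts[:, perm, :], proto, counts.seed)
        dec2 = decompose_sinogram(shuffled, spectrum, det, ["water", "iodine"])
        inv = np.argsort(perm)
        for mat in ("water", "iodine"):
            assert np.array_equal(dec2.materials[mat][inv], dec1.materials[mat])

    def test_convergence_fraction_reported(self):
        _, counts, spectrum, det, proto = _tiny_phantom_scan(noise=True)
        dec = decompose_sinogram(counts, spectrum, det, ["water", "iodine"])
        assert isinstance(dec, DecomposedSinogram)
        assert dec.convergence_fraction > 0.99
        assert dec.water_equivalent.shape == (proto.n_views, proto.n_detectors)
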