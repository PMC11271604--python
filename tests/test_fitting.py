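"""Design matrix, NNLS spectrum inversion, refinement, fraction aggregation."""

import itertools

import numpy as np
import pytest
from scipy.optimize import nnls

from cdbsi.dictionary import (
    AnisotropicModel,
    assemble_dictionary,
    build_isotropic_spectrum,
    make_direction_set,
)
from cdbsi.fitting import (
    COMPARTMENTS,
    DegenerateVoxelError,
    VoxelSpectrum,
    aggregate_fractions,
    atom_signal,
    build_design_matrix,
    fit_volume,
    fit_voxel,
    median_nonzero,
    refine_voxel,
)
from cdbsi.phantom import forward_voxel
from cdbsi.scheme import AcquisitionScheme, default_scheme


class TestAtomSignal:
    def test_b0_is_unity(self):
        assert atom_signal(0.0, np.zeros(3), iso_diffusivity=5.0) == 1.0
        assert atom_signal(0.0, np.zeros(3), ad=1.8, rd=0.3,
                           direction=[0, 0, 1]) == 1.0

    def test_isotropic_closed_form(self):
        s = atom_signal(1000.0, [0, 0, 1.0], iso_diffusivity=3.0)
        assert s == pytest.approx(np.exp(-3.0), rel=1e-12)

    def test_parallel_gradient_sees_axial_diffusivity(self):
        s = atom_signal(1000.0, [0, 0, 1.0], ad=1.8, rd=0.3,
                        direction=[0, 0, 1.0])
        assert s == pytest.approx(np.exp(-1.8), rel=1e-12)

    def test_perpendicular_gradient_sees_radial_diffusivity(self):
        s = atom_signal(1000.0, [1.0, 0, 0], ad=1.8, rd=0.3,
                        direction=[0, 0, 1.0])
        assert s == pytest.approx(np.exp(-0.3), rel=1e-12)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            atom_signal(-1.0, np.zeros(3), iso_diffusivity=1.0)


class TestDesignMatrix:
    def test_default_shape_and_b0_rows(self, design, scheme):
        assert design.A.shape == (74, 375)
        assert np.all(design.A[scheme.b0_mask] == 1.0)
        assert np.all((design.A > 0) & (design.A <= 1.0))

    def test_all_b0_scheme_gives_ones(self, dictionary):
        sch = AcquisitionScheme(np.zeros(3), np.zeros((3, 3)))
        d = build_design_matrix(dictionary, sch)
        assert np.all(d.A == 1.0)

    def test_isotropic_columns_direction_independent(self, dictionary):
        b = np.array([0.0, 1000.0, 1000.0])
        v = np.array([[0, 0, 0], [0, 0, 1.0], [1.0, 0, 0]])
        A = build_design_matrix(dictionary, AcquisitionScheme(b, v)).A
        np.testing.assert_allclose(A[1, :150], A[2, :150])


class TestFitVoxel:
    def test_single_atom_recovery(self, design, dictionary):
        target_d = 3.0
        col = int(np.argmin(np.abs(dictionary.iso_diffusivities() - target_d)))
        signal = 700.0 * design.A[:, col]
        spec = fit_voxel(signal, design, reg=0.0)
        frac = spec.fractions()
        ds = dictionary.iso_diffusivities()
        near = np.abs(ds - target_d) <= 0.2
        assert frac[: len(ds)][near].sum() >= 0.95
        assert spec.s0 == pytest.approx(700.0)

    def test_pure_free_water_lands_in_free_band(self, design):
        signal = design.A[:, 30]  # D = 3.0
        spec = fit_voxel(signal, design, reg=0.0)
        agg = aggregate_fractions(spec, design)
        assert agg["free"] >= 0.95

    def test_even_restricted_free_mixture(self, design):
        signal = 0.5 * design.A[:, 3] + 0.5 * design.A[:, 30]
        agg = aggregate_fractions(fit_voxel(signal, design, reg=0.0), design)
        assert agg["cell"] == pytest.approx(0.5, abs=0.05)
        assert agg["free"] == pytest.approx(0.5, abs=0.05)

    def test_nonpositive_b0_flags_degenerate_voxel(self, design):
        with pytest.raises(DegenerateVoxelError):
            fit_voxel(np.zeros(74), design)

    def test_matches_exhaustive_active_set_oracle(self, rng):
        """reg=0 NNLS agrees with brute-force support enumeration on random
        10-atom sub-dictionaries (K=20) to 1e-6."""
        iso = build_isotropic_spectrum(start=0.2, step=1.4, count=10)
        v = rng.normal(size=(18, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        sch = AcquisitionScheme(np.concatenate([[0.0, 0.0],
                                                rng.uniform(200, 2000, 18)]),
                                np.vstack([np.zeros((2, 3)), v]))
        d = assemble_dictionary(iso, [AnisotropicModel(1, 1.8, 0.3)],
                                make_direction_set(1))
        design = build_design_matrix(d, sch)
        A = design.A[:, :10]  # isotropic sub-dictionary

        def brute_force(A, y):
            best_w, best_r = None, np.inf
            n = A.shape[1]
            for size in range(n + 1):
                for support in itertools.combinations(range(n), size):
                    w = np.zeros(n)
                    if support:
                        ws, *_ = np.linalg.lstsq(A[:, support], y, rcond=None)
                        if np.any(ws < -1e-12):
                            continue
                        w[list(support)] = np.clip(ws, 0, None)
                    r = np.linalg.norm(A @ w - y)
                    if r < best_r - 1e-12:
                        best_r, best_w = r, w
            return best_w

        for trial in range(5):
            f_true = rng.random(10) * (rng.random(10) < 0.3)
            y = A @ f_true + rng.normal(0, 0.01, A.shape[0])
            w_pkg, _ = nnls(A, y)
            w_oracle = brute_force(A, y)
            assert np.linalg.norm(A @ w_pkg - y) == pytest.approx(
                np.linalg.norm(A @ w_oracle - y), abs=1e-6)
            np.testing.assert_allclose(w_pkg, w_oracle, atol=1e-6)


class TestAggregation:
    def _spectrum(self, design, weights):
        return VoxelSpectrum(weights, s0=1.0, residual=0.0)

    def test_single_restricted_atom_is_pure_cell(self, design):
        w = np.zeros(design.n_atoms)
        w[2] = 0.7  # D = 0.2, restricted band
        agg = aggregate_fractions(self._spectrum(design, w), design)
        assert agg["cell"] == 1.0
        assert sum(agg.values()) == pytest.approx(1.0)

    def test_equal_muscle_and_free_weights(self, design):
        w = np.zeros(design.n_atoms)
        w[30] = 0.4  # free atom
        muscle_cols = np.flatnonzero(design.compartments == "muscle")
        w[muscle_cols[0]] = 0.4
        agg = aggregate_fractions(self._spectrum(design, w), design)
        assert agg["muscle"] == pytest.approx(0.5)
        assert agg["free"] == pytest.approx(0.5)

    def test_all_zero_spectrum_flagged_absent(self, design):
        assert aggregate_fractions(
            self._spectrum(design, np.zeros(design.n_atoms)), design) is None

    def test_merge_other_into_hindered(self, design):
        w = np.zeros(design.n_atoms)
        other_cols = np.flatnonzero(design.compartments == "other_fiber")
        w[other_cols[0]] = 1.0
        agg = aggregate_fractions(self._spectrum(design, w), design,
                                  merge_other_into_hindered=True)
        assert agg["hindered"] == 1.0
        assert "other_fiber" not in agg


class TestRefinement:
    def test_five_compartment_noiseless_recovery(self, design, dictionary,
                                                 scheme, rng):
        truth = {"cell": 0.10, "hindered": 0.05, "free": 0.60, "ivim": 0.0,
                 "collagen": 0.05, "muscle": 0.20}
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        y = forward_voxel(truth, u, dictionary, scheme)
        spec = fit_voxel(y, design)
        frac = refine_voxel(y, design, spec)
        for c in COMPARTMENTS:
            assert frac[c] == pytest.approx(truth[c], abs=0.02)

    def test_median_recovery_under_noise(self, design, dictionary, scheme, rng):
        """SNR-50 per-compartment estimates are median-unbiased within 0.05."""
        truth = {"cell": 0.10, "hindered": 0.05, "free": 0.60, "ivim": 0.0,
                 "collagen": 0.05, "muscle": 0.20}
        u = np.array([0.0, 0.0, 1.0])
        clean = forward_voxel(truth, u, dictionary, scheme, s0=500.0)
        outs = []
        for _ in range(100):
            n1, n2 = rng.normal(0, 10.0, (2, clean.size))
            y = np.sqrt((clean + n1) ** 2 + n2**2)
            spec = fit_voxel(y, design)
            outs.append(refine_voxel(y / spec.s0, design, spec))
        for c in COMPARTMENTS:
            med = np.median([o[c] for o in outs])
            assert med == pytest.approx(truth[c], abs=0.05)

    def test_rotation_equivariance(self, dictionary, rng):
        """Rotating fiber direction and b-vectors together leaves fractions
        unchanged within 0.02."""
        from scipy.spatial.transform import Rotation

        truth = {"cell": 0.05, "hindered": 0.30, "free": 0.25, "ivim": 0.0,
                 "collagen": 0.15, "muscle": 0.25}
        sch = default_scheme()
        u = np.array([0.0, 0.0, 1.0])
        R = Rotation.from_euler("xyz", [30, 45, 10], degrees=True).as_matrix()
        sch_rot = AcquisitionScheme(sch.bvalues, sch.bvectors @ R.T)

        def fractions(scheme_, direction):
            y = forward_voxel(truth, direction, dictionary, scheme_)
            design = build_design_matrix(dictionary, scheme_)
            spec = fit_voxel(y, design)
            return refine_voxel(y, design, spec)

        f0 = fractions(sch, u)
        f1 = fractions(sch_rot, R @ u)
        for c in COMPARTMENTS:
            assert f1[c] == pytest.approx(f0[c], abs=0.02)


class TestFitVolume:
    def test_volume_equals_voxelwise_fits(self, dictionary, scheme, design):
        rng = np.random.default_rng(5)
        shape = (2, 2, 2)
        dwi = np.empty(shape + (scheme.n_measurements,))
        for idx in np.ndindex(shape):
            f = rng.dirichlet([4, 8, 6, 1, 3, 4])
            frac = dict(zip(COMPARTMENTS, f))
            dwi[idx] = forward_voxel(frac, np.array([0, 0, 1.0]), dictionary,
                                     scheme, s0=400.0)
        maps = fit_volume(dwi, scheme, dictionary)
        for idx in np.ndindex(shape):
            spec = fit_voxel(dwi[idx], design)
            frac = refine_voxel(dwi[idx] / spec.s0, design, spec)
            for c in COMPARTMENTS:
                assert maps.maps[c][idx] == pytest.approx(frac[c], abs=1e-6)
        assert maps.check_normalization()

    def test_empty_mask_returns_empty_maps(self, dictionary, scheme):
        dwi = np.ones((2, 2, 1, scheme.n_measurements))
        maps = fit_volume(dwi, scheme, dictionary,
                          mask=np.zeros((2, 2, 1), bool))
        assert not maps.mask.any()
        assert all(np.all(m == 0) for m in maps.maps.values())

    def test_shape_mismatch_rejected(self, dictionary, scheme):
        with pytest.raises(ValueError):
            fit_volume(np.ones((2, 2, 1, 5)), scheme, dictionary)


class TestMedianNonzero:
    def test_ignores_zeros(self):
        assert median_nonzero(np.array([0.0, 0.0, 2.0, 4.0])) == 3.0

    def test_all_zero_is_absent(self):
        assert median_nonzero(np.zeros(5)) is None

    def test_single_value(self):
        assert median_nonzero(np.array([0.0, 0.7])) == pytest.approx(0.7)

    def test_respects_mask(self):
        vals = np.array([[5.0, 1.0], [0.0, 9.0]])
        mask = np.array([[True, False], [True, False]])
        assert median_nonzero(vals, mask) == 5.0
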