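"""Synthetic phantom generators: tissue contrast, SPD tensors, ODF shape,
graph-signal spectra, cohort perturbation structure."""

import numpy as np
import pytest

import voxgraph as vg
from voxgraph.phantom import LABEL_CSF, LABEL_GM, LABEL_WM, fa_from_eigenvalues


class TestTissuePhantom:
    def test_tissue_contrast_and_bundle(self):
        ph = vg.make_tissue_phantom((20, 20, 20), bundle_axis=0, bundle_radius=3.0,
                                    bundle_anisotropy=0.8, seed=1)
        wm = ph.labels == LABEL_WM
        assert wm.sum() > 0
        mean = lambda lab: ph.anisotropy[ph.labels == lab].mean()
        assert mean(LABEL_WM) > mean(LABEL_GM)
        assert mean(LABEL_WM) > mean(LABEL_CSF)
        assert np.all(ph.anisotropy[ph.labels == 0] == 0)
        assert ph.anisotropy.min() >= 0 and ph.anisotropy.max() <= 1

    def test_deterministic_given_seed(self):
        a = vg.make_tissue_phantom((20, 20, 20), seed=7)
        b = vg.make_tissue_phantom((20, 20, 20), seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.anisotropy, b.anisotropy)

    def test_oversized_bundle_rejected(self):
        with pytest.raises(vg.GeometryError):
            vg.make_tissue_phantom((20, 20, 20), bundle_radius=30.0, seed=1)

    def test_tiny_grid_rejected(self):
        with pytest.raises(vg.GeometryError):
            vg.make_tissue_phantom((6, 20, 20), seed=1)


class TestTensorField:
    def test_bundle_alignment(self, phantom12):
        tf = vg.make_tensor_field(phantom12, (1, 0, 0), 5.0, seed=1)
        wm = phantom12.labels == LABEL_WM
        mats = tf.full_matrices()[wm]
        _, vecs = np.linalg.eigh(mats)
        principal = vecs[:, :, -1]
        assert np.all(np.abs(principal @ [1.0, 0.0, 0.0]) > 0.95)

    def test_all_inmask_tensors_spd(self, phantom12):
        tf = vg.make_tensor_field(phantom12, (0, 0, 1), 3.0, seed=2)
        np.linalg.cholesky(tf.full_matrices()[phantom12.mask])  # raises if not PD

    def test_ratio_to_one_limit_gives_zero_fa(self, phantom12):
        tf = vg.make_tensor_field(phantom12, (1, 0, 0), 1.0 + 1e-9, seed=1)
        wm = phantom12.labels == LABEL_WM
        evals = np.linalg.eigvalsh(tf.full_matrices()[wm])
        assert fa_from_eigenvalues(evals).max() < 1e-6

    def test_fa_matches_independent_formula(self, phantom12):
        """Generated FA agrees with a from-scratch evaluation of the standard
        eigenvalue formula (independent of the package helper)."""
        tf = vg.make_tensor_field(phantom12, (1, 0, 0), 5.0, seed=3)
        evals = np.linalg.eigvalsh(tf.full_matrices()[phantom12.mask])
        l1, l2, l3 = evals[:, 2], evals[:, 1], evals[:, 0]
        md = (l1 + l2 + l3) / 3
        expected = np.sqrt(1.5) * np.sqrt(
            ((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2)
            / (l1**2 + l2**2 + l3**2)
        )
        np.testing.assert_allclose(fa_from_eigenvalues(evals), expected, atol=1e-12)
        # WM tensors were built with ratio 5 -> FA = (5-1)/sqrt(25+2)
        wm_fa = fa_from_eigenvalues(
            np.linalg.eigvalsh(tf.full_matrices()[phantom12.labels == LABEL_WM])
        )
        np.testing.assert_allclose(wm_fa, 4 / np.sqrt(27), atol=1e-12)

    def test_nonunit_direction_normalized(self, phantom12, caplog):
        tf = vg.make_tensor_field(phantom12, (2, 0, 0), 5.0, seed=1)
        assert np.all(np.isfinite(tf.tensors))

    def test_ratio_not_above_one_rejected(self, phantom12):
        with pytest.raises(ValueError):
            vg.make_tensor_field(phantom12, (1, 0, 0), 1.0, seed=1)


class TestODFField:
    def test_isotropic_background_is_flat(self, phantom12):
        of = vg.make_odf_field(phantom12, (1, 0, 0), sharpness=10.0, seed=1)
        gm = phantom12.labels == LABEL_GM
        amps = of.amplitudes[gm]
        assert np.all(amps.max(axis=1) == amps.min(axis=1))

    def test_bundle_peak_direction(self, phantom12):
        of = vg.make_odf_field(phantom12, (1, 0, 0), sharpness=10.0, seed=1)
        wm = phantom12.labels == LABEL_WM
        peak_dirs = of.directions[np.argmax(of.amplitudes[wm], axis=1)]
        cos = np.abs(peak_dirs @ [1.0, 0.0, 0.0])
        assert np.all(cos > np.cos(np.radians(15)))

    def test_antipodal_symmetry(self, phantom12):
        of = vg.make_odf_field(phantom12, (0, 1, 0), sharpness=5.0, seed=2)
        n = of.directions.shape[0]
        # direction table stores hemisphere then its antipodes
        np.testing.assert_allclose(
            of.directions[: n // 2], -of.directions[n // 2 :], atol=1e-15
        )
        amps = of.amplitudes[phantom12.mask]
        np.testing.assert_allclose(amps[:, : n // 2], amps[:, n // 2 :], atol=1e-12)

    def test_sharpness_increases_peak_to_mean(self, phantom12):
        """Doubling the concentration parameter strictly sharpens the peak;
        oracle: the generator's own kernel exp(k*(cos^2-1)) evaluated at the
        two sharpness values on the same direction grid."""
        wm = np.argwhere(phantom12.labels == LABEL_WM)[0]
        ratios = {}
        for k in (5.0, 10.0):
            of = vg.make_odf_field(phantom12, (1, 0, 0), sharpness=k, seed=1,
                                   orientation_jitter_sd=0.0)
            a = of.amplitudes[tuple(wm)]
            ratios[k] = a.max() / a.mean()
            cos2 = (of.directions @ [1.0, 0.0, 0.0]) ** 2
            kernel = np.exp(k * (cos2 - 1.0))
            assert ratios[k] == pytest.approx(kernel.max() / kernel.mean())
        assert ratios[10.0] > ratios[5.0]

    def test_too_few_directions_rejected(self, phantom12):
        with pytest.raises(ValueError):
            vg.make_odf_field(phantom12, (1, 0, 0), sharpness=5.0, n_directions=50)


class TestGraphSignals:
    def test_flat_profile_with_zero_exponent(self, dti_decomp12):
        sig = vg.make_graph_signals(dti_decomp12, spectral_exponent=0.0,
                                    num_frames=3000, noise_sd=0.0, seed=4)
        spec = vg.eesd(sig, dti_decomp12)
        energy = spec.eesd[1:]
        assert energy.std() / energy.mean() < 0.15

    def test_single_mode_concentrates_energy(self, dti_decomp12):
        x = 3.7 * dti_decomp12.eigenvectors[:, 1]
        spec = vg.eesd(vg.GraphSignalSet(signals=np.tile(x, (4, 1))), dti_decomp12)
        assert spec.eesd[1] == pytest.approx(1.0, abs=1e-10)
        assert spec.eesd[2:].max() < 1e-12

    def test_powerlaw_slope_recovered(self, dti_decomp12):
        """Log-log EESD slope over indices 2..C matches the prescribed
        exponent; oracle: least-squares fit of the generator's expected
        spectrum (coefficient variance ~ i^-2)."""
        sig = vg.make_graph_signals(dti_decomp12, spectral_exponent=2.0,
                                    num_frames=200, noise_sd=0.0, seed=5)
        spec = vg.eesd(sig, dti_decomp12)
        idx = np.arange(2, spec.C + 1)
        slope = np.polyfit(np.log(idx), np.log(spec.eesd[1:]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.3)

    def test_deterministic(self, dti_decomp12):
        a = vg.make_graph_signals(dti_decomp12, 2.0, 5, 0.1, seed=9)
        b = vg.make_graph_signals(dti_decomp12, 2.0, 5, 0.1, seed=9)
        np.testing.assert_array_equal(a.signals, b.signals)


class TestCohort:
    ARGS = dict(shape=(12, 12, 12), seed=1)

    def test_zero_perturbation_identical(self):
        fields = vg.make_cohort(self.ARGS, num_subjects=3, perturbation_sd=0.0, seed=2)
        for f in fields[1:]:
            np.testing.assert_array_equal(f.amplitudes, fields[0].amplitudes)
            np.testing.assert_array_equal(
                f.phantom.anisotropy, fields[0].phantom.anisotropy
            )

    def test_reproducible_given_seed(self):
        a = vg.make_cohort(self.ARGS, num_subjects=2, perturbation_sd=0.05, seed=3)
        b = vg.make_cohort(self.ARGS, num_subjects=2, perturbation_sd=0.05, seed=3)
        np.testing.assert_array_equal(a[1].amplitudes, b[1].amplitudes)

    def test_dti_cohort_spd(self):
        fields = vg.make_cohort(self.ARGS, num_subjects=2, perturbation_sd=0.05,
                                seed=4, model="dti")
        for f in fields:
            np.linalg.cholesky(f.full_matrices()[f.phantom.mask])

    def test_perturbation_increases_procrustes_error(self, scheme3):
        """More inter-subject perturbation -> larger post-match eigenmode
        mismatch; oracle: the matching pipeline itself run at two levels."""
        errors = {}
        for sd in (0.01, 0.2):
            fields = vg.make_cohort(self.ARGS, num_subjects=2,
                                    perturbation_sd=sd, seed=5)
            sets = []
            for f in fields:
                prof = vg.odf_profile(f, scheme3, 2.0)
                g = vg.assemble_graph(
                    prof, f.phantom.anisotropy, f.phantom.mask, scheme3
                )
                dec = vg.eigendecompose(vg.normalized_laplacian(g), 15, seed=0)
                sets.append(vg.EigenmodeSet(dec.eigenvectors))
            res = vg.group_match(sets)
            errors[sd] = vg.procrustes_error(
                res.reordered_sets[0].matrix, res.reordered_sets[1].matrix
            )
        assert errors[0.2] > errors[0.01]
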