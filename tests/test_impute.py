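"""Midsagittal-plane fitting, mirror imputation, TPS, and observer error."""

import numpy as np
import pytest

from craniomorph.gpa import reflect_relabel
from craniomorph.impute import (
    InsufficientConstraintsError,
    SingularTpsError,
    fit_midsagittal_plane,
    fit_tps,
    impute_dataset,
    impute_mirror,
    impute_tps,
    intra_observer_error,
)
from craniomorph.landmarks import LandmarkSet
from craniomorph.synthetic import make_template

from conftest import random_rotation


def _as_set(coords, missing=None, **kw):
    if missing is None:
        missing = np.zeros(len(coords), bool)
    coords = np.array(coords, dtype=float)
    coords[missing] = np.nan
    return LandmarkSet("s", coords, np.asarray(missing, bool), **kw)


class TestMidsagittalPlane:
    def test_exact_symmetry_gives_y_plane(self, cranium_scheme, cranium_template):
        lm = _as_set(cranium_template)
        plane = fit_midsagittal_plane(lm, cranium_scheme)
        np.testing.assert_allclose(np.abs(plane.normal), [0, 1, 0], atol=1e-10)
        assert abs(plane.offset) < 1e-10

    def test_equivariance_under_rotation(self, cranium_scheme, cranium_template, rng):
        rot = random_rotation(rng)
        shift = rng.normal(0, 30, 3)
        lm = _as_set(cranium_template @ rot.T + shift)
        plane = fit_midsagittal_plane(lm, cranium_scheme)
        expected = rot @ np.array([0.0, 1.0, 0.0])
        cosine = abs(plane.normal @ expected)
        assert cosine > 1 - 1e-9

    def test_noisy_plane_within_one_degree(self, cranium_scheme, cranium_template):
        worst = 0.0
        for seed in range(100):
            r = np.random.default_rng(seed)
            lm = _as_set(cranium_template + r.normal(0, 0.01, cranium_template.shape))
            plane = fit_midsagittal_plane(lm, cranium_scheme)
            angle = np.degrees(np.arccos(min(abs(plane.normal[1]), 1.0)))
            worst = max(worst, angle)
        assert worst < 1.0

    def test_pairs_only_suffice(self, cranium_scheme, cranium_template):
        missing = np.zeros(len(cranium_template), bool)
        missing[list(cranium_scheme.midline)] = True
        lm = _as_set(cranium_template, missing)
        plane = fit_midsagittal_plane(lm, cranium_scheme)
        np.testing.assert_allclose(np.abs(plane.normal), [0, 1, 0], atol=1e-8)

    def test_insufficient_constraints_error(self, cranium_scheme, cranium_template):
        missing = np.ones(len(cranium_template), bool)
        missing[list(cranium_scheme.midline)[:2]] = False  # 2 midline, 0 pairs
        lm = _as_set(cranium_template, missing)
        with pytest.raises(InsufficientConstraintsError, match="TPS"):
            fit_midsagittal_plane(lm, cranium_scheme)


class TestMirrorImputation:
    def test_exact_recovery_on_symmetric_shape(self, cranium_scheme, cranium_template):
        left, right = cranium_scheme.paired[3]
        missing = np.zeros(len(cranium_template), bool)
        missing[left] = True
        lm = _as_set(cranium_template, missing)
        out = impute_mirror(lm, cranium_scheme)
        assert not out.missing.any()
        np.testing.assert_allclose(out.coords[left], cranium_template[left], atol=1e-10)
        assert out.provenance["imputed"][left] == "mirror"

    def test_both_sides_missing_left_untouched(self, cranium_scheme, cranium_template):
        left, right = cranium_scheme.paired[0]
        missing = np.zeros(len(cranium_template), bool)
        missing[[left, right]] = True
        out = impute_mirror(_as_set(cranium_template, missing), cranium_scheme)
        assert out.missing[left] and out.missing[right]
        assert out.missing.sum() == 2

    def test_recovery_error_scales_with_asymmetric_noise(
        self, cranium_scheme, cranium_template
    ):
        sigma = 0.5
        errors = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            noisy = cranium_template + r.normal(0, sigma, cranium_template.shape)
            left, right = cranium_scheme.paired[seed % len(cranium_scheme.paired)]
            missing = np.zeros(len(noisy), bool)
            missing[left] = True
            truth = noisy[left].copy()
            out = impute_mirror(_as_set(noisy, missing), cranium_scheme)
            errors.append(np.linalg.norm(out.coords[left] - truth))
        mean_err = np.mean(errors)
        # reflection of an independently-perturbed partner: error ~ 2 sigma scale
        assert mean_err < 4 * sigma
        assert mean_err > 0.5 * sigma

    def test_reflection_consistency_involution(self, cranium_scheme, cranium_template):
        # reflecting the recovered landmark back reproduces its partner
        left, right = cranium_scheme.paired[5]
        missing = np.zeros(len(cranium_template), bool)
        missing[left] = True
        out = impute_mirror(_as_set(cranium_template, missing), cranium_scheme)
        plane = fit_midsagittal_plane(out, cranium_scheme)
        back = plane.reflect(out.coords[left])[0]
        np.testing.assert_allclose(back, cranium_template[right], atol=1e-10)


class TestTps:
    def test_identity_map(self, cranium_template):
        model = fit_tps(cranium_template, cranium_template)
        np.testing.assert_allclose(
            model.affine, np.hstack([np.zeros((3, 1)), np.eye(3)]), atol=1e-9
        )
        assert np.abs(model.weights).max() < 1e-9
        assert model.bending_energy < 1e-9

    def test_affine_exactness(self, cranium_template, rng):
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        b = rng.normal(size=3)
        target = cranium_template @ A.T + b
        model = fit_tps(cranium_template, target)
        assert np.abs(model.weights).max() < 1e-9
        assert model.bending_energy < 1e-8
        np.testing.assert_allclose(model.affine[:, 0], b, atol=1e-9)
        np.testing.assert_allclose(model.affine[:, 1:], A, atol=1e-9)

    def test_interpolation_residual(self, cranium_template, rng):
        target = cranium_template + rng.normal(0, 5, cranium_template.shape)
        model = fit_tps(cranium_template, target)
        residual = np.abs(model(cranium_template) - target).max()
        assert residual < 1e-8

    def test_duplicate_landmarks_named(self, cranium_template):
        ref = cranium_template.copy()
        ref[4] = ref[2]
        with pytest.raises(SingularTpsError, match="2 and 4"):
            fit_tps(ref, cranium_template)

    def test_bending_energy_rigid_invariance(self, cranium_template, rng):
        target = cranium_template + rng.normal(0, 3, cranium_template.shape)
        e0 = fit_tps(cranium_template, target).bending_energy
        rot = random_rotation(rng)
        e1 = fit_tps(cranium_template, target @ rot.T + rng.normal(0, 10, 3)).bending_energy
        np.testing.assert_allclose(e0, e1, rtol=1e-8)


class TestTpsImputation:
    def test_identity_case_exact(self, cranium_scheme, cranium_template):
        mid = cranium_scheme.midline[2]
        missing = np.zeros(len(cranium_template), bool)
        missing[mid] = True
        out = impute_tps(_as_set(cranium_template, missing), cranium_template)
        np.testing.assert_allclose(out.coords[mid], cranium_template[mid], atol=1e-8)
        assert out.provenance["imputed"][mid] == "tps"

    def test_affine_deformation_recovered(self, cranium_scheme, cranium_template, rng):
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        target = cranium_template @ A.T + rng.normal(size=3)
        missing = np.zeros(len(target), bool)
        missing[[1, 10, 20]] = True
        out = impute_tps(_as_set(target, missing), cranium_template)
        np.testing.assert_allclose(out.coords[[1, 10, 20]], target[[1, 10, 20]], atol=1e-8)

    def test_leave_one_out_under_smooth_warp(self, cranium_template):
        # smooth nonlinear warp + small noise: LOO recovery error stays at the
        # noise scale, not the warp scale
        rng = np.random.default_rng(5)
        scale = np.abs(cranium_template).max()
        warped = cranium_template + 0.08 * scale * np.sin(cranium_template / scale * 2.5)
        noise_sd = 0.5
        warped += rng.normal(0, noise_sd, warped.shape)
        errors = []
        for j in range(len(warped)):
            missing = np.zeros(len(warped), bool)
            missing[j] = True
            out = impute_tps(_as_set(warped, missing), cranium_template)
            errors.append(np.linalg.norm(out.coords[j] - warped[j]))
        assert np.median(errors) < 2 * noise_sd * np.sqrt(3)

    def test_missingness_cap_enforced(self, cranium_template):
        missing = np.zeros(len(cranium_template), bool)
        missing[:10] = True  # 10/39 > 20%
        with pytest.raises(ValueError, match="20%"):
            impute_tps(_as_set(cranium_template, missing), cranium_template)


class TestImputeDataset:
    def test_mirror_then_tps_completes_everything(self, cranium_scheme, rng):
        template = make_template(cranium_scheme, seed=3)
        sets = []
        for i in range(8):
            coords = template + rng.normal(0, 0.5, template.shape)
            missing = np.zeros(len(template), bool)
            if i >= 5:
                left, right = cranium_scheme.paired[i]
                missing[left] = True  # mirror-recoverable
                missing[cranium_scheme.midline[0]] = True  # TPS-only
            coords[missing] = np.nan
            sets.append(LandmarkSet(f"s{i}", coords, missing, group="C-group"))
        out = impute_dataset(sets, cranium_scheme)
        assert not any(s.missing.any() for s in out)
        methods = {m for s in out for m in s.provenance.get("imputed", {}).values()}
        assert methods == {"mirror", "tps"}

    def test_never_increases_missing(self, cranium_scheme, rng):
        template = make_template(cranium_scheme, seed=3)
        missing = np.zeros(len(template), bool)
        missing[[cranium_scheme.paired[0][0], cranium_scheme.paired[1][0]]] = True
        lm = _as_set(template + rng.normal(0, 0.5, template.shape), missing)
        before = lm.n_missing
        out = impute_mirror(lm, cranium_scheme)
        assert out.n_missing <= before


class TestIntraObserverError:
    def test_identical_replicates_zero(self, cranium_template):
        reps = {"a": [_as_set(cranium_template) for _ in range(3)]}
        per_landmark, grand = intra_observer_error(reps)
        assert grand < 1e-12
        assert per_landmark.max() < 1e-12

    def test_matches_chi_distribution_mean(self, cranium_template):
        # replicates = truth + isotropic N(0, sigma^2 I): the deviation from the
        # replicate centroid is chi_3 with scale sigma*sqrt(1 - 1/r)
        sigma, r = 0.6, 6
        rng = np.random.default_rng(11)
        reps = {
            f"sp{i}": [
                _as_set(cranium_template + rng.normal(0, sigma, cranium_template.shape))
                for _ in range(r)
            ]
            for i in range(60)
        }
        _, grand = intra_observer_error(reps)
        expected = sigma * np.sqrt(1 - 1 / r) * 2 * np.sqrt(2 / np.pi)
        np.testing.assert_allclose(grand, expected, rtol=0.03)

    def test_reported_precision_fixture(self, cranium_template):
        # six extractions on ten specimens with digitization noise tuned to the
        # reported grand-mean precision of 0.8 mm
        target, r = 0.8, 6
        sigma = target / (np.sqrt(1 - 1 / r) * 2 * np.sqrt(2 / np.pi))
        rng = np.random.default_rng(8)
        reps = {
            f"sp{i}": [
                _as_set(cranium_template + rng.normal(0, sigma, cranium_template.shape))
                for _ in range(r)
            ]
            for i in range(10)
        }
        _, grand = intra_observer_error(reps)
        assert abs(grand - target) < 0.1

    def test_mismatched_k_raises(self, cranium_template):
        reps = {
            "a": [
                _as_set(cranium_template),
                _as_set(cranium_template[:-1]),
            ]
        }
        with pytest.raises(ValueError, match="mismatch"):
            intra_observer_error(reps)
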