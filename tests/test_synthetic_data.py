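import numpy as np
import pytest

from cortexdiff.cortical_grid import LABEL_INTERIOR
from cortexdiff.synthetic_data import (
    FiberPopulation,
    LesionSpec,
    PhantomSpec,
    apply_lesion,
    add_rician_noise,
    default_scheme,
    make_phantom,
    make_study,
    noiseless_signal,
    simulate_signal,
)
from cortexdiff.tensor_models import fa


class TestMakePhantom:
    def test_slab_dimensions(self):
        spec = PhantomSpec(length_mm=8.75, thickness_mm=1.75)
        truth = make_phantom(spec)
        interior = truth.labels.data == LABEL_INTERIOR
        assert interior.sum() == 50 * 10
        assert truth.labels.data.shape == (12, 50)

    def test_annulus_fields_orthonormal(self):
        spec = PhantomSpec(geometry="quarter_annulus")
        truth = make_phantom(spec)
        rib = truth.ribbon
        rad = truth.axes[rib][:, 0, :]
        tan = truth.axes[rib][:, 1, :]
        assert np.allclose(np.linalg.norm(rad, axis=1), 1.0)
        assert np.allclose(np.linalg.norm(tan, axis=1), 1.0)
        assert np.allclose(np.sum(rad * tan, axis=1), 0.0, atol=1e-12)

    def test_determinism(self):
        spec = PhantomSpec()
        t1, t2 = make_phantom(spec, 5), make_phantom(spec, 5)
        assert np.array_equal(t1.lambda_par, t2.lambda_par)
        assert np.array_equal(t1.axes, t2.axes)

    def test_too_thin_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(thickness_mm=0.3)

    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            PhantomSpec(
                populations=(
                    FiberPopulation("radial", fraction=0.6),
                    FiberPopulation("tangential", fraction=0.6),
                )
            )


class TestSimulateSignal:
    def test_b0_equals_s0(self):
        spec = PhantomSpec(s0=2.0)
        truth = make_phantom(spec)
        S = noiseless_signal(truth)
        b0 = S[truth.ribbon][:, truth.scheme.is_b0]
        assert np.allclose(b0, 2.0)

    def test_aligned_gradient_closed_form(self):
        # single radial population; probe the volume whose gradient is
        # closest to the radial axis at the highest shell
        spec = PhantomSpec(
            populations=(FiberPopulation("radial", 1.7e-3, 0.3e-3, 1.0),)
        )
        truth = make_phantom(spec)
        scheme = truth.scheme
        S = noiseless_signal(truth)
        u = truth.axes[2, 5, 0]
        weighted = np.flatnonzero(scheme.bvals == 2010.0)
        align = np.abs(scheme.bvecs[weighted] @ u)
        m = weighted[np.argmax(align)]
        c2 = float(align.max()) ** 2
        expect = np.exp(-2010.0 * (0.3e-3 + (1.7e-3 - 0.3e-3) * c2))
        assert S[2, 5, m] == pytest.approx(expect, abs=1e-9)

    def test_mixture_linearity(self):
        mix = PhantomSpec()
        only_rad = PhantomSpec(
            populations=(FiberPopulation("radial", 1.7e-3, 0.3e-3, 1.0),)
        )
        only_tan = PhantomSpec(
            populations=(FiberPopulation("tangential", 1.2e-3, 0.4e-3, 1.0),)
        )
        Sm = noiseless_signal(make_phantom(mix))
        Sr = noiseless_signal(make_phantom(only_rad))
        St = noiseless_signal(make_phantom(only_tan))
        assert np.allclose(Sm, 0.5 * Sr + 0.5 * St, atol=1e-12)

    def test_rician_noise_floor(self):
        """Mean noisy magnitude exceeds the noiseless signal at high b."""
        rng = np.random.default_rng(0)
        S = np.full(10_000, 0.05)  # low SNR regime
        noisy = add_rician_noise(S, s0=1.0, snr_b0=20.0, rng=rng)
        assert noisy.mean() > S.mean()

    def test_infinite_snr_noiseless(self):
        spec = PhantomSpec(snr_b0=np.inf)
        truth = make_phantom(spec)
        s1 = simulate_signal(truth, snr_b0=np.inf, seed=1)
        s2 = simulate_signal(truth, snr_b0=np.inf, seed=2)
        assert np.array_equal(s1, s2)


class TestLesionsAndStudies:
    def test_lesion_confined_to_block_in_truth(self):
        spec = PhantomSpec()
        lesion = LesionSpec((20, 30), (3, 7), "radial", 0.7)
        base = make_phantom(spec)
        les = apply_lesion(base, spec, lesion)
        changed = les.lambda_par != base.lambda_par
        assert changed.any()
        region = changed.any(axis=-1)
        # FA of the radial population drops only inside the block
        assert np.all(
            (base.line_frac[region] >= 0.4) & (base.line_frac[region] < 0.6)
        )
        assert np.all(
            (base.depth_frac[region] >= 0.3) & (base.depth_frac[region] < 0.7)
        )
        fa_les = fa(
            les.lambda_par[region][:, 0],
            les.lambda_perp[region][:, 0],
            les.lambda_perp[region][:, 0],
        )
        fa_base = fa(
            base.lambda_par[region][:, 0],
            base.lambda_perp[region][:, 0],
            base.lambda_perp[region][:, 0],
        )
        assert np.all(fa_les < fa_base)

    def test_empty_lesion_region_rejected(self):
        spec = PhantomSpec()
        with pytest.raises(ValueError):
            apply_lesion(
                make_phantom(spec), spec, LesionSpec((20, 20), (3, 7))
            )

    def test_missing_target_population_rejected(self):
        spec = PhantomSpec(
            populations=(FiberPopulation("radial", fraction=1.0),)
        )
        with pytest.raises(ValueError):
            apply_lesion(
                make_phantom(spec), spec, LesionSpec(target="tangential")
            )

    def test_study_determinism(self):
        spec = PhantomSpec(pixel_size=0.35)
        les = LesionSpec()
        s1 = make_study(spec, les, n_a=2, n_b=2, seed=9)
        s2 = make_study(spec, les, n_a=2, n_b=2, seed=9)
        for x, y in zip(s1.group_a + s1.group_b, s2.group_a + s2.group_b):
            assert np.array_equal(x, y)

    def test_identity_lesion_groups_exchangeable(self):
        spec = PhantomSpec(pixel_size=0.35, snr_b0=np.inf)
        les = LesionSpec(lambda_par_factor=1.0, lambda_perp_factor=1.0)
        study = make_study(spec, les, n_a=2, n_b=2, subject_cv=0.0, seed=3)
        # no jitter, no noise, unit lesion factor: all subjects identical
        assert np.allclose(study.group_a[0], study.group_b[0])

    def test_subject_jitter_creates_between_subject_variance(self):
        spec = PhantomSpec(pixel_size=0.35, snr_b0=np.inf)
        study = make_study(spec, None, n_a=3, n_b=2, subject_cv=0.05, seed=4)
        assert not np.allclose(study.group_a[0], study.group_a[1])


class TestScheme:
    def test_default_protocol_counts(self):
        sch = default_scheme()
        assert sch.n_volumes == 285
        assert sch.n_b0 == 15
        assert len(sch.shells) == 3

    def test_directions_cover_sphere(self):
        sch = default_scheme()
        dirs = sch.bvecs[~sch.is_b0][:90]
        # nearest-neighbor angle spread of a uniform 90-point set
        dots = np.clip(np.abs(dirs @ dirs.T) - np.eye(90), 0, 1)
        nn = np.degrees(np.arccos(dots.max(axis=1)))
        assert nn.max() < 30.0
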