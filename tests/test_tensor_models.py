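import numpy as np
import pytest

from cortexdiff.io_core import AcquisitionScheme
from cortexdiff.tensor_models import (
    ConditioningError,
    FitError,
    fa,
    fit_dti,
    fit_multi_tensor,
    fit_multi_tensor_batch,
    md,
)

from conftest import multi_tensor_signal

RAD = (1.7e-3, 0.3e-3)  # canonical prolate compartment


def closed_form_fa(l1, l2, l3):
    """Independent arithmetic oracle for FA."""
    m = (l1 + l2 + l3) / 3
    num = (l1 - m) ** 2 + (l2 - m) ** 2 + (l3 - m) ** 2
    den = l1**2 + l2**2 + l3**2
    return np.sqrt(1.5 * num / den)


class TestScalarMetricProperties:
    """Invariants of FA/MD over the whole eigenvalue domain."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    eigs = st.tuples(
        st.floats(0.0, 4e-3), st.floats(0.0, 4e-3), st.floats(0.0, 4e-3)
    )

    @given(eigs)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_fa_bounded_and_permutation_invariant(self, l):
        l1, l2, l3 = l
        v = fa(l1, l2, l3)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(fa(l3, l1, l2), abs=1e-12)

    @given(eigs, st.floats(1e-3, 1e3))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_fa_scale_invariant_md_linear(self, l, k):
        l1, l2, l3 = l
        assert fa(k * l1, k * l2, k * l3) == pytest.approx(
            fa(l1, l2, l3), abs=1e-9
        )
        assert md(k * l1, k * l2, k * l3) == pytest.approx(
            k * md(l1, l2, l3), rel=1e-12, abs=1e-300
        )


class TestScalarMetrics:
    @pytest.mark.parametrize("d", [1e-4, 1e-3, 3e-3])
    def test_isotropic(self, d):
        assert fa(d, d, d) == pytest.approx(0.0, abs=1e-12)
        assert md(d, d, d) == pytest.approx(d)

    def test_degenerate_zero(self):
        assert fa(0.0, 0.0, 0.0) == 0.0
        assert md(0.0, 0.0, 0.0) == 0.0

    def test_against_arithmetic_oracle(self):
        l = (1.7e-3, 0.3e-3, 0.3e-3)
        assert fa(*l) == pytest.approx(closed_form_fa(*l), abs=1e-12)
        assert md(*l) == pytest.approx(0.7667e-3, abs=1e-7)

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            fa(1e-3, -1e-4, 1e-4)
        with pytest.raises(ValueError):
            md(-1e-3, 1e-4, 1e-4)


class TestDTI:
    def test_isotropic_signal(self, scheme):
        sig = np.exp(-scheme.bvals * 1.0e-3)
        comp, s0 = fit_dti(sig, scheme)
        assert comp.md == pytest.approx(1.0e-3, abs=1e-6)
        assert comp.fa == pytest.approx(0.0, abs=1e-3)
        assert s0 == pytest.approx(1.0, abs=1e-6)

    def test_anisotropic_recovery(self, scheme, signal_factory):
        sig = signal_factory([((0.6, 0.8, 0.0), *RAD, 1.0)], s0=2.5)
        comp, s0 = fit_dti(sig, scheme)
        assert np.allclose(
            comp.eigenvalues, [1.7e-3, 0.3e-3, 0.3e-3], atol=1e-6
        )
        assert comp.fa == pytest.approx(
            closed_form_fa(1.7e-3, 0.3e-3, 0.3e-3), abs=1e-4
        )
        assert abs(comp.principal_axis @ [0.6, 0.8, 0.0]) > np.cos(
            np.deg2rad(1.0)
        )
        assert s0 == pytest.approx(2.5, rel=1e-6)

    def test_zero_b0_signal_rejected(self, scheme):
        sig = np.exp(-scheme.bvals * 1e-3)
        sig[0] = 0.0
        with pytest.raises(FitError):
            fit_dti(sig, scheme)

    def test_negative_signal_rejected(self, scheme):
        sig = np.exp(-scheme.bvals * 1e-3)
        sig[40] = -0.1
        with pytest.raises(FitError):
            fit_dti(sig, scheme)

    def test_coplanar_directions_ill_conditioned(self):
        # all gradients in the x-y plane cannot determine Dzz
        n = 30
        ang = np.linspace(0, np.pi, n, endpoint=False)
        bvecs = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
        bvals = np.full(n, 1000.0)
        bvals[0] = 0.0
        bvecs[0] = 0.0
        sch = AcquisitionScheme(bvals, bvecs)
        with pytest.raises(ConditioningError):
            fit_dti(np.exp(-bvals * 1e-3), sch)


class TestMultiTensor:
    def test_single_compartment(self, scheme, signal_factory):
        u = np.array([0.3, -0.5, 0.81])
        u /= np.linalg.norm(u)
        fit = fit_multi_tensor(signal_factory([(u, *RAD, 1.0)]), scheme)
        assert fit.n_selected == 1
        c = fit.compartments[0]
        ang = np.degrees(np.arccos(min(abs(c.principal_axis @ u), 1.0)))
        assert ang < 1.0
        assert np.allclose(c.eigenvalues, [1.7e-3, 0.3e-3, 0.3e-3], atol=2e-5)

    def test_orthogonal_crossing(self, scheme, signal_factory):
        fit = fit_multi_tensor(
            signal_factory(
                [((1, 0, 0), *RAD, 0.5), ((0, 1, 0), *RAD, 0.5)]
            ),
            scheme,
        )
        assert fit.n_selected == 2
        fr = sorted(c.fraction for c in fit.compartments)
        assert fr == pytest.approx([0.5, 0.5], abs=0.02)
        for c in fit.compartments:
            best = max(
                abs(c.principal_axis @ np.array([1.0, 0, 0])),
                abs(c.principal_axis @ np.array([0, 1.0, 0])),
            )
            assert np.degrees(np.arccos(min(best, 1.0))) < 2.0

    def test_shallow_crossing_merges(self, scheme, signal_factory):
        a = np.deg2rad(10)
        fit = fit_multi_tensor(
            signal_factory(
                [
                    ((1, 0, 0), *RAD, 0.5),
                    ((np.cos(a), np.sin(a), 0), *RAD, 0.5),
                ]
            ),
            scheme,
        )
        assert fit.n_selected == 1

    def test_sweep_transition_near_merge_angle(self, scheme):
        """Around the merge angle the 1->2 switch is sharp."""
        angles = np.arange(17, 24)
        Y = np.stack(
            [
                multi_tensor_signal(
                    scheme,
                    [
                        ((1, 0, 0), *RAD, 0.5),
                        (
                            (np.cos(np.deg2rad(t)), np.sin(np.deg2rad(t)), 0),
                            *RAD,
                            0.5,
                        ),
                    ],
                )
                for t in angles
            ]
        )
        ns = [f.n_selected for f in fit_multi_tensor_batch(Y, scheme)]
        assert ns == [1 if t < 20 else 2 for t in angles]

    def test_fraction_conservation_and_separation(self, scheme, signal_factory):
        fit = fit_multi_tensor(
            signal_factory(
                [((1, 0, 0), *RAD, 0.6), ((0.5, 0.866, 0), 1.2e-3, 0.4e-3, 0.4)]
            ),
            scheme,
        )
        assert sum(c.fraction for c in fit.compartments) == pytest.approx(
            1.0, abs=1e-6
        )
        for i, a in enumerate(fit.compartments):
            for b in fit.compartments[i + 1 :]:
                ang = np.degrees(
                    np.arccos(
                        min(abs(a.principal_axis @ b.principal_axis), 1.0)
                    )
                )
                assert ang >= 20.0 - 1e-2

    def test_antipodal_symmetry(self, scheme, signal_factory):
        """Negating gradient directions leaves the fit unchanged."""
        sig = multi_tensor_signal(
            scheme, [((1, 0, 0), *RAD, 0.5), ((0, 1, 0), *RAD, 0.5)]
        )
        flipped = AcquisitionScheme(scheme.bvals, -scheme.bvecs)
        f1 = fit_multi_tensor(sig, scheme)
        f2 = fit_multi_tensor(sig, flipped)
        assert f1.n_selected == f2.n_selected
        m1 = sorted(c.fa for c in f1.compartments)
        m2 = sorted(c.fa for c in f2.compartments)
        assert m1 == pytest.approx(m2, abs=1e-6)

    def test_noise_robustness_snr30(self, scheme):
        """Rician SNR 30, 90-degree crossing: median errors stay small."""
        rng = np.random.default_rng(11)
        V = 100
        S = multi_tensor_signal(
            scheme, [((1, 0, 0), *RAD, 0.5), ((0, 1, 0), *RAD, 0.5)]
        )
        sigma = 1.0 / 30.0
        Y = np.sqrt(
            (S[None] + rng.normal(0, sigma, (V, scheme.n_volumes))) ** 2
            + rng.normal(0, sigma, (V, scheme.n_volumes)) ** 2
        )
        fits = fit_multi_tensor_batch(Y, scheme)
        ang, ev = [], []
        for f in fits:
            if f.n_selected < 2:
                continue
            for c in f.compartments:
                best = max(
                    abs(c.principal_axis @ np.array([1.0, 0, 0])),
                    abs(c.principal_axis @ np.array([0, 1.0, 0])),
                )
                ang.append(np.degrees(np.arccos(min(best, 1.0))))
                ev.append(abs(c.eigenvalues[0] - 1.7e-3) / 1.7e-3)
                ev.append(abs(c.eigenvalues[1] - 0.3e-3) / 0.3e-3)
        assert np.mean([f.n_selected == 2 for f in fits]) > 0.9
        assert np.median(ang) < 10.0
        assert np.median(ev) < 0.10

    def test_single_shell_rejected(self):
        bvals = np.concatenate([[0.0], np.full(30, 1000.0)])
        rng = np.random.default_rng(2)
        v = rng.normal(size=(31, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        v[0] = 0.0
        sch = AcquisitionScheme(bvals, v)
        with pytest.raises(ConditioningError):
            fit_multi_tensor(np.exp(-bvals * 1e-3), sch)
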