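import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gctetra.descriptors import (
    NTOWeights,
    OmegaMatrix,
    describe_state,
    directed_ct,
    excitation_descriptors,
    fragment_weights,
    resonance_descriptors,
)
from gctetra.errors import InvalidWeightsError, UndefinedStateError


def brute_force_descriptors(m):
    """Independent direct-summation evaluation of all Omega descriptors."""
    w = m / m.sum()
    F = m.shape[0]
    h = np.array([sum(w[a, b] for b in range(F)) for a in range(F)])
    e = np.array([sum(w[a, b] for a in range(F)) for b in range(F)])
    ct = sum(w[a, b] for a in range(F) for b in range(F) if a != b)
    pr_h = 1.0 / sum(x * x for x in h)
    pr_e = 1.0 / sum(x * x for x in e)
    pos_h = sum((a + 1) * h[a] for a in range(F))
    pos_e = sum((b + 1) * e[b] for b in range(F))
    return ct, h, e, pr_h, pr_e, pos_h, pos_e


omega_matrices = arrays(
    float, (4, 4), elements=st.floats(0.0, 1.0, allow_nan=False)
).filter(lambda m: m.sum() > 1e-6)


class TestFragmentWeights:
    def test_pure_local_excitation(self):
        m = np.zeros((4, 4))
        m[0, 0] = 1.0
        w, h, e = fragment_weights(OmegaMatrix(m))
        assert h[0] == 1.0 and e[0] == 1.0 and h[1:].sum() == 0

    def test_pure_charge_transfer(self):
        m = np.zeros((4, 4))
        m[0, 1] = 1.0
        _, h, e = fragment_weights(OmegaMatrix(m))
        assert h[0] == 1.0 and e[1] == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedStateError):
            fragment_weights(OmegaMatrix(np.zeros((4, 4))))

    @given(omega_matrices)
    @settings(max_examples=200, deadline=None)
    def test_marginals_match_brute_force(self, m):
        w, h, e = fragment_weights(OmegaMatrix(m))
        _, h_ref, e_ref, *_ = brute_force_descriptors(m)
        assert abs(h.sum() - 1.0) < 1e-12
        assert abs(e.sum() - 1.0) < 1e-12
        assert abs(w.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(h, h_ref, atol=1e-12)
        np.testing.assert_allclose(e, e_ref, atol=1e-12)


class TestExcitationDescriptors:
    def test_local_excitation_signature(self):
        m = np.zeros((2, 2))
        m[0, 0] = 1.0
        d = excitation_descriptors(OmegaMatrix(m))
        assert d.ct == 0.0 and d.pr == 1.0 and d.pos_h == 1.0 and d.pos_e == 1.0

    def test_charge_resonance_signature(self):
        """Symmetric charge exchange: CT=1, PR=2, positions midway."""
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = 0.5
        d = excitation_descriptors(OmegaMatrix(m))
        assert d.ct == pytest.approx(1.0)
        assert d.pr_h == pytest.approx(2.0) and d.pr_e == pytest.approx(2.0)
        assert d.pr == pytest.approx(2.0)
        assert d.pos_h == pytest.approx(1.5) and d.pos_e == pytest.approx(1.5)

    def test_excimer_signature(self):
        """Half local, half charge-transfer: CT=0.5, asymmetric PR."""
        m = np.zeros((2, 2))
        m[0, 0] = m[0, 1] = 0.5
        d = excitation_descriptors(OmegaMatrix(m))
        assert d.ct == pytest.approx(0.5)
        assert d.pr_h == pytest.approx(1.0)
        assert d.pr_e == pytest.approx(2.0)
        assert d.pr == pytest.approx(1.5)

    @given(omega_matrices)
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_ranges(self, m):
        d = excitation_descriptors(OmegaMatrix(m))
        ct, h, e, pr_h, pr_e, pos_h, pos_e = brute_force_descriptors(m)
        assert d.ct == pytest.approx(ct, abs=1e-12)
        assert d.pr_h == pytest.approx(pr_h, abs=1e-9)
        assert d.pos_h == pytest.approx(pos_h, abs=1e-12)
        assert d.pos_e == pytest.approx(pos_e, abs=1e-12)
        eps = 1e-9
        assert -eps <= d.ct <= 1.0 + eps
        assert 1.0 - eps <= d.pr_h <= 4.0 + eps and 1.0 - eps <= d.pr_e <= 4.0 + eps
        assert 1.0 - eps <= d.pos_h <= 4.0 + eps and 1.0 - eps <= d.pos_e <= 4.0 + eps

    @given(omega_matrices, st.floats(1e-6, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, m, scale):
        d1 = excitation_descriptors(OmegaMatrix(m))
        d2 = excitation_descriptors(OmegaMatrix(m * scale))
        assert d1.ct == pytest.approx(d2.ct, abs=1e-10)
        assert d1.pr == pytest.approx(d2.pr, rel=1e-10)

    @given(omega_matrices, st.permutations(range(4)))
    @settings(max_examples=100, deadline=None)
    def test_permutation_equivariance(self, m, perm):
        perm = np.asarray(perm)
        d1 = excitation_descriptors(OmegaMatrix(m))
        d2 = excitation_descriptors(OmegaMatrix(m[np.ix_(perm, perm)]))
        assert d1.ct == pytest.approx(d2.ct, abs=1e-12)
        assert d1.pr == pytest.approx(d2.pr, rel=1e-10)
        np.testing.assert_allclose(d2.hole_weights, d1.hole_weights[perm], atol=1e-12)
        np.testing.assert_allclose(d2.electron_weights, d1.electron_weights[perm], atol=1e-12)


class TestResonanceDescriptors:
    def test_single_configuration(self):
        pr_nto, s_he, z_he = resonance_descriptors(NTOWeights(np.array([1.0])))
        assert pr_nto == 1.0 and s_he == 0.0 and z_he == 1.0

    def test_two_equal_configurations(self):
        pr_nto, s_he, z_he = resonance_descriptors(NTOWeights(np.array([0.5, 0.5])))
        assert pr_nto == pytest.approx(2.0)
        assert s_he == pytest.approx(1.0)
        assert z_he == pytest.approx(2.0)

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(InvalidWeightsError):
            NTOWeights(np.array([0.5, -0.1]))

    @given(arrays(float, 6, elements=st.floats(1e-6, 1.0)))
    @settings(max_examples=200, deadline=None)
    def test_entropy_participation_inequality(self, lam):
        """Z_HE <= PR_NTO <= n for any weight spectrum (Renyi ordering)."""
        pr_nto, s_he, z_he = resonance_descriptors(NTOWeights(lam))
        p = np.sort(lam)[::-1] / lam.sum()
        pr_ref = 1.0 / np.sum(p * p)
        s_ref = -np.sum(p * np.log2(p))
        assert pr_nto == pytest.approx(pr_ref, rel=1e-10)
        assert z_he == pytest.approx(2.0 ** s_ref, rel=1e-10)
        assert z_he >= pr_nto - 1e-9
        assert pr_nto <= len(lam) + 1e-9
        assert z_he >= 1.0 - 1e-12


def test_describe_state_combines_channels():
    m = np.zeros((4, 4))
    m[0, 2] = 0.9
    m[0, 0] = 0.1
    d = describe_state(OmegaMatrix(m), NTOWeights(np.array([0.9, 0.1])))
    assert d.ct == pytest.approx(0.9)
    assert d.pr_nto is not None and d.z_he is not None
    assert d.hole_fragment == 1 and d.electron_fragment == 3


def test_directed_ct_sums_block():
    m = np.zeros((4, 4))
    m[0, 2] = 0.5   # G1 -> C3
    m[1, 3] = 0.25  # G2 -> C4
    m[2, 0] = 0.25  # C -> G, excluded from the directed sum
    val = directed_ct(OmegaMatrix(m), hole_fragments=[1, 2], electron_fragments=[3, 4])
    assert val == pytest.approx(0.75)
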