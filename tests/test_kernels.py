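"""Structure functions and scalar coalescent kernels."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from groupsigma.errors import InvalidParameterError
from groupsigma.kernels import (
    MigrationPattern,
    ModelParams,
    global_coefficients,
    global_pattern,
    mutation_alpha,
    mutation_structure,
    pair_kernels,
    range_pattern,
    triple_kernels,
    well_mixed_pattern,
)


class TestModelParams:
    def test_scaled_rates(self):
        p = ModelParams(N=100, M=9, u=0.07, v=0.1)
        assert p.mu == pytest.approx(7.0)
        assert p.nu == pytest.approx(10.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=2, M=2, u=0.1, v=0.1),  # three-lineage kernels need N >= 3
            dict(N=10, M=0, u=0.1, v=0.1),
            dict(N=10, M=2, u=-0.1, v=0.1),
            dict(N=10, M=2, u=0.1, v=1.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ModelParams(**kwargs)


class TestPatterns:
    def test_global_pattern_values(self):
        pat = global_pattern(19)
        assert pat.value(19) == pytest.approx(1.0, abs=1e-12)
        pat9 = global_pattern(9)
        assert pat9.value(3) == pytest.approx(-1.0 / 8.0, abs=1e-12)
        assert global_pattern(2).value(1) == pytest.approx(-1.0, abs=1e-12)

    def test_global_pattern_needs_two_groups(self):
        with pytest.raises(InvalidParameterError):
            global_pattern(1)

    def test_range_pattern_examples(self):
        pat = range_pattern(9, 4)
        assert pat.value(9) == pytest.approx(1.0, abs=1e-12)
        # for odd M, the maximal range equals global migration
        for x in range(1, 9):
            assert pat.value(x) == pytest.approx(-1.0 / 8.0, abs=1e-12)
        two = range_pattern(9, 2)
        expected = (math.cos(2 * math.pi / 9) + math.cos(4 * math.pi / 9)) / 2
        assert two.value(1) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.46985, abs=1e-5)

    @pytest.mark.parametrize("r", [0, 5, -1])
    def test_range_pattern_rejects_bad_range(self, r):
        with pytest.raises(InvalidParameterError):
            range_pattern(9, r)

    @given(M=st.integers(2, 64), data=st.data())
    @settings(derandomize=True, max_examples=120, deadline=None)
    def test_pattern_invariants(self, M, data):
        """f(M)=1, mirror symmetry, boundedness for every generated pattern."""
        r = data.draw(st.integers(1, M // 2))
        for pat in (global_pattern(M), range_pattern(M, r)):
            assert pat.value(M) == pytest.approx(1.0, abs=1e-12)
            assert all(abs(f) <= 1 + 1e-12 for f in pat.f)
            for x in range(1, M):
                assert pat.value(x) == pytest.approx(pat.value(M - x), abs=1e-12)

    @pytest.mark.parametrize("M", [3, 5, 9, 17, 63])
    def test_odd_m_maximal_range_equals_global(self, M):
        rp = range_pattern(M, M // 2)
        gp = global_pattern(M)
        assert rp.f == pytest.approx(gp.f, abs=1e-12)

    @pytest.mark.parametrize("M", [2, 4, 10])
    def test_even_m_half_range_equals_global(self, M):
        assert range_pattern(M, M // 2).f == pytest.approx(global_pattern(M).f, abs=1e-12)

    def test_pattern_type_rejects_asymmetric_function(self):
        with pytest.raises(InvalidParameterError):
            MigrationPattern(M=3, f=(0.3, 0.1, 1.0))

    def test_well_mixed_pattern(self):
        pat = well_mixed_pattern()
        assert pat.M == 1 and pat.f == (1.0,)


class TestMutationStructure:
    @pytest.mark.parametrize("x,expected", [(2, 1.0), (1, 0.0), (0, 1.0), (-3, 0.0)])
    def test_two_strategy_values(self, x, expected):
        assert mutation_structure(x) == pytest.approx(expected, abs=1e-12)


class TestScalarKernels:
    def test_pair_kernels_frozen_values(self):
        # co-location kernel is exactly 1 when lineages never separate
        psi1, _ = pair_kernels(1.0, ModelParams(N=50, M=3, u=0.2, v=0.7))
        assert psi1 == pytest.approx(1.0, abs=1e-12)
        _, psi2 = pair_kernels(1.0, ModelParams(N=100, M=9, u=0.07, v=0.3))
        assert psi2 == pytest.approx(0.93 / 7.93, abs=1e-12)  # equals alpha_1
        psi1, _ = pair_kernels(-1.0 / 8.0, ModelParams(N=100, M=9, u=0.07, v=0.1))
        assert psi1 == pytest.approx(0.8875 / 12.1375, abs=1e-12)

    def test_pair_kernel_equals_alpha_at_f_one(self):
        p = ModelParams(N=100, M=9, u=0.07, v=0.3)
        assert pair_kernels(1.0, p)[1] == pytest.approx(mutation_alpha(p), abs=1e-14)

    def test_triple_kernels_frozen_values(self):
        p0 = ModelParams(N=37, M=4, u=0.0, v=0.6)
        assert triple_kernels(1.0, p0) == pytest.approx((1.0, 1.0, 1.0), abs=1e-12)
        p = ModelParams(N=100, M=9, u=0.07, v=0.3)
        phi3 = triple_kernels(1.0, p)[2]
        assert phi3 == pytest.approx(1.93 / (2 + 2 * 98 * 0.07 / 3), abs=1e-12)
        assert phi3 == pytest.approx(0.293611, abs=1e-6)

    @given(
        f=st.floats(-1.0, 1.0),
        u=st.floats(0.0, 1.0),
        v=st.floats(0.0, 1.0),
        N=st.integers(3, 500),
    )
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_kernel_ordering_and_bounds(self, f, u, v, N):
        """Psi1 <= 1 always; wherever the shared numerator 1 - v(1-f) is
        non-negative (always true for v <= 1/2 or f >= 0), all kernels lie in
        [0, 1] and Psi2 <= Psi1."""
        p = ModelParams(N=N, M=2, u=u, v=v)
        psi1, psi2 = pair_kernels(f, p)
        phis = triple_kernels(f, p)
        assert psi1 <= 1.0 + 1e-12
        if 1.0 - v * (1.0 - f) >= 0.0:
            assert psi2 <= psi1 + 1e-12
            assert -1e-12 <= psi2 and psi1 <= 1.0 + 1e-12
            assert all(-1e-12 <= x <= 1.0 + 1e-12 for x in phis)

    def test_psi2_equals_psi1_iff_no_mutation(self):
        p0 = ModelParams(N=20, M=3, u=0.0, v=0.4)
        psi1, psi2 = pair_kernels(0.2, p0)
        assert psi1 == pytest.approx(psi2, abs=1e-14)
        p1 = ModelParams(N=20, M=3, u=1e-4, v=0.4)
        psi1, psi2 = pair_kernels(0.2, p1)
        assert psi2 < psi1


class TestMutationAlpha:
    @pytest.mark.parametrize(
        "u,N,expected", [(0.0, 10, 1.0), (1.0, 10, 0.0), (0.07, 100, 0.93 / 7.93)]
    )
    def test_values(self, u, N, expected):
        assert mutation_alpha(ModelParams(N=N, M=2, u=u, v=0.1)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_decreasing_in_u(self):
        alphas = [mutation_alpha(ModelParams(N=30, M=2, u=u, v=0.1))
                  for u in (0.01, 0.1, 0.3, 0.7, 1.0)]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))


class TestThreeAlphaIdentity:
    @pytest.mark.parametrize("u", [0.01, 0.07, 0.3, 0.8, 1.0])
    @pytest.mark.parametrize("N", [3, 10, 100, 1000])
    def test_identity_on_grid(self, u, N):
        """2(Phi1(1) a1 + Phi2(1) + Phi3(1) a1) = 6 a1 for all (u, N)."""
        p = ModelParams(N=N, M=5, u=u, v=0.37)
        a1 = mutation_alpha(p)
        phi1, phi2, phi3 = triple_kernels(1.0, p)
        assert 2 * (phi1 * a1 + phi2 + phi3 * a1) == pytest.approx(6 * a1, abs=1e-12)

    @pytest.mark.parametrize("u", [0.05, 0.5, 0.95])
    @pytest.mark.parametrize("N", [4, 50, 300])
    def test_equivalent_psi_form(self, u, N):
        """3 Psi1(1) + 3 Psi2(1) - 2 Theta(1) = 3 (1 - alpha_1)."""
        p = ModelParams(N=N, M=3, u=u, v=0.81)
        a1 = mutation_alpha(p)
        psi1, psi2 = pair_kernels(1.0, p)
        phi1, phi2, phi3 = triple_kernels(1.0, p)
        theta = phi1 * psi2 + phi2 * psi1 + phi3 * a1
        assert 3 * psi1 + 3 * psi2 - 2 * theta == pytest.approx(3 * (1 - a1), abs=1e-12)


class TestGlobalCoefficients:
    def test_no_migration_limits(self):
        p = ModelParams(N=40, M=6, u=0.2, v=0.0)
        c = global_coefficients(p)
        assert c.alpha2 == pytest.approx(1.0, abs=1e-14)
        assert c.alpha3 == pytest.approx(c.alpha1, abs=1e-14)

    def test_full_migration_zeroes(self):
        M = 5
        p = ModelParams(N=40, M=M, u=0.2, v=(M - 1) / M)
        c = global_coefficients(p)
        assert c.alpha2 == pytest.approx(0.0, abs=1e-14)
        assert c.alpha3 == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize(
        "N,M,u,v", [(10, 3, 0.3, 0.2), (100, 19, 0.07, 0.9), (7, 2, 0.9, 0.5)]
    )
    def test_coefficients_are_kernels_at_global_f(self, N, M, u, v):
        """alpha2/alpha3 are the pair kernels and tau1..tau3 the (reordered)
        triple kernels evaluated at the off-diagonal global value -1/(M-1)."""
        p = ModelParams(N=N, M=M, u=u, v=v)
        c = global_coefficients(p)
        f = -1.0 / (M - 1)
        psi1, psi2 = pair_kernels(f, p)
        phi1, phi2, phi3 = triple_kernels(f, p)
        assert c.alpha2 == pytest.approx(psi1, abs=1e-12)
        assert c.alpha3 == pytest.approx(psi2, abs=1e-12)
        assert c.tau1 == pytest.approx(phi3, abs=1e-12)
        assert c.tau2 == pytest.approx(phi2, abs=1e-12)
        assert c.tau3 == pytest.approx(phi1, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            global_coefficients(ModelParams(N=10, M=1, u=0.1, v=0.1))
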