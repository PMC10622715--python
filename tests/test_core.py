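"""Constructions, optiscales and the Kabirian coefficient."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optinalysis import (
    AutomorphicParityError,
    DegenerateStructureError,
    InvalidParameterError,
    OpticalDistanceScale,
    PairingLengthError,
    PairingStyle,
    Regime,
    Sign,
    build_optiscale,
    central_rotation,
    classify_regime,
    construct_autoreflective,
    construct_isoreflective,
    isomorphic_sums,
    kc_automorphic,
    kc_isomorphic,
    kc_of_construction,
    numeration,
    optical_moment,
    pericentral_rotation,
    sum_of_scalements,
)

# structures of small non-degenerate values for property tests
positive_structures = st.lists(
    st.floats(min_value=0.5, max_value=500.0, allow_nan=False),
    min_size=1,
    max_size=50,
)


class TestOptiscale:
    @pytest.mark.parametrize(
        "n, k, sign, expected",
        [
            (6, 1, Sign.POSITIVE, tuple(range(1, 14))),
            (1, 1, Sign.POSITIVE, (1, 2, 3)),
            (2, 0.5, Sign.NEGATIVE, (-0.5, -1, -1.5, -2, -2.5)),
        ],
    )
    def test_ranks(self, n, k, sign, expected):
        scale = build_optiscale(n, interval=k, sign=sign)
        assert scale.ranks == pytest.approx(expected)
        assert scale.length == 2 * n + 1

    def test_median_rank_of_thirteen_rank_scale(self):
        assert build_optiscale(6).median_rank == 7

    @pytest.mark.parametrize("n, k", [(0, 1), (-1, 1), (3, 0), (3, -2.0)])
    def test_invalid_parameters(self, n, k):
        with pytest.raises(InvalidParameterError):
            build_optiscale(n, interval=k)


class TestConstructions:
    def test_head_to_head_layout_of_worked_pair(self, worked_pair):
        _, _, x, y = worked_pair
        c = construct_isoreflective(x, y)
        assert c.layout == (135, 126, 111, 0, 126, 135, 0, 135, 126, 0, 151, 0, 135)
        assert c.n_dimensions == 6
        assert c.left == tuple(x) and c.right == tuple(y)

    def test_single_element_pair(self):
        c = construct_isoreflective([1], [2], delta=0)
        assert c.layout == (1, 0, 2)

    def test_tail_to_tail_layout(self):
        c = construct_isoreflective([1, 2], [3, 4], PairingStyle.TAIL_TO_TAIL, delta=5)
        assert c.layout == (2, 1, 5, 3, 4)

    def test_length_mismatch_names_both_lengths(self):
        with pytest.raises(PairingLengthError, match="3 and 2"):
            construct_isoreflective([1, 2, 3], [1, 2])

    def test_autoreflective_uses_middle_element_as_centre(self):
        c = construct_autoreflective([1, 2, 3, 2, 1])
        assert c.layout == (1, 2, 3, 2, 1)
        assert c.delta == 3
        assert c.n_dimensions == 2

    def test_autoreflective_rejects_even_length(self):
        with pytest.raises(AutomorphicParityError, match="pad"):
            construct_autoreflective([1, 2, 3, 4])

    def test_autoreflective_rejects_singleton(self):
        with pytest.raises(InvalidParameterError):
            construct_autoreflective([5])


class TestSums:
    def test_worked_pair_sums_are_exact_integers(self, worked_pair):
        _, _, x, y = worked_pair
        num, den = isomorphic_sums(x, y)
        assert num == 8260
        assert den == 7790

    def test_scalement_sum_small_cases(self):
        c = construct_isoreflective([1], [1], delta=0)
        assert sum_of_scalements(c) == 1 * 1 + 3 * 1
        z = construct_isoreflective([0, 0], [0, 0], delta=0)
        assert sum_of_scalements(z) == 0

    def test_numeration_is_median_rank_times_total(self, worked_pair):
        _, _, x, y = worked_pair
        c = construct_isoreflective(x, y)
        assert numeration(c) == 7 * sum(c.layout)


class TestKabirianCoefficient:
    def test_worked_pair_coefficient(self, worked_pair):
        _, _, x, y = worked_pair
        assert kc_isomorphic(x, y) == pytest.approx(1.060334, abs=5e-7)

    def test_reference_first_and_variant_first_coefficients(self):
        from optinalysis import encode_sequence

        ref = encode_sequence("CTAGCTAGCTAG")
        var = encode_sequence("GTAGCTAGCTAG")
        assert kc_isomorphic(var, ref) == pytest.approx(1.011755, abs=5e-7)
        # role exchange moves the coefficient onto the other scale
        assert kc_isomorphic(ref, var) == pytest.approx(0.988515, abs=5e-7)

    def test_automorphic_examples(self):
        assert kc_automorphic([1, 2, 3, 2, 1]) == pytest.approx(1.0, abs=1e-12)
        assert kc_automorphic([1, 2, 3]) == pytest.approx(6 / 7)

    def test_degenerate_structures_raise(self):
        with pytest.raises(DegenerateStructureError):
            kc_automorphic([0, 0, 0])
        with pytest.raises(DegenerateStructureError):
            kc_isomorphic([0.0, 0.0], [0.0, 0.0], delta=0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(x=positive_structures, k=st.floats(min_value=0.01, max_value=100.0))
    def test_optiscale_interval_and_sign_cancel(self, x, k):
        base = kc_isomorphic(x, x[::-1])
        for sign in (Sign.POSITIVE, Sign.NEGATIVE):
            assert kc_isomorphic(x, x[::-1], interval=k, sign=sign) == pytest.approx(
                base, abs=1e-12
            )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(x=positive_structures)
    def test_identity_gives_unit_coefficient(self, x):
        assert kc_isomorphic(x, x) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(half=positive_structures, mid=st.floats(min_value=0.5, max_value=500.0))
    def test_palindrome_symmetry(self, half, mid):
        p = list(half) + [mid] + list(reversed(half))
        assert kc_automorphic(p) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        x=positive_structures,
        c=st.floats(min_value=0.01, max_value=50.0).filter(lambda v: v != 0),
    )
    def test_product_translation_invariance(self, x, c):
        y = x[::-1]
        base = kc_isomorphic(x, y, delta=0)
        scaled = kc_isomorphic([c * v for v in x], [c * v for v in y], delta=0)
        assert scaled == pytest.approx(base, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        x=positive_structures,
        t=st.floats(min_value=-100, max_value=100),
        c=st.floats(min_value=0.1, max_value=10),
    )
    def test_completeness_invariance_for_identical_pairs(self, x, t, c):
        """An identical pair stays at Kc=1 under shift, scaling and rotations."""
        shifted = [v + t for v in x]
        if abs(sum((i + 1) * v for i, v in enumerate(shifted + [0] + shifted[::-1]))) < 1e-6:
            return  # degenerate after shift
        assert kc_isomorphic(shifted, shifted) == pytest.approx(1.0, abs=1e-9)
        scaled = [c * v for v in x]
        assert kc_isomorphic(scaled, scaled) == pytest.approx(1.0, abs=1e-12)
        con = construct_isoreflective(x, x)
        assert kc_of_construction(pericentral_rotation(con)) == pytest.approx(
            1.0, abs=1e-12
        )
        assert kc_of_construction(central_rotation(con)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_closed_form_equals_elementwise_oracle(self, rng):
        """The quotient form must match an explicit rank-by-rank evaluation."""
        for _ in range(200):
            n = int(rng.integers(1, 51))
            x = rng.uniform(0.5, 300, n).tolist()
            y = rng.uniform(0.5, 300, n).tolist()
            layout = x + [0.0] + y[::-1]
            num = (n + 1) * math.fsum(layout)
            den = math.fsum((i + 1) * v for i, v in enumerate(layout))
            assert kc_isomorphic(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_bijectivity_first_element_recoverable_from_coefficient(self, rng):
        """Inverting the n=3 coefficient for x1 reproduces x1."""
        for _ in range(50):
            x1, x2, x3, y1, y2, y3 = rng.uniform(1, 200, 6)
            delta = 0.0
            kc = kc_isomorphic([x1, x2, x3], [y1, y2, y3], delta=delta)
            recovered = (
                kc * (2 * x2 + 3 * x3 + 4 * delta + 5 * y3 + 6 * y2 + 7 * y1)
                - 4 * (x2 + x3 + delta + y3 + y2 + y1)
            ) / (4 - kc)
            assert recovered == pytest.approx(x1, abs=1e-9 * max(1, abs(x1)))


class TestOpticalMoments:
    def test_first_element_gets_largest_distance(self):
        d = OpticalDistanceScale.uniform(2)
        assert optical_moment([1, 2], d) == 2 * 1 + 1 * 2

    def test_degenerate_halves(self):
        assert optical_moment([0, 0, 0], OpticalDistanceScale.uniform(3)) == 0
        assert optical_moment([5], OpticalDistanceScale.uniform(1)) == 5

    def test_length_mismatch(self):
        with pytest.raises(InvalidParameterError):
            optical_moment([1, 2, 3], OpticalDistanceScale.uniform(2))

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2], [1, 2], Regime.EQUAL),
            ([1, 1], [-1, -1], Regime.NEGATED),
            ([1, 1], [2, 2], Regime.LESS),
            ([2, 2], [1, 1], Regime.GREATER_BOUNDED),
        ],
    )
    def test_regime_classification(self, x, y, expected):
        assert classify_regime(construct_isoreflective(x, y)) == expected

    def test_unbounded_regime_for_sign_mixed_pair(self):
        # g(x) > g(y) but the coefficient escapes [1, n+1]
        c = construct_isoreflective([5.0, 1.0], [-4.9, -1.0])
        kc = kc_of_construction(c)
        assert kc < 0 or kc > 3
        assert classify_regime(c) == Regime.GREATER_UNBOUNDED


class TestRotations:
    def test_pericentral_reverses_each_half(self):
        c = construct_isoreflective([1, 2], [3, 4], delta=9)
        r = pericentral_rotation(c)
        assert r.layout == (2, 1, 9, 3, 4)
        assert r.pairing == PairingStyle.TAIL_TO_TAIL

    def test_pericentral_fixed_on_palindromic_halves(self):
        c = construct_isoreflective([1, 1], [2, 2], delta=0)
        assert pericentral_rotation(c).layout == c.layout

    def test_rotations_are_involutions(self):
        c = construct_isoreflective([1, 2, 3], [4, 5, 6], delta=7)
        assert pericentral_rotation(pericentral_rotation(c)).layout == c.layout
        assert central_rotation(central_rotation(c)).layout == c.layout

    def test_central_rotation_exchanges_structure_roles(self, rng):
        x = rng.uniform(1, 100, 5).tolist()
        y = rng.uniform(1, 100, 5).tolist()
        c = construct_isoreflective(x, y)
        assert kc_of_construction(central_rotation(c)) == pytest.approx(
            kc_isomorphic(y, x), abs=1e-12
        )
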