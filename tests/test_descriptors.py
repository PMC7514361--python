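import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracle_utils import all_perms, brute_cid, brute_cod
from spectrank import (
    InvalidInputError,
    InvalidParameterError,
    PowerSpectrum,
    cid,
    cid_bounds,
    cod,
    cod_bounds,
    describe,
    rank_vector,
    select_l,
)

permutations_st = st.integers(min_value=2, max_value=8).flatmap(
    lambda n: st.permutations(list(range(1, n + 1)))
)


class TestCid:
    @pytest.mark.parametrize(
        "prefix, expected",
        [
            ([1, 2, 3, 4], 1.5),  # monotone arrangement: the minimum 2(N-1)/N
            ([2, 4, 1, 3], 2.0),  # the maximum at N=4
            ([2, 3, 1], 4 / 3),
        ],
    )
    def test_examples(self, prefix, expected):
        assert cid(prefix) == pytest.approx(expected)

    def test_constant_across_all_permutations_at_n3(self):
        values = {cid(p) for p in all_perms(3)}
        assert len(values) == 1
        assert values.pop() == pytest.approx(4 / 3)

    @given(perm=permutations_st, shift=st.integers(min_value=0, max_value=7))
    def test_invariant_under_cyclic_rotation(self, perm, shift):
        rotated = np.roll(perm, shift % len(perm))
        assert cid(rotated) == pytest.approx(cid(perm), abs=1e-12)

    def test_requires_two_distinct_entries(self):
        with pytest.raises(InvalidInputError):
            cid([3])
        with pytest.raises(InvalidInputError):
            cid([3, 3])


class TestCod:
    @pytest.mark.parametrize(
        "prefix, expected",
        [
            ([1, 2, 3, 4], 0.0),  # perfectly ordered case
            ([4, 3, 2, 1], 2.0),  # reversal: the maximum at N=4
            ([2, 3, 1], 4 / 3),
        ],
    )
    def test_examples(self, prefix, expected):
        assert cod(prefix) == pytest.approx(expected)

    def test_distinctness_enforced(self):
        with pytest.raises(InvalidInputError):
            cod([1, 1, 2])


@pytest.mark.parametrize("n", [4, 5])
def test_descriptors_match_exact_brute_force(n):
    """Library values equal exact rational evaluation on every permutation."""
    for perm in all_perms(n):
        assert cid(perm) == float(brute_cid(perm))
        assert cod(perm) == float(brute_cod(perm))


@pytest.mark.parametrize("n", range(2, 7))
def test_bounds_attained_by_enumeration(n):
    cids = [cid(p) for p in all_perms(n)]
    cods = [cod(p) for p in all_perms(n)]
    lo, hi = cid_bounds(n)
    assert min(cids) == pytest.approx(lo)
    assert max(cids) == pytest.approx(hi)
    assert cid(list(range(1, n + 1))) == pytest.approx(lo)  # monotone attains min
    lo_cod, hi_cod = cod_bounds(n)
    assert min(cods) == pytest.approx(lo_cod)
    assert max(cods) == pytest.approx(hi_cod)
    assert cod(list(range(n, 0, -1))) == pytest.approx(hi_cod)  # reversal attains max


@pytest.mark.parametrize("n", [4, 5])
def test_descriptors_break_permutation_invariance(n):
    """Some rearrangements of the same power multiset change CiD and CoD."""
    cids = {round(cid(p), 12) for p in all_perms(n)}
    cods = {round(cod(p), 12) for p in all_perms(n)}
    assert len(cids) > 1
    assert len(cods) > 1


class TestSelectL:
    @pytest.mark.parametrize(
        "values, q, expected",
        [
            ([0.05, 0.6, 0.3, 0.05], 0.9, 2),
            ([0.05, 0.6, 0.3, 0.05], 1.0, 4),
            ([0.05, 0.6, 0.3, 0.05], 1e-9, 1),
        ],
    )
    def test_examples(self, values, q, expected):
        ps = PowerSpectrum(np.array(values))
        assert select_l(ps, rank_vector(ps), q) == expected

    def test_q_one_always_selects_all(self, rng):
        values = rng.exponential(1.0, 33)
        ps = PowerSpectrum(values)
        assert select_l(ps, rank_vector(ps), 1.0) == 33

    @pytest.mark.parametrize("q", [0.0, -0.5, 1.5])
    def test_q_out_of_range_rejected(self, q):
        ps = PowerSpectrum(np.array([1.0, 2.0]))
        with pytest.raises(InvalidParameterError):
            select_l(ps, rank_vector(ps), q)


class TestDescribe:
    def test_full_path_hand_computed(self):
        result = describe(PowerSpectrum(np.array([0.1, 0.7, 0.2])), q=1.0)
        assert result.cid == pytest.approx(4 / 3)
        assert result.cod == pytest.approx(4 / 3)
        assert result.n_used == result.n_total == 3
        assert result.spectral_entropy == pytest.approx(
            -sum(p * math.log(p) for p in (0.1, 0.7, 0.2))
        )

    def test_single_component_yields_nan_cid_with_warning(self):
        ps = PowerSpectrum(np.array([0.97, 0.01, 0.01, 0.01]))
        with pytest.warns(UserWarning, match="CiD undefined"):
            result = describe(ps, q=0.9)
        assert math.isnan(result.cid)
        assert result.n_used == 1
        assert result.cod == pytest.approx(0.0)

    def test_tie_break_warns_and_reports(self):
        ps = PowerSpectrum(np.array([0.3, 0.3, 0.2, 0.2]))
        with pytest.warns(UserWarning, match="tie"):
            result = describe(ps, q=1.0)
        assert result.ties_broken == 2

    def test_entropy_always_on_full_spectrum(self):
        ps = PowerSpectrum(np.array([0.6, 0.3, 0.05, 0.05]))
        full = describe(ps, q=1.0)
        truncated = describe(ps, q=0.9)
        assert truncated.n_used < truncated.n_total
        assert truncated.spectral_entropy == full.spectral_entropy


@given(perm=permutations_st)
def test_thresholded_cid_within_prefix_bounds(perm):
    """Any length-L prefix respects the circular-variation lower bound 2(L-1)/L."""
    for length in range(2, len(perm) + 1):
        value = cid(perm[:length])
        assert value >= 2 * (length - 1) / length - 1e-12
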