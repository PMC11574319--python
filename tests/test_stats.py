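"""Paired t, exact Mann-Whitney U, and the paired-condition table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from thermoclamp.errors import DegenerateInputError, PairingError
from thermoclamp.stats import (
    compare_conditions,
    mann_whitney_u,
    paired_t_test,
    type_i_error_rate,
)


class TestPairedT:
    def test_known_differences(self):
        y = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        x = y + np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = paired_t_test(x, y)
        assert res.statistic == pytest.approx(4.2426, abs=1e-4)
        assert res.df == 4
        assert res.p_two_sided == pytest.approx(0.0132, abs=1e-3)

    def test_identical_samples_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            paired_t_test(x, x)

    def test_sign_flip_negates_t_preserves_p(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 10)
        a = paired_t_test(x, y)
        b = paired_t_test(y, x)
        assert b.statistic == pytest.approx(-a.statistic, rel=1e-12)
        assert b.p_two_sided == pytest.approx(a.p_two_sided, rel=1e-12)

    def test_matches_reference_implementation(self):
        """100 random datasets: t to 1e-9 and p to 1e-6 against scipy."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(3, 30)
            x = rng.normal(0, 1, n)
            y = x + rng.normal(0.2, 0.7, n)
            ours = paired_t_test(x, y)
            ref = sps.ttest_rel(x, y)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-6)

    def test_length_mismatch_is_pairing_error(self):
        with pytest.raises(PairingError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(0.1)

    def test_group_swap_symmetry(self):
        x, y = [1.0, 5.0, 2.0], [3.0, 4.0, 6.0, 7.0]
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(y, x)
        assert b.statistic == pytest.approx(len(x) * len(y) - a.statistic)
        assert b.p_two_sided == pytest.approx(a.p_two_sided)

    def test_all_tied_gives_p_one(self):
        res = mann_whitney_u([3.0, 3.0, 3.0], [3.0, 3.0])
        assert res.p_two_sided == 1.0

    def test_exact_matches_scipy_enumeration(self):
        """Tie-free small samples agree with scipy's exact method."""
        rng = np.random.default_rng(11)
        checked = 0
        for n1 in range(1, 9):
            for n2 in range(1, 9):
                if n1 + n2 > 10:
                    continue
                for _ in range(4):
                    pool = rng.permutation(np.arange(1.0, n1 + n2 + 1.0))
                    x, y = pool[:n1], pool[n1:]
                    ours = mann_whitney_u(x, y)
                    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
                    assert ours.statistic == pytest.approx(ref.statistic)
                    assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)
                    checked += 1
        assert checked >= 100

    def test_large_sample_normal_approximation_close_to_exact_tail(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, 12)
        y = rng.normal(1.2, 1.0, 12)
        res = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided")
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=0.05)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=6),
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=6),
    )
    def test_p_value_in_unit_interval_and_symmetric(self, x, y):
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(y, x)
        assert 0.0 <= a.p_two_sided <= 1.0
        assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)


class TestCompareConditions:
    def _results(self, rng, shift=0.0):
        out = {}
        for k in range(8):
            out[f"c{k}"] = {
                "r_rest_mohm": 90.0 + rng.normal(0, 5) + shift,
                "tau_ms": 9.0 + rng.normal(0, 0.5),
                "rheobase_pa": 300.0 + rng.normal(0, 20),
                "fmax_hz": 40.0 + rng.normal(0, 3),
                "kv_tau_ms": {0.0: 4.0 + rng.normal(0, 0.2)},
            }
        return out

    def test_sem_equals_direct_recomputation(self):
        rng = np.random.default_rng(0)
        a, b = self._results(rng), self._results(rng, shift=-20.0)
        cmp = compare_conditions(a, b)
        row = cmp.row("r_rest_mohm")
        vals = np.array([a[c]["r_rest_mohm"] for c in sorted(a)])
        assert row.sem_a == pytest.approx(np.std(vals, ddof=1) / np.sqrt(len(vals)))
        assert row.n == 8

    def test_identical_conditions_yield_null_pvalues(self):
        rng = np.random.default_rng(1)
        a = self._results(rng)
        cmp = compare_conditions(a, {k: dict(v) for k, v in a.items()})
        for row in cmp.rows:
            assert row.test.p_two_sided == pytest.approx(1.0)

    def test_broken_pairing_lists_offenders(self):
        rng = np.random.default_rng(2)
        a, b = self._results(rng), self._results(rng)
        del b["c3"]
        with pytest.raises(PairingError, match="c3"):
            compare_conditions(a, b, pairing=sorted(a))

    def test_kv_rows_use_mann_whitney(self):
        rng = np.random.default_rng(3)
        cmp = compare_conditions(self._results(rng), self._results(rng, shift=5.0))
        row = cmp.row("kv_tau_ms", command_mv=0.0)
        assert "Mann-Whitney" in row.test.method


def test_type_i_error_calibration_quick():
    """Paired t under a true null rejects at about the nominal level."""
    rate = type_i_error_rate(n_pairs=15, reps=400, seed=123)
    assert 0.02 <= rate <= 0.08
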