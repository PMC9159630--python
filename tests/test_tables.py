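"""2x2 table model, modifications, and the five association tests."""

import math

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hs

from fragility import (
    Modification,
    TestSpec,
    TwoByTwoTable,
    apply_modification,
    chisq_p,
    continuity_correct,
    effect_estimate,
    fisher_p,
    p_value,
    p_values_batch,
    wald_p,
)
from fragility.tables import DegenerateTableWarning

from conftest import random_table


def fisher_oracle(t: TwoByTwoTable) -> float:
    """Independent probability-mass enumeration over the hypergeometric support."""
    total = t.e0 + t.e1
    lo, hi = max(0, total - t.n1), min(total, t.n0)
    pmf = {k: st.hypergeom.pmf(k, t.n0 + t.n1, total, t.n0) for k in range(lo, hi + 1)}
    obs = pmf[t.e0]
    return min(1.0, sum(p for p in pmf.values() if p <= obs * (1 + 1e-7)))


tables_strategy = hs.builds(
    lambda n0, n1, u0, u1: TwoByTwoTable(round(u0 * n0), n0, round(u1 * n1), n1),
    hs.integers(2, 40), hs.integers(2, 40),
    hs.floats(0, 1), hs.floats(0, 1),
)


class TestTableModel:
    def test_valid_counts_required(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(5, 4, 0, 10)
        with pytest.raises(ValueError):
            TwoByTwoTable(-1, 4, 0, 10)
        with pytest.raises(ValueError):
            TwoByTwoTable(0, 0, 0, 10)

    @pytest.mark.parametrize(
        "table, mod, expected",
        [
            ((7, 107, 12, 105), (0, 0), (7, 107, 12, 105)),
            ((7, 107, 12, 105), (6, 0), (13, 107, 12, 105)),
            ((7, 107, 12, 105), (-2, 3), (5, 107, 15, 105)),
        ],
    )
    def test_apply_modification(self, table, mod, expected):
        out = apply_modification(TwoByTwoTable(*table), Modification(*mod))
        assert (out.e0, out.n0, out.e1, out.n1) == expected

    def test_out_of_range_modification_names_group(self):
        with pytest.raises(ValueError, match="group 0"):
            apply_modification(TwoByTwoTable(0, 10, 5, 10), Modification(-1, 0))
        with pytest.raises(ValueError, match="group 1"):
            apply_modification(TwoByTwoTable(0, 10, 5, 10), Modification(0, 6))

    @pytest.mark.parametrize(
        "table, expected",
        [
            ((0, 10, 5, 10), (0.5, 10.5, 5.5, 5.5)),
            ((3, 24, 4, 20), (3.0, 21.0, 4.0, 16.0)),  # no zero cell: unchanged
            ((0, 3, 3, 3), (0.5, 3.5, 3.5, 0.5)),
        ],
    )
    def test_continuity_correction(self, table, expected):
        assert continuity_correct(TwoByTwoTable(*table)) == expected


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected, tol",
        [
            ((5, 10, 5, 10), 1.0, 1e-12),
            ((0, 3, 3, 3), 0.1, 1e-12),       # 2 / C(6,3)
            ((7, 107, 12, 105), 0.2375580514, 1e-9),
        ],
    )
    def test_known_values(self, table, expected, tol):
        assert fisher_p(TwoByTwoTable(*table)) == pytest.approx(expected, abs=tol)

    def test_degenerate_margin_gives_one(self):
        assert fisher_p(TwoByTwoTable(0, 5, 0, 7)) == 1.0
        assert fisher_p(TwoByTwoTable(5, 5, 7, 7)) == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(200):
            t = random_table(rng)
            p = fisher_p(t)
            assert 0 < p <= 1
            assert p == pytest.approx(fisher_oracle(t), abs=1e-12)

    def test_matches_scipy(self, rng):
        for _ in range(100):
            t = random_table(rng)
            ref = st.fisher_exact([[t.e0, t.n0 - t.e0], [t.e1, t.n1 - t.e1]])[1]
            assert fisher_p(t) == pytest.approx(ref, abs=1e-12)


class TestChisq:
    def test_symmetric_table_is_one(self):
        assert chisq_p(TwoByTwoTable(5, 10, 5, 10), yates=False) == pytest.approx(1.0)

    def test_pearson_value(self):
        # X^2 = 515 * (30*214 - 222*49)^2 / (252*263*79*436) = 4.4835...
        assert chisq_p(TwoByTwoTable(30, 252, 49, 263), yates=False) == pytest.approx(
            0.034223501882, abs=1e-9
        )

    def test_matches_scipy_with_and_without_yates(self, rng):
        for _ in range(50):
            t = random_table(rng)
            obs = [[t.e0, t.n0 - t.e0], [t.e1, t.n1 - t.e1]]
            if min(t.e0 + t.e1, (t.n0 - t.e0) + (t.n1 - t.e1)) == 0:
                continue
            for yates in (False, True):
                ref = st.chi2_contingency(obs, correction=yates)[1]
                assert chisq_p(t, yates=yates) == pytest.approx(ref, abs=1e-12)

    def test_yates_never_more_significant(self):
        t = TwoByTwoTable(30, 252, 49, 263)
        assert chisq_p(t, yates=True) > chisq_p(t, yates=False)

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(DegenerateTableWarning):
            assert chisq_p(TwoByTwoTable(0, 5, 0, 7)) == 1.0


class TestEffectAndWald:
    def test_identical_groups_log_or(self):
        est = effect_estimate(TwoByTwoTable(5, 10, 5, 10), "OR")
        assert est.y == 0.0
        assert est.se == pytest.approx(math.sqrt(0.8))

    def test_printed_formula_arithmetic(self):
        est = effect_estimate(TwoByTwoTable(7, 107, 12, 105), "OR")
        assert est.y == pytest.approx(0.611567, abs=1e-6)
        assert est.se == pytest.approx(0.496934, abs=1e-6)
        est = effect_estimate(TwoByTwoTable(7, 107, 12, 105), "RD")
        assert est.y == pytest.approx(0.0488652, abs=1e-6)
        assert est.se == pytest.approx(0.0391848, abs=1e-6)

    def test_zero_cell_never_infinite(self, rng):
        for table in [TwoByTwoTable(0, 10, 5, 10), TwoByTwoTable(3, 3, 0, 9),
                      TwoByTwoTable(0, 4, 4, 4)]:
            for measure in ("OR", "RR", "RD"):
                est = effect_estimate(table, measure)
                assert np.isfinite(est.y) and np.isfinite(est.se) and est.corrected

    def test_wald_null_gives_one(self):
        est = effect_estimate(TwoByTwoTable(5, 10, 5, 10), "OR")
        assert wald_p(est, TestSpec("OR")) == pytest.approx(1.0)

    def test_wald_known_z(self):
        est = effect_estimate(TwoByTwoTable(7, 107, 12, 105), "OR")
        assert wald_p(est, TestSpec("OR")) == pytest.approx(0.21845, abs=1e-4)

    @given(tables_strategy)
    @settings(max_examples=60, deadline=None)
    def test_one_sided_is_half_two_sided(self, table):
        for method in ("OR", "RR", "RD"):
            est = effect_estimate(table, method)
            two = wald_p(est, TestSpec(method))
            one = wald_p(est, TestSpec(method, alternative="one_sided"))
            assert one == pytest.approx(two / 2)

    def test_nondefault_null_shifts_reference(self):
        est = effect_estimate(TwoByTwoTable(20, 50, 30, 50), "OR")
        at_null = wald_p(est, TestSpec("OR", null_value=math.exp(est.y)))
        assert at_null == pytest.approx(1.0)


class TestDispatchAndBatch:
    def test_dispatch_matches_components(self):
        t = TwoByTwoTable(5, 10, 5, 10)
        assert p_value(t, TestSpec("fisher")) == pytest.approx(1.0)
        assert p_value(t, TestSpec("OR")) == pytest.approx(1.0)

    def test_rd_on_corrected_cells(self):
        # direct formula on corrected cells (0.5, 10.5, 5.5, 5.5)
        a, b, c, d = 0.5, 10.5, 5.5, 5.5
        m0, m1 = a + b, c + d
        y = c / m1 - a / m0
        se = math.sqrt(a * b / m0**3 + c * d / m1**3)
        expected = 2 * st.norm.cdf(-abs(y) / se)
        assert p_value(TwoByTwoTable(0, 10, 5, 10), TestSpec("RD")) == pytest.approx(expected)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            TestSpec("barnard")

    def test_one_sided_fisher_rejected(self):
        with pytest.raises(ValueError, match="two-sided only"):
            TestSpec("fisher", alternative="one_sided")

    def test_batch_agrees_with_scalar(self, rng):
        """The vectorised kernel and the scalar functions are one code path."""
        for _ in range(20):
            t = random_table(rng, n_max=15)
            f0 = np.arange(-t.e0, t.n0 - t.e0 + 1)
            f1 = np.zeros_like(f0)
            for spec in [TestSpec(m) for m in ("fisher", "chisq", "OR", "RR", "RD")]:
                batch = p_values_batch(t, spec, f0, f1)
                for fv, pv in zip(f0, batch):
                    mod_t = apply_modification(t, Modification(int(fv), 0))
                    with np.errstate(all="ignore"):
                        import warnings

                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            scalar = p_value(mod_t, spec)
                    assert pv == pytest.approx(scalar, abs=1e-13)

    def test_swap_invariance_two_sided(self, rng):
        """Swapping the two groups leaves two-sided p-values unchanged."""
        for _ in range(30):
            t = random_table(rng)
            s = TwoByTwoTable(t.e1, t.n1, t.e0, t.n0)
            assert fisher_p(t) == pytest.approx(fisher_p(s), abs=1e-12)
            assert chisq_p(t) == pytest.approx(chisq_p(s), abs=1e-12)
            for m in ("OR", "RD"):
                assert p_value(t, TestSpec(m)) == pytest.approx(
                    p_value(s, TestSpec(m)), abs=1e-12
                )
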