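"""Network meta-analysis engine: contrasts, multi-arm adjustment, WLS fit."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import block_diag

from fragility import (
    ArmRecord,
    MADataset,
    NMADataset,
    TwoByTwoTable,
    arms_to_contrasts,
    gen_nma,
    ma_fit,
    nma_fit,
)


def gls_oracle(dataset: NMADataset):
    """Independent fixed-effect estimate via GLS on baseline-arm contrasts
    with the full within-study covariance (arms share the baseline cell).
    A completely different computational route from the graph-theoretical
    WLS in the package; only valid when no arm has a zero cell."""
    treats = dataset.treatments
    tindex = {t: i for i, t in enumerate(treats)}

    def logodds(e, n):
        return math.log(e / (n - e))

    def var_arm(e, n):
        return 1 / e + 1 / (n - e)

    ys, Xs, Vs = [], [], []
    for arms in dataset.study_arms().values():
        arms = sorted(arms, key=lambda a: a.tid)
        for a in arms:
            assert 0 < a.e < a.n, "oracle requires no zero cells"
        base = arms[0]
        p = len(arms)
        X = np.zeros((p - 1, len(treats)))
        V = np.zeros((p - 1, p - 1))
        y = np.zeros(p - 1)
        for i, a in enumerate(arms[1:]):
            y[i] = logodds(a.e, a.n) - logodds(base.e, base.n)
            X[i, tindex[a.tid]] = 1
            X[i, tindex[base.tid]] = -1
            for j, b in enumerate(arms[1:]):
                V[i, j] = var_arm(base.e, base.n) + (var_arm(a.e, a.n) if i == j else 0)
        ys.append(y)
        Xs.append(X)
        Vs.append(V)
    y = np.concatenate(ys)
    X = np.vstack(Xs)
    Vi = np.linalg.inv(block_diag(*Vs))
    Xr = X[:, 1:]
    cov_r = np.linalg.inv(Xr.T @ Vi @ Xr)
    beta = cov_r @ Xr.T @ Vi @ y
    nu = np.concatenate([[0.0], beta])
    cov = np.zeros((len(treats), len(treats)))
    cov[1:, 1:] = cov_r
    theta = nu[None, :] - nu[:, None]
    d = np.diag(cov)
    se = np.sqrt(d[:, None] + d[None, :] - 2 * cov)
    return theta, se


class TestDatasetModel:
    def test_single_arm_study_rejected(self):
        with pytest.raises(ValueError, match="fewer than two arms"):
            NMADataset((ArmRecord(1, 1, 2, 10),))

    def test_repeated_treatment_rejected(self):
        with pytest.raises(ValueError, match="repeats"):
            NMADataset((ArmRecord(1, 1, 2, 10), ArmRecord(1, 1, 3, 12)))

    def test_disconnected_network_names_components(self):
        ds = NMADataset((
            ArmRecord(1, 1, 2, 10), ArmRecord(1, 2, 3, 10),
            ArmRecord(2, 3, 2, 10), ArmRecord(2, 4, 3, 10),
        ))
        with pytest.raises(ValueError, match="disconnected"):
            ds.check_connected()


class TestContrasts:
    def test_two_arm_study_single_unadjusted_contrast(self):
        ds = NMADataset((ArmRecord(1, 1, 5, 50), ArmRecord(1, 2, 9, 50)))
        cs = arms_to_contrasts(ds)
        assert len(cs) == 1
        assert cs[0].var == cs[0].var_adj

    def test_multiarm_inflates_variances(self, copd):
        cs = arms_to_contrasts(copd)
        multi = [c for c in cs if c.sid == 2]
        assert len(multi) == 6  # four arms -> six contrasts
        for c in multi:
            assert c.var_adj > c.var

    def test_zero_cell_corrected(self):
        ds = NMADataset((ArmRecord(1, 1, 0, 20), ArmRecord(1, 2, 4, 20)))
        c = arms_to_contrasts(ds)[0]
        expected = math.log((4.5 / 16.5) / (0.5 / 20.5))
        assert c.y == pytest.approx(expected)

    def test_double_zero_two_arm_dropped_unless_allstudies(self):
        ds = NMADataset((
            ArmRecord(1, 1, 0, 20), ArmRecord(1, 2, 0, 20),
            ArmRecord(2, 1, 3, 20), ArmRecord(2, 2, 6, 20),
        ))
        assert len(arms_to_contrasts(ds)) == 1
        assert len(arms_to_contrasts(ds, allstudies=True)) == 2


class TestFit:
    def test_two_treatment_network_equals_pairwise(self):
        """Fixed- and random-effects network fits on a 2-treatment network
        coincide with the pairwise engine to 1e-8."""
        for seed in range(5):
            ds, _ = gen_nma(2, 6, seed=seed)
            tables = []
            for arms in ds.study_arms().values():
                by_tid = {a.tid: a for a in arms}
                tables.append(TwoByTwoTable(by_tid[1].e, by_tid[1].n,
                                            by_tid[2].e, by_tid[2].n))
            pairwise = MADataset(tuple(tables))
            for random, tau2_method in ((False, "fixed"), (True, "DL")):
                nf = nma_fit(ds, random=random)
                mf = ma_fit(pairwise, tau2_method=tau2_method)
                th, se, lo, hi = nf.comparison(2, 1)
                assert th == pytest.approx(mf.theta_hat, abs=1e-8)
                assert lo == pytest.approx(mf.ci_low, abs=1e-8)
                assert hi == pytest.approx(mf.ci_high, abs=1e-8)
                if random:
                    assert nf.tau2 == pytest.approx(mf.tau2, abs=1e-8)

    def test_matches_gls_oracle_on_copd(self, copd):
        fit = nma_fit(copd, random=False)
        theta, se = gls_oracle(copd)
        np.testing.assert_allclose(fit.theta, theta, atol=1e-6)
        np.testing.assert_allclose(fit.se, se, atol=1e-6)

    def test_matches_gls_oracle_on_random_networks(self):
        for seed in (3, 4):
            ds, _ = gen_nma(4, 8, seed=seed, baseline=0.3)
            if any(a.e == 0 or a.e == a.n for a in ds.arms):
                continue
            fit = nma_fit(ds, random=False)
            theta, se = gls_oracle(ds)
            np.testing.assert_allclose(fit.theta, theta, atol=1e-8)
            np.testing.assert_allclose(fit.se, se, atol=1e-8)

    def test_triple_consistency(self):
        """theta_AB + theta_BC + theta_CA = 0 for every treatment triple."""
        ds, _ = gen_nma(5, 12, seed=10)
        for random in (False, True):
            fit = nma_fit(ds, random=random)
            k = len(fit.treatments)
            for i, j, l in itertools.combinations(range(k), 3):
                s = fit.theta[i, j] + fit.theta[j, l] - fit.theta[i, l]
                assert s == pytest.approx(0.0, abs=1e-10)

    def test_antisymmetry_and_se_symmetry(self):
        ds, _ = gen_nma(4, 8, seed=1)
        fit = nma_fit(ds)
        np.testing.assert_allclose(fit.theta, -fit.theta.T, atol=1e-12)
        np.testing.assert_allclose(fit.se, fit.se.T, atol=1e-12)

    def test_tree_network_consistency_equation(self):
        """On a tree (no loops) the fitted indirect effect is exactly the sum
        of the direct ones."""
        ds = NMADataset((
            ArmRecord(1, 1, 5, 60), ArmRecord(1, 2, 9, 55),
            ArmRecord(2, 2, 7, 70), ArmRecord(2, 3, 12, 65),
        ))
        fit = nma_fit(ds, random=False)
        t12 = fit.theta[0, 1]
        t23 = fit.theta[1, 2]
        assert fit.theta[0, 2] == pytest.approx(t12 + t23, abs=1e-10)
        # and the direct edges equal the single-study contrasts
        cs = arms_to_contrasts(ds)
        assert t12 == pytest.approx(cs[0].y, abs=1e-10)

    def test_fixed_is_random_with_zero_tau2(self, copd):
        fe = nma_fit(copd, random=False)
        re = nma_fit(copd, random=True)
        if re.tau2 == 0.0:
            np.testing.assert_allclose(fe.theta, re.theta)
            np.testing.assert_allclose(fe.se, re.se)

    def test_tau2_nonnegative_and_zero_when_homogeneous(self):
        ds, _ = gen_nma(3, 10, seed=2, tau2=0.0, n_min=200, n_max=400)
        fit = nma_fit(ds, random=True)
        assert fit.tau2 >= 0.0

    def test_tau2_reduces_to_pairwise_dl(self):
        """On a network of two-arm studies of one comparison the generalized
        moments estimator is exactly DerSimonian-Laird."""
        from fragility.meta import study_effects, tau2_dl

        ds, _ = gen_nma(2, 8, seed=13, tau2=0.3)
        tables = []
        for arms in ds.study_arms().values():
            by_tid = {a.tid: a for a in arms}
            tables.append(TwoByTwoTable(by_tid[1].e, by_tid[1].n,
                                        by_tid[2].e, by_tid[2].n))
        y, s = study_effects(MADataset(tuple(tables)), "OR")
        assert nma_fit(ds, random=True).tau2 == pytest.approx(tau2_dl(y, s), abs=1e-10)
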