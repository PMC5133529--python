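"""Estimating equations, working covariance, solver and sandwich inference."""

import numpy as np
import pytest

from longimap.estimator import (GeneData, GeneFit, InformativeDataError,
                                WorkingCov, bonferroni_threshold,
                                estimate_working_cov, estimating_functions,
                                sandwich_variance, scan_genes, solve_delta,
                                wald_test_c)
from longimap.ldmodel import ModelParams, dmu_ddelta, mu1, mu2
from longimap.transmission import ZMatrix


def make_zmatrix(z, m, affected, family, visit=None):
    z = np.asarray(z, float).copy()
    m = np.asarray(m, np.uint8)
    z[m == 0] = np.nan
    visit = np.ones(len(z), int) if visit is None else np.asarray(visit)
    return ZMatrix(z, m, np.asarray(affected, bool), np.asarray(family),
                   visit, [f"o{i}" for i in range(len(z))])


class TestWorkingCov:
    def test_single_marker_is_sample_variance(self):
        rng = np.random.default_rng(0)
        z = rng.choice([-2.0, -1, 0, 1, 2], size=(50, 1))
        zm = make_zmatrix(z, np.full((50, 1), 2), [True] * 50, np.arange(50))
        cov = estimate_working_cov(zm)
        assert cov.cov[0, 0] == pytest.approx(np.var(z, ddof=1))

    def test_independent_columns_decorrelate(self):
        rng = np.random.default_rng(1)
        z = rng.choice([-1.0, 0, 1], size=(10000, 3))
        zm = make_zmatrix(z, np.full(z.shape, 2), [True] * len(z),
                          np.arange(len(z)))
        cov = estimate_working_cov(zm)
        corr = cov.cov / np.sqrt(np.outer(np.diag(cov.cov), np.diag(cov.cov)))
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_inverse_residual_small(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(200, 6))
        zm = make_zmatrix(z, np.full(z.shape, 2), [True] * 200, np.arange(200))
        cov = estimate_working_cov(zm)
        M = cov.cov.shape[0]
        assert np.linalg.norm(cov.cov @ cov.inv - np.eye(M)) < 1e-6

    def test_full_shrinkage_is_diagonal(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(30, 4))
        S = np.cov(z.T)
        lam = 1.0
        Sreg = (1 - lam) * S + lam * np.diag(np.diag(S))
        assert np.allclose(Sreg, np.diag(np.diag(S)))

    def test_too_few_rows_error(self):
        zm = make_zmatrix([[1.0]], [[2]], [True], [1])
        with pytest.raises(InformativeDataError):
            estimate_working_cov(zm)


def toy_gene_data(seed=0, n_fam=5, M=3, L=2):
    """Small dense dataset plus matching GeneData and model pieces."""
    rng = np.random.default_rng(seed)
    positions = np.linspace(0.0, 1.0, M)
    pi = rng.uniform(0.4, 0.9, M)
    rows, aff, fam, vis = [], [], [], []
    for i in range(n_fam):
        for l in range(L):
            for k in range(2):
                rows.append(rng.choice([-2, -1, 0, 1, 2], M).astype(float))
                aff.append(k == 0)
                fam.append(i + 1)
                vis.append(l + 1)
    z = np.array(rows)
    m = np.full(z.shape, 2, np.uint8)
    zm = make_zmatrix(z, m, aff, fam, vis)
    cov_a = estimate_working_cov(zm, affected=True)
    cov_u = estimate_working_cov(zm, affected=False)
    data = GeneData.build(zm, positions, pi, cov_a, cov_u)
    return zm, positions, pi, cov_a, cov_u, data


def quadruple_loop_reference(delta, zm, positions, pi, cov_a, cov_u):
    """Literal nested-sum reference implementation of S1 + S2."""
    S = np.zeros(4)
    M = len(positions)
    for which, affected, cov, coef in ((1, True, cov_a, delta.c_eff),
                                       (2, False, cov_u, delta.c_star)):
        winv = np.linalg.inv(cov.cov)
        mu_fn = mu1 if which == 1 else mu2
        for i in sorted(set(zm.family)):                  # families
            for l in sorted(set(zm.visit)):               # visits
                for r in range(zm.n_rows):                # offspring k_il
                    if zm.family[r] != i or zm.visit[r] != l \
                            or zm.affected[r] != affected:
                        continue
                    for j in range(M):                    # markers
                        dmu_j = dmu_ddelta(delta, pi[j], positions[j], which)[:, 0]
                        for jp in range(M):
                            resid = zm.z[r, jp] - 2.0 * mu_fn(
                                delta, pi[jp], positions[jp])
                            S += dmu_j * winv[j, jp] * resid
    return S


class TestEstimatingFunctions:
    def test_matches_quadruple_loop_reference(self):
        zm, positions, pi, cov_a, cov_u, data = toy_gene_data()
        delta = ModelParams(0.43, 17.0, 0.35, -0.15)
        got = estimating_functions(delta, data)
        want = quadruple_loop_reference(delta, zm, positions, pi, cov_a, cov_u)
        assert np.allclose(got, want, atol=1e-10)

    def test_zero_residual_construction(self):
        """Rows built exactly as Z = 2*mu give S(delta_true) = 0."""
        positions = np.linspace(0, 2, 5)
        pi = np.full(5, 0.8)
        delta = ModelParams(0.9, 30.0, 0.5, -0.2)
        z1 = 2 * mu1(delta, pi, positions)
        z2 = 2 * mu2(delta, pi, positions)
        z = np.vstack([np.tile(z1, (4, 1)), np.tile(z2, (4, 1))])
        zm = make_zmatrix(z, np.full(z.shape, 2), [True] * 4 + [False] * 4,
                          np.arange(8))
        eye = WorkingCov(np.eye(5), np.eye(5), 0.0, 4)
        data = GeneData.build(zm, positions, pi, eye, eye)
        assert np.allclose(estimating_functions(delta, data), 0.0, atol=1e-12)

    def test_raw_zmatrix_entry_point(self):
        zm, positions, pi, cov_a, cov_u, data = toy_gene_data()
        delta = ModelParams(0.5, 10.0, 0.1, 0.0)
        a = estimating_functions(delta, data)
        b = estimating_functions(delta, zm, pi=pi, cov=(cov_a, cov_u),
                                 positions=positions)
        assert np.allclose(a, b)


class TestSolve:
    def test_all_zero_statistics_flagged_non_identifiable(self):
        z = np.zeros((20, 4))
        zm = make_zmatrix(z, np.full(z.shape, 2), [True] * 10 + [False] * 10,
                          np.arange(20))
        data = GeneData.build(zm, np.linspace(0, 2, 4), np.full(4, 0.8))
        fit = solve_delta(data)
        assert not fit.identifiable
        assert fit.params.c_eff == 0.0

    def test_recovers_truth_on_clean_signal(self, recovery_fits):
        taus = np.array([f.params.tau for f in recovery_fits[:40]])
        assert abs(taus.mean() - 1.0) < 0.05
        assert np.mean([f.converged for f in recovery_fits[:40]]) > 0.9

    def test_tau_stays_in_region(self, recovery_fits):
        for f in recovery_fits[:40]:
            assert 0.0 <= f.params.tau <= 2.0


class TestSandwich:
    def test_duplicating_families_halves_variance(self):
        zm, positions, pi, cov_a, cov_u, data = toy_gene_data(seed=5, n_fam=12)
        fit = solve_delta(data)
        fit = sandwich_variance(fit, data)
        z2 = np.vstack([zm.z, zm.z])
        m2 = np.vstack([zm.m, zm.m])
        fam2 = np.concatenate([zm.family, zm.family + 1000])
        zm2 = make_zmatrix(np.nan_to_num(z2), m2,
                           np.concatenate([zm.affected, zm.affected]), fam2,
                           np.concatenate([zm.visit, zm.visit]))
        data2 = GeneData.build(zm2, positions, pi, cov_a, cov_u)
        fit2 = GeneFit(gene="dup", params=fit.params)
        fit2 = sandwich_variance(fit2, data2)
        ratio = np.diag(fit.vcov)[:3] / np.diag(fit2.vcov)[:3]
        assert np.allclose(ratio, 2.0, rtol=0.01)

    def test_b_matrix_positive_semidefinite(self):
        from longimap.estimator import _family_contributions
        zm, positions, pi, cov_a, cov_u, data = toy_gene_data(seed=6)
        delta = ModelParams(0.5, 20.0, 0.2, -0.1)
        B = sum(np.outer(s, s)
                for s in _family_contributions(delta, data).values())
        assert np.linalg.eigvalsh(B).min() >= -1e-10

    def test_ci_definition(self, recovery_fits):
        f = next(f for f in recovery_fits if np.isfinite(f.se_tau))
        lo, hi = f.ci_tau_95
        assert lo == pytest.approx(f.params.tau - 1.96 * f.se_tau)
        assert hi == pytest.approx(f.params.tau + 1.96 * f.se_tau)


class TestWald:
    def _fit(self, c, se):
        f = GeneFit(gene="g", params=ModelParams(0, 10, c, 0))
        f.se_c = se
        return f

    def test_zero_effect_gives_one(self):
        assert wald_test_c(self._fit(0.0, 0.1)) == pytest.approx(1.0)

    def test_critical_value(self):
        assert wald_test_c(self._fit(0.196, 0.1)) == pytest.approx(0.05, abs=1e-3)

    def test_degenerate_se_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert wald_test_c(self._fit(0.3, 0.0)) == 0.0


class TestScan:
    def test_bonferroni_values(self):
        assert bonferroni_threshold(1) == 0.05
        assert bonferroni_threshold(1095) == pytest.approx(0.05 / 1095)
        with pytest.raises(ValueError):
            bonferroni_threshold(0)

    def test_short_gene_skipped_and_order_permutes(self, demo_sim):
        import pandas as pd
        trios = demo_sim.to_trios()
        panel = demo_sim.panel()
        table = pd.DataFrame({
            "gene": ["B", "A", "TINY"],
            "chrom": ["1"] * 3,
            "start_cm": [0.0, 1.0, 0.049],
            "end_cm": [1.0, 2.0, 0.051],
        })
        with pytest.warns(UserWarning, match="TINY"):
            fits, thr = scan_genes(trios, panel, demo_sim.status_table(),
                                   table, "baseline")
        assert [f.gene for f in fits] == ["B", "A"]
        assert thr == pytest.approx(0.05 / 2)
        with pytest.warns(UserWarning, match="TINY"):
            fits2, _ = scan_genes(trios, panel, demo_sim.status_table(),
                                  table.iloc[::-1], "baseline")
        assert [f.gene for f in fits2] == ["A", "B"]
        by_gene = {f.gene: f for f in fits2}
        for f in fits:
            assert by_gene[f.gene].params.tau == pytest.approx(f.params.tau)
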