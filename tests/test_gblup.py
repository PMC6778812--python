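"""Univariate GBLUP with G×E: designs, Gibbs sampler, predictions.

The mixed-model-equations (MME) oracle used throughout: with the variance
components frozen, the joint posterior of (beta, g, gE) is Gaussian with
precision C = B'B/s2e + blockdiag(I/1e10, Ginv/s2g, I_I⊗Ginv/s2ge) for the
stacked incidence B = [X Z1 Z2], so the Gibbs posterior means must agree
with the direct solve C^{-1} B'y/s2e up to Monte-Carlo error.
"""

import numpy as np
import pytest

from bmors import GBLUPGxE, GenomicRelationship, PhenotypeTable, build_designs
from bmors.samplers import FLAT_PRIOR_VARIANCE, KernelEigen
from bmors.simulate import default_scenario, simulate_markers
from bmors.qc import compute_grm


def mme_solve(y, d, G, s2g, s2ge, s2e):
    """Direct mixed-model-equations solve; the conjugate-Gibbs oracle."""
    I, J = d.n_envs, d.n_lines
    B = np.hstack([d.X, d.Z1, d.Z2])
    Ginv = KernelEigen(G).pinv
    P = np.zeros((I + J + I * J, I + J + I * J))
    P[:I, :I] = np.eye(I) / FLAT_PRIOR_VARIANCE
    P[I:I + J, I:I + J] = Ginv / s2g
    for i in range(I):
        s = I + J + i * J
        P[s:s + J, s:s + J] = Ginv / s2ge
    C = B.T @ B / s2e + P
    sol = np.linalg.solve(C, B.T @ y / s2e)
    return sol[:I], sol[I:I + J], sol[I + J:].reshape(I, J)


def small_problem(J=8, I=2, seed=5):
    markers = simulate_markers(J, 50, maf_range=(0.2, 0.5), seed=seed)
    grm = compute_grm(markers)
    rng = np.random.default_rng(seed + 1)
    y = rng.normal(10, 1.5, size=(J * I, 1))
    pheno = PhenotypeTable(markers.line_ids, [f"E{i+1}" for i in range(I)],
                           ["GY"], y)
    return pheno, grm


class TestBuildDesigns:
    def test_full_grid_shapes(self):
        pheno, _ = small_problem(J=3, I=2)
        y, d = build_designs(pheno, "GY")
        assert y.shape == (6,)
        assert d.X.shape == (6, 2) and d.Z1.shape == (6, 3) and d.Z2.shape == (6, 6)
        for M in (d.X, d.Z1, d.Z2):
            np.testing.assert_array_equal(M.sum(axis=1), np.ones(6))

    def test_masked_cell_dropped(self):
        pheno, _ = small_problem(J=3, I=2)
        tmask = np.ones(6, dtype=bool)
        tmask[pheno.cell_index("L0002", "E1")] = False
        y, d = build_designs(pheno, "GY", tmask)
        assert d.n_records == 5

    def test_empty_environment_is_error(self):
        pheno, _ = small_problem(J=3, I=2)
        tmask = np.ones(6, dtype=bool)
        for l in pheno.line_ids:
            tmask[pheno.cell_index(l, "E2")] = False
        with pytest.raises(ValueError, match="E2.*unidentifiable"):
            build_designs(pheno, "GY", tmask)


class TestGibbsAgainstMME:
    def test_frozen_variances_match_direct_solve(self):
        pheno, grm = small_problem(J=8, I=2)
        fixed = dict(sigma2_g=1.0, sigma2_ge=0.5, sigma2_e=0.5)
        model = GBLUPGxE(pheno, grm)
        res = model.fit(iterations=7000, burnin=1000, thin=1, seed=3,
                        fixed_variances=fixed)
        beta, g, ge = mme_solve(model.y, model.designs, model.G, **{
            "s2g": 1.0, "s2ge": 0.5, "s2e": 0.5})
        assert np.abs(res.beta_env - beta).max() < 0.05
        assert np.abs(res.g_mean - g).max() < 0.05
        assert np.abs(res.ge_mean - ge).max() < 0.05

    def test_ridge_equivalence_identity_kernel_single_env(self):
        # G = I, I = 1: posterior-mean g equals ridge of centered y on line
        # indicators with penalty s2e/s2g
        J = 12
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, size=(J, 1))
        pheno = PhenotypeTable([f"L{j}" for j in range(J)], ["E1"], ["GY"], y)
        grm = GenomicRelationship(pheno.line_ids, np.eye(J))
        s2g, s2e = 1.0, 0.5
        res = GBLUPGxE(pheno, grm).fit(
            iterations=21000, burnin=1000, thin=1, seed=4,
            fixed_variances=dict(sigma2_g=s2g, sigma2_ge=1e-8, sigma2_e=s2e))
        lam = s2e / s2g
        g_ridge = (y[:, 0] - y[:, 0].mean()) / (1 + lam)
        assert np.abs(res.g_mean - g_ridge).max() < 0.02


class TestFitBehaviour:
    def test_constant_response_collapses_to_env_means(self):
        pheno, grm = small_problem(J=8, I=2)
        pheno.values[:] = 3.0
        res = GBLUPGxE(pheno, grm).fit(iterations=800, burnin=400, thin=1, seed=0)
        assert np.abs(res.beta_env - 3.0).max() < 0.05 * 3.0
        assert np.abs(res.g_mean).max() < 0.05 * 3.0
        assert np.abs(res.ge_mean).max() < 0.05 * 3.0

    def test_chain_determinism(self):
        pheno, grm = small_problem()
        a = GBLUPGxE(pheno, grm).fit(iterations=300, burnin=100, thin=2, seed=9)
        b = GBLUPGxE(pheno, grm).fit(iterations=300, burnin=100, thin=2, seed=9)
        np.testing.assert_array_equal(a.beta_draws, b.beta_draws)
        np.testing.assert_array_equal(a.g_mean, b.g_mean)
        for k in a.variance_draws:
            np.testing.assert_array_equal(a.variance_draws[k],
                                          b.variance_draws[k])

    def test_masked_value_never_read(self):
        pheno, grm = small_problem()
        tmask = np.ones(pheno.n_cells, dtype=bool)
        hidden = pheno.cell_index("L0003", "E2")
        tmask[hidden] = False
        fits = []
        for planted in (0.0, 1e6):
            p2 = PhenotypeTable(pheno.line_ids, pheno.env_ids,
                                pheno.trait_names, pheno.values.copy())
            p2.values[hidden, 0] = planted
            fits.append(GBLUPGxE(p2, grm, training_mask=tmask).fit(
                iterations=300, burnin=100, thin=1, seed=1))
        np.testing.assert_array_equal(fits[0].beta_draws, fits[1].beta_draws)
        np.testing.assert_array_equal(fits[0].g_mean, fits[1].g_mean)

    def test_bad_chain_settings(self):
        pheno, grm = small_problem()
        with pytest.raises(ValueError, match="burnin"):
            GBLUPGxE(pheno, grm).fit(iterations=100, burnin=100)

    def test_retained_draw_count(self):
        pheno, grm = small_problem()
        res = GBLUPGxE(pheno, grm).fit(iterations=1000, burnin=400, thin=3, seed=0)
        assert res.beta_draws.shape[0] == (1000 - 400) // 3
        assert res.chain_meta["n_retained"] == 200


class TestPredict:
    def test_prediction_is_linear_predictor_not_observed_y(self):
        pheno, grm = small_problem()
        res = GBLUPGxE(pheno, grm).fit(iterations=600, burnin=300, thin=1, seed=2)
        cell = (pheno.line_ids[0], pheno.env_ids[0])
        pred = res.predict([cell])[0]
        expected = (res.beta_env[0] + res.g_mean[0] + res.ge_mean[0, 0])
        assert pred == pytest.approx(expected, abs=1e-12)
        assert pred != pheno.values[pheno.cell_index(*cell), 0]

    def test_unknown_line_or_env_errors(self):
        pheno, grm = small_problem()
        res = GBLUPGxE(pheno, grm).fit(iterations=200, burnin=100, thin=1, seed=0)
        with pytest.raises(KeyError, match="line"):
            res.predict([("nope", "E1")])
        with pytest.raises(KeyError, match="environment"):
            res.predict([(pheno.line_ids[0], "nope")])

    def test_variance_collapse_gives_environment_means(self):
        pheno, grm = small_problem(J=10, I=2)
        res = GBLUPGxE(pheno, grm).fit(
            iterations=2000, burnin=500, thin=1, seed=6,
            fixed_variances=dict(sigma2_g=1e-10, sigma2_ge=1e-10, sigma2_e=1.0))
        preds = res.predict()
        env_idx, _ = pheno.cell_line_env_index()
        for i in range(2):
            sel = env_idx == i
            assert np.ptp(preds[sel]) < 1e-3  # all lines identical per env
            assert np.allclose(preds[sel], res.beta_env[i], atol=1e-3)

    def test_duplicate_lines_in_kernel_get_equal_predictions(self):
        J = 12
        markers = simulate_markers(J, 80, maf_range=(0.2, 0.5), seed=12)
        markers.dosages[1] = markers.dosages[0]  # two clonal lines
        grm = compute_grm(markers)
        rng = np.random.default_rng(13)
        y = rng.normal(0, 1, size=(J * 2, 1))
        pheno = PhenotypeTable(markers.line_ids, ["E1", "E2"], ["GY"], y)
        res = GBLUPGxE(pheno, grm).fit(iterations=4000, burnin=1000, thin=1,
                                       seed=14)
        p = res.predict([(markers.line_ids[0], "E1"),
                         (markers.line_ids[1], "E1")])
        # identical kernel rows pin the two lines' genetic effects together
        assert abs(p[0] - p[1]) < 1e-2

    def test_whole_line_masked_predicted_through_kernel(self):
        pheno, grm = small_problem(J=10, I=2)
        tmask = np.ones(pheno.n_cells, dtype=bool)
        for e in pheno.env_ids:
            tmask[pheno.cell_index("L0005", e)] = False
        res = GBLUPGxE(pheno, grm, training_mask=tmask).fit(
            iterations=600, burnin=300, thin=1, seed=3)
        pred = res.predict([("L0005", "E1")])
        assert np.isfinite(pred).all()
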