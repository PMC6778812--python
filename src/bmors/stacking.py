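"""Bayesian multi-output regressor stacking (BMORS).

Two-stage meta-learning for L correlated traits measured on the same
line × environment grid:

stage 1 — one univariate GBLUP with G×E per trait, fitted on the training
cells; its posterior-mean predictions are produced for *all* grid cells
(training and testing), which needs no test-set labels;

stage 2 — per target trait, a Bayesian ridge regression of the observed
training values on the *scaled* stage-1 predictions of all L traits,

    y_ij = b0 + beta_1 Zhat_1ij + ... + beta_L Zhat_Lij + e_ij,

where Zhat_lij = (yhat_lij - mu_l) / s_l with (mu_l, s_l) the mean and
sample standard deviation of trait l's stage-1 prediction vector over all
N cells.  Coefficients share a common Gaussian prior N(0, sigma2_beta) with
a scaled inverse chi-square hyperprior (v = 5, S = Var(y) * 0.5 * 7), the
stage-2 error variance gets (v = 5, S = Var(y) * 0.25 * 7), and the
intercept the same flat Gaussian as environment effects.  Coefficients are
deliberately unconstrained and the original marker features are not added
to stage 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenomicRelationship, PhenotypeTable
from .gblup import GBLUPGxE, GBLUPResults
from .samplers import FLAT_PRIOR_VARIANCE, variance_prior

__all__ = ["StackedCovariates", "RidgeStagePosterior", "BMORS", "BMORSResults",
           "stage1_predict_all", "scale_predictions"]


@dataclass
class StackedCovariates:
    """Scaled stage-1 predictions (meta-features) for all N grid cells."""

    Z_hat: np.ndarray            # (N, L), each column mean 0 / sd 1
    mu: np.ndarray               # (L,) per-trait centering constants
    sigma: np.ndarray            # (L,) per-trait scaling constants
    provenance: list             # stage-1 chain_meta per trait


@dataclass
class RidgeStagePosterior:
    """Stage-2 ridge posterior for one target trait."""

    trait: str
    coef: np.ndarray             # (L,) posterior-mean beta
    intercept: float
    sigma2_beta: float           # posterior-mean coefficient prior variance
    sigma2_e: float              # posterior-mean stage-2 residual variance
    coef_draws: np.ndarray       # (n_retained, L)
    intercept_draws: np.ndarray


def stage1_predict_all(pheno: PhenotypeTable, grm: GenomicRelationship,
                       training_mask=None, iterations: int = 10000,
                       burnin: int = 5000, thin: int = 5, seed: int = 0,
                       fits: list | None = None):
    """Fit one GBLUP per trait on the training cells and predict all N cells.

    Returns (raw N×L prediction matrix, list of GBLUPResults).  Pre-computed
    ``fits`` (e.g. shared with a univariate baseline run on the same mask)
    are reused instead of refitting.
    """
    if fits is None:
        # one chain seed shared by every trait: chains are functions of the
        # trait's own data, so duplicated traits yield identical columns
        fits = []
        for trait in pheno.trait_names:
            model = GBLUPGxE(pheno, grm, trait=trait, training_mask=training_mask)
            fits.append(model.fit(iterations=iterations, burnin=burnin,
                                  thin=thin, seed=seed))
    raw = np.column_stack([f.predict() for f in fits])
    return raw, fits


def scale_predictions(raw: np.ndarray) -> StackedCovariates:
    """Standardise each trait's prediction column over all N cells.

    Uses the sample standard deviation (n-1 denominator).  A column with no
    spread cannot be scaled and is an error.
    """
    raw = np.asarray(raw, dtype=float)
    mu = raw.mean(axis=0)
    sigma = raw.std(axis=0, ddof=1)
    if np.any(sigma <= 0) or np.any(~np.isfinite(sigma)):
        bad = int(np.flatnonzero((sigma <= 0) | ~np.isfinite(sigma))[0])
        raise ValueError(f"degenerate stage-1 predictions in column {bad}")
    return StackedCovariates((raw - mu) / sigma, mu, sigma, provenance=[])


def _ridge_gibbs(y: np.ndarray, Z: np.ndarray, iterations: int, burnin: int,
                 thin: int, rng: np.random.Generator,
                 fixed_sigma2_beta: float | None = None,
                 fixed_sigma2_e: float | None = None):
    """Gibbs sampler for y = b0 + Z beta + e with beta ~ N(0, s2b I)."""
    n, L = Z.shape
    if n < 2:
        raise ValueError("stage 2 needs at least 2 training records")
    var_y = max(float(np.var(y, ddof=1)), 1e-8)
    pr_b = variance_prior(var_y, 0.5)
    pr_e = variance_prior(var_y, 0.25)
    s2b = fixed_sigma2_beta if fixed_sigma2_beta is not None else pr_b.S / (pr_b.v + 2)
    s2e = fixed_sigma2_e if fixed_sigma2_e is not None else pr_e.S / (pr_e.v + 2)
    b0 = float(y.mean())
    beta = np.zeros(L)
    ZtZ = Z.T @ Z
    n_ret = (iterations - burnin) // thin
    coef_draws = np.empty((n_ret, L))
    b0_draws = np.empty(n_ret)
    s2b_draws = np.empty(n_ret)
    s2e_draws = np.empty(n_ret)
    kept = 0
    for it in range(iterations):
        # intercept
        r0 = y - Z @ beta
        prec0 = n / s2e + 1.0 / FLAT_PRIOR_VARIANCE
        b0 = r0.sum() / s2e / prec0 + rng.standard_normal() / np.sqrt(prec0)
        # coefficient block
        C = ZtZ / s2e + np.eye(L) / s2b
        rhs = Z.T @ (y - b0) / s2e
        Lc = np.linalg.cholesky(C)
        mean = np.linalg.solve(C, rhs)
        beta = mean + np.linalg.solve(Lc.T, rng.standard_normal(L))
        resid = y - b0 - Z @ beta
        if fixed_sigma2_beta is None:
            s2b = (pr_b.S + beta @ beta) / rng.chisquare(pr_b.v + L)
        if fixed_sigma2_e is None:
            s2e = (pr_e.S + resid @ resid) / rng.chisquare(pr_e.v + n)
        if it >= burnin and (it - burnin) % thin == 0:
            coef_draws[kept] = beta
            b0_draws[kept] = b0
            s2b_draws[kept] = s2b
            s2e_draws[kept] = s2e
            kept += 1
    return coef_draws, b0_draws, s2b_draws, s2e_draws


def fit_stage2(pheno: PhenotypeTable, covariates: StackedCovariates,
               training_mask=None, iterations: int = 10000, burnin: int = 5000,
               thin: int = 5, seed: int = 0,
               fixed_sigma2_beta: float | None = None,
               fixed_sigma2_e: float | None = None) -> list:
    """Fit the per-trait ridge meta-models on the training cells."""
    out = []
    for l, trait in enumerate(pheno.trait_names):
        use = pheno.mask[:, l].copy()
        if training_mask is not None:
            use &= np.asarray(training_mask, dtype=bool)
        y = pheno.values[use, l]
        Z = covariates.Z_hat[use]
        rng = np.random.default_rng(seed)
        coef_draws, b0_draws, s2b_draws, s2e_draws = _ridge_gibbs(
            y, Z, iterations, burnin, thin, rng, fixed_sigma2_beta,
            fixed_sigma2_e)
        out.append(RidgeStagePosterior(
            trait=trait, coef=coef_draws.mean(axis=0),
            intercept=float(b0_draws.mean()),
            sigma2_beta=float(s2b_draws.mean()), sigma2_e=float(s2e_draws.mean()),
            coef_draws=coef_draws, intercept_draws=b0_draws))
    return out


class BMORS:
    """Bayesian multi-output regressor stacking model.

    Both stages are trained on exactly the same training-cell mask; hidden
    cells are never read.  ``fit()`` returns a :class:`BMORSResults`.
    """

    def __init__(self, pheno: PhenotypeTable, grm: GenomicRelationship,
                 training_mask=None):
        self.pheno = pheno
        self.grm = grm
        self.training_mask = training_mask

    def fit(self, iterations: int = 10000, burnin: int = 5000, thin: int = 5,
            seed: int = 0, stage1_fits: list | None = None,
            stage2_iterations: int | None = None) -> "BMORSResults":
        it2 = stage2_iterations or iterations
        raw, fits = stage1_predict_all(
            self.pheno, self.grm, self.training_mask,
            iterations=iterations, burnin=burnin, thin=thin, seed=seed,
            fits=stage1_fits)
        covariates = scale_predictions(raw)
        covariates.provenance = [f.chain_meta for f in fits]
        stage2 = fit_stage2(self.pheno, covariates, self.training_mask,
                            iterations=it2, burnin=min(burnin, it2 // 2),
                            thin=thin, seed=seed)
        return BMORSResults(model=self, stage1=fits, covariates=covariates,
                            stage2=stage2)


@dataclass
class BMORSResults:
    """Fitted BMORS pipeline: stage-1 GBLUPs, meta-features, stage-2 ridges."""

    model: BMORS
    stage1: list            # L GBLUPResults
    covariates: StackedCovariates
    stage2: list            # L RidgeStagePosterior

    def predict(self, cells=None) -> np.ndarray:
        """Stage-2 predictions, (n_cells, L); default all N grid cells."""
        pheno = self.model.pheno
        if cells is None:
            rows = np.arange(pheno.n_cells)
        else:
            rows = np.array([pheno.cell_index(l, e) for l, e in cells])
        Z = self.covariates.Z_hat[rows]
        out = np.empty((rows.size, pheno.n_traits))
        for l, post in enumerate(self.stage2):
            out[:, l] = post.intercept + Z @ post.coef
        return out

    def summary(self) -> str:
        pheno = self.model.pheno
        lines = [
            "Bayesian multi-output regressor stacking (BMORS)",
            f"traits: {', '.join(pheno.trait_names)}   grid: "
            f"{pheno.n_lines} lines x {pheno.n_envs} environments",
            "",
            "Stage-2 ridge coefficients (rows: target trait; "
            "columns: scaled stage-1 predictor):",
        ]
        tbl = pd.DataFrame(
            np.vstack([p.coef for p in self.stage2]),
            index=pheno.trait_names,
            columns=[f"Zhat[{t}]" for t in pheno.trait_names],
        )
        tbl["intercept"] = [p.intercept for p in self.stage2]
        tbl["sigma2_beta"] = [p.sigma2_beta for p in self.stage2]
        tbl["sigma2_e"] = [p.sigma2_e for p in self.stage2]
        lines.append(tbl.to_string(float_format=lambda x: f"{x:#.4g}"))
        return "\n".join(lines)
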