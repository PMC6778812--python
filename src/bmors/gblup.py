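"""Univariate Bayesian GBLUP with genotype × environment interaction.

The model for the response of line j in environment i is

    y_ij = E_i + g_j + gE_ij + e_ij

with E_i a fixed environment effect (Gaussian prior with very large
variance 1e10), g ~ N(0, sigma2_g * G) the genomic line effects under the
genomic relationship kernel G, gE ~ N(0, sigma2_ge * I_I ⊗ G) the
genotype-by-environment interaction, and e_ij ~ N(0, sigma2_e) iid
residuals.  Variance components carry scaled inverse chi-square priors
with v = 5 and scales set from the training-set phenotypic variance so the
prior modes partition Var(y) as 0.5 (genomic) + 0.25 (G×E) + 0.25 (error).

Everything is fitted by Gibbs sampling with exact conjugate block updates:
the g block is drawn jointly from its J-dimensional Gaussian full
conditional, and the gE block factorises over environments into I
independent J-dimensional Gaussians because both its prior precision
(I_I ⊗ G)^{-1} and the incidence crossproduct are block diagonal.

Follows the statsmodels convention: ``GBLUPGxE`` is the model,
``GBLUPGxE.fit()`` returns a ``GBLUPResults`` carrying posterior summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .data import GenomicRelationship, PhenotypeTable
from .samplers import (
    FLAT_PRIOR_VARIANCE,
    KernelEigen,
    PriorSpec,
    draw_scaled_inv_chi2,
    variance_prior,
)

__all__ = ["DesignMatrices", "build_designs", "GBLUPGxE", "GBLUPResults",
           "default_priors"]


@dataclass
class DesignMatrices:
    """Incidence structure of the training records.

    Stored sparsely as per-record environment and line indices; the dense
    X (n × I), Z1 (n × J) and Z2 (n × I·J) matrices are materialised on
    demand (mainly for small oracles and tests).
    """

    env_idx: np.ndarray
    line_idx: np.ndarray
    n_envs: int
    n_lines: int

    @property
    def n_records(self) -> int:
        return self.env_idx.size

    @property
    def X(self) -> np.ndarray:
        X = np.zeros((self.n_records, self.n_envs))
        X[np.arange(self.n_records), self.env_idx] = 1.0
        return X

    @property
    def Z1(self) -> np.ndarray:
        Z = np.zeros((self.n_records, self.n_lines))
        Z[np.arange(self.n_records), self.line_idx] = 1.0
        return Z

    @property
    def Z2(self) -> np.ndarray:
        Z = np.zeros((self.n_records, self.n_envs * self.n_lines))
        Z[np.arange(self.n_records),
          self.env_idx * self.n_lines + self.line_idx] = 1.0
        return Z


def build_designs(pheno: PhenotypeTable, trait, training_mask=None):
    """Extract the training response and incidence structure for one trait.

    ``training_mask`` is a boolean vector over the N grid cells (True =
    usable for training); it is intersected with the trait's observation
    mask.  Raises if any environment ends up with zero training records,
    since its fixed effect would be unidentifiable.
    """
    k = pheno.trait_names.index(trait)
    use = pheno.mask[:, k].copy()
    if training_mask is not None:
        training_mask = np.asarray(training_mask, dtype=bool)
        if training_mask.shape != (pheno.n_cells,):
            raise ValueError("training_mask must have one entry per grid cell")
        use &= training_mask
    if not use.any():
        raise ValueError("no training records")
    env_idx, line_idx = pheno.cell_line_env_index()
    env_idx, line_idx = env_idx[use], line_idx[use]
    counts = np.bincount(env_idx, minlength=pheno.n_envs)
    if (counts == 0).any():
        bad = pheno.env_ids[int(np.flatnonzero(counts == 0)[0])]
        raise ValueError(
            f"environment {bad!r} has no training records; its effect is "
            "unidentifiable"
        )
    y = pheno.values[use, k]
    return y, DesignMatrices(env_idx, line_idx, pheno.n_envs, pheno.n_lines)


def default_priors(var_y: float, v: float = 5.0) -> dict:
    """Variance priors partitioning Var(y): 0.5 genomic, 0.25 G×E, 0.25 error."""
    return {
        "sigma2_g": variance_prior(var_y, 0.5, v),
        "sigma2_ge": variance_prior(var_y, 0.25, v),
        "sigma2_e": variance_prior(var_y, 0.25, v),
    }


# module-level cache of kernel eigendecompositions, keyed by array content
_EIGEN_CACHE: dict = {}


def _kernel_eigen(G: np.ndarray) -> KernelEigen:
    key = G.tobytes()
    eig = _EIGEN_CACHE.get(key)
    if eig is None:
        eig = KernelEigen(G)
        _EIGEN_CACHE.clear()  # keep at most one (fits of a run share G)
        _EIGEN_CACHE[key] = eig
    return eig


class GBLUPGxE:
    """Model object for the univariate GBLUP with G×E.

    Parameters
    ----------
    pheno : PhenotypeTable
    grm : GenomicRelationship
        Must cover every line in ``pheno``; reordered internally.
    trait : str, optional
        Trait to fit (default: the first trait).
    training_mask : bool array over grid cells, optional
        Cells excluded here are never read during fitting.
    priors : dict of PriorSpec, optional
        Keys sigma2_g / sigma2_ge / sigma2_e; default derived from the
        training-set variance via ``default_priors``.
    """

    def __init__(self, pheno: PhenotypeTable, grm: GenomicRelationship,
                 trait=None, training_mask=None, priors=None):
        self.pheno = pheno
        self.trait = trait if trait is not None else pheno.trait_names[0]
        missing = set(pheno.line_ids) - set(grm.line_ids)
        if missing:
            raise ValueError(f"GRM lacks lines: {sorted(missing)[:5]} ...")
        pos = [grm.line_ids.index(l) for l in pheno.line_ids]
        self.G = grm.G[np.ix_(pos, pos)]
        self.y, self.designs = build_designs(pheno, self.trait, training_mask)
        self.training_mask = training_mask
        if priors is None:
            # floor keeps prior scales positive for a (near-)constant response
            priors = default_priors(max(float(np.var(self.y, ddof=1)), 1e-8))
        self.priors = priors

    def fit(self, iterations: int = 10000, burnin: int = 5000, thin: int = 5,
            seed: int = 0, fixed_variances: dict | None = None,
            rng: np.random.Generator | None = None,
            store_effect_draws: bool = False) -> "GBLUPResults":
        """Run the Gibbs sampler and return posterior summaries.

        ``fixed_variances`` freezes any of sigma2_g / sigma2_ge / sigma2_e
        at the given value (its conjugate update is skipped), which turns
        the sampler into the exact conditional Gaussian used by the
        mixed-model-equation oracles.
        """
        if burnin >= iterations:
            raise ValueError("burnin must be smaller than iterations")
        if thin < 1:
            raise ValueError("thin must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        fixed = fixed_variances or {}

        d = self.designs
        J, I, n = d.n_lines, d.n_envs, d.n_records
        y = self.y
        eig = _kernel_eigen(self.G)
        Ginv = eig.pinv

        n_env = np.bincount(d.env_idx, minlength=I).astype(float)
        n_line = np.bincount(d.line_idx, minlength=J).astype(float)
        obs = np.zeros((I, J))
        obs[d.env_idx, d.line_idx] = 1.0

        pr = self.priors

        def init_var(name):
            if name in fixed:
                return float(fixed[name])
            p = pr[name]
            return p.S / (p.v + 2)  # prior mode

        s2g = init_var("sigma2_g")
        s2ge = init_var("sigma2_ge")
        s2e = init_var("sigma2_e")

        beta = np.bincount(d.env_idx, weights=y, minlength=I) / np.maximum(n_env, 1)
        g = np.zeros(J)
        ge = np.zeros((I, J))

        n_ret = (iterations - burnin) // thin
        beta_draws = np.empty((n_ret, I))
        var_draws = {k: np.empty(n_ret) for k in ("sigma2_g", "sigma2_ge", "sigma2_e")}
        g_sum = np.zeros(J)
        ge_sum = np.zeros((I, J))
        g_draws = np.empty((n_ret, J)) if store_effect_draws else None
        ge_draws = np.empty((n_ret, I, J)) if store_effect_draws else None

        resid = y - beta[d.env_idx] - g[d.line_idx] - ge[d.env_idx, d.line_idx]
        kept = 0
        for it in range(iterations):
            # --- environment fixed effects (diagonal full conditional)
            r = resid + beta[d.env_idx]
            rhs = np.bincount(d.env_idx, weights=r, minlength=I) / s2e
            prec = n_env / s2e + 1.0 / FLAT_PRIOR_VARIANCE
            beta = rhs / prec + rng.standard_normal(I) / np.sqrt(prec)
            # --- genomic line effects (joint J-dim Gaussian)
            r = r - beta[d.env_idx] + g[d.line_idx]
            rhs = np.bincount(d.line_idx, weights=r, minlength=J) / s2e
            C = Ginv / s2g
            C[np.diag_indices_from(C)] += n_line / s2e
            cf = cho_factor(C, lower=True)
            g = cho_solve(cf, rhs) + solve_triangular(
                cf[0], rng.standard_normal(J), lower=True, trans="T")
            # --- G×E effects, one J-dim block per environment
            r = r - g[d.line_idx] + ge[d.env_idx, d.line_idx]
            rmat = np.zeros((I, J))
            rmat[d.env_idx, d.line_idx] = r
            for i in range(I):
                C = Ginv / s2ge
                C[np.diag_indices_from(C)] += obs[i] / s2e
                cf = cho_factor(C, lower=True)
                ge[i] = cho_solve(cf, rmat[i] / s2e) + solve_triangular(
                    cf[0], rng.standard_normal(J), lower=True, trans="T")
            resid = r - ge[d.env_idx, d.line_idx]
            # --- variance components (conjugate scaled-inv-chi2 updates)
            if "sigma2_g" not in fixed:
                q = float(g @ (Ginv @ g))
                s2g = (pr["sigma2_g"].S + q) / rng.chisquare(pr["sigma2_g"].v + J)
            if "sigma2_ge" not in fixed:
                q = float(np.einsum("ij,jk,ik->", ge, Ginv, ge))
                s2ge = (pr["sigma2_ge"].S + q) / rng.chisquare(
                    pr["sigma2_ge"].v + I * J)
            if "sigma2_e" not in fixed:
                q = float(resid @ resid)
                s2e = (pr["sigma2_e"].S + q) / rng.chisquare(pr["sigma2_e"].v + n)

            if it >= burnin and (it - burnin) % thin == 0:
                beta_draws[kept] = beta
                var_draws["sigma2_g"][kept] = s2g
                var_draws["sigma2_ge"][kept] = s2ge
                var_draws["sigma2_e"][kept] = s2e
                g_sum += g
                ge_sum += ge
                if store_effect_draws:
                    g_draws[kept] = g
                    ge_draws[kept] = ge
                kept += 1

        chain_meta = dict(iterations=iterations, burnin=burnin, thin=thin,
                          seed=seed, n_retained=n_ret)
        return GBLUPResults(
            model=self, beta_draws=beta_draws, g_mean=g_sum / n_ret,
            ge_mean=ge_sum / n_ret, variance_draws=var_draws,
            chain_meta=chain_meta, g_draws=g_draws, ge_draws=ge_draws)


@dataclass
class GBLUPResults:
    """Posterior summaries of one GBLUP G×E fit."""

    model: GBLUPGxE
    beta_draws: np.ndarray          # (n_retained, I)
    g_mean: np.ndarray              # (J,)
    ge_mean: np.ndarray             # (I, J)
    variance_draws: dict
    chain_meta: dict
    g_draws: np.ndarray | None = None
    ge_draws: np.ndarray | None = None

    @property
    def beta_env(self) -> np.ndarray:
        return self.beta_draws.mean(axis=0)

    @property
    def variances(self) -> pd.DataFrame:
        rows = {k: {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
                for k, v in self.variance_draws.items()}
        return pd.DataFrame(rows).T

    def predict(self, cells=None) -> np.ndarray:
        """Posterior-mean prediction E_i + g_j + gE_ij per requested cell.

        ``cells`` is a list of (line, env) pairs; default all N grid cells
        in cell order.  Lines with no training records are predicted via
        their prior correlation with trained lines through the kernel (they
        were sampled in every Gibbs iteration).
        """
        pheno = self.model.pheno
        if cells is None:
            env_idx, line_idx = pheno.cell_line_env_index()
        else:
            line_idx = np.empty(len(cells), dtype=int)
            env_idx = np.empty(len(cells), dtype=int)
            for r, (line, env) in enumerate(cells):
                if line not in pheno.line_ids:
                    raise KeyError(f"unknown line {line!r}")
                if env not in pheno.env_ids:
                    raise KeyError(f"unknown environment {env!r}")
                line_idx[r] = pheno.line_ids.index(line)
                env_idx[r] = pheno.env_ids.index(env)
        return (self.beta_env[env_idx] + self.g_mean[line_idx]
                + self.ge_mean[env_idx, line_idx])

    def summary(self) -> str:
        m = self.model
        lines = [
            "GBLUP with genotype x environment interaction (Gibbs)",
            f"trait: {m.trait}   records: {m.designs.n_records}   "
            f"lines: {m.designs.n_lines}   environments: {m.designs.n_envs}",
            f"chain: {self.chain_meta['iterations']} iterations, "
            f"burn-in {self.chain_meta['burnin']}, thin {self.chain_meta['thin']}"
            f" ({self.chain_meta['n_retained']} retained), "
            f"seed {self.chain_meta['seed']}",
            "",
            "Variance components (posterior mean ± sd):",
        ]
        for k, row in self.variances.iterrows():
            lines.append(f"  {k:<10s} {row['mean']:#10.4g} ± {row['sd']:#.3g}")
        lines.append("")
        lines.append("Environment effects (posterior mean):")
        for i, e in enumerate(m.pheno.env_ids):
            lines.append(f"  {e:<10s} {self.beta_env[i]:#10.4g}")
        return "\n".join(lines)
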