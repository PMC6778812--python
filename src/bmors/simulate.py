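"""Synthetic multi-trait multi-environment breeding data with known truth.

Phenotypes are drawn from the matrix-variate mixed model

    Y = X beta + Z1 b1 + Z2 b2 + E,

with Y the n×L phenotype matrix (n = J×I cells), b1 ~ MN(0, G, Sigma_t)
the genotype×trait effects (row covariance the genomic kernel G, column
covariance the L×L genetic trait covariance Sigma_t), b2 ~
MN(0, Sigma_E ⊗ G, Sigma_t) the genotype×environment×trait effects, and E
with iid rows N(0, R_e).  This is the natural fully multivariate generative
model for correlated traits with G×E, so the univariate GBLUP and the
stacked BMORS pipeline can be compared on data whose cross-trait signal is
controlled exactly.

Markers are independent biallelic loci (no linkage disequilibrium or
population structure); the kernel is recomputed from them so the bundle is
self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenomicRelationship, MarkerMatrix, PhenotypeTable
from .qc import compute_grm

__all__ = ["SimulationTruth", "SimBundle", "simulate_markers",
           "inject_missing_dosages", "simulate_phenotypes",
           "mask_for_scenario", "default_scenario"]

CHOL_JITTER_REL = 1e-8  # relative ridge added to G before factorisation


@dataclass
class SimulationTruth:
    """Everything that generated a simulated phenotype table."""

    beta: np.ndarray       # (I, L) environment-by-trait means
    Sigma_t: np.ndarray    # (L, L) genetic trait covariance
    Sigma_E: np.ndarray    # (I, I) environment covariance of the G×E term
    Re: np.ndarray         # (L, L) residual trait covariance
    b1: np.ndarray         # (J, L) genomic effects
    b2: np.ndarray         # (I*J, L) G×E effects, env-major
    seed: int | None = None


@dataclass
class SimBundle:
    markers: MarkerMatrix
    grm: GenomicRelationship
    pheno: PhenotypeTable
    truth: SimulationTruth


def simulate_markers(J: int, p: int, maf_range=(0.05, 0.5),
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> MarkerMatrix:
    """Independent biallelic markers: dosage ~ Binomial(2, f) per line,
    with each marker's allele frequency f uniform on ``maf_range``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if J < 2 or p < 1:
        raise ValueError("need J >= 2 lines and p >= 1 markers")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie inside (0, 0.5]")
    freqs = rng.uniform(lo, hi, size=p)
    dosages = rng.binomial(2, freqs, size=(J, p)).astype(float)
    return MarkerMatrix(
        [f"L{j+1:04d}" for j in range(J)],
        [f"M{k+1:05d}" for k in range(p)],
        dosages,
    )


def inject_missing_dosages(markers: MarkerMatrix, frac: float,
                           rng: np.random.Generator) -> MarkerMatrix:
    """Set a random ``frac`` of calls to missing (for QC/imputation tests)."""
    if not 0.0 <= frac < 1.0:
        raise ValueError("frac must be in [0, 1)")
    d = markers.dosages.copy()
    d[rng.random(d.shape) < frac] = np.nan
    return MarkerMatrix(markers.line_ids, markers.marker_ids, d)


def _chol_psd(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    lam_max = max(float(np.linalg.eigvalsh(M).max()), np.finfo(float).tiny)
    return np.linalg.cholesky(M + CHOL_JITTER_REL * lam_max * np.eye(M.shape[0]))


def simulate_phenotypes(markers: MarkerMatrix, beta, Sigma_t, Sigma_E, Re,
                        sigma2_ge_scale: float = 1.0,
                        rng: np.random.Generator | None = None,
                        seed: int | None = None,
                        env_ids=None, trait_names=None,
                        grm: GenomicRelationship | None = None) -> SimBundle:
    """Draw one phenotype table from the matrix-variate model.

    ``sigma2_ge_scale`` multiplies the G×E covariance Sigma_E ⊗ G.  The
    Kronecker square roots are used directly: chol(Sigma_E ⊗ G) =
    chol(Sigma_E) ⊗ chol(G), so b2 is assembled environment-block-wise
    without ever forming the IJ×IJ matrix.  ``grm`` overrides the kernel
    recomputed from the markers (controlled experiments with, e.g., an
    identity kernel); by default the bundle's kernel is exactly
    ``compute_grm(markers)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    Sigma_t = np.atleast_2d(np.asarray(Sigma_t, dtype=float))
    Sigma_E = np.atleast_2d(np.asarray(Sigma_E, dtype=float))
    Re = np.atleast_2d(np.asarray(Re, dtype=float))
    I, L = beta.shape
    J = markers.n_lines
    for name, M, dim in (("Sigma_t", Sigma_t, L), ("Sigma_E", Sigma_E, I),
                         ("Re", Re, L)):
        if M.shape != (dim, dim):
            raise ValueError(f"{name} must be {dim}x{dim}")
        if np.linalg.eigvalsh(M).min() <= 0:
            raise ValueError(f"{name} must be positive definite")
    if grm is None:
        grm = compute_grm(markers)
    elif grm.line_ids != markers.line_ids:
        raise ValueError("grm line IDs must match the marker matrix")
    Lg = _chol_psd(grm.G)
    Lt = _chol_psd(Sigma_t)
    Le = _chol_psd(Sigma_E)

    b1 = Lg @ rng.standard_normal((J, L)) @ Lt.T
    # b2 env-major: stack of I blocks, block i = (Le row i scaled) G-correlated draws
    Zb = rng.standard_normal((I, J, L))
    b2 = np.einsum("ik,kjl->ijl", Le, Lg @ Zb @ Lt.T)
    b2 *= np.sqrt(sigma2_ge_scale)
    E = rng.standard_normal((I * J, L)) @ _chol_psd(Re).T

    env_idx = np.repeat(np.arange(I), J)
    line_idx = np.tile(np.arange(J), I)
    Y = beta[env_idx] + b1[line_idx] + b2.reshape(I * J, L) + E

    if env_ids is None:
        env_ids = [f"E{i+1}" for i in range(I)]
    if trait_names is None:
        trait_names = [f"T{l+1}" for l in range(L)]
    pheno = PhenotypeTable(markers.line_ids, env_ids, trait_names, Y)
    truth = SimulationTruth(beta=beta, Sigma_t=Sigma_t, Sigma_E=Sigma_E,
                            Re=Re, b1=b1, b2=b2.reshape(I * J, L), seed=seed)
    return SimBundle(markers=markers, grm=grm, pheno=pheno, truth=truth)


def mask_for_scenario(pheno: PhenotypeTable, scenario: str = "random_cells",
                      p_testing: float = 0.2,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> np.ndarray:
    """Training mask for one random incomplete-field-trial split."""
    from .crossval import CVConfig, cells_to_training_mask, make_partitions

    if scenario != "random_cells":
        raise ValueError(f"unknown scenario {scenario!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    cfg = CVConfig(p_testing=p_testing, n_partitions=1)
    part = make_partitions(pheno, cfg, rng=rng)[0]
    return cells_to_training_mask(pheno, part.test_cells)


def default_scenario(J: int = 300, I: int = 3, L: int = 3, p: int = 1000,
                     gcor: float = 0.5, sigma2_g: float = 1.0,
                     sigma2_ge: float = 0.5, sigma2_e: float = 0.5,
                     seed: int = 0) -> SimBundle:
    """A realistic mid-size trial: J lines, I environments, L traits.

    ``gcor`` is the off-diagonal genetic correlation in Sigma_t;
    environment means are spread a couple of phenotypic SDs apart, the G×E
    covariance is sigma2_ge * I_I and residual covariance sigma2_e * I_L
    (cross-trait residual correlation is left to Sigma_t's genetic channel).
    """
    rng = np.random.default_rng(seed)
    markers = simulate_markers(J, p, maf_range=(0.05, 0.5), rng=rng)
    Sigma_t = sigma2_g * ((1 - gcor) * np.eye(L) + gcor * np.ones((L, L)))
    Sigma_E = sigma2_ge * np.eye(I)
    Re = sigma2_e * np.eye(L)
    beta = np.add.outer(np.linspace(-1.0, 1.0, I), np.linspace(8.0, 12.0, L))
    return simulate_phenotypes(markers, beta, Sigma_t, Sigma_E, Re,
                               rng=rng, env_ids=None, trait_names=None)
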