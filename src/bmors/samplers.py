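"""Conjugate MCMC primitives shared by the GBLUP and ridge samplers.

Parameterisation note.  The scaled inverse chi-square used throughout is the
distribution of S / chi2_v, with density proportional to
(s2)^{-(v/2+1)} exp(-S / (2 s2)).  Its mode is S/(v+2) and its mean
S/(v-2) for v > 2.  This convention (shared with BGLR) is what makes the
prior-scale rule S = Var(y) * R2 * (v+2) place the prior mode at
Var(y) * R2; rival parameterisations differ by factors of v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

__all__ = [
    "PriorSpec",
    "variance_prior",
    "KernelEigen",
    "draw_scaled_inv_chi2",
    "conditional_variance_update",
    "draw_gaussian_block",
]

FLAT_PRIOR_VARIANCE = 1e10  # "flat" Gaussian prior for fixed effects


@dataclass
class PriorSpec:
    """Scaled inverse chi-square prior with shape v and scale S.

    When S is derived from the phenotypic variance as
    S = var_y * R2 * (v + 2), ``derivation`` records (R2, var_y) so the
    arithmetic can be audited.
    """

    v: float
    S: float
    derivation: tuple | None = None  # (R2, var_y)

    def __post_init__(self):
        if self.v <= 0:
            raise ValueError("degrees of freedom v must be positive")
        if self.S <= 0:
            raise ValueError("scale S must be positive")
        if self.derivation is not None:
            r2, var_y = self.derivation
            expected = var_y * r2 * (self.v + 2)
            if abs(self.S - expected) > 1e-12 * max(1.0, abs(expected)):
                raise ValueError("S inconsistent with var_y * R2 * (v + 2)")


def variance_prior(var_y: float, r2: float, v: float = 5.0) -> PriorSpec:
    """Prior with mode var_y * r2: S = var_y * r2 * (v + 2)."""
    return PriorSpec(v=v, S=var_y * r2 * (v + 2), derivation=(r2, var_y))


def draw_scaled_inv_chi2(v: float, S: float, rng: np.random.Generator) -> float:
    """One draw of S / chi2_v."""
    if v <= 0 or S <= 0:
        raise ValueError("v and S must be positive")
    return S / rng.chisquare(v)


def conditional_variance_update(effects: np.ndarray, prior: PriorSpec,
                                metric: np.ndarray | None,
                                rng: np.random.Generator) -> float:
    """Conjugate update of a variance component given its effects.

    Draws (S + q) / chi2_{v + k} where q = effects' metric effects (metric
    None means the identity) and k is the number of effect coordinates.
    k = 0 falls back to a pure prior draw.
    """
    effects = np.atleast_1d(np.asarray(effects, dtype=float)).ravel()
    k = effects.size
    if k == 0:
        return draw_scaled_inv_chi2(prior.v, prior.S, rng)
    if metric is None:
        q = float(effects @ effects)
    else:
        q = float(effects @ (metric @ effects))
    if q < -1e-10 * max(1.0, abs(q)):
        raise ValueError("quadratic form is negative; metric not PSD")
    q = max(q, 0.0)
    return (prior.S + q) / rng.chisquare(prior.v + k)


class KernelEigen:
    """Eigendecomposition of a PSD kernel, with a floored pseudo-inverse.

    Eigenvalues are stored in descending order; values below
    ``floor_rel * lambda_max`` are treated as zero for reconstruction and
    floored at ``floor_rel * lambda_max`` when inverting, which regularises
    the precision metric used in variance updates.
    """

    def __init__(self, K: np.ndarray, floor_rel: float = 1e-8):
        K = np.asarray(K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        w, U = np.linalg.eigh(K)
        order = np.argsort(w)[::-1]
        w, U = w[order], U[:, order]
        lam_max = max(float(w[0]), 0.0)
        if w[-1] < -1e-8 * max(lam_max, 1.0):
            raise ValueError("kernel is not PSD within tolerance")
        self.eigenvalues = np.clip(w, 0.0, None)
        self.eigenvectors = U
        self.floor = floor_rel * max(lam_max, np.finfo(float).tiny)

    @property
    def pinv(self) -> np.ndarray:
        """Eigen-pseudoinverse with the eigenvalue floor."""
        d = np.maximum(self.eigenvalues, self.floor)
        return (self.eigenvectors / d) @ self.eigenvectors.T

    def reconstruct(self) -> np.ndarray:
        return (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.T


def draw_gaussian_block(rhs: np.ndarray, precision: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Exact draw from N(C^{-1} r, C^{-1}) for precision C and RHS r.

    This is the Gibbs full conditional of any Gaussian effect block: C is
    the conditional precision (crossproduct over error variance plus prior
    precision) and r the matching right-hand side.
    """
    precision = np.atleast_2d(np.asarray(precision, dtype=float))
    rhs = np.atleast_1d(np.asarray(rhs, dtype=float))
    try:
        c, low = cho_factor(precision, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise ValueError("singular conditional precision") from exc
    mean = cho_solve((c, low), rhs)
    z = rng.standard_normal(rhs.size)
    # c holds L with C = L L'; solving L' x = z gives x ~ N(0, C^{-1})
    return mean + solve_triangular(c, z, lower=low, trans="T")
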