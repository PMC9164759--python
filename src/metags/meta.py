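"""Across-population meta-analysis mixed model equations.

Treats the same trait in c populations as c correlated traits.  With the
per-SNP effect covariance across populations

    Σ_ik = corr_ik · √(σ²_i σ²_k) · √(θ_i θ_k),

the joint prior on stacked effects is G = Σ ⊗ I_m (every block a scalar
multiple of the identity), so G⁻¹ = Σ⁻¹ ⊗ I_m and only the c × c matrix Σ
is ever inverted.  The meta equations assemble each population's shared
precision matrix on the diagonal plus the Σ⁻¹ scalars:

    [ Z'₁R⁻¹₁Z₁ + Σ⁻¹₁₁ I   …   Σ⁻¹₁c I ]   [ ĝ₁ ]   [ Z'₁R⁻¹₁y₁ ]
    [        …                     …    ] × [  … ] = [     …     ]
    [ symm.            Z'cR⁻¹cZc + Σ⁻¹cc I] [ ĝc ]   [ Z'cR⁻¹cyc ]

Right-hand sides come from the summaries directly, or are recovered from
shared effects via (lhs + λI)·ĝ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, sparse
from scipy.sparse.linalg import LinearOperator, cg

from .errors import (AlignmentError, DomainError, SingularSystemError,
                     SnpSetMismatchError)
from .popsum import compute_dgv, recover_rhs
from .types import CovarianceSpec, MetaSystem, PopulationSummary

__all__ = ["build_sigma", "invert_g", "assemble_meta", "solve_meta",
           "predict_and_evaluate", "PredictionResult"]

#: correlations this close to ±1 make Σ numerically singular
_CORR_LIMIT = 0.999


def build_sigma(spec: CovarianceSpec) -> np.ndarray:
    """c × c across-population per-SNP effect covariance Σ.

    Σ_ik = σ_ik √(θ_i θ_k) with σ_ik = corr_ik √(σ²_i σ²_k); the full prior
    G expands each entry SNP-wise as Σ_ik·I and is never materialized.
    """
    eig = np.linalg.eigvalsh(spec.corr)
    if eig[0] < -1e-10:
        raise DomainError(
            f"correlation matrix is not positive semidefinite "
            f"(smallest eigenvalue {eig[0]:.3e})")
    sd = np.sqrt(spec.dgv_var)
    cov = spec.corr * np.outer(sd, sd)
    rt = np.sqrt(spec.theta)
    return cov * np.outer(rt, rt)


def invert_g(sigma: np.ndarray) -> np.ndarray:
    """Scalar coefficients of G⁻¹: entry (i,k) multiplies the identity in
    block (i,k) of the joint prior precision."""
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    c = sigma.shape[0]
    if c > 1:
        d = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(d, d)
        off = corr[~np.eye(c, dtype=bool)]
        if (np.abs(off) > _CORR_LIMIT).any():
            raise SingularSystemError(
                f"across-population correlation |r| > {_CORR_LIMIT} makes the "
                "effect covariance numerically singular; perturb the "
                "correlation away from ±1")
    try:
        return linalg.inv(sigma)
    except linalg.LinAlgError:
        raise SingularSystemError(
            "across-population covariance is singular; perturb the "
            "correlation matrix", float(np.linalg.cond(sigma))) from None


def _summary_rhs(s: PopulationSummary, spec: CovarianceSpec, i: int) -> np.ndarray:
    if s.rhs is not None:
        return s.rhs
    if s.effects is None:
        raise AlignmentError(
            f"summary {i} carries neither rhs nor effects")
    return recover_rhs(s, theta=spec.theta[i])


def assemble_meta(summaries: list[PopulationSummary],
                  spec: CovarianceSpec) -> MetaSystem:
    """Assemble the block mixed model equations from shared summaries.

    All summaries must share one identically-ordered SNP list; harmonize
    differing SNP sets first with :mod:`metags.sumstat_ops` (block-wise
    summary-statistic imputation).
    """
    c = len(summaries)
    if c != spec.n_pops:
        raise AlignmentError(f"{c} summaries for a {spec.n_pops}-population spec")
    snp_ids = summaries[0].snp_ids
    for i, s in enumerate(summaries[1:], start=1):
        if not np.array_equal(s.snp_ids, snp_ids):
            raise SnpSetMismatchError(
                f"summary {i} has a different SNP list than summary 0; "
                "impute the summaries onto a common SNP list first "
                "(metags.sumstat_ops.build_T / impute_rhs / impute_lhs)")
    m = len(snp_ids)
    siginv = invert_g(build_sigma(spec))
    A = np.zeros((c * m, c * m))
    b = np.empty(c * m)
    for i, s in enumerate(summaries):
        lhs = s.lhs
        asym = np.abs(lhs - lhs.T).max()
        scale = max(np.abs(lhs).max(), 1.0)
        if asym > 1e-8 * scale:
            warnings.warn(
                f"summary {i} lhs asymmetry {asym:.3e} exceeds 1e-8 relative; "
                "symmetrizing as (A + A')/2", stacklevel=2)
        lhs = 0.5 * (lhs + lhs.T)
        blk = A[i * m:(i + 1) * m, i * m:(i + 1) * m]
        blk[:] = lhs
        blk[np.diag_indices(m)] += siginv[i, i]
        for k in range(i + 1, c):
            idx = np.arange(m)
            A[i * m + idx, k * m + idx] = siginv[i, k]
            A[k * m + idx, i * m + idx] = siginv[k, i]
        b[i * m:(i + 1) * m] = _summary_rhs(s, spec, i)
    return MetaSystem(block_lhs=A, block_rhs=b, n_pops=c, snp_ids=snp_ids)


def solve_meta(system: MetaSystem, method: str = "auto",
               tol: float = 1e-8, direct_limit: int = 20000) -> list[np.ndarray]:
    """Solve the assembled meta equations; returns per-population effects.

    Direct symmetric factorization up to ``direct_limit`` unknowns;
    beyond that, conjugate gradients preconditioned with the
    block-diagonal part, to ``tol`` on the relative residual.
    """
    A, b = system.block_lhs, system.block_rhs
    n = A.shape[0]
    if method not in ("auto", "direct", "cg"):
        raise DomainError(f"unknown solver method {method!r}")
    if method == "direct" or (method == "auto" and n <= direct_limit):
        try:
            cfac = linalg.cho_factor(A, lower=True, check_finite=False)
            x = linalg.cho_solve(cfac, b, check_finite=False)
        except linalg.LinAlgError:
            raise SingularSystemError(
                "meta mixed model equations are singular",
                float(np.linalg.cond(A))) from None
    else:
        m = system.n_snps
        pre_factors = [
            linalg.cho_factor(A[i * m:(i + 1) * m, i * m:(i + 1) * m],
                              lower=True, check_finite=False)
            for i in range(system.n_pops)]

        def precond(v):
            out = np.empty_like(v)
            for i, fac in enumerate(pre_factors):
                out[i * m:(i + 1) * m] = linalg.cho_solve(
                    fac, v[i * m:(i + 1) * m], check_finite=False)
            return out

        M = LinearOperator((n, n), matvec=precond)
        x, info = cg(A, b, rtol=tol, maxiter=10 * system.n_pops * 100, M=M)
        if info != 0:
            raise SingularSystemError(
                f"conjugate-gradient solve did not converge (info={info})")
    m = system.n_snps
    sols = [x[i * m:(i + 1) * m] for i in range(system.n_pops)]
    system.solutions = sols
    return sols


@dataclass
class PredictionResult:
    """DGV for a validation set with its accuracy metrics."""

    dgv: np.ndarray
    correlation: float
    slope: float


def predict_and_evaluate(Z_rows: np.ndarray, effects: np.ndarray,
                         phenotypes: np.ndarray) -> PredictionResult:
    """Predict DGV and score against phenotypes.

    ``correlation`` is the Pearson correlation between phenotype and DGV
    (the prediction-accuracy measure); ``slope`` the coefficient of the
    regression of phenotype on DGV (1 = unbiased dispersion).
    """
    y = np.asarray(phenotypes, dtype=float)
    dgv = compute_dgv(Z_rows, effects)
    if dgv.shape != y.shape:
        raise AlignmentError("phenotype vector does not match genotype rows")
    vd = np.var(dgv)
    if vd == 0:
        raise DomainError("DGV has zero variance; correlation undefined")
    dc = dgv - dgv.mean()
    yc = y - y.mean()
    corr = float(np.dot(dc, yc) / np.sqrt(np.dot(dc, dc) * np.dot(yc, yc)))
    slope = float(np.dot(dc, yc) / np.dot(dc, dc))
    return PredictionResult(dgv=dgv, correlation=corr, slope=slope)
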