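"""Joint multi-population SNP-BLUP on raw pooled data (mBLUP).

Ground truth for the meta-analysis: the bivariate/multivariate model that
treats the same trait in c populations as c correlated traits and solves on
the pooled raw genotypes and phenotypes.  Each population's phenotypes
inform only its own trait; information flows across populations through the
SNP-effect prior cov(g_i[j], g_k[j]) = corr_ik √(σ²_iσ²_k) √(θ_iθ_k).

Deliberately written with none of the assembly code of :mod:`metags.meta`:
the prior here is the dense c·m × c·m Kronecker product, inverted as such,
so agreement between the two solvers is evidence rather than tautology.
Population means are absorbed by precision-weighted centring of each y,
matching the summary-construction convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SingularSystemError
from .types import JointDataset

__all__ = ["solve_joint_mblup", "OracleResult"]


@dataclass
class OracleResult:
    """Per-population SNP effects and fitted GEBV from the joint solve."""

    effects: list[np.ndarray]
    gebv: list[np.ndarray]


def solve_joint_mblup(data: JointDataset) -> OracleResult:
    """Solve the joint multi-trait mixed model equations directly.

    Builds blockdiag(Z_i'R_i⁻¹Z_i) + G⁻¹ with G = Σ ⊗ I materialized and
    inverted densely, stacks Z_i'R_i⁻¹(y_i − ȳ_i) and solves in one shot.
    Variance components are taken from ``data.spec`` as fixed inputs.
    """
    spec = data.spec
    c = spec.n_pops
    m = data.panels[0].n_snps
    sd = np.sqrt(np.asarray(spec.dgv_var, dtype=float))
    sig = spec.corr * np.outer(sd, sd)
    rt = np.sqrt(np.asarray(spec.theta, dtype=float))
    S = sig * np.outer(rt, rt)
    G = np.kron(S, np.eye(m))
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        raise SingularSystemError(
            "joint SNP-effect prior is singular") from None

    A = Ginv  # prior precision; data terms added in place below
    b = np.empty(c * m)
    Zs = []
    for i, (panel, rec) in enumerate(zip(data.panels, data.records)):
        freq = panel.dosage.mean(axis=0) / 2.0
        Z = panel.dosage.astype(float) - 2.0 * freq
        Zs.append(Z)
        w = rec.n_daughters / data.err_var[i]
        ybar = np.dot(w, rec.y) / w.sum()
        yc = rec.y - ybar
        Zw = Z * w[:, None]
        A[i * m:(i + 1) * m, i * m:(i + 1) * m] += Z.T @ Zw
        b[i * m:(i + 1) * m] = Zw.T @ yc
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        raise SingularSystemError("joint mixed model equations are singular",
                                  float(np.linalg.cond(A))) from None
    effects = [x[i * m:(i + 1) * m] for i in range(c)]
    gebv = [Z @ g for Z, g in zip(Zs, effects)]
    return OracleResult(effects=effects, gebv=gebv)
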