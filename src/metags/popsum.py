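"""Single-population SNP-BLUP and the summary statistics built from it.

Each data holder fits, within its own population, the sire-model SNP-BLUP

    y = μ·1 + Z g + e,      var(e)⁻¹ = R⁻¹ = diag{n_k / σ²_e},
    var(g) = σ²·θ·I,        θ = 1 / Σ_j 2 p_j (1 − p_j),

where y are daughter-average phenotypes corrected for everything but the
genomic effect, Z the allele-frequency-centred dosages, σ² the variance of
direct genomic values and n_k the effective daughter count of sire k.  What
leaves the data holder is not raw data but the summary:  Z'R⁻¹Z, Z'R⁻¹y
(and/or the solved effects ĝ), allele frequencies and the two variance
components — exactly the pieces needed to rebuild these equations centrally.

The population mean is absorbed rather than carried: y is centred at its
precision-weighted mean before Z'R⁻¹y is formed, which equals fitting μ and
then eliminating it when the weighted mean of Zg is negligible (centred
genotypes).  This keeps the shared summaries mean-free, so the across-
population equations need no fixed-effect block.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .errors import (AlignmentError, DomainError, InvalidFrequencyError,
                     MonomorphicSNPError, SingularSystemError)
from .types import (GenotypePanel, PhenotypeRecords, PopulationSummary,
                    ScalingTheta)

__all__ = [
    "center_genotypes", "residual_precision", "compute_theta",
    "solve_single_pop", "solve_absorbed", "compute_dgv",
    "summarize_population", "recover_rhs", "weighted_center",
]


def _check_freq(freq: np.ndarray, m: int) -> np.ndarray:
    freq = np.asarray(freq, dtype=float)
    if freq.shape != (m,):
        raise AlignmentError(f"frequency vector length {freq.shape} for {m} SNPs")
    if ((freq <= 0) | (freq >= 1)).any():
        bad = int(np.argmax((freq <= 0) | (freq >= 1)))
        raise InvalidFrequencyError(
            f"allele frequency {freq[bad]} at SNP index {bad} is outside (0, 1)")
    return freq


def center_genotypes(panel: GenotypePanel, freq: np.ndarray) -> np.ndarray:
    """Centre dosages: Z[k, j] = dosage[k, j] − 2·freq[j].

    Genotypes AA/AB/BB become 2−2p, 1−2p and −2p.  Any frequency vector in
    (0,1) is admissible; with a fitted (or absorbed) mean the resulting BLUP
    of g does not depend on the choice.
    """
    freq = _check_freq(freq, panel.n_snps)
    return panel.dosage.astype(float) - 2.0 * freq


def residual_precision(records: PhenotypeRecords, err_var: float) -> np.ndarray:
    """Diagonal of R⁻¹ for a sire model: entry k is n_k / σ²_e.

    Returned as a 1-D vector; off-diagonal elements of R⁻¹ are zero.
    """
    if not err_var > 0:
        raise DomainError(f"err_var must be positive, got {err_var}")
    return records.n_daughters / float(err_var)


def compute_theta(freq: np.ndarray) -> ScalingTheta:
    """θ = 1 / Σ_j 2 p_j (1 − p_j), the DGV-variance-to-SNP-variance scaling."""
    freq = np.asarray(freq, dtype=float)
    if freq.size == 0:
        raise DomainError("cannot compute theta for an empty SNP list")
    freq = _check_freq(freq, freq.size)
    return ScalingTheta(1.0 / float(np.sum(2.0 * freq * (1.0 - freq))))


def _theta_value(theta) -> float:
    return theta.theta if isinstance(theta, ScalingTheta) else float(theta)


def _solve_spd(A: np.ndarray, b: np.ndarray, what: str) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(A, lower=True, check_finite=False)
    except linalg.LinAlgError:
        cond = float(np.linalg.cond(A))
        raise SingularSystemError(
            f"{what} coefficient matrix is not positive definite", cond) from None
    return linalg.cho_solve((c, low), b, check_finite=False)


def weighted_center(y: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Centre y at its precision-weighted mean; returns (centred y, mean)."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    ybar = float(np.dot(w, y) / np.sum(w))
    return y - ybar, ybar


def solve_single_pop(Z: np.ndarray, rinv_diag: np.ndarray, y: np.ndarray,
                     dgv_var: float, theta) -> tuple[float, np.ndarray]:
    """Solve the single-population mixed model equations with explicit mean.

        [ 1'R⁻¹1   1'R⁻¹Z          ] [ μ̂ ]   [ 1'R⁻¹y ]
        [ Z'R⁻¹1   Z'R⁻¹Z + λI     ] [ ĝ ] = [ Z'R⁻¹y ],   λ = 1/(σ²·θ).

    Returns (μ̂, ĝ).  ĝ is invariant to the frequency vector used to centre
    Z because the mean is fitted.
    """
    if not dgv_var > 0:
        raise DomainError("dgv_var must be positive")
    th = _theta_value(theta)
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(rinv_diag, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = Z.shape
    if w.shape != (n,) or y.shape != (n,):
        raise AlignmentError("Z, rinv_diag and y are not conformable")
    lam = 1.0 / (dgv_var * th)
    Zw = Z * w[:, None]
    A = np.empty((m + 1, m + 1))
    A[0, 0] = w.sum()
    A[0, 1:] = A[1:, 0] = Zw.sum(axis=0)
    A[1:, 1:] = Z.T @ Zw
    A[1:, 1:][np.diag_indices(m)] += lam
    b = np.concatenate(([np.dot(w, y)], Zw.T @ y))
    sol = _solve_spd(A, b, "single-population MME")
    return float(sol[0]), sol[1:]


def solve_absorbed(lhs: np.ndarray, rhs: np.ndarray, dgv_var: float,
                   theta) -> np.ndarray:
    """Solve (Z'R⁻¹Z + λI) g = rhs on mean-absorbed summaries, λ = 1/(σ²θ)."""
    th = _theta_value(theta)
    if not dgv_var > 0:
        raise DomainError("dgv_var must be positive")
    lam = 1.0 / (dgv_var * th)
    A = np.array(lhs, dtype=float, copy=True)
    A[np.diag_indices_from(A)] += lam
    return _solve_spd(A, np.asarray(rhs, dtype=float), "absorbed SNP-BLUP")


def compute_dgv(Z_rows: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """Direct genomic values: DGV_k = z_k · g, the sum of all SNP effects."""
    Z_rows = np.atleast_2d(np.asarray(Z_rows, dtype=float))
    effects = np.asarray(effects, dtype=float)
    if Z_rows.shape[1] != effects.shape[0]:
        raise AlignmentError(
            f"{Z_rows.shape[1]} genotype columns vs {effects.shape[0]} effects")
    return Z_rows @ effects


def summarize_population(panel: GenotypePanel, records: PhenotypeRecords,
                         err_var: float, dgv_var: float, *,
                         population: str = "pop", trait: str = "trait",
                         n_geno: int | None = None) -> PopulationSummary:
    """Build the full shareable summary for one population and trait.

    Computes allele frequencies from the panel, forms lhs = Z'R⁻¹Z and
    rhs = Z'R⁻¹(y − ȳ_w) with ȳ_w the precision-weighted phenotype mean
    (mean absorption), and solves for the population's own SNP effects.
    Monomorphic SNPs are rejected: fixed alleles carry no information and
    break the θ scaling — filter on minor allele frequency first.
    """
    if panel.n_indiv != len(records):
        raise AlignmentError("panel individuals and phenotype records differ "
                             f"({panel.n_indiv} vs {len(records)})")
    freq = panel.allele_freq()
    if ((freq <= 0) | (freq >= 1)).any():
        fixed = panel.snp_ids[(freq <= 0) | (freq >= 1)]
        raise MonomorphicSNPError(
            f"{len(fixed)} monomorphic SNP(s) in population {population!r} "
            f"(e.g. {fixed[0]}); apply a minor-allele-frequency filter")
    theta = compute_theta(freq)
    Z = center_genotypes(panel, freq)
    w = residual_precision(records, err_var)
    yc, _ = weighted_center(records.y, w)
    Zw = Z * w[:, None]
    lhs = Z.T @ Zw
    lhs = 0.5 * (lhs + lhs.T)
    rhs = Zw.T @ yc
    effects = solve_absorbed(lhs, rhs, dgv_var, theta)
    return PopulationSummary(
        snp_ids=panel.snp_ids, allele_freq=freq, lhs=lhs, rhs=rhs,
        effects=effects, dgv_var=float(dgv_var), err_var=float(err_var),
        n_pheno=len(records),
        n_geno=int(n_geno) if n_geno is not None else panel.n_indiv,
        population=population, trait=trait)


def recover_rhs(summary: PopulationSummary, theta=None) -> np.ndarray:
    """Rebuild Z'R⁻¹y from shared effects:  rhs = (lhs + λI)·ĝ.

    Inverts the mean-absorbed solve, so a holder may share effects instead
    of the right-hand side.  θ defaults to the value implied by the
    summary's allele frequencies; pass ``theta`` to override.
    """
    if summary.effects is None:
        raise AlignmentError("summary carries no effects; cannot recover rhs")
    th = _theta_value(theta) if theta is not None else \
        compute_theta(summary.allele_freq).theta
    lam = 1.0 / (summary.dgv_var * th)
    return summary.lhs @ summary.effects + lam * summary.effects
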