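"""Operations on shared summary statistics.

Two practical obstacles stand between per-population summaries and a joint
analysis, and this module removes both without touching raw data:

* **Rescaling** — a data holder shares one precision matrix Z'R⁻¹Z built on
  all α genotyped individuals; for a trait phenotyped on only n of them the
  matrix is rescaled by n/α, since Z'R⁻¹Z captures the population's LD
  structure and differs between traits essentially by scale.

* **Summary-statistic imputation** — populations genotyped (or filtered) to
  different SNP sets are harmonized by regressing, on a reference panel,
  the complete SNP set on the observed one: T = (Z_i'Z_i)⁻¹ Z_i'Z_c,
  computed in blocks of adjacent SNPs per chromosome so the inverse stays
  small and well conditioned.  Then rhs_c = T' rhs_i, lhs_c = T' lhs_i T,
  and solved complete-set effects map back as g_i = T g_c.  What is imputed
  is never the genotypes but the matrices entering the meta equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .errors import AlignmentError, DomainError, SingularSystemError
from .popsum import (center_genotypes, compute_theta, residual_precision,
                     solve_absorbed, weighted_center)
from .types import (GenotypePanel, ImputationBlock, ImputationMap,
                    PhenotypeRecords)

__all__ = ["rescale_lhs", "build_T", "impute_rhs", "impute_lhs",
           "map_solutions", "mask_and_evaluate", "rescale_and_evaluate",
           "MaskEvaluation"]

logger = logging.getLogger(__name__)

#: automatic ridge, as a fraction of the mean diagonal of Z_i'Z_i
_AUTO_RIDGE_FRAC = 1e-6


def rescale_lhs(lhs_full: np.ndarray, n_pheno: int, n_geno: int) -> np.ndarray:
    """Rescale an all-genotyped-individuals Z'R⁻¹Z to a trait's phenotyped
    count: every entry multiplied by n_pheno/n_geno."""
    if not 0 < n_pheno <= n_geno:
        raise DomainError(
            f"need 0 < n_pheno <= n_geno, got n_pheno={n_pheno}, n_geno={n_geno}")
    return np.asarray(lhs_full, dtype=float) * (n_pheno / n_geno)


def _block_bounds(chrom: np.ndarray, block_size: int) -> list[tuple[int, int]]:
    """Contiguous runs of <= block_size adjacent SNPs within a chromosome."""
    bounds = []
    start = 0
    m = len(chrom)
    while start < m:
        chrom_end = start
        while chrom_end < m and chrom[chrom_end] == chrom[start]:
            chrom_end += 1
        for s in range(start, chrom_end, block_size):
            bounds.append((s, min(s + block_size, chrom_end)))
        start = chrom_end
    return bounds


def build_T(ref_panel: GenotypePanel, observed_ids, complete_ids,
            block_size: int = 200, ridge: float | str = "auto") -> ImputationMap:
    """Estimate the block-diagonal T matrix on a reference panel.

    Per block of up to ``block_size`` adjacent SNPs on one chromosome,
    T = (Z_i'Z_i + ridge·I)⁻¹ Z_i'Z_c on column-centred reference genotypes
    (frequencies from the reference panel itself).  With ridge 0 and a
    nonsingular Z_i'Z_i, the columns of observed SNPs are exact indicators,
    so observed statistics pass through unchanged.

    ``ridge="auto"`` uses 0 wherever Z_i'Z_i is invertible and falls back to
    a small multiple of its mean diagonal (logged) when a block is rank
    deficient or has more observed SNPs than reference individuals.
    """
    observed_ids = np.asarray(observed_ids, dtype=object)
    complete_ids = np.asarray(complete_ids, dtype=object)
    if block_size < 1:
        raise DomainError("block_size must be >= 1")
    obs_set = {s: i for i, s in enumerate(observed_ids)}
    if len(obs_set) != len(observed_ids):
        raise AlignmentError("observed SNP ids are not unique")
    missing = [s for s in observed_ids if s not in set(complete_ids)]
    if missing:
        raise AlignmentError(
            f"observed ids not in the complete list (e.g. {missing[0]})")
    ref_pos = {s: j for j, s in enumerate(ref_panel.snp_ids)}
    try:
        ref_cols = np.array([ref_pos[s] for s in complete_ids])
    except KeyError as e:
        raise AlignmentError(
            f"reference panel does not cover complete SNP {e.args[0]!r}") from None
    ref = ref_panel.subset_snps(ref_cols)
    Zr = ref.dosage.astype(float)
    Zr = Zr - Zr.mean(axis=0)
    n_ref = Zr.shape[0]

    auto = isinstance(ridge, str)
    if auto and ridge != "auto":
        raise DomainError(f"ridge must be a number or 'auto', got {ridge!r}")
    if not auto and float(ridge) < 0:
        raise DomainError("ridge must be nonnegative")

    blocks: list[ImputationBlock] = []
    ridge_used = 0.0
    for start, stop in _block_bounds(ref.chrom, block_size):
        width = stop - start
        in_block = [(j - start, obs_set[s])
                    for j, s in enumerate(complete_ids[start:stop], start=start)
                    if s in obs_set]
        obs_local = np.array([a for a, _ in in_block], dtype=int)
        obs_rows = np.array([b for _, b in in_block], dtype=int)
        if len(obs_local) == 0:
            T = np.zeros((0, width))
            blocks.append(ImputationBlock(str(ref.chrom[start]), start, stop,
                                          obs_local, obs_rows, T))
            continue
        Zi = Zr[:, start + obs_local]
        Zc = Zr[:, start:stop]
        A = Zi.T @ Zi
        ZiZc = Zi.T @ Zc
        r = 0.0 if auto else float(ridge)
        T = None
        if not (auto and len(obs_local) >= n_ref):
            try:
                Ar = A if r == 0 else A + r * np.eye(len(obs_local))
                cfac = linalg.cho_factor(Ar, lower=True, check_finite=False)
                T = linalg.cho_solve(cfac, ZiZc, check_finite=False)
            except linalg.LinAlgError:
                T = None
        if T is None:
            if not auto:
                raise SingularSystemError(
                    f"Z_i'Z_i singular in block [{start}, {stop}) "
                    f"({len(obs_local)} observed SNPs, {n_ref} reference "
                    "individuals); supply a positive ridge or ridge='auto'")
            r = _AUTO_RIDGE_FRAC * float(np.mean(np.diag(A)))
            r = max(r, np.finfo(float).tiny)
            logger.warning(
                "block [%d, %d): Z_i'Z_i rank-deficient or observed count "
                "(%d) >= reference size (%d); applying ridge %.3e",
                start, stop, len(obs_local), n_ref, r)
            ridge_used = max(ridge_used, r)
            T = linalg.solve(A + r * np.eye(len(obs_local)), ZiZc,
                             assume_a="pos")
        elif not auto:
            ridge_used = max(ridge_used, r)
        blocks.append(ImputationBlock(str(ref.chrom[start]), start, stop,
                                      obs_local, obs_rows, T))
    return ImputationMap(blocks=blocks, observed_ids=observed_ids,
                         complete_ids=complete_ids, ridge=ridge_used)


def _full_T(imap: ImputationMap) -> sparse.csr_matrix:
    """Assemble the sparse (n_observed × m_complete) block-diagonal T."""
    rows, cols, data = [], [], []
    for b in imap.blocks:
        if b.T.shape[0] == 0:
            continue
        r = np.repeat(b.obs_rows, b.width)
        c = np.tile(np.arange(b.start, b.stop), len(b.obs_rows))
        rows.append(r)
        cols.append(c)
        data.append(b.T.ravel())
    if not rows:
        return sparse.csr_matrix((imap.n_observed, imap.n_complete))
    return sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(imap.n_observed, imap.n_complete))


def impute_rhs(imap: ImputationMap, rhs_obs: np.ndarray) -> np.ndarray:
    """Right-hand side on the complete SNP list: rhs_c = T'·rhs_i per block.

    Blocks without any observed SNP cannot be imputed and contribute zeros.
    """
    rhs_obs = np.asarray(rhs_obs, dtype=float)
    if rhs_obs.shape != (imap.n_observed,):
        raise AlignmentError(
            f"rhs length {rhs_obs.shape} does not match "
            f"{imap.n_observed} observed SNPs")
    out = np.zeros(imap.n_complete)
    for b in imap.blocks:
        if b.T.shape[0]:
            out[b.start:b.stop] = b.T.T @ rhs_obs[b.obs_rows]
    return out


def impute_lhs(imap: ImputationMap, lhs_obs: np.ndarray,
               atol_asym: float = 1e-8) -> np.ndarray:
    """Precision matrix on the complete SNP list: lhs_c = T'·lhs_i·T.

    T is block-diagonal but lhs_i carries cross-block LD, so cross-block
    products T_a'·lhs_ab·T_b are retained.  The result is symmetrized and
    positive semidefinite by construction.
    """
    lhs_obs = np.asarray(lhs_obs, dtype=float)
    n = imap.n_observed
    if lhs_obs.shape != (n, n):
        raise AlignmentError(
            f"lhs shape {lhs_obs.shape} does not match {n} observed SNPs")
    scale = max(np.abs(lhs_obs).max(), 1.0)
    if np.abs(lhs_obs - lhs_obs.T).max() > atol_asym * scale:
        raise AlignmentError("observed lhs is asymmetric beyond tolerance")
    T = _full_T(imap)
    out = T.T @ (T.T @ lhs_obs).T  # (T' L T)' computed via two sparse products
    return 0.5 * (out + out.T)


def map_solutions(imap: ImputationMap, g_complete: np.ndarray) -> np.ndarray:
    """Map complete-set solutions back to the population's own SNP list:
    g_i = T·g_c per block."""
    g_complete = np.asarray(g_complete, dtype=float)
    if g_complete.shape != (imap.n_complete,):
        raise AlignmentError(
            f"solution length {g_complete.shape} does not match "
            f"{imap.n_complete} complete SNPs")
    return _full_T(imap) @ g_complete


# ---------------------------------------------------------------------------
# Masking / validation protocols
# ---------------------------------------------------------------------------

@dataclass
class MaskEvaluation:
    """Replicate-level and aggregated accuracies of a masking experiment."""

    replicates: pd.DataFrame
    summary: pd.DataFrame


def _summarize_reps(df: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in df.columns if c != "replicate"]
    rows = []
    n = len(df)
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        mean = v.mean()
        half = 1.96 * v.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        rows.append({"metric": c, "mean": mean,
                     "ci95_lo": mean - half, "ci95_hi": mean + half})
    return pd.DataFrame(rows).set_index("metric")


def _masked_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def mask_and_evaluate(panel: GenotypePanel, records: PhenotypeRecords,
                      err_var: float, dgv_var: float, mask_fraction: float,
                      n_replicates: int, seed: int, *,
                      block_size: int = 200,
                      ridge: float | str = "auto") -> MaskEvaluation:
    """SNP-masking validation protocol on one population.

    The population is split into thirds: a reference third on which T is
    built, a training third whose summary statistics are masked and
    imputed, and an evaluation third scoring prediction accuracy.  Per
    replicate a random ``mask_fraction`` of SNPs is hidden from the
    training summaries, the missing entries are imputed block-wise, and
    imputed lhs/rhs/effects are correlated with their full-data values over
    the masked entries only.  Deterministic given ``seed``.
    """
    if not 0 < mask_fraction < 1:
        raise DomainError("mask_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = panel.n_indiv
    perm = rng.permutation(n)
    third = n // 3
    ref_idx, train_idx, eval_idx = (perm[:third], perm[third:2 * third],
                                    perm[2 * third:])
    ref_panel = panel.subset_individuals(ref_idx)
    train_panel = panel.subset_individuals(train_idx)
    eval_panel = panel.subset_individuals(eval_idx)
    y = records.y
    nd = records.n_daughters

    freq = train_panel.allele_freq()
    freq = np.clip(freq, 0.5 / (2 * len(train_idx)),
                   1 - 0.5 / (2 * len(train_idx)))
    theta = compute_theta(freq)
    Z = center_genotypes(train_panel, freq)
    w = residual_precision(
        PhenotypeRecords(y[train_idx], nd[train_idx]), err_var)
    yc, _ = weighted_center(y[train_idx], w)
    Zw = Z * w[:, None]
    lhs_full = Z.T @ Zw
    lhs_full = 0.5 * (lhs_full + lhs_full.T)
    rhs_full = Zw.T @ yc
    g_full = solve_absorbed(lhs_full, rhs_full, dgv_var, theta)

    Z_eval = center_genotypes(eval_panel, freq)
    y_eval = y[eval_idx] - y[eval_idx].mean()
    acc_full = _masked_corr(Z_eval @ g_full, y_eval)

    m = panel.n_snps
    n_mask = int(round(mask_fraction * m))
    n_mask = min(max(n_mask, 1), m - 1)
    tril = np.tril_indices(m)
    rows = []
    for rep in range(n_replicates):
        masked = np.sort(rng.choice(m, size=n_mask, replace=False))
        observed = np.setdiff1d(np.arange(m), masked)
        imap = build_T(ref_panel, panel.snp_ids[observed], panel.snp_ids,
                       block_size=block_size, ridge=ridge)
        rhs_imp = impute_rhs(imap, rhs_full[observed])
        lhs_imp = impute_lhs(imap, lhs_full[np.ix_(observed, observed)])
        g_imp = solve_absorbed(lhs_imp, rhs_imp, dgv_var, theta)

        in_mask = np.zeros(m, dtype=bool)
        in_mask[masked] = True
        sel = in_mask[tril[0]] | in_mask[tril[1]]
        rows.append({
            "replicate": rep,
            "corr_lhs": _masked_corr(lhs_imp[tril][sel], lhs_full[tril][sel]),
            "corr_rhs": _masked_corr(rhs_imp[masked], rhs_full[masked]),
            "corr_g": _masked_corr(g_imp[masked], g_full[masked]),
            "acc_imputed": _masked_corr(Z_eval @ g_imp, y_eval),
            "acc_full": acc_full,
            "n_masked": n_mask,
            "n_empty_blocks": len(imap.empty_blocks),
        })
    df = pd.DataFrame(rows)
    return MaskEvaluation(replicates=df, summary=_summarize_reps(df))


def rescale_and_evaluate(panel: GenotypePanel, records: PhenotypeRecords,
                         err_var: float, mask_fraction: float,
                         n_replicates: int, seed: int) -> MaskEvaluation:
    """Phenotype-masking validation of precision-matrix rescaling.

    Per replicate, phenotypes of a random ``mask_fraction`` of individuals
    are hidden; the precision matrix rebuilt from the remaining subset is
    compared (correlation and regression slope over lower-triangle entries)
    with the full-population matrix rescaled by n_pheno/n_geno.
    """
    if not 0 < mask_fraction < 1:
        raise DomainError("mask_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = panel.n_indiv
    freq = panel.allele_freq()
    Z = center_genotypes(panel, freq)
    w = residual_precision(records, err_var)
    lhs_full = Z.T @ (Z * w[:, None])
    tril = np.tril_indices(panel.n_snps)
    full_entries = lhs_full[tril]

    n_drop = int(round(mask_fraction * n))
    n_drop = min(max(n_drop, 1), n - 1)
    rows = []
    for rep in range(n_replicates):
        keep = np.sort(rng.choice(n, size=n - n_drop, replace=False))
        Zs = Z[keep]
        lhs_sub = Zs.T @ (Zs * w[keep][:, None])
        scaled = rescale_lhs(lhs_full, len(keep), n)[tril]
        sub = lhs_sub[tril]
        slope = float(np.dot(scaled - scaled.mean(), sub - sub.mean())
                      / np.dot(scaled - scaled.mean(), scaled - scaled.mean()))
        rows.append({
            "replicate": rep,
            "corr": _masked_corr(sub, scaled),
            "slope": slope,
            "n_pheno": len(keep),
        })
    df = pd.DataFrame(rows)
    return MaskEvaluation(replicates=df, summary=_summarize_reps(df))
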