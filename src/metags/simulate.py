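"""Synthetic multi-population sire-model datasets with block LD.

Genotypes come from a founder-pool copy-with-mutation scheme: within each
LD block of adjacent SNPs a small pool of founder haplotypes is drawn once
(shared by all populations, emulating common ancestral LD), every sampled
haplotype copies one founder and flips each allele with a mutation
probability μ.  With the default two complementary founders every SNP is
polymorphic near frequency 0.5 and the dosage correlation between any two
SNPs of a block is approximately (1 − 2μ)², so a target within-block LD r
maps to μ = (1 − √r)/2; a target of 0 gives μ = ½, i.e. independent sites.
Blocks are independent, so LD is block-diagonal by construction.

Per-SNP effects across the c populations are multivariate normal with the
covariance Σ_ik = corr_ik √(σ²_iσ²_k) √(θ_iθ_k) computed from realized
frequencies, which makes the expected DGV variance equal σ²_i exactly.
Phenotypes follow the sire model directly: y_k = μ_pop + DGV_k + e_k with
var(e_k) = σ²_e / n_k and effective daughter counts n_k drawn uniformly —
equivalent to averaging individually simulated daughters, at no cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .types import (CovarianceSpec, GenotypePanel, JointDataset,
                    PhenotypeRecords, SimScenario)

__all__ = ["simulate_genotypes", "simulate_effects_and_phenotypes",
           "simulate_dataset", "SimulatedPopulation"]


def _mutation_rate(within_block_ld: float) -> float:
    # adjacent-dosage correlation ~ (1-2mu)^2 with complementary founders
    return 0.5 * (1.0 - np.sqrt(within_block_ld))


def simulate_genotypes(scenario: SimScenario) -> list[GenotypePanel]:
    """Draw per-population genotype panels; deterministic given the seed.

    SNPs falling below ``maf_min`` minor allele frequency in any population
    are dropped from all populations, so panels share one SNP list.
    """
    rng = np.random.default_rng(scenario.seed)
    m, K = scenario.n_snps, scenario.n_founders
    mu = _mutation_rate(scenario.within_block_ld)

    # chromosome labels, then blocks of block_len within each chromosome
    per_chrom = np.full(scenario.n_chrom, m // scenario.n_chrom)
    per_chrom[:m % scenario.n_chrom] += 1
    chrom = np.concatenate([np.full(c, str(i + 1), dtype=object)
                            for i, c in enumerate(per_chrom)])
    blocks = []
    pos = 0
    for c in per_chrom:
        for s in range(pos, pos + c, scenario.block_len):
            blocks.append((s, min(s + scenario.block_len, pos + c)))
        pos += c

    founders = np.empty((K, m), dtype=np.int8)
    for start, stop in blocks:
        width = stop - start
        if K == 2:
            f0 = rng.integers(0, 2, size=width, dtype=np.int8)
            founders[0, start:stop] = f0
            founders[1, start:stop] = 1 - f0
        else:
            founders[:, start:stop] = rng.integers(0, 2, size=(K, width),
                                                   dtype=np.int8)

    snp_ids = np.array([f"{c}:snp{j:06d}" for j, c in enumerate(chrom)],
                       dtype=object)
    panels = []
    for p, n in enumerate(scenario.n_indiv):
        hap = np.empty((2 * n, m), dtype=np.int8)
        for start, stop in blocks:
            pick = rng.integers(0, K, size=2 * n)
            block = founders[pick][:, start:stop]
            flips = rng.random((2 * n, stop - start)) < mu
            hap[:, start:stop] = block ^ flips
        dosage = hap[0::2] + hap[1::2]
        indiv_ids = np.array([f"p{p + 1}_i{k:05d}" for k in range(n)],
                             dtype=object)
        panels.append(GenotypePanel(snp_ids, chrom, dosage, indiv_ids))

    keep = np.ones(m, dtype=bool)
    for panel in panels:
        freq = panel.allele_freq()
        maf = np.minimum(freq, 1 - freq)
        keep &= maf >= scenario.maf_min
    if not keep.any():
        raise DomainError("minor-allele-frequency filter removed every SNP")
    return [panel.subset_snps(np.flatnonzero(keep)) for panel in panels]


@dataclass
class SimulatedPopulation:
    """Ground truth attached to one simulated population."""

    true_effects: np.ndarray
    records: PhenotypeRecords
    true_dgv: np.ndarray


def simulate_effects_and_phenotypes(
        scenario: SimScenario,
        panels: list[GenotypePanel]) -> list[SimulatedPopulation]:
    """Draw correlated per-SNP effects and sire-model phenotypes.

    Uses a seed derived from the scenario so that genotype and phenotype
    draws are independent streams but jointly reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(1)[0])
    c = scenario.n_pops
    m = panels[0].n_snps
    theta = np.array([1.0 / np.sum(2 * f * (1 - f))
                      for f in (p.allele_freq() for p in panels)])
    sd = np.sqrt(np.asarray(scenario.dgv_var))
    S = scenario.effect_corr * np.outer(sd, sd) * np.outer(np.sqrt(theta),
                                                           np.sqrt(theta))
    L = np.linalg.cholesky(S + 1e-12 * np.eye(c) * np.trace(S))
    effects = L @ rng.standard_normal((c, m))

    out = []
    lo, hi = scenario.daughter_count_range
    for i, panel in enumerate(panels):
        freq = panel.allele_freq()
        Z = panel.dosage.astype(float) - 2 * freq
        dgv = Z @ effects[i]
        n_k = rng.integers(lo, hi + 1, size=panel.n_indiv).astype(float)
        e = rng.standard_normal(panel.n_indiv) * np.sqrt(
            scenario.err_var[i] / n_k)
        y = scenario.mean[i] + dgv + e
        out.append(SimulatedPopulation(
            true_effects=effects[i],
            records=PhenotypeRecords(y=y, n_daughters=n_k,
                                     indiv_ids=panel.indiv_ids),
            true_dgv=dgv))
    return out


def simulate_dataset(scenario: SimScenario) -> tuple[JointDataset,
                                                     list[SimulatedPopulation]]:
    """Genotypes, effects and phenotypes bundled as a JointDataset."""
    panels = simulate_genotypes(scenario)
    sims = simulate_effects_and_phenotypes(scenario, panels)
    theta = np.array([1.0 / np.sum(2 * f * (1 - f))
                      for f in (p.allele_freq() for p in panels)])
    spec = CovarianceSpec(dgv_var=np.asarray(scenario.dgv_var),
                          corr=scenario.effect_corr, theta=theta)
    data = JointDataset(panels=panels, records=[s.records for s in sims],
                        spec=spec, err_var=scenario.err_var)
    return data, sims
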