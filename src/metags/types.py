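"""Core data containers shared across the metags modules.

The containers mirror what actually moves between parties in a
summary-statistic genomic evaluation: raw genotype/phenotype panels stay
with each data holder (:class:`GenotypePanel`, :class:`PhenotypeRecords`),
while :class:`PopulationSummary` is the complete set of statistics a holder
shares — the precision matrix Z'R⁻¹Z, the right-hand side Z'R⁻¹y and/or the
solved SNP effects, allele frequencies, and the variance components needed
to rebuild the mixed model equations centrally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import AlignmentError, DomainError, InvalidFrequencyError


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class GenotypePanel:
    """Genotype dosages for one population.

    ``dosage`` holds counts of the reference allele (0/1/2) with one row per
    individual and one column per SNP, the coding every participating
    population must share for their summaries to be combinable.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    dosage: np.ndarray
    indiv_ids: np.ndarray

    def __post_init__(self):
        self.snp_ids = _as_str_array(self.snp_ids)
        self.chrom = _as_str_array(self.chrom)
        self.indiv_ids = _as_str_array(self.indiv_ids)
        self.dosage = np.asarray(self.dosage)
        n, m = self.dosage.shape
        if len(self.snp_ids) != m:
            raise AlignmentError(
                f"{len(self.snp_ids)} SNP ids for {m} dosage columns")
        if len(self.chrom) != m:
            raise AlignmentError(
                f"{len(self.chrom)} chromosome labels for {m} SNPs")
        if len(self.indiv_ids) != n:
            raise AlignmentError(
                f"{len(self.indiv_ids)} individual ids for {n} dosage rows")
        if len(set(self.snp_ids)) != m:
            raise AlignmentError("SNP ids are not unique")
        if not np.isin(self.dosage, (0, 1, 2)).all():
            bad = self.dosage[~np.isin(self.dosage, (0, 1, 2))]
            raise DomainError(
                f"dosage entries must be 0, 1 or 2; found e.g. {bad.flat[0]!r}")

    @property
    def n_indiv(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Reference-allele frequency per SNP: mean dosage / 2."""
        return self.dosage.mean(axis=0) / 2.0

    def subset_individuals(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(self.snp_ids, self.chrom,
                             self.dosage[idx], self.indiv_ids[idx])

    def subset_snps(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(self.snp_ids[idx], self.chrom[idx],
                             self.dosage[:, idx], self.indiv_ids)


@dataclass
class PhenotypeRecords:
    """Corrected phenotypes with sire-model weights.

    ``y`` is the phenotype corrected for everything but the additive genomic
    effect (a daughter average in a sire model); ``n_daughters`` is the
    effective number of daughters n_ik behind each average, which sets the
    residual precision n_ik/σ²_e of that record.
    """

    y: np.ndarray
    n_daughters: np.ndarray
    indiv_ids: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.n_daughters = np.asarray(self.n_daughters, dtype=float)
        if self.y.shape != self.n_daughters.shape or self.y.ndim != 1:
            raise AlignmentError("y and n_daughters must be equal-length vectors")
        if not (self.n_daughters > 0).all():
            raise DomainError("effective daughter counts must be strictly positive")
        if self.indiv_ids is not None:
            self.indiv_ids = _as_str_array(self.indiv_ids)
            if len(self.indiv_ids) != len(self.y):
                raise AlignmentError("indiv_ids length does not match y")

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class ScalingTheta:
    """θ = 1 / Σ_j 2 p_j (1 − p_j): converts the variance of direct genomic
    values into the common per-SNP effect variance σ²·θ."""

    theta: float

    def __post_init__(self):
        self.theta = float(self.theta)
        if not self.theta > 0:
            raise DomainError(f"theta must be positive, got {self.theta}")


@dataclass
class PopulationSummary:
    """Everything one data holder shares for one population and trait."""

    snp_ids: np.ndarray
    allele_freq: np.ndarray
    lhs: np.ndarray
    dgv_var: float
    err_var: float
    n_pheno: int
    n_geno: int
    rhs: np.ndarray | None = None
    effects: np.ndarray | None = None
    population: str = "pop"
    trait: str = "trait"

    def __post_init__(self):
        self.snp_ids = _as_str_array(self.snp_ids)
        self.allele_freq = np.asarray(self.allele_freq, dtype=float)
        self.lhs = np.asarray(self.lhs, dtype=float)
        m = len(self.snp_ids)
        if self.allele_freq.shape != (m,):
            raise AlignmentError("allele_freq does not match snp_ids")
        if ((self.allele_freq <= 0) | (self.allele_freq >= 1)).any():
            raise InvalidFrequencyError(
                "allele frequencies must lie strictly inside (0, 1)")
        if self.lhs.shape != (m, m):
            raise AlignmentError(f"lhs shape {self.lhs.shape}, expected ({m}, {m})")
        if self.rhs is not None:
            self.rhs = np.asarray(self.rhs, dtype=float)
            if self.rhs.shape != (m,):
                raise AlignmentError("rhs does not match snp_ids")
        if self.effects is not None:
            self.effects = np.asarray(self.effects, dtype=float)
            if self.effects.shape != (m,):
                raise AlignmentError("effects do not match snp_ids")
        if self.rhs is None and self.effects is None:
            raise AlignmentError("summary must carry rhs or effects (or both)")
        if not self.dgv_var > 0:
            raise DomainError("dgv_var must be positive")
        if not self.err_var > 0:
            raise DomainError("err_var must be positive")
        if not 0 < self.n_pheno <= self.n_geno:
            raise DomainError(
                f"need 0 < n_pheno <= n_geno, got {self.n_pheno}, {self.n_geno}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class CovarianceSpec:
    """Across-population SNP-effect covariance inputs.

    ``corr`` is the genetic correlation of breeding values between
    populations (estimated externally, e.g. with REML software); together
    with the per-population DGV variances and θ scalings it defines the
    across-population effect covariance Σ_ik = corr_ik √(σ²_i σ²_k) √(θ_i θ_k).
    """

    dgv_var: np.ndarray
    corr: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        self.dgv_var = np.atleast_1d(np.asarray(self.dgv_var, dtype=float))
        self.corr = np.atleast_2d(np.asarray(self.corr, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        c = len(self.dgv_var)
        if self.corr.shape != (c, c):
            raise AlignmentError(f"corr shape {self.corr.shape}, expected ({c}, {c})")
        if self.theta.shape != (c,):
            raise AlignmentError("theta length does not match dgv_var")
        if not (self.dgv_var > 0).all():
            raise DomainError("dgv_var entries must be positive")
        if not (self.theta > 0).all():
            raise DomainError("theta entries must be positive")
        if not np.allclose(self.corr, self.corr.T, atol=1e-12):
            raise AlignmentError("corr must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-12):
            raise DomainError("corr must have a unit diagonal")
        if (np.abs(self.corr) > 1 + 1e-12).any():
            raise DomainError("corr entries must lie in [-1, 1]")

    @property
    def n_pops(self) -> int:
        return len(self.dgv_var)


@dataclass
class MetaSystem:
    """Assembled across-population mixed model equations.

    Block ordering is population-major: rows/columns [0, m) belong to
    population 1's SNP effects, [m, 2m) to population 2's, and so on.
    """

    block_lhs: np.ndarray
    block_rhs: np.ndarray
    n_pops: int
    snp_ids: np.ndarray
    solutions: list[np.ndarray] | None = None

    def __post_init__(self):
        self.block_lhs = np.asarray(self.block_lhs, dtype=float)
        self.block_rhs = np.asarray(self.block_rhs, dtype=float)
        self.snp_ids = _as_str_array(self.snp_ids)
        cm = self.n_pops * len(self.snp_ids)
        if self.block_lhs.shape != (cm, cm):
            raise AlignmentError(
                f"block_lhs shape {self.block_lhs.shape}, expected ({cm}, {cm})")
        if self.block_rhs.shape != (cm,):
            raise AlignmentError("block_rhs length does not match block_lhs")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class ImputationBlock:
    """One LD block of the block-diagonal T matrix."""

    chrom: str
    start: int                # first complete-list index of the block
    stop: int                 # one past the last complete-list index
    obs_local: np.ndarray     # observed SNP positions within [start, stop)
    obs_rows: np.ndarray      # positions of those SNPs in the observed list
    T: np.ndarray             # (n_observed_in_block, stop - start)

    @property
    def width(self) -> int:
        return self.stop - self.start


@dataclass
class ImputationMap:
    """Block-diagonal mapping from a population's observed SNP set to the
    complete SNP set, estimated on a reference genotype panel."""

    blocks: list[ImputationBlock]
    observed_ids: np.ndarray
    complete_ids: np.ndarray
    ridge: float

    def __post_init__(self):
        self.observed_ids = _as_str_array(self.observed_ids)
        self.complete_ids = _as_str_array(self.complete_ids)
        covered = sorted(i for b in self.blocks for i in range(b.start, b.stop))
        if covered != list(range(len(self.complete_ids))):
            raise AlignmentError("blocks do not partition the complete SNP list")

    @property
    def empty_blocks(self) -> list[int]:
        """Indices of blocks containing no observed SNP (not imputable)."""
        return [i for i, b in enumerate(self.blocks) if b.T.shape[0] == 0]

    @property
    def n_observed(self) -> int:
        return len(self.observed_ids)

    @property
    def n_complete(self) -> int:
        return len(self.complete_ids)


@dataclass
class SimScenario:
    """Parameters of the synthetic multi-population sire-model dataset.

    Defaults describe the standard two-breed benchmark used throughout the
    test-suite: a large and a small population (800 and 300 sires), 2,000
    SNPs in 200-SNP LD blocks with strong within-block dosage correlation,
    cross-population effect correlation 0.5, unit DGV variance and a
    daughter-average error variance of 10 trait-units² spread over 10–100
    effective daughters per sire.
    """

    n_pops: int = 2
    n_indiv: Sequence[int] = (800, 300)
    n_snps: int = 2000
    n_chrom: int = 2
    block_len: int = 200
    within_block_ld: float = 0.8
    maf_min: float = 0.05
    effect_corr: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.5], [0.5, 1.0]]))
    dgv_var: Sequence[float] = (1.0, 1.0)
    err_var: Sequence[float] = (10.0, 10.0)
    daughter_count_range: Sequence[int] = (10, 100)
    mean: Sequence[float] | None = None
    n_founders: int = 2
    seed: int = 0

    def __post_init__(self):
        self.n_indiv = tuple(int(n) for n in self.n_indiv)
        self.effect_corr = np.atleast_2d(np.asarray(self.effect_corr, dtype=float))
        self.dgv_var = tuple(float(v) for v in self.dgv_var)
        self.err_var = tuple(float(v) for v in self.err_var)
        self.daughter_count_range = tuple(int(v) for v in self.daughter_count_range)
        if self.mean is None:
            self.mean = tuple(1.0 + 0.5 * i for i in range(self.n_pops))
        else:
            self.mean = tuple(float(v) for v in self.mean)
        c = self.n_pops
        if len(self.n_indiv) != c or len(self.dgv_var) != c or \
                len(self.err_var) != c or len(self.mean) != c:
            raise AlignmentError("per-population parameter lengths must equal n_pops")
        if self.effect_corr.shape != (c, c):
            raise AlignmentError("effect_corr must be n_pops x n_pops")
        if not 0 < self.maf_min < 0.5:
            raise DomainError("maf_min must lie in (0, 0.5)")
        if not 0.0 <= self.within_block_ld < 1.0:
            raise DomainError(
                "within_block_ld must lie in [0, 1); a target of 1 or more "
                "is infeasible")
        if self.block_len < 1 or self.n_snps < 1 or self.n_chrom < 1:
            raise DomainError("n_snps, n_chrom and block_len must be positive")
        if self.n_founders < 2:
            raise DomainError("need at least two founder haplotypes")
        lo, hi = self.daughter_count_range
        if not 0 < lo <= hi:
            raise DomainError("daughter_count_range must be positive and ordered")


@dataclass
class JointDataset:
    """Raw multi-population data for the joint (oracle) analysis."""

    panels: list[GenotypePanel]
    records: list[PhenotypeRecords]
    spec: CovarianceSpec
    err_var: Sequence[float] = ()

    def __post_init__(self):
        self.err_var = tuple(float(v) for v in self.err_var)
        if len(self.err_var) != self.spec.n_pops:
            raise AlignmentError("err_var must list one value per population")
        if not all(v > 0 for v in self.err_var):
            raise DomainError("err_var entries must be positive")
        if not (len(self.panels) == len(self.records) == self.spec.n_pops):
            raise AlignmentError("panels, records and spec must agree on n_pops")
        ref = self.panels[0].snp_ids
        for p in self.panels[1:]:
            if not np.array_equal(p.snp_ids, ref):
                raise AlignmentError("all panels must share one ordered SNP list")
        for p, r in zip(self.panels, self.records):
            if p.n_indiv != len(r):
                raise AlignmentError("panel and phenotype record lengths differ")
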