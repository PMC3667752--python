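"""Simulation frameworks: synthetic genotype cohorts with imposed pairwise
IBD structure, and split-chromosome phenotypes over real genotype input.

Synthetic-genotype design
-------------------------
Individuals carry two binary haplotypes per SNP, drawn Bernoulli(p_i) with
minor allele frequencies p_i ~ U(0.05, 0.5).  Observed SNPs stand for the
genotyping platform; an equally sized unobserved set stands for variants
not in LD with it.  A pair sharing fraction ``x`` of its genome IBD is made
by copying the first member's haplotypes onto the second at a uniformly
random subset of positions: both haplotypes at an ``ibd2`` fraction of
positions and one haplotype at a disjoint ``2 (x - ibd2)`` fraction, so the
expected standardized-IBS relatedness equals ``x`` and the both-chromosome
fraction equals ``ibd2``.  By default ``ibd2 = x`` (both haplotypes copied
everywhere selected); sib-realistic pairs use ``(0.5, 0.25)`` and
parent-offspring-like pairs ``(0.5, 0.0)``.

The phenotype is additive over all SNPs: each standardized genotype
(realized sample moments) times a per-SNP effect ``sqrt(h2_set / m_set)``,
plus Gaussian noise — at the defaults (5,000 + 5,000 SNPs, h2 0.25 + 0.25)
the effect is ``sqrt(0.5/10000)`` and the noise variance 0.5, giving a
trait with variance ~1 and heritability 50%, half from observed SNPs.  An
optional dominance-like variance adds a pair-shared component whose
covariance structure matches the IBD2 matrix.

Split-chromosome design
-----------------------
On any genotype matrix with chromosome labels, causal variants are picked
every ``spacing`` SNPs along the even chromosomes (observed set) and again
along the odd chromosomes (unobserved set); sub-phenotypes are allele
counts times per-set effect sizes plus per-set noise, and the true
heritabilities follow from the realized genotypic variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PairwiseIBDTable, PhenotypeTable


@dataclass(frozen=True)
class PairBlock:
    """A block of independent pairs sharing a common IBD structure."""
    n_pairs: int
    ibd: float
    ibd2: float | None = None  # None -> ibd (both haplotypes copied)

    def resolved_ibd2(self) -> float:
        return self.ibd if self.ibd2 is None else self.ibd2

    def validate(self) -> None:
        x, x2 = self.ibd, self.resolved_ibd2()
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"ibd fraction {x} outside [0, 1]")
        if not (0.0 <= x2 <= x):
            raise ValueError(f"need 0 <= ibd2 <= ibd, got ({x}, {x2})")
        if 2 * x - x2 > 1.0 + 1e-12:
            raise ValueError(
                f"ibd structure ({x}, {x2}) needs more than the whole genome")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")


@dataclass
class SimulationSpec:
    """Generative conditions for one synthetic cohort.

    Defaults are the reference design: 700 pairs at 50% IBD, 5,000 observed
    and 5,000 unobserved SNPs, MAF ~ U(0.05, 0.5), heritability 0.25 from
    each SNP set (per-SNP effect sqrt(0.5/10000)), noise variance 0.5.
    """

    pair_blocks: list = field(default_factory=lambda: [PairBlock(700, 0.5)])
    m_observed: int = 5000
    m_unobserved: int = 5000
    maf_range: tuple = (0.05, 0.5)
    h2_observed: float = 0.25
    h2_unobserved: float = 0.25
    dominance_var: float = 0.0
    shared_pair_var: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.pair_blocks = [b if isinstance(b, PairBlock) else PairBlock(*b)
                            for b in self.pair_blocks]
        for b in self.pair_blocks:
            b.validate()
        tot = (self.h2_observed + self.h2_unobserved + self.dominance_var
               + self.shared_pair_var)
        if not (0.0 <= tot < 1.0):
            raise ValueError("variance shares must sum to less than 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must lie inside (0, 1)")

    @property
    def n_individuals(self) -> int:
        return 2 * sum(b.n_pairs for b in self.pair_blocks)


@dataclass
class SimulatedCohort:
    observed: GenotypeMatrix
    unobserved: GenotypeMatrix
    true_ibd: PairwiseIBDTable
    phenotype: PhenotypeTable
    true_params: dict  # h2_total, h2_g

    @property
    def sample_ids(self) -> list[str]:
        return self.observed.sample_ids


def _standardize(counts: np.ndarray) -> np.ndarray:
    """Column-standardize allele counts with realized sample moments.

    Columns that happen to be monomorphic in the realized draw are zeroed
    (they carry no genetic variance)."""
    n = counts.shape[0]
    x = counts.astype(np.float64)
    mu = x.mean(axis=0)
    # single-pass second moment; entries are small integers so this is exact
    var = np.einsum("ij,ij->j", x, x) / n - mu * mu
    sd = np.sqrt(np.maximum(var, 0.0))
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd_safe
    z[:, sd == 0] = 0.0
    return z


def simulate_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Generate one cohort under the synthetic-genotype design.

    All randomness flows from ``spec.seed``; identical specs give
    byte-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    m = spec.m_observed + spec.m_unobserved
    lo, hi = spec.maf_range
    p = rng.uniform(lo, hi, size=m)

    h1 = (rng.random((n, m)) < p).astype(np.int8)
    h2 = (rng.random((n, m)) < p).astype(np.int8)

    ids = [f"i{k:05d}" for k in range(n)]
    table = PairwiseIBDTable()
    pair_index = []  # (row_a, row_b, realized_ibd2) for phenotype structure
    row = 0
    for block in spec.pair_blocks:
        x, x2 = block.ibd, block.resolved_ibd2()
        n_both = int(np.floor(x2 * m))
        n_one = int(np.floor(2.0 * (x - x2) * m))
        for _ in range(block.n_pairs):
            a, b = row, row + 1
            perm = rng.permutation(m)
            both = perm[:n_both]
            one = perm[n_both:n_both + n_one]
            h1[b, both] = h1[a, both]
            h2[b, both] = h2[a, both]
            h1[b, one] = h1[a, one]
            ibd_real = (n_both + 0.5 * n_one) / m
            ibd2_real = n_both / m
            if ibd_real > 0:
                table.add_pair(ids[a], ids[b], ibd_real, ibd2_real)
            pair_index.append((a, b, ibd2_real))
            row += 2

    counts = h1 + h2
    mo = spec.m_observed
    observed = GenotypeMatrix(ids, [f"snp{j}" for j in range(mo)],
                              counts[:, :mo],
                              haplotypes=(h1[:, :mo].copy(), h2[:, :mo].copy()))
    unobserved = GenotypeMatrix(ids, [f"usnp{j}" for j in range(m - mo)],
                                counts[:, mo:])

    # additive genetic values on standardized genotypes
    z = _standardize(counts)
    g = np.zeros(n)
    if spec.m_observed and spec.h2_observed > 0:
        g += z[:, :mo] @ np.full(mo, np.sqrt(spec.h2_observed / mo))
    if spec.m_unobserved and spec.h2_unobserved > 0:
        g += z[:, mo:] @ np.full(m - mo, np.sqrt(spec.h2_unobserved / (m - mo)))

    # optional dominance-like pair component whose covariance matrix is
    # exactly dominance_var * K_IBD2 (pair covariance scales with the
    # realized IBD2 fraction)
    d = np.zeros(n)
    if spec.dominance_var > 0:
        sd_d = np.sqrt(spec.dominance_var)
        for a, b, x2 in pair_index:
            shared = rng.standard_normal()
            own_a, own_b = rng.standard_normal(2)
            d[a] = sd_d * (np.sqrt(x2) * shared + np.sqrt(1 - x2) * own_a)
            d[b] = sd_d * (np.sqrt(x2) * shared + np.sqrt(1 - x2) * own_b)

    # optional shared-pair effect: an identical draw added to both members
    # of every IBD2-sharing pair (covariance = variance = shared_pair_var),
    # emulating a common family environment for full sibs
    s = np.zeros(n)
    if spec.shared_pair_var > 0:
        sd_s = np.sqrt(spec.shared_pair_var)
        for a, b, x2 in pair_index:
            if x2 > 0:
                s[a] = s[b] = sd_s * rng.standard_normal()
            else:
                s[a], s[b] = sd_s * rng.standard_normal(2)

    noise_var = (1.0 - spec.h2_observed - spec.h2_unobserved
                 - spec.dominance_var - spec.shared_pair_var)
    y = g + d + s + rng.normal(0.0, np.sqrt(noise_var), size=n)

    pheno = PhenotypeTable(pd.DataFrame({"trait": y}, index=pd.Index(ids, name="id")))
    true_params = {"h2_total": spec.h2_observed + spec.h2_unobserved,
                   "h2_g": spec.h2_observed,
                   "dominance_var": spec.dominance_var}
    return SimulatedCohort(observed, unobserved, table, pheno, true_params)


def split_chromosome_phenotype(G: GenotypeMatrix, spacing: int,
                               alpha1: float, alpha2: float,
                               noise1: float, noise2: float,
                               seed: int = 0) -> tuple[PhenotypeTable, dict]:
    """Phenotype from causal variants on even vs odd chromosomes.

    Causal set C1 takes every ``spacing``-th SNP (map order) among the
    even-chromosome SNPs, C2 likewise among the odd; sub-phenotype k sums
    allele counts times ``alpha_k`` plus N(0, noise_k) noise, and the final
    phenotype is their sum.  Even chromosomes play the role of the observed
    genotypes, so the true SNP heritability uses the realized genotypic
    variance of C1 only.
    """
    if G.chrom is None:
        raise ValueError("genotype matrix has no chromosome labels")
    if spacing < 1:
        raise ValueError("spacing must be at least 1")
    chrom = np.asarray(G.chrom)
    if np.unique(chrom).size < 2:
        raise ValueError("need at least two chromosomes")
    for c in np.unique(chrom):
        if spacing > (chrom == c).sum():
            warnings.warn(f"spacing {spacing} exceeds the {int((chrom == c).sum())} "
                          f"SNPs on chromosome {c}; it contributes no causal "
                          "variant", RuntimeWarning)
    rng = np.random.default_rng(seed)
    counts = np.where(G.counts == -1, 0, G.counts).astype(float)
    even_idx = np.flatnonzero(chrom % 2 == 0)
    odd_idx = np.flatnonzero(chrom % 2 == 1)
    C1 = even_idx[::spacing]
    C2 = odd_idx[::spacing]
    for name, C in (("C1", C1), ("C2", C2)):
        if C.size == 0:
            warnings.warn(f"causal set {name} is empty", RuntimeWarning)
    n = G.n_samples
    g1 = counts[:, C1].sum(axis=1) * alpha1 if C1.size else np.zeros(n)
    g2 = counts[:, C2].sum(axis=1) * alpha2 if C2.size else np.zeros(n)
    y = (g1 + rng.normal(0.0, np.sqrt(noise1), n)
         + g2 + rng.normal(0.0, np.sqrt(noise2), n))
    v1 = float(np.var(g1, ddof=1)) if n > 1 else 0.0
    v2 = float(np.var(g2, ddof=1)) if n > 1 else 0.0
    vtot = v1 + v2 + noise1 + noise2
    true_params = {"h2_total": (v1 + v2) / vtot, "h2_g": v1 / vtot,
                   "causal_observed": [G.snp_ids[j] for j in C1],
                   "causal_unobserved": [G.snp_ids[j] for j in C2]}
    pheno = PhenotypeTable(pd.DataFrame({"trait": y},
                                        index=pd.Index(G.sample_ids, name="id")))
    return pheno, true_params


def replicate_study(spec: SimulationSpec, n_replicates: int,
                    estimators: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run estimators over replicate cohorts; per-replicate seeds are
    ``spec.seed + replicate index``.

    ``estimators`` maps a name to a callable ``cohort -> float``.  Returns
    (summary with mean/sd per estimator, per-replicate values).
    """
    records = {name: [] for name in estimators}
    for i in range(n_replicates):
        cohort = simulate_cohort(replace(spec, seed=spec.seed + i))
        for name, fn in estimators.items():
            records[name].append(float(fn(cohort)))
    values = pd.DataFrame(records)
    summary = pd.DataFrame({
        "estimator": list(estimators),
        "mean": [values[n].mean() for n in estimators],
        "sd": [values[n].std(ddof=1) if n_replicates > 1 else np.nan
               for n in estimators],
        "n_replicates": n_replicates,
    }).set_index("estimator")
    return summary, values
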