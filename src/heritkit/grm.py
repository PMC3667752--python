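"""Genetic relationship matrices: standardized IBS, thresholded IBS, IBD, IBD2.

Four covariance structures drive the mixed models:

* ``IBS`` — the standardized allele-sharing correlation.  Off-diagonal entry
  (j,k) is ``(1/N) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``
  over N SNPs with in-sample frequencies p_i; the diagonal is ``1 + F_j``
  with F_j the usual inbreeding-coefficient estimate.
* ``IBS_THRESHOLDED`` — the IBS matrix with every off-diagonal entry at or
  below a threshold t set to zero (the diagonal is never changed), which
  isolates close relatives.
* ``IBD`` — realized genome-sharing fractions; entry (j,k) is the fraction
  of the genome shared identical-by-descent (sharing one of the two
  haplotypes at a site counts 1/2, sharing both counts 1), and the diagonal
  is 1 plus the maternal-paternal sharing fraction.
* ``IBD2`` — the fraction of the genome where both chromosomes are shared;
  the diagonal is fixed at 1.

IBS-type matrices may additionally be mean-centered on the off-diagonal;
IBD-type matrices are never centered.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PairwiseIBDTable, ValidationError


class Kind(enum.Enum):
    IBS = "IBS"
    IBS_THRESHOLDED = "IBS_THRESHOLDED"
    IBD = "IBD"
    IBD2 = "IBD2"


class DegenerateSNPError(ValueError):
    """A SNP is monomorphic in-sample, so its standardized score is undefined."""


@dataclass
class KinshipMatrix:
    """Symmetric relatedness matrix tagged with its kind and conventions."""

    kind: Kind
    values: np.ndarray
    sample_ids: list[str]
    threshold: float | None = None
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError("kinship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("kinship matrix is not symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([index[s] for s in ids])
        return KinshipMatrix(self.kind, self.values[np.ix_(rows, rows)],
                             list(ids), self.threshold, self.centered)


def _standardized_scores(G: GenotypeMatrix) -> np.ndarray:
    """Centered, variance-standardized genotype scores with mean imputation.

    Missing entries are imputed to 2 p_i (a centered score of zero), so they
    contribute nothing to cross-products.
    """
    freqs = G.freqs
    degenerate = ~((freqs > 0.0) & (freqs < 1.0))
    if degenerate.any():
        bad = [G.snp_ids[i] for i in np.flatnonzero(degenerate)[:5]]
        raise DegenerateSNPError(
            f"monomorphic or all-missing SNP(s) in sample: {bad}")
    x = G.counts.astype(np.float64)
    x[G.counts == MISSING] = np.nan
    z = (x - 2.0 * freqs) / np.sqrt(2.0 * freqs * (1.0 - freqs))
    return np.nan_to_num(z, nan=0.0)


def build_ibs(G: GenotypeMatrix) -> KinshipMatrix:
    """Standardized IBS relationship matrix from an allele-count matrix.

    Off-diagonal entries are the average standardized-score cross-products;
    diagonal entry (j,j) is ``1 + F_j`` where F_j averages
    ``(x^2 - (1 + 2p) x + 2 p^2) / (2 p (1 - p))`` over SNPs, the
    inbreeding-coefficient estimate.
    """
    z = _standardized_scores(G)
    N = G.n_snps
    K = (z @ z.T) / N
    # replace the diagonal with the inbreeding-based estimate; missing
    # entries contribute zero (their imputed centered score carries no
    # information about inbreeding)
    p = G.freqs
    x = G.counts.astype(np.float64)
    diag_terms = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / (2.0 * p * (1.0 - p))
    diag_terms[G.counts == MISSING] = 0.0
    np.fill_diagonal(K, 1.0 + diag_terms.mean(axis=1))
    return KinshipMatrix(Kind.IBS, K, list(G.sample_ids))


def threshold_ibs(K: KinshipMatrix, t: float) -> KinshipMatrix:
    """Zero all off-diagonal entries at or below ``t``; diagonal untouched.

    Thresholding retains close relatives only: with t around 0.05 the
    (numerically mean-zero) entries between distant relatives vanish while
    sib- and parent-offspring-level relatedness survives.  Idempotent.
    """
    if K.kind not in (Kind.IBS, Kind.IBS_THRESHOLDED):
        raise ValidationError(f"cannot threshold a {K.kind.name} matrix")
    if t < 0:
        raise ValueError("threshold t must be non-negative")
    V = K.values.copy()
    diag = np.diag(V).copy()
    V[V <= t] = 0.0
    np.fill_diagonal(V, diag)
    return KinshipMatrix(Kind.IBS_THRESHOLDED, V, list(K.sample_ids),
                         threshold=t, centered=K.centered)


def center_ibs(K: KinshipMatrix) -> KinshipMatrix:
    """Shift off-diagonal entries to grand mean zero; diagonal untouched.

    Only IBS-type matrices are centered; IBD-type matrices keep their
    absolute genome-sharing scale.  Calling it twice is a no-op.
    """
    if K.kind not in (Kind.IBS, Kind.IBS_THRESHOLDED):
        raise ValidationError(f"{K.kind.name} matrices are not centered")
    if K.centered:
        return KinshipMatrix(K.kind, K.values.copy(), list(K.sample_ids),
                             K.threshold, centered=True)
    V = K.values.copy()
    n = V.shape[0]
    mask = ~np.eye(n, dtype=bool)
    V[mask] -= V[mask].mean()
    return KinshipMatrix(K.kind, V, list(K.sample_ids), K.threshold,
                         centered=True)


def build_ibd(table: PairwiseIBDTable, ids: Sequence[str]) -> KinshipMatrix:
    """IBD relationship matrix from a pairwise table.

    Entry (j,k) is the recorded genome-sharing fraction (0 when absent);
    entry (j,j) is 1 plus the maternal-paternal sharing fraction.
    """
    V = _from_table(table, ids, which=0)
    np.fill_diagonal(V, [1.0 + table.get_selfing(s) for s in ids])
    return KinshipMatrix(Kind.IBD, V, list(ids))


def build_ibd2(table: PairwiseIBDTable, ids: Sequence[str]) -> KinshipMatrix:
    """IBD2 relationship matrix: both-chromosome sharing, unit diagonal."""
    V = _from_table(table, ids, which=1)
    np.fill_diagonal(V, 1.0)
    return KinshipMatrix(Kind.IBD2, V, list(ids))


def prune_pairs(K: KinshipMatrix, t: float) -> list[str]:
    """Greedily drop one member of every pair with relatedness above ``t``.

    Returns the retained sample ids (original order); afterwards no kept
    pair exceeds ``t``.  This is the classical alternative to the joint
    model: estimate SNP heritability on nominally unrelated individuals
    only, at the cost of sample size and estimator variance.
    """
    n = K.n
    keep = np.ones(n, dtype=bool)
    ii, jj = np.nonzero(np.triu(K.values > t, k=1))
    for i, j in zip(ii, jj):
        if keep[i] and keep[j]:
            keep[j] = False
    return [s for s, k in zip(K.sample_ids, keep) if k]


def _from_table(table: PairwiseIBDTable, ids: Sequence[str], which: int) -> np.ndarray:
    n = len(ids)
    V = np.zeros((n, n))
    index = {s: i for i, s in enumerate(ids)}
    for key, vals in table.pairs.items():
        pair = tuple(key)
        if len(pair) != 2:
            continue
        a, b = pair
        if a in index and b in index:
            i, j = index[a], index[b]
            V[i, j] = V[j, i] = vals[which]
    return V
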