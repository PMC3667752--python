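"""Readers and writers for the external formats the toolbox touches.

Formats
-------
* PLINK ``.bed/.bim/.fam`` triples (SNP-major 2-bit genotypes).
* GCTA binary GRM triples (``.grm.bin``, ``.grm.N.bin``, ``.grm.id``).
* Plain-text genotype matrices (rows = samples, columns = SNPs).
* Pairwise IBD/IBD2 fraction tables.
* Phenotype + covariate tables.

Conventions: genotype entries are allele counts in {0, 1, 2}; missing
genotypes are stored as ``-1`` in the integer matrix; sample alignment
between any two inputs is always by identifier, in the order of the first
input.  All text output is UTF-8 and tab-delimited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

# PLINK bed magic: 0x6c 0x1b, then 0x01 for SNP-major layout.
_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# 2-bit bed codes -> allele count of the alternate allele.
# 0b00 = homozygous reference (0 copies), 0b10 = heterozygote (1),
# 0b11 = homozygous alternate (2), 0b01 = missing.
_BED_CODE_TO_COUNT = np.array([0, MISSING, 1, 2], dtype=np.int8)
_COUNT_TO_BED_CODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}


class FormatError(ValueError):
    """A file does not conform to its declared binary/text format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix with in-sample frequencies.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per row.
    snp_ids : list of str
        One identifier per column.
    counts : ndarray of int8, shape (n, m)
        Allele counts in {0, 1, 2}; missing entries are ``-1``.
    haplotypes : optional pair of (n, m) binary arrays
        Maternal/paternal 0-1 matrices whose elementwise sum equals
        ``counts`` wherever counts is non-missing.
    chrom : optional ndarray of int, shape (m,)
        Chromosome label per SNP (used by the split-chromosome simulator).
    """

    sample_ids: list[str]
    snp_ids: list[str]
    counts: np.ndarray
    haplotypes: tuple[np.ndarray, np.ndarray] | None = None
    chrom: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        n, m = self.counts.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValidationError("id lists do not match matrix shape")
        valid = np.isin(self.counts, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValidationError("genotype entries must be 0, 1, 2 or missing")
        if self.haplotypes is not None:
            h1, h2 = self.haplotypes
            ok = self.counts == MISSING
            if not np.array_equal((h1 + h2)[~ok], self.counts[~ok]):
                raise ValidationError("haplotypes do not sum to counts")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        """In-sample frequency of the counted allele, missing excluded."""
        c = self.counts
        obs = c != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs, c, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        """Rows for ``ids`` in the given order (frequencies recompute lazily)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        haps = None
        if self.haplotypes is not None:
            haps = (self.haplotypes[0][rows], self.haplotypes[1][rows])
        return GenotypeMatrix(list(ids), list(self.snp_ids), self.counts[rows],
                              haplotypes=haps, chrom=self.chrom)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        snp_ids = [s for s, keep in zip(self.snp_ids, mask) if keep]
        haps = None
        if self.haplotypes is not None:
            haps = (self.haplotypes[0][:, mask], self.haplotypes[1][:, mask])
        chrom = self.chrom[mask] if self.chrom is not None else None
        return GenotypeMatrix(list(self.sample_ids), snp_ids,
                              self.counts[:, mask], haplotypes=haps, chrom=chrom)


@dataclass
class PairwiseIBDTable:
    """Pairwise genome-sharing fractions plus per-individual self records.

    ``pairs`` maps an unordered id pair to ``(ibd, ibd2)`` genome fractions;
    ``selfing`` maps an id to the maternal-paternal sharing fraction used on
    the IBD-matrix diagonal (1 + selfing).  Absent pairs are 0.
    """

    pairs: dict[frozenset, tuple[float, float]] = field(default_factory=dict)
    selfing: dict[str, float] = field(default_factory=dict)

    def add_pair(self, a: str, b: str, ibd: float, ibd2: float = 0.0) -> None:
        if not (0.0 <= ibd2 <= ibd <= 1.0):
            raise ValidationError(
                f"pair ({a},{b}): need 0 <= ibd2 <= ibd <= 1, got ibd={ibd}, ibd2={ibd2}")
        key = frozenset((a, b))
        if key in self.pairs and self.pairs[key] != (ibd, ibd2):
            raise ValidationError(f"conflicting records for pair ({a},{b})")
        self.pairs[key] = (float(ibd), float(ibd2))

    def get(self, a: str, b: str) -> tuple[float, float]:
        return self.pairs.get(frozenset((a, b)), (0.0, 0.0))

    def get_selfing(self, a: str) -> float:
        return self.selfing.get(a, 0.0)


@dataclass
class PhenotypeTable:
    """Trait values and fixed-effect covariates keyed by sample id."""

    data: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in phenotype table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def trait(self, name: str) -> pd.Series:
        return self.data[name]

    def aligned(self, ids: Sequence[str]) -> pd.DataFrame:
        missing = set(ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"ids absent from phenotype table: {sorted(missing)[:5]}")
        return self.data.loc[list(ids)]


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a SNP-major PLINK ``.bed/.bim/.fam`` triple.

    The heterozygote code maps to 1 and the homozygous-alternate code to 2;
    the missing code is preserved as missing.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      dtype=str)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      dtype={0: str, 1: str})
    sample_ids = list(fam[1])
    snp_ids = list(bim[1])
    chrom = pd.to_numeric(bim[0], errors="coerce").fillna(0).astype(int).to_numpy()
    n, m = len(sample_ids), len(snp_ids)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise FormatError(f"{prefix}.bed: individual-major layout is unsupported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise FormatError(
            f"{prefix}.bed: expected {bytes_per_snp * m} data bytes, found {body.size}")
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample 0 in the lowest-order bits of each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    counts = _BED_CODE_TO_COUNT[codes].T.copy()
    return GenotypeMatrix(sample_ids, snp_ids, counts, chrom=chrom)


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a SNP-major PLINK triple."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.counts.shape
    with open(prefix.with_suffix(".fam"), "w", encoding="utf-8") as fh:
        for s in G.sample_ids:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    chrom = G.chrom if G.chrom is not None else np.ones(m, dtype=int)
    with open(prefix.with_suffix(".bim"), "w", encoding="utf-8") as fh:
        for j, s in enumerate(G.snp_ids):
            fh.write(f"{chrom[j]}\t{s}\t0\t{j + 1}\tA\tB\n")
    code_lut = np.empty(4, dtype=np.uint8)
    for cnt, code in _COUNT_TO_BED_CODE.items():
        code_lut[cnt % 4] = code  # MISSING=-1 wraps to index 3
    codes = code_lut[G.counts.T % 4].astype(np.uint8)  # (m, n)
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes.reshape(m, -1, 4) << shifts[None, None, :]).sum(axis=2,
                                                                    dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Plain-text genotypes
# ---------------------------------------------------------------------------


def read_genotype_text(path: str | Path) -> GenotypeMatrix:
    """Read a plain-text genotype matrix: header of SNP ids, rows = samples."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    counts = df.to_numpy()
    counts = np.where(pd.isna(counts), MISSING, counts).astype(np.int8)
    return GenotypeMatrix([str(s) for s in df.index], [str(c) for c in df.columns],
                          counts)


def write_genotype_text(G: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(G.counts, index=G.sample_ids, columns=G.snp_ids)
    df = df.astype(object).where(df != MISSING, other="NA")
    df.to_csv(path, sep="\t", index_label="id")


# ---------------------------------------------------------------------------
# GCTA binary GRM
# ---------------------------------------------------------------------------


def read_grm_gcta(prefix: str | Path):
    """Read a GCTA GRM triple (``.grm.bin`` lower triangle of 4-byte reals,
    ``.grm.id`` two-column text, optional ``.grm.N.bin``).

    Returns a :class:`~heritkit.grm.KinshipMatrix` with kind taken from the
    companion ``.grm.kind`` metadata file when present, else ``IBS``.
    """
    from .grm import KinshipMatrix, Kind  # local import: avoid cycle

    prefix = Path(prefix)
    ids = pd.read_csv(Path(str(prefix) + ".grm.id"), sep=r"\s+", header=None,
                      dtype=str)
    sample_ids = list(ids[1])
    n = len(sample_ids)
    raw = Path(str(prefix) + ".grm.bin").read_bytes()
    n_tri = n * (n + 1) // 2
    if len(raw) != 4 * n_tri:
        raise FormatError(
            f"{prefix}.grm.bin holds {len(raw)} bytes; need {4 * n_tri} for n={n}")
    tri = np.frombuffer(raw, dtype="<f4").astype(np.float64)
    K = np.zeros((n, n))
    iu = np.tril_indices(n)
    K[iu] = tri
    K = K + K.T - np.diag(np.diag(K))
    kind, threshold, centered = Kind.IBS, None, False
    meta = Path(str(prefix) + ".grm.kind")
    if meta.exists():
        fields = dict(line.split("=", 1) for line in
                      meta.read_text().strip().splitlines())
        kind = Kind[fields["kind"]]
        t = fields.get("threshold", "none")
        threshold = None if t == "none" else float(t)
        centered = fields.get("centered", "false") == "true"
    return KinshipMatrix(kind=kind, values=K, sample_ids=sample_ids,
                         threshold=threshold, centered=centered)


def write_grm_gcta(K, prefix: str | Path, n_snps: int | None = None) -> None:
    """Write a kinship matrix as a GCTA triple plus a ``.grm.kind`` tag file."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = len(K.sample_ids)
    iu = np.tril_indices(n)
    tri = K.values[iu].astype("<f4")
    Path(str(prefix) + ".grm.bin").write_bytes(tri.tobytes())
    nsnp = float(n_snps if n_snps is not None else 0)
    Path(str(prefix) + ".grm.N.bin").write_bytes(
        np.full(tri.shape, nsnp, dtype="<f4").tobytes())
    with open(str(prefix) + ".grm.id", "w", encoding="utf-8") as fh:
        for s in K.sample_ids:
            fh.write(f"{s}\t{s}\n")
    with open(str(prefix) + ".grm.kind", "w", encoding="utf-8") as fh:
        fh.write(f"kind={K.kind.name}\n")
        fh.write(f"threshold={'none' if K.threshold is None else K.threshold}\n")
        fh.write(f"centered={'true' if K.centered else 'false'}\n")


# ---------------------------------------------------------------------------
# IBD tables
# ---------------------------------------------------------------------------


def read_ibd_table(path: str | Path) -> PairwiseIBDTable:
    """Read a pairwise IBD table.

    Whitespace- or comma-delimited text with a header naming at least
    ``id_a id_b ibd`` (``ibd2`` optional).  Rows with ``id_a == id_b`` are
    self records whose ``ibd`` column is the maternal-paternal sharing
    fraction.  Absent pairs imply 0.
    """
    import csv

    table = PairwiseIBDTable()
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype={0: str, 1: str})
    except (pd.errors.EmptyDataError, csv.Error):
        # empty file (or header-only content the sniffer cannot type)
        if Path(path).read_text(encoding="utf-8").strip():
            raise
        return table
    if df.empty:
        return table
    cols = {c.lower(): c for c in df.columns}
    a_col, b_col = cols.get("id_a", df.columns[0]), cols.get("id_b", df.columns[1])
    ibd_col = cols.get("ibd", df.columns[2])
    ibd2_col = cols.get("ibd2")
    for _, row in df.iterrows():
        a, b = str(row[a_col]), str(row[b_col])
        ibd = float(row[ibd_col])
        ibd2 = float(row[ibd2_col]) if ibd2_col is not None else 0.0
        if a == b:
            table.selfing[a] = ibd
        else:
            table.add_pair(a, b, ibd, ibd2)
    return table


def write_ibd_table(table: PairwiseIBDTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tibd\tibd2\n")
        for key in sorted(table.pairs, key=lambda k: tuple(sorted(k))):
            a, b = sorted(key)
            ibd, ibd2 = table.pairs[key]
            fh.write(f"{a}\t{b}\t{ibd:.10g}\t{ibd2:.10g}\n")
        for s in sorted(table.selfing):
            fh.write(f"{s}\t{s}\t{table.selfing[s]:.10g}\t0\n")


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype/covariate table; first column is the sample id."""
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="id")
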