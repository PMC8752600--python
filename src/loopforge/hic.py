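"""Contact-matrix container, COO text I/O, cis normalization and O/E transforms.

The matrix model is deliberately minimal: one chromosome per
:class:`ContactMatrix`, binned at a fixed resolution, symmetric counts
stored as the upper triangle of a sparse matrix.  ``total_cis`` counts
every unordered bin pair once and includes the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "read_coo",
    "write_coo",
    "read_chromsizes",
    "normalize_cis",
    "expected_profile",
    "oe_transform",
]


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact map for one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    resolution : int
        Bin size in bp.
    counts : scipy.sparse.csr_matrix
        Upper-triangular (including diagonal) count storage; the full
        symmetric matrix is materialized on access via :meth:`dense`.
    """

    chrom: str
    resolution: int
    counts: sp.csr_matrix
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        if self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contact matrix must be square")
        self.n_bins = self.counts.shape[0]
        if (self.counts.data < 0).any():
            raise ValueError("negative contact counts")
        # canonical storage: upper triangle only
        self.counts = sp.triu(self.counts, k=0).tocsr()

    @classmethod
    def from_dense(cls, dense: np.ndarray, chrom: str = "chrS", resolution: int = 10_000) -> "ContactMatrix":
        dense = np.asarray(dense, dtype=float)
        if not np.allclose(dense, dense.T):
            raise ValueError("dense input must be symmetric")
        return cls(chrom=chrom, resolution=resolution, counts=sp.csr_matrix(np.triu(dense)))

    def dense(self) -> np.ndarray:
        """Full symmetric matrix (upper triangle mirrored)."""
        upper = self.counts.toarray()
        return upper + np.triu(upper, k=1).T

    @property
    def total_cis(self) -> float:
        """Sum over unique unordered bin pairs, diagonal counted once."""
        return float(self.counts.sum())

    def copy_with(self, dense: np.ndarray) -> "ContactMatrix":
        return ContactMatrix.from_dense(dense, chrom=self.chrom, resolution=self.resolution)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactMatrix):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.resolution == other.resolution
            and self.n_bins == other.n_bins
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class ExpectedProfile:
    """Mean count per diagonal offset, the distance-decay background."""

    values: np.ndarray  # length n_bins, values[d] = mean count at offset d
    smoothing_window: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("expected profile must be nonnegative")


def read_chromsizes(path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` text file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes


def read_coo(path, chrom: str, chrom_length: int, resolution: int) -> ContactMatrix:
    """Read ``bin1 bin2 count`` triplets into a ContactMatrix.

    Entries may appear in either triangle; they are mirrored into the
    upper triangle.  Duplicate pixels are summed.
    """
    n_bins = -(-chrom_length // resolution)
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            if i >= n_bins or j >= n_bins or i < 0 or j < 0:
                raise ValueError(f"{path}:{lineno}: bin id out of range (n_bins={n_bins})")
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if i > j:
                i, j = j, i
            rows.append(i)
            cols.append(j)
            vals.append(v)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n_bins, n_bins)).tocsr()
    return ContactMatrix(chrom=chrom, resolution=resolution, counts=mat)


def write_coo(matrix: ContactMatrix, path) -> None:
    """Write the upper triangle as ``bin1 bin2 count`` triplets."""
    coo = matrix.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            if v == int(v):
                fh.write(f"{i}\t{j}\t{int(v)}\n")
            else:
                fh.write(f"{i}\t{j}\t{v!r}\n")


def normalize_cis(matrix: ContactMatrix, target_total: float) -> ContactMatrix:
    """Scale counts so the total cis pairs equal ``target_total``."""
    total = matrix.total_cis
    if total == 0:
        raise ValueError("cannot normalize a matrix with zero cis contacts")
    scaled = matrix.counts * (target_total / total)
    return ContactMatrix(chrom=matrix.chrom, resolution=matrix.resolution, counts=scaled)


def expected_profile(matrix: ContactMatrix, smooth: bool = False) -> ExpectedProfile:
    """Mean count per diagonal offset.

    ``expected[d]`` is the mean over the ``n_bins - d`` pixels at offset
    ``d``.  With ``smooth=True`` a 3-bin running mean is applied beyond
    offset 2 (kept off by default so small-matrix oracles are exact).
    """
    n = matrix.n_bins
    upper = matrix.counts.toarray()
    exp = np.zeros(n)
    for d in range(n):
        exp[d] = np.diagonal(upper, offset=d).mean()
    if smooth:
        sm = exp.copy()
        for d in range(2, n - 1):
            sm[d] = exp[d - 1 : d + 2].mean()
        exp = sm
    return ExpectedProfile(values=exp, smoothing_window=3 if smooth else 0)


def oe_transform(matrix: ContactMatrix, profile: ExpectedProfile | None = None) -> np.ndarray:
    """Observed-over-expected dense matrix; 0 where the expectation is 0."""
    if profile is None:
        profile = expected_profile(matrix)
    dense = matrix.dense()
    n = matrix.n_bins
    offs = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp = profile.values[offs]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, dense / np.where(exp > 0, exp, 1.0), 0.0)
    return oe
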