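"""Bit-sliced genotype representation and popcount contingency tables.

Each SNP is stored as three binary presence/absence vectors, one per
genotype value (0, 1, 2), split by phenotype class and packed into 64-bit
words.  The cell count for any genotype combination of a k-SNP tuple is
then the popcount of the bitwise AND of the k corresponding class
vectors, so building a 2 x 3^k contingency table costs O(3^k * k * n/64)
word operations instead of O(k * n) per-sample comparisons.

Missing genotypes set no bit in any of the three vectors, so a sample
with a failed call at any SNP of a tuple silently drops out of every
cell of that tuple's table (tuple-wise complete-case analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class ContingencyTable:
    """2 x 3^k phenotype-by-genotype-combination count table.

    Row 0 holds controls, row 1 cases.  Column ``j`` corresponds to the
    genotype combination whose base-3 digits are ``j`` written with the
    FIRST SNP of the tuple as the most significant digit (a fixed,
    documented enumeration; the chi-squared statistic is invariant to it).
    """

    k: int
    counts: np.ndarray  # (2, 3**k) int64

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (2, 3**self.k):
            raise ValueError(f"counts must be 2 x {3**self.k} for k={self.k}")
        if (counts < 0).any():
            raise ValueError("negative cell count")
        object.__setattr__(self, "counts", counts)

    @property
    def n_cells(self) -> int:
        """|V| = 3^k, the number of genotype combinations."""
        return 3**self.k

    @property
    def row_marginals(self) -> np.ndarray:
        """n_i+ : per-phenotype-class totals."""
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        """n_+j : per-genotype-combination totals."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        """n : samples with complete genotypes at every SNP of the tuple."""
        return int(self.counts.sum())


@dataclass
class BitSlicedDataset:
    """Packed per-class binary genotype vectors for a whole cohort.

    ``words[c]`` has shape (m, 3, words_per_class[c]) with dtype uint64;
    bit ``j`` of word ``w`` for (SNP s, genotype g, class c) is set iff
    the (w*64+j)-th class-c sample (in stable input order) carries
    genotype ``g`` at SNP ``s``.  Padding bits beyond the class size are
    always zero.
    """

    m: int
    class_sizes: tuple[int, int]  # (n_controls, n_cases)
    words: tuple[np.ndarray, np.ndarray]  # per class: (m, 3, n_words) uint64
    snp_ids: list[str]

    @property
    def words_per_class(self) -> tuple[int, int]:
        return (self.words[0].shape[2], self.words[1].shape[2])


def _pack_bool(mask: np.ndarray) -> np.ndarray:
    """Pack a (m, n) boolean array into (m, ceil(n/64)) uint64 words."""
    m, n = mask.shape
    n_words = max(1, (n + 63) // 64)
    packed8 = np.packbits(mask, axis=1, bitorder="little")
    out8 = np.zeros((m, n_words * 8), dtype=np.uint8)
    out8[:, : packed8.shape[1]] = packed8
    return out8.view(np.uint64)


def binarise(gm: GenotypeMatrix) -> BitSlicedDataset:
    """Convert a genotype matrix into the bit-sliced per-class form.

    Samples are grouped by phenotype class before packing, so each
    (SNP, genotype, class) vector spans only that class's samples, in
    their stable order of appearance in ``gm``.
    """
    per_class = []
    sizes = []
    for c in (0, 1):
        idx = np.flatnonzero(gm.phenotypes == c)
        sizes.append(len(idx))
        sub = gm.genotypes[:, idx]
        planes = [_pack_bool(sub == g) for g in (0, 1, 2)]
        per_class.append(np.ascontiguousarray(np.stack(planes, axis=1)))
    return BitSlicedDataset(
        m=gm.m,
        class_sizes=(sizes[0], sizes[1]),
        words=(per_class[0], per_class[1]),
        snp_ids=list(gm.snp_ids),
    )


def _check_tuple(indices: Sequence[int], m: int) -> tuple[int, ...]:
    tup = tuple(int(i) for i in indices)
    if len(tup) < 1:
        raise ValueError("tuple must contain at least one SNP index")
    if len(set(tup)) != len(tup):
        raise ValueError(f"duplicate SNP index in tuple {tup}")
    for i in tup:
        if not 0 <= i < m:
            raise ValueError(f"SNP index {i} out of range [0, {m})")
    return tup


def build_contingency_table(
    ds: BitSlicedDataset, indices: Sequence[int]
) -> ContingencyTable:
    """Build the 2 x 3^k table for a SNP tuple with AND + popcount."""
    tup = _check_tuple(indices, ds.m)
    k = len(tup)
    counts = np.zeros((2, 3**k), dtype=np.int64)
    for c in (0, 1):
        w = ds.words[c]
        for j in range(3**k):
            digits = []
            v = j
            for _ in range(k):
                digits.append(v % 3)
                v //= 3
            digits.reverse()  # first tuple SNP = most significant digit
            acc = w[tup[0], digits[0]]
            for snp, g in zip(tup[1:], digits[1:]):
                acc = acc & w[snp, g]
            counts[c, j] = int(np.bitwise_count(acc).sum())
    return ContingencyTable(k=k, counts=counts)


def naive_contingency_table(
    gm: GenotypeMatrix, indices: Sequence[int]
) -> ContingencyTable:
    """Reference oracle: build the same table by per-sample iteration.

    Iterates over samples one by one, skipping any sample with a MISSING
    genotype at any SNP of the tuple; uses the identical column
    enumeration as :func:`build_contingency_table`.
    """
    tup = _check_tuple(indices, gm.m)
    k = len(tup)
    counts = np.zeros((2, 3**k), dtype=np.int64)
    for s in range(gm.n):
        col = 0
        ok = True
        for snp in tup:
            g = int(gm.genotypes[snp, s])
            if g == MISSING:
                ok = False
                break
            col = col * 3 + g
        if ok:
            counts[int(gm.phenotypes[s]), col] += 1
    return ContingencyTable(k=k, counts=counts)
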