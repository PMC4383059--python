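"""Combinadic tuple indexing, workload partitioning and the scan executor.

Every k-SNP tuple (x_k > ... > x_1, 0-based) maps to a unique linear
index via the combinatorial number system,

    index = C(x_k, k) + ... + C(x_2, 2) + C(x_1, 1),

a bijection onto [0, C(m, k)).  The index space is split into contiguous,
near-equal intervals, one per worker; each worker decodes its interval,
builds contingency tables from the shared bit-sliced dataset, scores
them, and a single merge step concatenates the per-worker results in
rank order.  Output is bit-identical for any worker count.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from ._kernels import scan_interval_chi2
from .bitslice import BitSlicedDataset, binarise, build_contingency_table
from .genotype_io import GenotypeMatrix
from .stats import DegenerateTableError, evaluate_statistic


class ResultCapExceeded(RuntimeError):
    """A scan kept more results than the configured cap."""


def count_interactions(m: int, k: int) -> int:
    """Total number of k-way interactions among m SNPs: C(m, k), exact."""
    if k < 1:
        raise ValueError(f"order k must be >= 1, got {k}")
    if k > m:
        raise ValueError(f"order k={k} exceeds SNP count m={m}")
    return math.comb(m, k)


def rank_tuple(indices: Sequence[int]) -> int:
    """Map a strictly decreasing SNP tuple to its combinadic linear index."""
    tup = tuple(int(i) for i in indices)
    k = len(tup)
    if k < 1:
        raise ValueError("empty tuple")
    for a, b in zip(tup, tup[1:]):
        if a <= b:
            raise ValueError(
                f"tuple {tup} must be strictly decreasing (x_k > ... > x_1) "
                "to avoid duplicate tests"
            )
    if tup[-1] < 0:
        raise ValueError("SNP indices must be non-negative")
    return sum(math.comb(x, k - i) for i, x in enumerate(tup))


def unrank_index(index: int, k: int) -> tuple[int, ...]:
    """Inverse of :func:`rank_tuple` by greedy combinadic decoding.

    For i = k down to 1, picks the largest x_i with C(x_i, i) <= the
    remaining index, subtracts, and continues.
    """
    if index < 0:
        raise ValueError(f"index must be non-negative, got {index}")
    if k < 1:
        raise ValueError(f"order k must be >= 1, got {k}")
    rem = int(index)
    out: list[int] = []
    for i in range(k, 0, -1):
        x = i - 1  # C(i-1, i) = 0, always admissible
        while math.comb(x + 1, i) <= rem:
            x += 1
        rem -= math.comb(x, i)
        out.append(x)
    return tuple(out)


@dataclass(frozen=True)
class WorkPartition:
    """A worker's contiguous slice [start, end) of the linear index space."""

    rank: int
    n_workers: int
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start


def assign_interactions(rank: int, n_workers: int, m: int, k: int) -> WorkPartition:
    """Compute worker ``rank``'s interval of the C(m, k) interaction indices.

    Base size floor(C(m,k)/N_P); the first C(m,k) mod N_P workers get one
    extra, so sizes differ by at most one and the intervals tile
    [0, C(m,k)) disjointly.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if not 0 <= rank < n_workers:
        raise ValueError(f"rank {rank} out of range [0, {n_workers})")
    total = count_interactions(m, k)
    base, rem = divmod(total, n_workers)
    start = rank * base + min(rank, rem)
    end = start + base + (1 if rank < rem else 0)
    return WorkPartition(rank=rank, n_workers=n_workers, start=start, end=end)


class InteractionResult(NamedTuple):
    """One scored SNP tuple kept by the scan."""

    snp_indices: tuple[int, ...]  # strictly decreasing (x_k > ... > x_1)
    linear_index: int
    score: float
    p_value: float
    df: int


@dataclass
class ScanConfig:
    """Configuration of an exhaustive k-way interaction scan."""

    k: int
    threshold: float = -math.inf
    threshold_space: str = "score"  # "score": keep score >= t; "p_value": keep p <= t
    statistic: str = "chi2"
    n_workers: int = 1
    chunk_size: int = 4096  # sub-scheduling granularity inside a worker
    max_results: int = 10**7
    seed: int | None = field(default=None)  # reserved; the scan is deterministic

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("interaction order k must be >= 1")
        if self.threshold_space not in ("score", "p_value"):
            raise ValueError("threshold_space must be 'score' or 'p_value'")
        if math.isnan(self.threshold):
            raise ValueError("threshold must not be NaN")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")


def _score_threshold(cfg: ScanConfig, df: int) -> float:
    """Translate the configured threshold into score space (chi2 fast path)."""
    if cfg.threshold_space == "score":
        return cfg.threshold
    # p <= t  <=>  score >= isf(t, df), by monotonicity of the sf
    if cfg.threshold >= 1.0:
        return -math.inf
    if cfg.threshold <= 0.0:
        return math.inf
    return float(_chi2_dist.isf(cfg.threshold, df))


def _scan_arrays(
    ds: BitSlicedDataset, cfg: ScanConfig
) -> tuple[np.ndarray, np.ndarray, int]:
    """Chi-squared fast path: scan all intervals, return merged arrays.

    Returns (linear_indices, scores, df); the merge is the rank-0
    concatenation of per-worker buffers in rank order, which preserves
    ascending linear-index order because intervals are contiguous.
    """
    m, k = ds.m, cfg.k
    total = count_interactions(m, k)
    df = 3**k - 1
    thresh = _score_threshold(cfg, df)
    parts = [assign_interactions(r, cfg.n_workers, m, k) for r in range(cfg.n_workers)]

    def work(part: WorkPartition) -> tuple[np.ndarray, np.ndarray, int]:
        if part.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.float64), -1
        x0 = np.array(unrank_index(part.start, k)[::-1], dtype=np.int64)  # ascending
        out_idx = np.empty(part.size, dtype=np.int64)
        out_score = np.empty(part.size, dtype=np.float64)
        n_kept, err = scan_interval_chi2(
            ds.words[0], ds.words[1], x0, part.start, part.end, thresh,
            out_idx, out_score,
        )
        return out_idx[:n_kept], out_score[:n_kept], int(err)

    if cfg.n_workers == 1:
        outputs = [work(parts[0])]
    else:
        with ThreadPoolExecutor(max_workers=cfg.n_workers) as pool:
            outputs = list(pool.map(work, parts))

    for _, _, err in outputs:
        if err >= 0:
            tup = unrank_index(err, k)
            raise DegenerateTableError(
                f"degenerate contingency table (empty phenotype row) for tuple "
                f"{tup} at linear index {err}"
            )
    idx = np.concatenate([o[0] for o in outputs])
    scores = np.concatenate([o[1] for o in outputs])
    if idx.size > cfg.max_results:
        raise ResultCapExceeded(
            f"scan kept {idx.size} results, exceeding max_results="
            f"{cfg.max_results}; raise the threshold or the cap"
        )
    assert idx.size <= total
    return idx, scores, df


def _scan_generic(ds: BitSlicedDataset, cfg: ScanConfig) -> list[InteractionResult]:
    """Registry path: per-tuple Python evaluation of any named statistic.

    Iterates each worker interval in chunks of ``cfg.chunk_size`` tuples
    (the desk-scale analogue of a dynamic sub-scheduler).
    """
    m, k = ds.m, cfg.k
    results: list[InteractionResult] = []
    for r in range(cfg.n_workers):
        part = assign_interactions(r, cfg.n_workers, m, k)
        for chunk_start in range(part.start, part.end, cfg.chunk_size):
            chunk_end = min(chunk_start + cfg.chunk_size, part.end)
            for lin in range(chunk_start, chunk_end):
                tup = unrank_index(lin, k)
                ct = build_contingency_table(ds, tup)
                try:
                    res = evaluate_statistic(ct, cfg.statistic)
                except Exception as exc:
                    raise type(exc)(
                        f"statistic {cfg.statistic!r} failed on tuple {tup} "
                        f"(linear index {lin}): {exc}"
                    ) from exc
                keep = (
                    res.score >= cfg.threshold
                    if cfg.threshold_space == "score"
                    else res.p_value <= cfg.threshold
                )
                if keep:
                    results.append(
                        InteractionResult(tup, lin, res.score, res.p_value, res.df)
                    )
                if len(results) > cfg.max_results:
                    raise ResultCapExceeded(
                        f"scan kept more than max_results={cfg.max_results}"
                    )
    return results


def run_scan(gm: GenotypeMatrix, cfg: ScanConfig) -> list[InteractionResult]:
    """Exhaustively score every k-SNP tuple and keep the passing ones.

    The genotype matrix is bit-sliced once and shared read-only by all
    workers; each worker evaluates a private contiguous interval of the
    combinadic index space and the results are merged in linear-index
    order.  The output is identical for any ``cfg.n_workers``.
    """
    if cfg.k > gm.m:
        raise ValueError(f"order k={cfg.k} exceeds SNP count m={gm.m}")
    ds = binarise(gm)
    if cfg.statistic == "chi2":
        idx, scores, df = _scan_arrays(ds, cfg)
        pvals = _chi2_dist.sf(scores, df)
        return [
            InteractionResult(unrank_index(int(i), cfg.k), int(i), float(s), float(p), df)
            for i, s, p in zip(idx, scores, pvals)
        ]
    return _scan_generic(ds, cfg)


def write_results(
    results: Sequence[InteractionResult], gm: GenotypeMatrix, path: str
) -> None:
    """Write scan results as a TSV, one row per kept interaction.

    Columns: comma-joined SNP ids (descending-index tuple order),
    comma-joined 0-based indices, linear index, score, df, p-value.
    Rows must already be sorted by linear index.
    """
    last = -1
    with open(path, "w") as fh:
        fh.write("snp_ids\tsnp_indices\tlinear_index\tscore\tdf\tp_value\n")
        for res in results:
            if res.linear_index <= last:
                raise ValueError("results must be sorted by linear_index")
            last = res.linear_index
            ids = ",".join(gm.snp_ids[i] for i in res.snp_indices)
            idxs = ",".join(str(i) for i in res.snp_indices)
            fh.write(
                f"{ids}\t{idxs}\t{res.linear_index}\t{res.score:.10g}\t"
                f"{res.df}\t{res.p_value:.6g}\n"
            )
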