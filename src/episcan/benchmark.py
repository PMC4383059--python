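"""Strong-scaling measurement and cross-study runtime projection.

Strong scaling fixes the problem (one keep-all scan of a fixed cohort)
and varies the worker count N, reporting speedup S = t_1 / t_N and
efficiency E = S / N.  Timings cover binarisation, the scan kernel and
the rank-0 merge of per-worker result buffers; file I/O and conversion
of kept results into Python objects are excluded.  Each configuration
is measured ``repeats`` times and the minimum wall time kept, damping
scheduler noise.

Runtime projection re-expresses runtimes reported by other pairwise
interaction studies on common hardware and data size (1.1 million SNPs,
2000 samples) via

    t = t_orig * (1.1e6 / n_SNP)^2 * (2000 / n_sample)
               * (n_cores / C_ref) * (f_clock / f_ref)

with (C_ref, f_ref) = (262144, 1.6 GHz) for CPU studies and
(448, 1.22 GHz) for GPU studies, assuming runtime linear in the number
of pairs, in samples, and inversely in aggregate thread throughput.
Projection across interaction orders assumes perfectly linear scaling
with the interaction count: t_k_to = t_k_from * C(m, k_to) / C(m, k_from).
"""

from __future__ import annotations

import math
import os
import time
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

from .genotype_io import GenotypeMatrix
from .partition import ScanConfig, _scan_arrays, count_interactions
from .bitslice import binarise

#: Reference hardware of the scaling formulas: (threads, clock GHz).
CPU_REFERENCE = (262144, 1.6)
GPU_REFERENCE = (448, 1.22)
#: Reference dataset: 1.1 million SNPs, 2000 samples.
REFERENCE_SNPS = 1.1e6
REFERENCE_SAMPLES = 2000.0


@dataclass(frozen=True)
class ScalingRecord:
    """One strong-scaling measurement at a given worker count."""

    n_workers: int
    runtime_seconds: float
    speedup: float  # S = t_1 / t_N
    efficiency: float  # E = S / N


@dataclass(frozen=True)
class RuntimeScalingParams:
    """Hardware and data size under which a runtime was reported."""

    t_orig: float  # reported runtime, minutes
    n_snp: float
    n_sample: float
    n_cores: float  # hardware threads
    f_clock: float  # GHz
    platform: str  # "CPU" or "GPU"

    def __post_init__(self) -> None:
        for name in ("t_orig", "n_snp", "n_sample", "n_cores", "f_clock"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.platform not in ("CPU", "GPU"):
            raise ValueError("platform must be 'CPU' or 'GPU'")


def measure_strong_scaling(
    gm: GenotypeMatrix,
    cfg: ScanConfig,
    worker_counts: Sequence[int],
    repeats: int = 3,
) -> list[ScalingRecord]:
    """Run the identical scan at each worker count and record S and E.

    ``worker_counts`` must start with 1 (the serial baseline t_1).
    Worker counts beyond the machine's core count are measured anyway,
    with a warning — oversubscription cannot speed up a CPU-bound scan.
    """
    counts = list(worker_counts)
    if not counts or counts[0] != 1 or any(c < 1 for c in counts):
        raise ValueError("worker_counts must be non-empty and start with 1")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    available = os.cpu_count() or 1
    records: list[ScalingRecord] = []
    t1 = None
    for n_workers in counts:
        if n_workers > available:
            warnings.warn(
                f"{n_workers} workers on {available} available core(s); "
                "no speedup is possible beyond the core count",
                stacklevel=2,
            )
        run_cfg = replace(cfg, n_workers=n_workers)
        best = math.inf
        for _ in range(repeats):
            start = time.perf_counter()
            ds = binarise(gm)
            _scan_arrays(ds, run_cfg)
            best = min(best, time.perf_counter() - start)
        if t1 is None:
            t1 = best
        speedup = t1 / best
        records.append(
            ScalingRecord(
                n_workers=n_workers,
                runtime_seconds=best,
                speedup=speedup,
                efficiency=speedup / n_workers,
            )
        )
    return records


def scale_reported_runtime(p: RuntimeScalingParams) -> float:
    """Project a reported runtime onto the reference hardware/data size.

    Returns minutes at full precision; round only for presentation.
    """
    ref_cores, ref_clock = CPU_REFERENCE if p.platform == "CPU" else GPU_REFERENCE
    return (
        p.t_orig
        * (REFERENCE_SNPS / p.n_snp) ** 2
        * (REFERENCE_SAMPLES / p.n_sample)
        * (p.n_cores / ref_cores)
        * (p.f_clock / ref_clock)
    )


def extrapolate_higher_order(
    t_measured: float, m: int, k_from: int, k_to: int
) -> float:
    """Project a measured order-k_from runtime to order k_to.

    Assumes runtime perfectly linear in the number of interactions:
    t * C(m, k_to) / C(m, k_from), evaluated in exact rational
    arithmetic before the final float conversion.
    """
    if k_from >= k_to:
        raise ValueError(f"need k_from < k_to, got {k_from} >= {k_to}")
    ratio = Fraction(count_interactions(m, k_to), count_interactions(m, k_from))
    return float(Fraction(t_measured) * ratio)
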