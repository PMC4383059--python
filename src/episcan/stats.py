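"""Contingency-table statistics: Pearson's chi-squared and a registry.

The scan scores each k-way SNP tuple by a statistic computed on its
2 x 3^k contingency table.  Pearson's chi-squared,

    chi2 = sum_ij (n_ij - E_ij)^2 / E_ij,   E_ij = n_i+ * n_+j / n,

with df = |V| - 1 = 3^k - 1, ships as the default ("chi2"); any other
table-based statistic can be registered and selected by name.

Genotype combinations absent from the data (zero column marginal) have
E_ij = 0 and contribute nothing to the sum; the degrees of freedom stay
|V| - 1 regardless (``df_mode="observed"`` switches to counting only
non-empty columns, an intentionally more conservative alternative).  No
continuity correction or minimum-expected-count guard is applied — this
is a fast screening statistic — but results flag tables with any
expected count below 5 so downstream filters can treat them cautiously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .bitslice import ContingencyTable


class DegenerateTableError(ValueError):
    """The table cannot support an independence test (n = 0 or empty row)."""


class UnknownStatisticError(KeyError):
    """Requested statistic name is not registered."""


@dataclass(frozen=True)
class StatisticResult:
    """Score, degrees of freedom and upper-tail p-value for one table."""

    score: float
    df: int
    p_value: float
    low_expected: bool = False  # any cell with expected count < 5


def chi_squared(ct: ContingencyTable, df_mode: str = "full") -> StatisticResult:
    """Pearson's chi-squared test of phenotype/genotype independence.

    Parameters
    ----------
    ct
        The 2 x 3^k contingency table.
    df_mode
        ``"full"`` (default): df = 3^k - 1 regardless of empty columns.
        ``"observed"``: df = (number of non-empty columns) - 1.
    """
    counts = ct.counts.astype(np.float64)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    if n <= 0:
        raise DegenerateTableError("empty table: no samples with complete genotypes")
    if (row <= 0).any():
        raise DegenerateTableError(
            "a phenotype class has no samples; independence is untestable"
        )
    nonzero = col > 0
    expected = np.outer(row, col[nonzero]) / n
    observed = counts[:, nonzero]
    score = float(((observed - expected) ** 2 / expected).sum())
    if df_mode == "full":
        df = ct.n_cells - 1
    elif df_mode == "observed":
        df = max(int(nonzero.sum()) - 1, 1)
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    p_value = float(_chi2_dist.sf(score, df))
    return StatisticResult(
        score=score,
        df=df,
        p_value=p_value,
        low_expected=bool((expected < 5).any()),
    )


Statistic = Callable[[ContingencyTable], StatisticResult]

_REGISTRY: dict[str, Statistic] = {}


def register_statistic(name: str, fn: Statistic) -> None:
    """Register a user-supplied table-based statistic under ``name``."""
    _REGISTRY[name] = fn


def available_statistics() -> list[str]:
    return sorted(_REGISTRY)


def evaluate_statistic(ct: ContingencyTable, statistic: str = "chi2") -> StatisticResult:
    """Dispatch to the named registered statistic."""
    try:
        fn = _REGISTRY[statistic]
    except KeyError:
        raise UnknownStatisticError(
            f"unknown statistic {statistic!r}; available: {available_statistics()}"
        ) from None
    return fn(ct)


register_statistic("chi2", chi_squared)
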