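import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from episcan import (
    ScanConfig,
    assign_interactions,
    count_interactions,
    rank_tuple,
    run_scan,
    unrank_index,
    write_results,
    simulate_dataset,
    PenetranceModel,
)
from episcan.stats import DegenerateTableError
from conftest import make_random_gm


# ---------------------------------------------------------------- combinadics

def test_count_interactions_values():
    assert count_interactions(4, 2) == 6
    assert count_interactions(1_100_000, 2) == 604_999_450_000
    assert count_interactions(10_000, 2) == 49_995_000
    with pytest.raises(ValueError):
        count_interactions(3, 4)
    with pytest.raises(ValueError):
        count_interactions(5, 0)


def test_rank_tuple_examples():
    assert rank_tuple((1, 0)) == 0
    assert rank_tuple((3, 1, 0)) == 1  # C(3,3)+C(1,2)+C(0,1)


def test_rank_is_colex_order_on_all_triples():
    # colex order on the sets = lexicographic order of the descending tuples
    triples = sorted(
        tuple(sorted(t, reverse=True)) for t in itertools.combinations(range(6), 3)
    )
    assert [rank_tuple(t) for t in triples] == list(range(20))


def test_rank_rejects_non_decreasing():
    for bad in [(0, 1), (2, 2), (1,) * 3]:
        with pytest.raises(ValueError):
            rank_tuple(bad)


def test_unrank_examples():
    assert unrank_index(0, 2) == (1, 0)
    assert unrank_index(2, 3) == (3, 2, 0)  # C(3,3)+C(2,2) = 2
    with pytest.raises(ValueError):
        unrank_index(-1, 2)


@pytest.mark.parametrize("m,k", [(25, 2), (25, 3), (25, 4), (7, 1)])
def test_rank_unrank_bijection(m, k):
    total = math.comb(m, k)
    seen = set()
    for idx in range(total):
        tup = unrank_index(idx, k)
        assert rank_tuple(tup) == idx
        assert all(a > b for a, b in zip(tup, tup[1:]))
        assert tup[0] < m
        seen.add(tup)
    assert len(seen) == total


# ----------------------------------------------------------------- partitions

def test_single_worker_takes_all():
    p = assign_interactions(0, 1, 5, 2)
    assert (p.start, p.end) == (0, 10)


def test_remainder_policy_sizes():
    parts = [assign_interactions(r, 3, 5, 2) for r in range(3)]
    assert [p.size for p in parts] == [4, 3, 3]
    assert parts[0].start == 0 and parts[-1].end == 10
    for a, b in zip(parts, parts[1:]):
        assert a.end == b.start


def test_rank_out_of_range():
    with pytest.raises(ValueError):
        assign_interactions(3, 3, 5, 2)
    with pytest.raises(ValueError):
        assign_interactions(-1, 3, 5, 2)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    m=st.integers(2, 40),
    k=st.integers(1, 4),
    n_workers=st.integers(1, 17),
)
def test_partitions_tile_index_space(m, k, n_workers):
    """Union of all worker intervals is [0, C(m,k)), disjoint, near-equal."""
    k = min(k, m)
    total = math.comb(m, k)
    parts = [assign_interactions(r, n_workers, m, k) for r in range(n_workers)]
    assert parts[0].start == 0 and parts[-1].end == total
    for a, b in zip(parts, parts[1:]):
        assert a.end == b.start
    sizes = {p.size for p in parts}
    assert max(sizes) - min(sizes) <= 1


# ----------------------------------------------------------------------- scan

def test_keep_all_scan_counts_and_order():
    gm = make_random_gm(10, 60, seed=0)
    results = run_scan(gm, ScanConfig(k=2))
    assert len(results) == 45
    assert [r.linear_index for r in results] == list(range(45))
    for r in results:
        assert r.snp_indices[0] > r.snp_indices[1]
        assert rank_tuple(r.snp_indices) == r.linear_index
        assert r.df == 8 and 0 <= r.p_value <= 1


def test_keep_none_scan():
    gm = make_random_gm(10, 60, seed=0)
    assert run_scan(gm, ScanConfig(k=2, threshold=math.inf)) == []


def test_worker_count_invariance():
    gm = make_random_gm(30, 150, seed=13, missing_rate=0.05)
    baseline = run_scan(gm, ScanConfig(k=2))
    for n_workers in (2, 3, 8):
        assert run_scan(gm, ScanConfig(k=2, n_workers=n_workers)) == baseline


def test_fast_path_matches_registry_path():
    """The numba chi2 kernel and the generic per-tuple path agree."""
    gm = make_random_gm(12, 90, seed=6, missing_rate=0.05)
    fast = run_scan(gm, ScanConfig(k=2))
    slow = []
    from episcan.bitslice import binarise
    from episcan.partition import _scan_generic

    slow = _scan_generic(binarise(gm), ScanConfig(k=2))
    assert len(fast) == len(slow)
    for a, b in zip(fast, slow):
        assert a.snp_indices == b.snp_indices
        assert a.linear_index == b.linear_index
        assert a.score == pytest.approx(b.score, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)


def test_score_and_pvalue_thresholds_agree():
    """Thresholding on p <= t keeps the same set as the matched score cut."""
    gm = make_random_gm(15, 120, seed=21)
    by_p = run_scan(gm, ScanConfig(k=2, threshold=0.05, threshold_space="p_value"))
    all_res = run_scan(gm, ScanConfig(k=2))
    expected = [r for r in all_res if r.p_value <= 0.05]
    assert by_p == expected
    assert 0 < len(by_p) < len(all_res)


def test_k3_scan_counts():
    gm = make_random_gm(9, 50, seed=8)
    results = run_scan(gm, ScanConfig(k=3))
    assert len(results) == math.comb(9, 3)
    assert all(r.df == 26 for r in results)


def test_k_exceeds_m_errors():
    gm = make_random_gm(4, 30, seed=1)
    with pytest.raises(ValueError):
        run_scan(gm, ScanConfig(k=5))


def test_degenerate_tuple_identified():
    """A SNP that is entirely missing in one class degenerates every table
    containing it; the error names the offending tuple."""
    gm = make_random_gm(5, 40, seed=2)
    geno = gm.genotypes.copy()
    geno[3, :] = -1  # all calls missing at SNP 3
    gm2 = type(gm)(gm.snp_ids, geno, gm.phenotypes)
    with pytest.raises(DegenerateTableError, match=r"\(3,"):
        run_scan(gm2, ScanConfig(k=2))


def test_embedded_pair_is_top_hit():
    gm = simulate_dataset(
        m=50, n=400, seed=17,
        model=PenetranceModel.xor_pair(high=0.8, low=0.1),
        effect_tuple=(10, 3), target_cases=200,
    )
    results = run_scan(gm, ScanConfig(k=2))
    top = max(results, key=lambda r: r.score)
    assert top.snp_indices == (10, 3)


# --------------------------------------------------------------------- output

def test_write_results_empty(tmp_path):
    gm = make_random_gm(4, 20, seed=0)
    out = tmp_path / "res.tsv"
    write_results([], gm, out)
    assert out.read_text().splitlines() == [
        "snp_ids\tsnp_indices\tlinear_index\tscore\tdf\tp_value"
    ]


def test_write_results_round_trip(tmp_path):
    gm = make_random_gm(10, 80, seed=4)
    results = run_scan(gm, ScanConfig(k=2))
    out = tmp_path / "res.tsv"
    write_results(results, gm, out)
    lines = out.read_text().splitlines()
    assert len(lines) == 46  # header + C(10,2)
    fields = lines[1].split("\t")
    r0 = results[0]
    assert fields[0] == ",".join(gm.snp_ids[i] for i in r0.snp_indices)
    assert tuple(int(x) for x in fields[1].split(",")) == r0.snp_indices
    assert int(fields[2]) == r0.linear_index
    assert float(fields[3]) == pytest.approx(r0.score, rel=1e-9)
    assert int(fields[4]) == r0.df
    assert float(fields[5]) == pytest.approx(r0.p_value, rel=1e-5)


def test_write_results_requires_sorted(tmp_path):
    gm = make_random_gm(10, 80, seed=4)
    results = run_scan(gm, ScanConfig(k=2))
    with pytest.raises(ValueError):
        write_results(results[::-1], gm, tmp_path / "res.tsv")
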