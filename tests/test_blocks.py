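import numpy as np
import pytest

from methylhap.blocks import adjacent_pair_ld, pairwise_r2, partition_blocks
from methylhap.errors import MethylhapError
from methylhap.records import CpGIndex, HaplotypeRecord
from tests.conftest import make_reads
from tests._oracles import maximal_runs, r2_bruteforce


def test_perfect_ld_and_independence():
    perfect = make_reads(("11", 5), ("00", 5))
    assert pairwise_r2(perfect, 0, 1, min_pairs=1).r2 == pytest.approx(1.0)
    balanced = make_reads(("11", 2), ("10", 2), ("01", 2), ("00", 2))
    assert pairwise_r2(balanced, 0, 1, min_pairs=1).r2 == pytest.approx(0.0)


def test_partial_ld_matches_hand_value_and_expansion():
    reads = make_reads(("11", 4), ("10", 1), ("01", 1), ("00", 4))
    ld = pairwise_r2(reads, 0, 1, min_pairs=1)
    assert ld.n_pairs == 10
    assert ld.r2 == pytest.approx(0.36, abs=1e-12)
    oracle = r2_bruteforce({(1, 1): 4, (1, 0): 1, (0, 1): 1, (0, 0): 4})
    assert ld.r2 == pytest.approx(oracle, abs=1e-12)


def test_r2_undefined_for_constant_margin_or_few_pairs():
    constant = make_reads(("11", 5), ("10", 5))  # right site varies, left constant
    assert pairwise_r2(constant, 0, 1, min_pairs=1).r2 is None
    few = make_reads(("11", 3))
    assert pairwise_r2(few, 0, 1, min_pairs=10).r2 is None
    with pytest.raises(MethylhapError):
        pairwise_r2(few, 0, 2)  # non-adjacent ordinals


def test_random_pair_tables_match_pearson_expansion():
    rng = np.random.default_rng(11)
    for _ in range(100):
        counts = {k: int(c) for k, c in zip(
            [(0, 0), (0, 1), (1, 0), (1, 1)], rng.integers(0, 8, 4)
        ) if c > 0}
        reads = [
            HaplotypeRecord("chr1", 0, f"{a}{b}", c) for (a, b), c in counts.items()
        ]
        if not reads:
            continue
        got = pairwise_r2(reads, 0, 1, min_pairs=1).r2
        expected = r2_bruteforce(counts)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)


def test_threshold_split_into_expected_block(tiny_index):
    # pair r2 pattern (1.0, ~0.9, ~0.1) over 4 sites -> one block {0,1,2}
    reads = (
        make_reads(("111", 18), ("000", 18), ("110", 2), ("001", 2))
        + make_reads((2, "10", 5), (2, "01", 5), (2, "11", 5), (2, "00", 5))
    )
    regions = partition_blocks(reads, tiny_index, min_pairs=5)
    assert len(regions) == 1
    assert list(regions[0].site_indices) == [0, 1, 2]


def test_no_blocks_when_all_pairs_below_threshold(tiny_index):
    reads = make_reads(("11", 3), ("10", 3), ("01", 3), ("00", 3))
    assert partition_blocks(reads, tiny_index, min_pairs=1) == []


def test_partition_matches_maximal_run_oracle_on_random_instances():
    rng = np.random.default_rng(23)
    for _ in range(25):
        n_sites = int(rng.integers(10, 100))
        index = CpGIndex({"chr1": np.arange(n_sites) * 20})
        reads = [
            HaplotypeRecord(
                "chr1",
                int(rng.integers(0, n_sites - 1)),
                "".join(rng.choice(["0", "1"], size=int(rng.integers(2, 5)))),
                int(rng.integers(1, 4)),
            )
            for _ in range(300)
        ]
        reads = [r for r in reads if r.start_index + r.n_sites <= n_sites]
        # independent path: brute-force r2 per adjacent pair, then run scan
        linked = []
        for k in range(n_sites - 1):
            counts: dict[tuple[int, int], int] = {}
            for r in reads:
                off = k - r.start_index
                if 0 <= off and off + 1 < r.n_sites:
                    key = (int(r.calls[off]), int(r.calls[off + 1]))
                    counts[key] = counts.get(key, 0) + r.count
            n_pairs = sum(counts.values())
            r2 = r2_bruteforce(counts)
            # ties at the threshold are excluded; tolerance absorbs corrcoef noise
            linked.append(n_pairs >= 5 and r2 is not None and r2 > 0.5 + 1e-9)
        expected = maximal_runs(linked)
        got = partition_blocks(reads, index, min_pairs=5)
        assert [(r.first_index, r.first_index + r.n_sites - 1) for r in got] == expected


def test_blocks_invariant_to_read_order_and_count_splitting(tiny_index):
    reads = make_reads(("1111", 6), ("0000", 6), (2, "11", 4), (2, "00", 4))
    split = []
    for r in reads:
        split.extend(HaplotypeRecord(r.chrom, r.start_index, r.calls, 1)
                     for _ in range(r.count))
    a = partition_blocks(reads, tiny_index, min_pairs=5)
    b = partition_blocks(list(reversed(split)), tiny_index, min_pairs=5)
    assert a == b


def test_raising_threshold_only_refines_blocks():
    rng = np.random.default_rng(5)
    n_sites = 60
    index = CpGIndex({"chr1": np.arange(n_sites) * 10})
    reads = []
    for _ in range(400):
        start = int(rng.integers(0, n_sites - 3))
        calls = "".join(rng.choice(["0", "1"], 4)) if rng.random() < 0.4 else \
            rng.choice(["1111", "0000"])
        reads.append(HaplotypeRecord("chr1", start, calls, 1))
    loose = partition_blocks(reads, index, r2_threshold=0.2, min_pairs=5)
    tight = partition_blocks(reads, index, r2_threshold=0.6, min_pairs=5)
    loose_spans = [set(r.site_indices) for r in loose]
    for r in tight:
        assert any(set(r.site_indices) <= span for span in loose_spans)


def test_max_gap_breaks_distant_pairs():
    index = CpGIndex({"chr1": [0, 20, 2000, 2020]})
    reads = make_reads(("1111", 10), ("0000", 10))
    regions = partition_blocks(reads, index, min_pairs=5, max_gap=500)
    assert [list(r.site_indices) for r in regions] == [[0, 1], [2, 3]]


def test_per_sample_mode_matches_pooled_on_homogeneous_samples(tiny_index):
    haps = {
        "a": make_reads(("11", 10), ("00", 10)),
        "b": make_reads(("11", 8), ("00", 12)),
    }
    pooled = adjacent_pair_ld(haps, tiny_index, "chr1", min_pairs=5)
    per_sample = adjacent_pair_ld(haps, tiny_index, "chr1", min_pairs=5,
                                  mode="per_sample")
    assert pooled[0].r2 == pytest.approx(1.0)
    assert per_sample[0].r2 == pytest.approx(1.0)
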