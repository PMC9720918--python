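import pytest

import methylhap as mh
from methylhap.markers import FilterConfig, scaled_min_detected, select_markers
from methylhap.records import CpGIndex, HaplotypeRecord, MHBRegion


@pytest.fixture
def tiny_index():
    """Six CpGs on one chromosome, 20 bp apart."""
    return CpGIndex({"chr1": [100, 120, 140, 160, 180, 200]})


@pytest.fixture
def block2():
    return MHBRegion("b2", "chr1", 0, 2, 100, 122)


@pytest.fixture
def block4():
    return MHBRegion("b4", "chr1", 0, 4, 100, 162)


def make_reads(*specs):
    """specs: (calls, count) or (start_index, calls, count) tuples on chr1."""
    out = []
    for s in specs:
        if len(s) == 2:
            out.append(HaplotypeRecord("chr1", 0, s[0], s[1]))
        else:
            out.append(HaplotypeRecord("chr1", s[0], s[1], s[2]))
    return out


@pytest.fixture(scope="session")
def strong_cohort():
    """Well-separated cohort plus its MHL/UMHL matrices (shared across tests)."""
    cohort = mh.simulate_cohort(mh.strong_signal_spec(1))
    matrices = {
        kind: mh.score_cohort(cohort.haplotypes, cohort.regions, mh.LoadParams(), kind)
        for kind in ("MHL", "UMHL")
    }
    return cohort, matrices


@pytest.fixture(scope="session")
def strong_markers(strong_cohort):
    """HCC (paired signed-rank) and MVI (rank-sum) marker sets on the strong cohort."""
    cohort, matrices = strong_cohort
    floor = scaled_min_detected(len(cohort.regions))
    hcc = select_markers(
        matrices["MHL"],
        cohort.metadata,
        FilterConfig(min_detected_per_sample=floor, test="signed_rank"),
        contrast="tumor_vs_normal",
    )
    mvi = select_markers(
        matrices,
        cohort.metadata,
        FilterConfig(min_detected_per_sample=floor),
        contrast="mvi",
    )
    return hcc, mvi
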