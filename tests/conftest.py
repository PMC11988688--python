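import numpy as np
import pytest

from erv_antigen.erv_catalog import ErvRecord, PeakRecord
from erv_antigen.sixframe_db import OrfProtein, build_search_db


@pytest.fixture
def toy_genome():
    return {"chrA": "AACCGGTT", "chrB": "ACGTACGTACGT"}


@pytest.fixture
def toy_ervs():
    return [
        ErvRecord("ERV0001", "chr1", 100, 200, "+"),
        ErvRecord("ERV0002", "chr1", 5000, 5400, "-"),
        ErvRecord("ERV0003", "chr2", 50, 450, "+"),
    ]


@pytest.fixture
def toy_peaks():
    return [
        PeakRecord("peak_a", "chr1", 150, 160),
        PeakRecord("peak_b", "chr1", 5600, 5700),
        PeakRecord("peak_c", "chr3", 0, 100),
    ]


@pytest.fixture
def small_db():
    reference = [
        ("REF1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
        ("REF2", "MAYIKSPQLTT"),
    ]
    orfs = [
        OrfProtein("ERV0001", 1, 0, "LLDPKTGSWWT"),
        OrfProtein("ERV0002", 2, 3, "QQLLDPKTGSWWTRR"),
    ]
    return build_search_db(reference, orfs, [("CON1", "GGGGGGGGGG")])


def random_intervals(rng: np.random.Generator, n: int, kind: str, chroms=("chr1", "chr2")):
    """Random half-open intervals for oracle-equivalence tests."""
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, 50_000))
        length = int(rng.integers(1, 2_000))
        if kind == "erv":
            out.append(ErvRecord(f"ERV{i:05d}", chrom, start, start + length))
        else:
            out.append(PeakRecord(f"peak{i:05d}", chrom, start, start + length))
    return out
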