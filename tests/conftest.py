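import numpy as np
import pandas as pd
import pytest

from cnvscape import (
    GenomeModel,
    NoiseModel,
    TrueCNVR,
    build_marker_map,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    return GenomeModel({"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 1_000_000})


@pytest.fixture(scope="session")
def small_map(small_genome) -> pd.DataFrame:
    return build_marker_map(small_genome, 500, seed=7)


@pytest.fixture(scope="session")
def two_pop_cohort(small_map):
    """Two populations with well-separated, high-frequency truth regions."""
    pos1 = small_map.loc[small_map["chrom"] == "chr1", "pos"].to_numpy()
    pos2 = small_map.loc[small_map["chrom"] == "chr2", "pos"].to_numpy()
    truth = [
        TrueCNVR("chr1", int(pos1[30]), int(pos1[44]), {"A": 0.7, "B": 0.0}, "loss"),
        TrueCNVR("chr1", int(pos1[120]), int(pos1[134]), {"A": 0.0, "B": 0.7}, "gain"),
        TrueCNVR("chr2", int(pos2[50]), int(pos2[64]), {"A": 0.6, "B": 0.6}, "loss"),
    ]
    cohort = simulate_cohort(
        small_map,
        truth,
        {"A": 12, "B": 12},
        NoiseModel(lrr_sd=0.12, gc_coeff_sd=0.0),
        seed=21,
        qc_fail_rate=0.0,
    )
    return small_map, truth, cohort


def make_calls(rows) -> pd.DataFrame:
    """Call-table helper: rows of (sample, pop, chrom, start, end, state)."""
    return pd.DataFrame(
        rows, columns=["sample", "population", "chrom", "start", "end", "state"]
    )
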