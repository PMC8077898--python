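"""Standard synthetic benchmarks exercising the pipeline end to end.

These functions define the package's reference study conditions — a
three-population cohort on a 24-autosome genome with embedded CNVRs of
known frequency, and Balding–Nichols SNP panels — and measure how well the
stack recovers the planted truth.  They are used by the test suite and the
reproduction script, and are part of the public API so users can rerun
them at other seeds or scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cnvscape.evaluate import RecoveryMetrics, match_calls_to_truth
from cnvscape.popstruct import code_cnv_states, pca, weir_cockerham_fst
from cnvscape.regions import merge_cnvs_to_cnvrs
from cnvscape.segmentation import SegmentationParams, detect_cnvs
from cnvscape.synthetic import (
    GenomeModel,
    NoiseModel,
    TrueCNVR,
    buffalo_like_genome,
    build_marker_map,
    random_truth_set,
    simulate_cohort,
    simulate_snp_genotypes,
)

__all__ = ["recovery_benchmark", "fst_recovery", "pca_separation"]

#: Reference cohort: three populations at a 3:2:1 size ratio.
DEFAULT_POP_SIZES: dict[str, int] = {"POP1": 60, "POP2": 40, "POP3": 20}


@dataclass
class RecoveryBenchmarkResult:
    metrics: RecoveryMetrics  # events spanning >= min_markers_eval markers
    metrics_all: RecoveryMetrics
    n_calls: int
    n_truth_events: int


def recovery_benchmark(
    seed: int,
    n_markers: int = 5_000,
    n_regions: int = 30,
    pop_sizes: Mapping[str, int] | None = None,
    noise: NoiseModel | None = None,
    min_markers_eval: int = 10,
) -> RecoveryBenchmarkResult:
    """Detection benchmark: simulate a cohort with known CNVRs, call, score.

    The default conditions — 120 samples in three populations, 5,000
    markers on 24 autosomes, 30 truth regions of 5–25 markers at carrier
    frequencies 5–30%, noise sd 0.15 and the standard copy-number shift
    map — are sized so a full run takes a few minutes on one core.
    Recall and boundary error are reported for events spanning at least
    ``min_markers_eval`` markers (and separately for all events).
    """
    pop_sizes = dict(pop_sizes or DEFAULT_POP_SIZES)
    genome = buffalo_like_genome()
    marker_map = build_marker_map(genome, n_markers, seed=seed)
    truth_set = random_truth_set(marker_map, n_regions, list(pop_sizes), seed=seed + 1)
    cohort = simulate_cohort(marker_map, truth_set, pop_sizes, noise, seed=seed + 2)
    calls = detect_cnvs(
        marker_map, cohort.lrr, cohort.populations, SegmentationParams(seed=seed + 3)
    )
    return RecoveryBenchmarkResult(
        metrics=match_calls_to_truth(cohort.truth, calls, min_markers=min_markers_eval),
        metrics_all=match_calls_to_truth(cohort.truth, calls, min_markers=1),
        n_calls=int(len(calls)),
        n_truth_events=int(len(cohort.truth)),
    )


def fst_recovery(
    seed: int,
    fst_values: Sequence[float] = (0.0, 0.02, 0.05, 0.10),
    n_loci: int = 5_000,
    samples_per_pop: int = 100,
) -> dict[float, float]:
    """Weir–Cockerham estimates on Balding–Nichols panels at known divergence."""
    out: dict[float, float] = {}
    for k, f in enumerate(fst_values):
        snp = simulate_snp_genotypes(
            n_loci, {"A": samples_per_pop, "B": samples_per_pop}, fst=f, seed=seed + k
        )
        out[f] = weir_cockerham_fst(snp.genotypes, snp.populations)
    return out


def pca_separation(seed: int, n_markers: int = 360, samples_per_pop: int = 12):
    """CNV-state PCA on two populations with disjoint CNVR frequency profiles.

    Population A carries only the first half of the truth regions and
    population B only the second half (carrier frequency 0.8), so the coded
    state matrix should separate the populations on PC1.  Returns
    ``(overlap_count, scores, populations)`` where ``overlap_count`` is the
    number of samples inside the other population's PC1 range.
    """
    genome = GenomeModel({f"chr{i + 1}": 2_000_000 for i in range(3)})
    marker_map = build_marker_map(genome, n_markers, seed=seed)
    base = random_truth_set(
        marker_map, 6, ["A", "B"], seed=seed + 1, span_range=(10, 16)
    )
    truth = [
        TrueCNVR(
            r.chrom,
            r.start,
            r.end,
            {"A": 0.8, "B": 0.0} if k < 3 else {"A": 0.0, "B": 0.8},
            "loss" if k % 2 == 0 else "gain",
        )
        for k, r in enumerate(base)
    ]
    cohort = simulate_cohort(
        marker_map,
        truth,
        {"A": samples_per_pop, "B": samples_per_pop},
        NoiseModel(lrr_sd=0.15),
        seed=seed + 2,
    )
    calls = detect_cnvs(
        marker_map, cohort.lrr, cohort.populations, SegmentationParams(seed=seed + 3)
    )
    regions = []
    for pop in ("A", "B"):
        regions.extend(
            merge_cnvs_to_cnvrs(calls.loc[calls["population"] == pop], population=pop)
        )
    region_frame = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
        }
    ).drop_duplicates()
    states = code_cnv_states(calls, region_frame, samples=list(cohort.lrr.columns))
    result = pca(states, n_components=2)
    pc1 = result.scores["PC1"]
    pops = cohort.populations
    a = pc1[pops == "A"]
    b = pc1[pops == "B"]
    if a.mean() > b.mean():
        a, b = b, a
    overlap = int((a >= b.min()).sum() + (b <= a.max()).sum())
    return overlap, result.scores, cohort.populations
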