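"""Synthetic SNP-array cohorts with known CNV ground truth.

Generates the inputs the analysis pipeline consumes — a marker map, a
per-sample Log R Ratio (LRR) matrix, array QC metadata, population labels
and SNP genotypes — from an explicit generative model, so that every
downstream stage (QC, segmentation, CNVR consolidation, population
structure) can be validated against a truth table.

Generative model
----------------
* A genome of autosomes with fixed lengths; markers placed uniformly at
  random, in numbers proportional to chromosome length.
* Each true copy-number-variable region (CNVR) has a genomic span and a
  per-population carrier frequency; carriers are drawn independently per
  sample.  A carrier's copy number shifts the mean LRR of the markers in
  the region according to a fixed shift map (two copies = 0).
* Marker-level noise is i.i.d. Gaussian per sample; an optional per-sample
  GC-wave term adds ``coeff * (gc - mean(gc))`` to every marker, emulating
  GC-content-driven baseline waves.
* SNP genotypes for population-structure analyses follow the
  Balding–Nichols model: ancestral frequencies Uniform(0.05, 0.95),
  per-population frequencies Beta(p(1-F)/F, (1-p)(1-F)/F), genotypes
  Binomial(2, p_pop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "TrueCNVR",
    "NoiseModel",
    "SimulatedCohort",
    "SNPCohort",
    "buffalo_like_genome",
    "build_marker_map",
    "random_truth_set",
    "simulate_cohort",
    "simulate_snp_genotypes",
]

#: LRR mean shift per integer copy number (two copies = diploid baseline).
DEFAULT_SHIFTS: dict[int, float] = {0: -3.0, 1: -0.45, 2: 0.0, 3: 0.30, 4: 0.58}


@dataclass(frozen=True)
class GenomeModel:
    """Autosome names and lengths (bp); the coordinate backbone."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome must contain at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def n_autosomes(self) -> int:
        return len(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def buffalo_like_genome(
    n_autosomes: int = 24, total_length: int = 2_478_740_000
) -> GenomeModel:
    """A water-buffalo-like autosome set: 24 autosomes, 2478.74 Mb total.

    Chromosome lengths decrease linearly from ~167 Mb to ~39 Mb and are
    scaled so they sum exactly to ``total_length``.
    """
    weights = np.arange(n_autosomes + 6, 6, -1, dtype=float)
    raw = weights / weights.sum() * total_length
    lengths = _largest_remainder(raw, total_length)
    return GenomeModel(
        {f"chr{i + 1}": int(lengths[i]) for i in range(n_autosomes)}
    )


def _largest_remainder(raw: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment: floors plus largest fractional remainders."""
    floors = np.floor(raw).astype(np.int64)
    shortfall = int(total - floors.sum())
    order = np.argsort(-(raw - floors), kind="stable")
    floors[order[:shortfall]] += 1
    return floors


@dataclass(frozen=True)
class TrueCNVR:
    """A ground-truth copy-number-variable region.

    ``frequencies`` maps population name to carrier frequency in [0, 1].
    ``state`` is the kind of event carriers receive: ``loss`` (copy number
    1, occasionally 0), ``gain`` (3, occasionally 4) or ``complex``
    (each carrier independently loss or gain).
    """

    chrom: str
    start: int
    end: int
    frequencies: Mapping[str, float]
    state: str = "loss"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.state not in ("loss", "gain", "complex"):
            raise ValueError(f"unknown region state {self.state!r}")
        for pop, freq in self.frequencies.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"frequency {freq} for {pop} outside [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Marker-level noise for the LRR signal.

    ``lrr_sd`` is the per-marker Gaussian standard deviation (default 0.15,
    a mid-range value for genotyping arrays at which single-copy events
    spanning >= 10 markers are detectable but not trivial).
    ``gc_coeff_sd`` is the spread of the per-sample GC-wave coefficient.
    ``shifts`` maps copy number to mean LRR shift and must be monotone
    increasing in copy number.
    """

    lrr_sd: float = 0.15
    gc_coeff_sd: float = 0.05
    shifts: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SHIFTS)
    )

    def __post_init__(self) -> None:
        if self.lrr_sd <= 0:
            raise ValueError("lrr_sd must be positive")
        ordered = [self.shifts[cn] for cn in sorted(self.shifts)]
        if any(b <= a for a, b in zip(ordered, ordered[1:])):
            raise ValueError("shift map must be monotone increasing in copy number")


@dataclass
class SimulatedCohort:
    """Outputs of :func:`simulate_cohort`."""

    lrr: pd.DataFrame  # markers x samples
    truth: pd.DataFrame  # one row per embedded per-sample event
    qc: pd.DataFrame  # sample, call_rate, dqc
    populations: pd.Series  # sample -> population label


@dataclass
class SNPCohort:
    """Outputs of :func:`simulate_snp_genotypes`."""

    genotypes: pd.DataFrame  # samples x loci, 0/1/2
    populations: pd.Series  # sample -> population label


def build_marker_map(
    genome: GenomeModel, n_markers: int, seed: int = 0
) -> pd.DataFrame:
    """Place array markers on a genome.

    Markers are apportioned to chromosomes proportionally to chromosome
    length (largest-remainder rounding, so counts are within +/- 1 of the
    exact proportion), positioned uniformly at random without duplicates,
    and given a GC fraction simulated as a smoothed Uniform(0.3, 0.7)
    series along each chromosome (a realistic wave backdrop for GC-wave
    QC statistics).

    Returns a DataFrame with columns ``marker_id, chrom, pos, gc`` sorted
    by (chromosome, position); ``chrom`` is categorical in genome order.
    """
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    if n_markers < 3 * genome.n_autosomes:
        raise ValueError(
            f"n_markers={n_markers} too small: need >= 3 markers per chromosome"
        )
    rng = np.random.default_rng(seed)
    lengths = np.array(list(genome.chrom_lengths.values()), dtype=float)
    counts = _largest_remainder(lengths / lengths.sum() * n_markers, n_markers)

    frames = []
    for chrom, count in zip(genome.chroms, counts):
        length = genome.chrom_lengths[chrom]
        pos = np.sort(_sample_unique_positions(rng, length, int(count)))
        gc = _smoothed_gc(rng, int(count))
        frames.append(
            pd.DataFrame(
                {
                    "marker_id": [f"{chrom}_m{i + 1}" for i in range(int(count))],
                    "chrom": chrom,
                    "pos": pos,
                    "gc": gc,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["chrom"] = pd.Categorical(out["chrom"], categories=genome.chroms)
    return out


def _sample_unique_positions(
    rng: np.random.Generator, length: int, count: int
) -> np.ndarray:
    """Draw ``count`` distinct 1-based positions in [1, length]."""
    if count > length:
        raise ValueError(f"cannot place {count} unique markers on {length} bp")
    positions: set[int] = set()
    while len(positions) < count:
        draw = rng.integers(1, length + 1, size=count - len(positions))
        positions.update(int(p) for p in draw)
    return np.fromiter(positions, dtype=np.int64, count=count)


def _smoothed_gc(
    rng: np.random.Generator, count: int, window: int = 25
) -> np.ndarray:
    raw = rng.uniform(0.3, 0.7, size=count)
    smoothed = (
        pd.Series(raw).rolling(window, min_periods=1, center=True).mean().to_numpy()
    )
    return np.clip(smoothed, 0.0, 1.0)


def random_truth_set(
    marker_map: pd.DataFrame,
    n_regions: int,
    pop_names: Sequence[str],
    seed: int = 0,
    span_range: tuple[int, int] = (5, 25),
    freq_range: tuple[float, float] = (0.05, 0.30),
) -> list[TrueCNVR]:
    """Draw a non-overlapping truth CNVR architecture on a marker map.

    Regions are dealt round-robin across chromosomes; within a chromosome
    each region is placed in its own marker block, so truth regions never
    overlap.  Spans are uniform in ``span_range`` markers and carrier
    frequencies uniform in ``freq_range`` per population (the span of
    frequencies retained by a 5%-of-cohort filter in population surveys).
    States cycle through loss, gain, complex.
    """
    rng = np.random.default_rng(seed)
    chroms = list(marker_map["chrom"].cat.categories)
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i in range(n_regions):
        per_chrom[chroms[i % len(chroms)]] += 1

    states = ["loss", "gain", "complex"]
    regions: list[TrueCNVR] = []
    state_i = 0
    for chrom in chroms:
        k = per_chrom[chrom]
        if k == 0:
            continue
        pos = marker_map.loc[marker_map["chrom"] == chrom, "pos"].to_numpy()
        n = len(pos)
        block = n // k
        for j in range(k):
            span = int(rng.integers(span_range[0], span_range[1] + 1))
            span = min(span, max(3, block - 2))
            lo = j * block
            hi = min((j + 1) * block, n) - span
            first = int(rng.integers(lo, max(lo + 1, hi + 1)))
            last = first + span - 1
            freqs = {
                p: float(rng.uniform(*freq_range)) for p in pop_names
            }
            regions.append(
                TrueCNVR(
                    chrom=chrom,
                    start=int(pos[first]),
                    end=int(pos[last]),
                    frequencies=freqs,
                    state=states[state_i % 3],
                )
            )
            state_i += 1
    return regions


def simulate_cohort(
    marker_map: pd.DataFrame,
    truth: Sequence[TrueCNVR],
    pop_sizes: Mapping[str, int],
    noise: NoiseModel | None = None,
    seed: int = 0,
    extreme_copy_prob: float = 0.1,
    qc_fail_rate: float = 0.02,
) -> SimulatedCohort:
    """Simulate an LRR matrix with embedded CNVs and QC metadata.

    For every population and truth region, carriers are drawn independently
    at the region's stated frequency; each carrier's markers in the region
    get the copy-number mean shift (single-copy change with probability
    ``1 - extreme_copy_prob``, two-copy change otherwise).  Non-CNV markers
    have mean zero.  Per-sample noise is Gaussian ``lrr_sd``; the per-sample
    GC term ``coeff * (gc - mean(gc))`` is added across all markers.

    QC metadata draws most samples as clean passes (call rate and Dish QC
    above threshold) and a ``qc_fail_rate`` fraction as failures, emulating
    the small share of arrays discarded in real cohorts.

    Raises ``ValueError`` if a truth region spans fewer than 3 markers —
    such an event cannot be recovered under a 3-marker minimum segment
    size and would silently corrupt recall statistics.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    n_markers = len(marker_map)
    chrom_arr = marker_map["chrom"].to_numpy()
    pos_arr = marker_map["pos"].to_numpy()
    gc = marker_map["gc"].to_numpy()

    # Resolve each truth region to global marker indices up front.
    region_idx: list[np.ndarray] = []
    for region in truth:
        mask = (
            (chrom_arr == region.chrom)
            & (pos_arr >= region.start)
            & (pos_arr <= region.end)
        )
        idx = np.flatnonzero(mask)
        if len(idx) < 3:
            raise ValueError(
                f"truth region {region.chrom}:{region.start}-{region.end} spans "
                f"{len(idx)} markers; at least 3 are required to be callable"
            )
        region_idx.append(idx)

    samples: list[str] = []
    pops: list[str] = []
    for pop, size in pop_sizes.items():
        if size <= 0:
            raise ValueError(f"population {pop} has non-positive size {size}")
        for i in range(size):
            samples.append(f"{pop}_{i + 1:03d}")
            pops.append(pop)
    n_samples = len(samples)

    lrr = rng.normal(0.0, noise.lrr_sd, size=(n_markers, n_samples))
    gc_coeff = rng.normal(0.0, noise.gc_coeff_sd, size=n_samples)
    lrr += np.outer(gc - gc.mean(), gc_coeff)

    # Precompute per-chromosome marker offsets for within-chromosome indices.
    chrom_first: dict[str, int] = {}
    for c in marker_map["chrom"].cat.categories:
        hits = np.flatnonzero(chrom_arr == c)
        if len(hits):
            chrom_first[str(c)] = int(hits[0])

    truth_rows: list[dict] = []
    pop_arr = np.array(pops)
    for region, idx in zip(truth, region_idx):
        for pop in pop_sizes:
            freq = region.frequencies.get(pop, 0.0)
            members = np.flatnonzero(pop_arr == pop)
            carrier_mask = rng.random(len(members)) < freq
            for s in members[carrier_mask]:
                if region.state == "complex":
                    kind = "loss" if rng.random() < 0.5 else "gain"
                else:
                    kind = region.state
                if kind == "loss":
                    cn = 0 if rng.random() < extreme_copy_prob else 1
                else:
                    cn = 4 if rng.random() < extreme_copy_prob else 3
                lrr[idx, s] += noise.shifts[cn]
                first_local = int(idx[0] - chrom_first[region.chrom])
                truth_rows.append(
                    {
                        "sample": samples[s],
                        "population": pops[s],
                        "chrom": region.chrom,
                        "start": int(pos_arr[idx[0]]),
                        "end": int(pos_arr[idx[-1]]),
                        "first_marker": first_local,
                        "last_marker": first_local + len(idx) - 1,
                        "n_markers": len(idx),
                        "copy_number": cn,
                        "state": kind,
                    }
                )

    truth_df = pd.DataFrame(
        truth_rows,
        columns=[
            "sample",
            "population",
            "chrom",
            "start",
            "end",
            "first_marker",
            "last_marker",
            "n_markers",
            "copy_number",
            "state",
        ],
    )

    fail = rng.random(n_samples) < qc_fail_rate
    call_rate = np.where(
        fail, rng.uniform(0.90, 0.969, n_samples), rng.uniform(0.975, 0.999, n_samples)
    )
    fail_dqc = rng.random(n_samples) < qc_fail_rate / 2
    dqc = np.where(
        fail_dqc, rng.uniform(0.75, 0.819, n_samples), rng.uniform(0.85, 0.99, n_samples)
    )
    qc = pd.DataFrame({"sample": samples, "call_rate": call_rate, "dqc": dqc})

    lrr_df = pd.DataFrame(
        lrr, index=pd.Index(marker_map["marker_id"], name="marker_id"), columns=samples
    )
    populations = pd.Series(pops, index=samples, name="population")
    return SimulatedCohort(lrr=lrr_df, truth=truth_df, qc=qc, populations=populations)


def simulate_snp_genotypes(
    n_loci: int,
    pop_sizes: Mapping[str, int],
    fst: float,
    seed: int = 0,
) -> SNPCohort:
    """Simulate biallelic SNP genotypes under the Balding–Nichols model.

    Ancestral allele frequencies are Uniform(0.05, 0.95).  For divergence
    ``fst`` = F > 0 each population's frequency is drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F); F = 0 means all populations share the
    ancestral frequency exactly.  Genotypes are Binomial(2, p_pop) counts
    of the alternate allele.
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    if n_loci < 100:
        raise ValueError("n_loci must be at least 100")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)

    samples: list[str] = []
    pops: list[str] = []
    blocks: list[np.ndarray] = []
    for pop, size in pop_sizes.items():
        if size <= 0:
            raise ValueError(f"population {pop} has non-positive size {size}")
        if fst == 0.0:
            p_pop = p_anc
        else:
            shape = (1.0 - fst) / fst
            p_pop = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        blocks.append(rng.binomial(2, p_pop, size=(size, n_loci)))
        samples.extend(f"{pop}_{i + 1:03d}" for i in range(size))
        pops.extend([pop] * size)

    genotypes = pd.DataFrame(
        np.vstack(blocks),
        index=samples,
        columns=[f"snp{i + 1}" for i in range(n_loci)],
        dtype=np.int8,
    )
    populations = pd.Series(pops, index=samples, name="population")
    return SNPCohort(genotypes=genotypes, populations=populations)
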