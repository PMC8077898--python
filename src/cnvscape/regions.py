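"""CNVR consolidation, cross-population sharing and cohort summaries.

Per-sample CNV calls of one population are merged into copy number
variable regions (CNVRs) by transitive closure of >= 1 bp overlap (the
``bedtools merge`` rule).  A region's state is ``gain`` or ``loss`` when
all constituent calls agree and ``complex`` when both occur; a region
carried by exactly one individual is a singleton.  Regions carried by at
least ``max(2, round-half-up(0.05 * n_samples))`` individuals survive the
population frequency filter — a rule that yields carrier minimums of
12, 5 and 2 for cohorts of 242, 100 and 19.

Regions from different populations are linked when their overlap spans at
least half the shorter region; connected components touching two or more
populations are ``common_CNVR``, the rest ``pop_CNVR``.  The non-redundant
cross-population set counts each component once, with span equal to the
union of member spans.

All coordinates are 1-based inclusive internally; BED emission converts
to 0-based half-open at the I/O boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cnvscape.synthetic import GenomeModel

__all__ = [
    "CNVR",
    "SharingResult",
    "PopulationSummary",
    "merge_cnvs_to_cnvrs",
    "frequency_threshold",
    "filter_by_frequency",
    "compare_populations",
    "summarize",
    "loss_gain_ratio",
    "percentage",
    "LENGTH_CLASSES",
]

#: CNV length classes (bp): label -> [low, high) with open-ended extremes.
LENGTH_CLASSES: dict[str, tuple[float, float]] = {
    "<10kb": (0, 10_000),
    "10-50kb": (10_000, 50_000),
    "50-100kb": (50_000, 100_000),
    "100-500kb": (100_000, 500_000),
    ">500kb": (500_000, math.inf),
}


@dataclass(frozen=True)
class CNVR:
    """A population-level merged copy-number region."""

    population: str
    chrom: str
    start: int
    end: int
    state: str
    carriers: tuple[str, ...]
    n_calls: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("CNVR start > end")
        if self.state not in ("loss", "gain", "complex"):
            raise ValueError(f"unknown CNVR state {self.state!r}")

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)

    @property
    def singleton(self) -> bool:
        return self.n_carriers == 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _combined_state(states: set[str]) -> str:
    if "complex" in states or {"gain", "loss"} <= states:
        return "complex"
    return next(iter(states))


def merge_cnvs_to_cnvrs(calls: pd.DataFrame, population: str | None = None) -> list[CNVR]:
    """Merge one population's CNV calls into CNVRs by >= 1 bp overlap.

    ``calls`` needs columns ``sample, chrom, start, end, state``
    (coordinates 1-based inclusive).  Overlap clustering is transitive:
    on a sorted sweep, a call joins the open cluster when its start does
    not pass the cluster's running end.  Merging is idempotent — feeding
    the resulting regions back in reproduces them.
    """
    if "population" in calls.columns and len(calls):
        pops = calls["population"].unique()
        if len(pops) > 1:
            raise ValueError(
                f"merge_cnvs_to_cnvrs expects one population at a time, got {list(pops)}"
            )
        population = population or str(pops[0])
    population = population or "pop"
    if len(calls) and (calls["end"] < calls["start"]).any():
        bad = calls.loc[calls["end"] < calls["start"]]
        raise ValueError(f"rejecting {len(bad)} calls with end < start")

    regions: list[CNVR] = []
    for chrom, group in calls.groupby("chrom", sort=False, observed=True):
        group = group.sort_values(["start", "end"], kind="stable")
        cluster: list[pd.Series] = []
        cluster_end = -1
        for _, row in group.iterrows():
            if cluster and row["start"] <= cluster_end:
                cluster.append(row)
                cluster_end = max(cluster_end, int(row["end"]))
            else:
                if cluster:
                    regions.append(_close_cluster(cluster, str(chrom), population))
                cluster = [row]
                cluster_end = int(row["end"])
        if cluster:
            regions.append(_close_cluster(cluster, str(chrom), population))
    return regions


def _close_cluster(cluster: list[pd.Series], chrom: str, population: str) -> CNVR:
    return CNVR(
        population=population,
        chrom=chrom,
        start=int(min(r["start"] for r in cluster)),
        end=int(max(r["end"] for r in cluster)),
        state=_combined_state({str(r["state"]) for r in cluster}),
        carriers=tuple(sorted({str(r["sample"]) for r in cluster})),
        n_calls=len(cluster),
    )


def frequency_threshold(n_samples: int, fraction: float = 0.05) -> int:
    """Minimum carrier count for a region to count as population-level.

    Round-half-up of ``fraction * n_samples`` with a floor of 2 (a region
    needs at least two carriers to be more than a singleton).  Reproduces
    carrier minimums 12 / 5 / 2 for cohorts of 242 / 100 / 19 at 5%.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    return max(2, math.floor(fraction * n_samples + 0.5))


def filter_by_frequency(cnvrs: Sequence[CNVR], threshold: int) -> list[CNVR]:
    """Retain regions with at least ``threshold`` carriers (inclusive)."""
    return [r for r in cnvrs if r.n_carriers >= threshold]


@dataclass
class SharingResult:
    """Cross-population sharing classification.

    ``labels`` maps (population, region index within that population's
    list) to ``pop_CNVR`` or ``common_CNVR``.  ``non_redundant`` has one
    row per connected component (span = union of members).  ``venn``
    counts components per population-membership pattern.
    """

    labels: dict[tuple[str, int], str]
    non_redundant: pd.DataFrame
    venn: dict[tuple[str, ...], int]

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def compare_populations(
    pop_sets: Mapping[str, Sequence[CNVR]], overlap_fraction: float = 0.5
) -> SharingResult:
    """Classify regions as population-private or shared across populations.

    Two regions from different populations are linked when their overlap
    is at least ``overlap_fraction`` of the shorter region's length
    (default 0.5: "at least 50% or full overlap").  Components containing
    two or more populations are common_CNVRs; each component appears once
    in the non-redundant set.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")
    if len(pop_sets) < 2:
        raise ValueError("compare_populations needs at least 2 populations")

    nodes: list[tuple[str, int, CNVR]] = []
    for pop, regions in pop_sets.items():
        for i, region in enumerate(regions):
            nodes.append((pop, i, region))

    uf = _UnionFind(len(nodes))
    for a in range(len(nodes)):
        pop_a, _, ra = nodes[a]
        for b in range(a + 1, len(nodes)):
            pop_b, _, rb = nodes[b]
            if pop_a == pop_b or ra.chrom != rb.chrom:
                continue
            overlap = min(ra.end, rb.end) - max(ra.start, rb.start) + 1
            if overlap <= 0:
                continue
            if overlap >= overlap_fraction * min(ra.length, rb.length):
                uf.union(a, b)

    components: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        components.setdefault(uf.find(i), []).append(i)

    labels: dict[tuple[str, int], str] = {}
    rows: list[dict] = []
    venn: dict[tuple[str, ...], int] = {}
    for comp_id, members in sorted(components.items()):
        pops = tuple(sorted({nodes[i][0] for i in members}))
        label = "common_CNVR" if len(pops) >= 2 else "pop_CNVR"
        for i in members:
            labels[(nodes[i][0], nodes[i][1])] = label
        venn[pops] = venn.get(pops, 0) + 1
        regions = [nodes[i][2] for i in members]
        carriers_by_pop = {
            pop: sum(r.n_carriers for r in regions if r.population == pop)
            for pop in pops
        }
        rows.append(
            {
                "chrom": regions[0].chrom,
                "start": min(r.start for r in regions),
                "end": max(r.end for r in regions),
                "state": _combined_state({r.state for r in regions}),
                "label": label,
                "populations": ",".join(pops),
                "n_members": len(members),
                "n_carriers_total": sum(r.n_carriers for r in regions),
                **{f"n_carriers_{p}": c for p, c in carriers_by_pop.items()},
            }
        )
    non_redundant = pd.DataFrame(rows).sort_values(
        ["chrom", "start", "end"], kind="stable", ignore_index=True
    )
    return SharingResult(labels=labels, non_redundant=non_redundant, venn=venn)


def loss_gain_ratio(n_loss: int, n_gain: int, decimals: int = 2) -> float:
    """Deletion / duplication count ratio, rounded; NaN when no gains."""
    if n_gain == 0:
        warnings.warn("loss/gain ratio undefined: zero gain calls", stacklevel=2)
        return math.nan
    return round(n_loss / n_gain, decimals)


def percentage(part: float, total: float, decimals: int = 2) -> float:
    """``100 * part / total`` rounded to ``decimals``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total, decimals)


@dataclass
class PopulationSummary:
    """Cohort descriptive statistics for one population."""

    population: str
    n_samples: int
    n_cnv: int
    n_loss: int
    n_gain: int
    loss_gain_ratio: float
    min_cnv_per_sample: int
    max_cnv_per_sample: int
    mean_cnv_per_sample: float
    min_length: int
    max_length: int
    mean_length: float
    n_cnvr: int
    n_cnvr_loss: int
    n_cnvr_gain: int
    n_cnvr_complex: int
    n_singleton: int
    singleton_pct: float
    coverage_mb: float
    coverage_pct: float
    length_class_proportions: dict[str, float]
    per_chromosome: pd.DataFrame  # chrom, n_cnvr, mean_length


def _length_class_proportions(lengths: np.ndarray) -> dict[str, float]:
    out = {}
    for label, (lo, hi) in LENGTH_CLASSES.items():
        out[label] = float(((lengths >= lo) & (lengths < hi)).mean()) if len(lengths) else 0.0
    return out


def summarize(
    calls: pd.DataFrame,
    cnvr_sets: Mapping[str, Sequence[CNVR]],
    genome: GenomeModel,
    pop_sizes: Mapping[str, int] | None = None,
) -> dict[str, PopulationSummary]:
    """Descriptive statistics per population from calls and merged regions.

    ``pop_sizes`` supplies cohort sizes (so samples without any call count
    in the per-sample mean); when omitted, the distinct samples seen in
    ``calls`` define the denominator.  Coverage is the union length of the
    population's regions (non-overlapping by construction) as Mb and as a
    percentage of the genome length.
    """
    genome_mb = genome.total_length / 1e6
    out: dict[str, PopulationSummary] = {}
    for pop, regions in cnvr_sets.items():
        pcalls = calls.loc[calls["population"] == pop] if len(calls) else calls
        lengths = (
            (pcalls["end"] - pcalls["start"] + 1).to_numpy()
            if len(pcalls)
            else np.array([], dtype=int)
        )
        n_loss = int((pcalls["state"] == "loss").sum()) if len(pcalls) else 0
        n_gain = int((pcalls["state"] == "gain").sum()) if len(pcalls) else 0
        per_sample = (
            pcalls.groupby("sample").size() if len(pcalls) else pd.Series(dtype=int)
        )
        n_samples = (
            pop_sizes[pop] if pop_sizes is not None else int(per_sample.size)
        )
        mean_per_sample = (
            round(len(pcalls) / n_samples, 2) if n_samples else math.nan
        )

        states = pd.Series([r.state for r in regions], dtype=object)
        n_singleton = sum(r.singleton for r in regions)
        coverage_bp = sum(r.length for r in regions)
        if regions:
            per_chrom = pd.DataFrame(
                {
                    "chrom": [r.chrom for r in regions],
                    "length": [r.length for r in regions],
                }
            )
            per_chrom = (
                per_chrom.groupby("chrom", sort=False)
                .agg(n_cnvr=("length", "size"), mean_length=("length", "mean"))
                .reset_index()
            )
        else:
            per_chrom = pd.DataFrame(columns=["chrom", "n_cnvr", "mean_length"])

        out[pop] = PopulationSummary(
            population=pop,
            n_samples=n_samples,
            n_cnv=int(len(pcalls)),
            n_loss=n_loss,
            n_gain=n_gain,
            loss_gain_ratio=loss_gain_ratio(n_loss, n_gain)
            if n_gain
            else math.nan,
            min_cnv_per_sample=int(per_sample.min()) if len(per_sample) else 0,
            max_cnv_per_sample=int(per_sample.max()) if len(per_sample) else 0,
            mean_cnv_per_sample=mean_per_sample,
            min_length=int(lengths.min()) if len(lengths) else 0,
            max_length=int(lengths.max()) if len(lengths) else 0,
            mean_length=float(lengths.mean()) if len(lengths) else math.nan,
            n_cnvr=len(regions),
            n_cnvr_loss=int((states == "loss").sum()),
            n_cnvr_gain=int((states == "gain").sum()),
            n_cnvr_complex=int((states == "complex").sum()),
            n_singleton=int(n_singleton),
            singleton_pct=percentage(n_singleton, len(regions))
            if regions
            else math.nan,
            coverage_mb=round(coverage_bp / 1e6, 2),
            coverage_pct=percentage(coverage_bp / 1e6, genome_mb),
            length_class_proportions=_length_class_proportions(lengths),
            per_chromosome=per_chrom,
        )
    return out


def cnvrs_to_frame(regions: Sequence[CNVR]) -> pd.DataFrame:
    """Tabular view of a CNVR list (1-based inclusive coordinates)."""
    return pd.DataFrame(
        {
            "population": [r.population for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "state": [r.state for r in regions],
            "n_carriers": [r.n_carriers for r in regions],
            "n_calls": [r.n_calls for r in regions],
            "singleton": [r.singleton for r in regions],
            "carriers": [",".join(r.carriers) for r in regions],
        }
    )
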