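"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: segmentation is
checked against exhaustive enumeration of breakpoint sets, and CNVR
consolidation / sharing against per-base-pair painting.  They are only
feasible on tiny inputs, which is the point.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def exhaustive_least_squares_breakpoints(
    values: np.ndarray, max_breakpoints: int = 2, min_markers: int = 3
) -> tuple[int, ...]:
    """Breakpoints of the best piecewise-constant fit, by enumeration.

    Scans breakpoint sets of size 0..``max_breakpoints`` (every segment at
    least ``min_markers`` long), scores each by within-segment sum of
    squares, and returns the smallest set achieving the minimal SSE
    (ties broken lexicographically).  A breakpoint k splits between
    indices k-1 and k.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)

    def sse(bounds: tuple[int, ...]) -> float:
        edges = (0, *bounds, n)
        total = 0.0
        for lo, hi in zip(edges, edges[1:]):
            seg = values[lo:hi]
            total += float(((seg - seg.mean()) ** 2).sum())
        return total

    best_sse = sse(())
    best: tuple[int, ...] = ()
    for size in range(1, max_breakpoints + 1):
        for bounds in combinations(range(min_markers, n - min_markers + 1), size):
            edges = (0, *bounds, n)
            if any(hi - lo < min_markers for lo, hi in zip(edges, edges[1:])):
                continue
            s = sse(bounds)
            if s < best_sse - 1e-9:
                best_sse = s
                best = bounds
    return best


def per_base_cnvrs(calls: list[dict], max_pos: int = 10_000) -> list[dict]:
    """Merge one population's calls into regions by per-base intersection.

    ``calls`` entries: dicts with sample, chrom, start, end (1-based
    inclusive), state.  Two calls are linked when the sets of base pairs
    they cover share at least one element (so bookended intervals stay
    apart); linkage propagates by breadth-first search.  Returns one dict
    per connected component with span, state (complex when both), carriers
    and singleton flag, sorted by position.
    """
    by_chrom: dict[str, list[dict]] = {}
    for call in calls:
        by_chrom.setdefault(str(call["chrom"]), []).append(call)

    regions: list[dict] = []
    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        bases = [set(range(c["start"], c["end"] + 1)) for c in group]
        adj = {i: set() for i in range(len(group))}
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                if bases[a] & bases[b]:
                    adj[a].add(b)
                    adj[b].add(a)
        seen: set[int] = set()
        for i in range(len(group)):
            if i in seen:
                continue
            queue, component = [i], []
            seen.add(i)
            while queue:
                j = queue.pop()
                component.append(j)
                for k in adj[j]:
                    if k not in seen:
                        seen.add(k)
                        queue.append(k)
            members = [group[j] for j in component]
            states = {c["state"] for c in members}
            carriers = sorted({c["sample"] for c in members})
            regions.append(
                {
                    "chrom": chrom,
                    "start": min(c["start"] for c in members),
                    "end": max(c["end"] for c in members),
                    "state": "complex" if len(states) > 1 else next(iter(states)),
                    "carriers": tuple(carriers),
                    "singleton": len(carriers) == 1,
                }
            )
    regions.sort(key=lambda r: (r["chrom"], r["start"], r["end"]))
    return regions


def per_base_sharing(
    pop_regions: dict[str, list[dict]], overlap_fraction: float = 0.5
) -> dict[tuple[str, int], str]:
    """Label regions pop_CNVR / common_CNVR by per-base overlap counting.

    Links region pairs from different populations when the number of
    shared base pairs (counted one by one) is at least
    ``overlap_fraction`` times the shorter region's base count, then
    propagates linkage by breadth-first search.
    """
    nodes: list[tuple[str, int, dict]] = [
        (pop, i, region)
        for pop, regions in pop_regions.items()
        for i, region in enumerate(regions)
    ]
    adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            pop_a, _, ra = nodes[a]
            pop_b, _, rb = nodes[b]
            if pop_a == pop_b or ra["chrom"] != rb["chrom"]:
                continue
            bases_a = set(range(ra["start"], ra["end"] + 1))
            bases_b = set(range(rb["start"], rb["end"] + 1))
            shared = len(bases_a & bases_b)
            if shared == 0:
                continue
            if shared >= overlap_fraction * min(len(bases_a), len(bases_b)):
                adj[a].add(b)
                adj[b].add(a)

    labels: dict[tuple[str, int], str] = {}
    seen: set[int] = set()
    for i in range(len(nodes)):
        if i in seen:
            continue
        queue = [i]
        component = []
        seen.add(i)
        while queue:
            j = queue.pop()
            component.append(j)
            for k in adj[j]:
                if k not in seen:
                    seen.add(k)
                    queue.append(k)
        pops = {nodes[j][0] for j in component}
        label = "common_CNVR" if len(pops) >= 2 else "pop_CNVR"
        for j in component:
            labels[(nodes[j][0], nodes[j][1])] = label
    return labels


def random_toy_calls(
    rng: np.random.Generator,
    populations: list[str],
    n_calls: int = 30,
    max_pos: int = 10_000,
) -> list[dict]:
    """Random small call tables for oracle comparisons."""
    calls = []
    for i in range(n_calls):
        start = int(rng.integers(1, max_pos - 100))
        length = int(rng.integers(1, 400))
        calls.append(
            {
                "sample": f"s{int(rng.integers(1, 9))}",
                "population": str(rng.choice(populations)),
                "chrom": f"chr{int(rng.integers(1, 4))}",
                "start": start,
                "end": min(start + length, max_pos),
                "state": str(rng.choice(["loss", "gain"])),
            }
        )
    return calls
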