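"""Benchmarking utilities: score recovered CNV calls against a truth table.

Used to measure detection performance of the segmentation/calling stack on
synthetic cohorts with known events — the standard way to validate a CNV
caller in the absence of molecularly confirmed reference calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RecoveryMetrics", "match_calls_to_truth"]


@dataclass
class RecoveryMetrics:
    """Recall and boundary accuracy of calls against truth events.

    ``recall`` is the fraction of truth events (optionally restricted to a
    minimum marker span) overlapped by at least one same-state call of the
    same sample.  ``median_boundary_error`` is the median over matched
    events of the larger boundary offset (|start offset|, |end offset|),
    in marker positions.
    """

    n_truth: int
    n_matched: int
    recall: float
    median_boundary_error: float
    boundary_errors: np.ndarray


def match_calls_to_truth(
    truth: pd.DataFrame,
    calls: pd.DataFrame,
    min_markers: int = 1,
) -> RecoveryMetrics:
    """Match per-sample truth events to same-state overlapping calls.

    Both tables carry 1-based inclusive ``start``/``end`` plus
    within-chromosome ``first_marker``/``last_marker`` indices.  A truth
    event is matched when a call of the same sample, chromosome and state
    overlaps it by >= 1 bp; the best-overlapping call defines the boundary
    error.  Events spanning fewer than ``min_markers`` markers are ignored.
    """
    events = truth.loc[truth["n_markers"] >= min_markers]
    by_sample: dict[tuple[str, str], pd.DataFrame] = (
        {k: g for k, g in calls.groupby(["sample", "chrom"], observed=True)}
        if len(calls)
        else {}
    )

    errors: list[float] = []
    matched = 0
    for ev in events.itertuples(index=False):
        group = by_sample.get((ev.sample, ev.chrom))
        if group is None:
            continue
        cand = group.loc[
            (group["state"] == ev.state)
            & (group["start"] <= ev.end)
            & (group["end"] >= ev.start)
        ]
        if cand.empty:
            continue
        matched += 1
        overlap = np.minimum(cand["end"], ev.end) - np.maximum(cand["start"], ev.start)
        best = cand.iloc[int(np.argmax(overlap.to_numpy()))]
        err = max(
            abs(int(best["first_marker"]) - int(ev.first_marker)),
            abs(int(best["last_marker"]) - int(ev.last_marker)),
        )
        errors.append(float(err))

    n_truth = int(len(events))
    return RecoveryMetrics(
        n_truth=n_truth,
        n_matched=matched,
        recall=matched / n_truth if n_truth else float("nan"),
        median_boundary_error=float(np.median(errors)) if errors else float("nan"),
        boundary_errors=np.asarray(errors),
    )
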