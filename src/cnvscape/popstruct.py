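"""Population structure: CNV-state PCA, SNP PCA and pairwise F_ST.

CNV states per sample and CNVR are coded deletion = -1, normal = 0,
duplication = +1; the PCA centres columns without scaling (the entries
already share one scale by construction) and decomposes by SVD.

Pairwise F_ST uses the Weir–Cockerham (1984) estimator: per-locus variance
components a (among populations), b (among individuals within
populations) and c (within individuals) are combined as the multi-locus
ratio of sums  sum(a) / sum(a + b + c), which handles unequal sample
sizes.  Monomorphic loci are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from cnvscape.regions import CNVR

__all__ = ["code_cnv_states", "pca", "pairwise_fst", "PCAResult", "weir_cockerham_fst"]


def code_cnv_states(
    calls: pd.DataFrame,
    regions: Sequence[CNVR] | pd.DataFrame,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Code each sample's state in each region: -1 deletion, 0 normal, +1 duplication.

    A sample is a deletion (duplication) carrier of a region when any of
    its loss (gain) calls overlaps the region by >= 1 bp.  When both
    states overlap, the state with the larger total overlap wins; an exact
    tie falls back to 0 with a warning.

    ``regions`` is the (typically non-redundant) region set; columns of
    the result follow its order.  ``samples`` fixes the row universe
    (default: samples present in ``calls``).
    """
    if isinstance(regions, pd.DataFrame):
        region_tuples = [
            (str(r.chrom), int(r.start), int(r.end))
            for r in regions.itertuples(index=False)
        ]
    else:
        region_tuples = [(r.chrom, r.start, r.end) for r in regions]
    region_ids = [f"{c}:{s}-{e}" for c, s, e in region_tuples]
    if samples is None:
        samples = list(pd.unique(calls["sample"]))

    matrix = pd.DataFrame(
        np.zeros((len(samples), len(region_tuples)), dtype=np.int8),
        index=pd.Index(samples, name="sample"),
        columns=region_ids,
    )
    by_sample = dict(tuple(calls.groupby("sample", observed=True))) if len(calls) else {}
    for sample in samples:
        sc = by_sample.get(sample)
        if sc is None:
            continue
        c_chrom = sc["chrom"].astype(str).to_numpy()
        c_start = sc["start"].to_numpy()
        c_end = sc["end"].to_numpy()
        c_state = sc["state"].to_numpy()
        for j, (chrom, start, end) in enumerate(region_tuples):
            mask = (c_chrom == chrom) & (c_start <= end) & (c_end >= start)
            if not mask.any():
                continue
            overlap = (
                np.minimum(c_end[mask], end) - np.maximum(c_start[mask], start) + 1
            )
            states = c_state[mask]
            loss_bp = int(overlap[states == "loss"].sum())
            gain_bp = int(overlap[states == "gain"].sum())
            if loss_bp > gain_bp:
                matrix.iloc[matrix.index.get_loc(sample), j] = -1
            elif gain_bp > loss_bp:
                matrix.iloc[matrix.index.get_loc(sample), j] = 1
            elif loss_bp:  # equal non-zero overlap: ambiguous state
                warnings.warn(
                    f"sample {sample} has equal loss/gain overlap in "
                    f"{region_ids[j]}; coding as normal",
                    stacklevel=2,
                )
    return matrix


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    explained_variance_ratio: np.ndarray
    zero_variance: bool = False


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Column-centred SVD principal component analysis.

    Columns are centred but not scaled.  A constant matrix is flagged
    ``zero_variance`` with all-zero explained-variance fractions.
    """
    if isinstance(matrix, np.ndarray):
        matrix = pd.DataFrame(matrix)
    n_samples, n_vars = matrix.shape
    if n_samples < 2 or n_vars < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    max_rank = min(n_samples, n_vars)
    k = min(n_components or max_rank, max_rank)

    values = matrix.to_numpy(dtype=float)
    if np.allclose(values, values[0], atol=0.0):
        comp_names = [f"PC{i + 1}" for i in range(k)]
        return PCAResult(
            scores=pd.DataFrame(0.0, index=matrix.index, columns=comp_names),
            loadings=pd.DataFrame(0.0, index=matrix.columns, columns=comp_names),
            explained_variance_ratio=np.zeros(k),
            zero_variance=True,
        )

    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(values)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(
            model.components_.T, index=matrix.columns, columns=comp_names
        ),
        explained_variance_ratio=model.explained_variance_ratio_,
        zero_variance=False,
    )


def weir_cockerham_fst(
    genotypes: pd.DataFrame | np.ndarray, labels: pd.Series | np.ndarray
) -> float:
    """Multi-locus Weir–Cockerham F_ST for the populations in ``labels``.

    ``genotypes`` is samples x loci with 0/1/2 alternate-allele counts
    (NaN = missing).  Loci monomorphic across the pooled sample, or with
    fewer than 2 genotyped individuals in any population, are skipped.
    """
    G = np.asarray(genotypes, dtype=float)
    labels = np.asarray(labels)
    pops = pd.unique(labels)
    r = len(pops)
    if r < 2:
        raise ValueError("F_ST needs at least 2 populations")

    n_i = np.zeros((r, G.shape[1]))
    p_i = np.zeros((r, G.shape[1]))
    h_i = np.zeros((r, G.shape[1]))
    for k, pop in enumerate(pops):
        block = G[labels == pop]
        called = np.isfinite(block)
        n = called.sum(axis=0)
        n_i[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.nansum(block, axis=0) / (2 * n)
            h_i[k] = (block == 1).sum(axis=0) / n
        if (n < 2).all():
            raise ValueError(
                f"population {pop} has fewer than 2 genotyped samples at every locus"
            )

    usable = (n_i >= 1).all(axis=0)
    n_bar = n_i.mean(axis=0)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    usable &= (p_bar > 0) & (p_bar < 1) & (n_bar > 1)
    if not usable.any():
        raise ValueError("no polymorphic loci usable for F_ST")

    n_i, p_i, h_i = n_i[:, usable], p_i[:, usable], h_i[:, usable]
    n_bar = n_bar[usable]
    p_bar = p_bar[usable]
    n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    denom = (a + b + c).sum()
    if denom == 0.0:
        return 0.0
    return float(a.sum() / denom)


def pairwise_fst(
    genotypes: pd.DataFrame, populations: pd.Series
) -> pd.DataFrame:
    """Weir–Cockerham F_ST for every pair of populations.

    Returns a DataFrame with columns ``pop_a, pop_b, fst`` (symmetric in
    the pair, pairs in sorted label order).
    """
    populations = populations.loc[genotypes.index]
    rows = []
    for pop_a, pop_b in combinations(sorted(populations.unique()), 2):
        mask = populations.isin([pop_a, pop_b]).to_numpy()
        est = weir_cockerham_fst(
            genotypes.to_numpy(dtype=float)[mask], populations.to_numpy()[mask]
        )
        rows.append({"pop_a": pop_a, "pop_b": pop_b, "fst": est})
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "fst"])
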