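"""Gene and QTL-trait annotation of CNVRs by interval intersection.

A gene is reported for a region when their intervals overlap by at least
1 bp (both 1-based inclusive, the ``bedtools intersect`` default), along
with the overlap extent in bp and as a fraction of the gene.  QTL traits
come from a local lookup table keyed by gene symbol (case-insensitive), a
reproducible snapshot standing in for interactive database queries.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from cnvscape.regions import CNVR

__all__ = ["annotate_cnvrs", "attach_qtl"]

logger = logging.getLogger(__name__)


def annotate_cnvrs(
    cnvrs: Sequence[CNVR] | pd.DataFrame, genes: pd.DataFrame
) -> pd.DataFrame:
    """Intersect regions with gene intervals (>= 1 bp overlap).

    ``genes`` needs columns ``gene, chrom, start, end`` (1-based
    inclusive).  Duplicate gene symbols with conflicting coordinates are
    an input error and are reported together.  The result has one row per
    (region, overlapping gene), ordered by gene position within region,
    with ``overlap_bp`` and ``gene_fraction`` columns; regions with no
    overlapping gene contribute no rows.
    """
    for col in ("gene", "chrom", "start", "end"):
        if col not in genes.columns:
            raise ValueError(f"gene table missing required column {col!r}")
    if genes["gene"].astype(str).str.len().eq(0).any():
        raise ValueError("gene table contains empty gene symbols")
    dup = genes.groupby("gene").filter(
        lambda g: g[["chrom", "start", "end"]].drop_duplicates().shape[0] > 1
    )
    if len(dup):
        offenders = sorted(dup["gene"].unique())
        raise ValueError(
            f"conflicting coordinates for duplicated gene symbols: {offenders}"
        )

    if isinstance(cnvrs, pd.DataFrame):
        region_rows = list(cnvrs.itertuples(index=False))
        get = lambda r, f: getattr(r, f)
    else:
        region_rows = list(cnvrs)
        get = lambda r, f: getattr(r, f)

    rows: list[dict] = []
    genes_sorted = genes.sort_values(["chrom", "start", "end"], kind="stable")
    by_chrom = {str(c): g for c, g in genes_sorted.groupby("chrom", observed=True)}
    for i, region in enumerate(region_rows):
        chrom = str(get(region, "chrom"))
        start = int(get(region, "start"))
        end = int(get(region, "end"))
        g = by_chrom.get(chrom)
        if g is None:
            continue
        hits = g.loc[(g["start"] <= end) & (g["end"] >= start)]
        for _, gene in hits.iterrows():
            overlap = min(end, int(gene["end"])) - max(start, int(gene["start"])) + 1
            gene_len = int(gene["end"]) - int(gene["start"]) + 1
            rows.append(
                {
                    "region_id": f"{chrom}:{start}-{end}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "gene": str(gene["gene"]),
                    "gene_start": int(gene["start"]),
                    "gene_end": int(gene["end"]),
                    "overlap_bp": int(overlap),
                    "gene_fraction": overlap / gene_len,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "chrom",
            "start",
            "end",
            "gene",
            "gene_start",
            "gene_end",
            "overlap_bp",
            "gene_fraction",
        ],
    )


def attach_qtl(gene_report: pd.DataFrame, qtl_table: pd.DataFrame) -> pd.DataFrame:
    """Attach QTL trait annotations to an annotated gene report.

    ``qtl_table`` columns: ``gene, trait_name, trait_type, trait_class,
    qtl_ids``.  Matching is case-insensitive on the gene symbol; genes
    absent from the table get empty annotation fields.  Malformed rows
    (missing gene or trait_name) are skipped and counted in the log.
    """
    required = {"gene", "trait_name"}
    missing = required - set(qtl_table.columns)
    if missing:
        raise ValueError(f"QTL table missing required columns: {sorted(missing)}")

    table = qtl_table.copy()
    malformed = table["gene"].isna() | table["trait_name"].isna()
    malformed |= table["gene"].astype(str).str.strip().eq("")
    if malformed.any():
        logger.warning("skipping %d malformed QTL table rows", int(malformed.sum()))
        table = table.loc[~malformed]
    table["_key"] = table["gene"].astype(str).str.upper()

    def _collect(column: str) -> pd.Series:
        if column not in table.columns:
            return pd.Series(dtype=str)
        return table.groupby("_key")[column].apply(
            lambda s: "; ".join(str(v) for v in s.dropna())
        )

    traits = _collect("trait_name")
    types = _collect("trait_type")
    classes = _collect("trait_class")
    ids = _collect("qtl_ids")

    out = gene_report.copy()
    key = out["gene"].astype(str).str.upper()
    out["trait_names"] = key.map(traits).fillna("")
    out["trait_types"] = key.map(types).fillna("")
    out["trait_classes"] = key.map(classes).fillna("")
    out["qtl_ids"] = key.map(ids).fillna("")
    return out
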