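"""File formats, pipeline configuration and the end-to-end driver.

All genomic intervals are written in the BED dialect (0-based, half-open,
tab-separated); the in-memory convention everywhere else in the package is
1-based inclusive, with conversion happening here at the I/O boundary.
Matrices (LRR, genotypes, CNV states) are TSV with a header row of sample
or locus ids.  Floats are written with Python's shortest round-tripping
representation, so generated files read back bit-identically.

:func:`run_pipeline` chains the stages in workflow order — QC →
segmentation → CNVR consolidation/sharing/summaries → gene/QTL annotation
→ CNV-state PCA → SNP PCA + F_ST — and writes a manifest recording
parameters, the seed, input checksums and output checksums, so a rerun
with an identical configuration is byte-identical and fully auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from cnvscape import regions as regions_mod
from cnvscape.popstruct import code_cnv_states, pairwise_fst, pca
from cnvscape.annotation import annotate_cnvrs, attach_qtl
from cnvscape.regions import (
    CNVR,
    cnvrs_to_frame,
    compare_populations,
    filter_by_frequency,
    frequency_threshold,
    merge_cnvs_to_cnvrs,
    summarize,
)
from cnvscape.segmentation import SegmentationParams, detect_cnvs
from cnvscape.signal_qc import QCThresholds, qc_report
from cnvscape.synthetic import GenomeModel

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "read_marker_map",
    "write_marker_map",
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "read_calls",
    "write_calls",
    "read_cnvrs",
    "write_cnvrs",
]

STAGES = ("qc", "segment", "cnvr", "annotate", "pca", "fst")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@contextmanager
def _stage_errors(name: str):
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(f"pipeline stage {name!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# readers / writers


def write_table(frame: pd.DataFrame, path: Path | str, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_table(path: Path | str) -> pd.DataFrame:
    # round_trip float parsing keeps write -> read -> write byte-identical
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_marker_map(marker_map: pd.DataFrame, path: Path | str) -> None:
    write_table(marker_map, path)


def read_marker_map(path: Path | str) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", float_precision="round_trip")
    # chromosome order = order of first appearance in the (sorted) file
    out["chrom"] = pd.Categorical(
        out["chrom"], categories=pd.unique(out["chrom"])
    )
    return out


def write_matrix(matrix: pd.DataFrame, path: Path | str) -> None:
    matrix.to_csv(path, sep="\t", index=True)


def read_matrix(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_calls(calls: pd.DataFrame, path: Path | str) -> None:
    """Write a CNV call table as BED-dialect TSV (0-based, half-open)."""
    out = calls.copy()
    out["start"] = out["start"] - 1
    write_table(out, path)


def read_calls(path: Path | str) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", float_precision="round_trip")
    calls["start"] = calls["start"] + 1
    if (calls["end"] < calls["start"]).any():
        raise ValueError("call table contains intervals with end < start")
    return calls


def write_cnvrs(cnvrs: list[CNVR], path: Path | str) -> None:
    frame = cnvrs_to_frame(cnvrs)
    frame["start"] = frame["start"] - 1
    write_table(frame, path)


def read_cnvrs(path: Path | str) -> list[CNVR]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            CNVR(
                population=str(row.population),
                chrom=str(row.chrom),
                start=int(row.start) + 1,
                end=int(row.end),
                state=str(row.state),
                carriers=tuple(str(row.carriers).split(",")),
                n_calls=int(row.n_calls),
            )
        )
    return out


def read_populations(path: Path | str) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    return pd.Series(
        frame["population"].to_numpy(), index=frame["sample"], name="population"
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Validated inputs and parameters for :func:`run_pipeline`."""

    marker_map: Path
    lrr: Path
    qc_metadata: Path
    populations: Path
    genes: Path | None = None
    qtl: Path | None = None
    genotypes: Path | None = None
    seed: int = 0
    frequency_fraction: float = 0.05
    overlap_fraction: float = 0.5
    loss_threshold: float = -0.20
    gain_threshold: float = 0.20
    genome_length: int = 2_478_740_000
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    qc: QCThresholds = field(default_factory=QCThresholds)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        inputs = raw.get("inputs", {})
        params = raw.get("params", {})
        seg = params.get("segmentation", {})
        qc = params.get("qc", {})
        base = Path(path).parent

        def _p(name: str) -> Path | None:
            value = inputs.get(name)
            return (base / value) if value is not None else None

        seed = int(params.get("seed", 0))
        config = cls(
            marker_map=_p("marker_map"),
            lrr=_p("lrr"),
            qc_metadata=_p("qc_metadata"),
            populations=_p("populations"),
            genes=_p("genes"),
            qtl=_p("qtl"),
            genotypes=_p("genotypes"),
            seed=seed,
            frequency_fraction=float(params.get("frequency_fraction", 0.05)),
            overlap_fraction=float(params.get("overlap_fraction", 0.5)),
            loss_threshold=float(params.get("loss_threshold", -0.20)),
            gain_threshold=float(params.get("gain_threshold", 0.20)),
            genome_length=int(params.get("genome_length", 2_478_740_000)),
            segmentation=SegmentationParams(seed=seed, **seg),
            qc=QCThresholds(**qc),
        )
        config.validate()
        return config

    def validate(self) -> None:
        for name in ("marker_map", "lrr", "qc_metadata", "populations"):
            path = getattr(self, name)
            if path is None:
                raise ValueError(f"pipeline config missing required input {name!r}")
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        for name in ("genes", "qtl", "genotypes"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if not 0.0 < self.frequency_fraction <= 1.0:
            raise ValueError("frequency_fraction must be in (0, 1]")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.loss_threshold >= self.gain_threshold:
            raise ValueError("loss_threshold must be below gain_threshold")


def _summary_frame(summaries: Mapping[str, "regions_mod.PopulationSummary"]) -> pd.DataFrame:
    rows = []
    for pop, s in summaries.items():
        row = {
            f: getattr(s, f)
            for f in (
                "population",
                "n_samples",
                "n_cnv",
                "n_loss",
                "n_gain",
                "loss_gain_ratio",
                "min_cnv_per_sample",
                "max_cnv_per_sample",
                "mean_cnv_per_sample",
                "min_length",
                "max_length",
                "mean_length",
                "n_cnvr",
                "n_cnvr_loss",
                "n_cnvr_gain",
                "n_cnvr_complex",
                "n_singleton",
                "singleton_pct",
                "coverage_mb",
                "coverage_pct",
            )
        }
        for label, prop in s.length_class_proportions.items():
            row[f"len_{label}"] = prop
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(
    config: PipelineConfig,
    out_dir: Path | str,
    upto: str = "fst",
    plot: bool = False,
) -> dict:
    """Run the analysis chain and write all outputs plus a manifest.

    ``upto`` truncates the chain after the named stage (stages run in the
    fixed order qc → segment → cnvr → annotate → pca → fst).  Stages whose
    optional inputs are missing are recorded as skipped.  Returns the
    manifest dictionary (also written to ``manifest.json``).
    """
    config.validate()
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; expected one of {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wanted = STAGES[: STAGES.index(upto) + 1]

    marker_map = read_marker_map(config.marker_map)
    lrr = read_matrix(config.lrr)
    metadata = read_table(config.qc_metadata)
    populations = read_populations(config.populations)
    genome = GenomeModel({"genome": config.genome_length})

    stages: list[dict] = []
    outputs: list[Path] = []

    def emit(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out_dir / name
        write_table(frame, path, index=index)
        outputs.append(path)

    # --- qc ---------------------------------------------------------------
    with _stage_errors("qc"):
        retained, report = qc_report(marker_map, lrr, metadata, config.qc)
    emit("qc_report.tsv", report)
    stages.append({"name": "qc", "status": "completed"})
    lrr = lrr[retained]

    calls = pd.DataFrame()
    cnvr_sets: dict[str, list[CNVR]] = {}
    filtered_sets: dict[str, list[CNVR]] = {}
    sharing = None

    if "segment" in wanted:
        with _stage_errors("segment"):
            calls = detect_cnvs(
                marker_map,
                lrr,
                populations,
                config.segmentation,
                config.loss_threshold,
                config.gain_threshold,
            )
            path = out_dir / "calls.tsv"
            write_calls(calls, path)
            outputs.append(path)
        stages.append({"name": "segment", "status": "completed"})

    if "cnvr" in wanted:
        with _stage_errors("cnvr"):
            pop_sizes = populations.loc[retained].value_counts().to_dict()
            for pop in pop_sizes:
                regions = merge_cnvs_to_cnvrs(
                    calls.loc[calls["population"] == pop], population=pop
                )
                cnvr_sets[pop] = regions
                threshold = frequency_threshold(pop_sizes[pop], config.frequency_fraction)
                filtered_sets[pop] = filter_by_frequency(regions, threshold)
                path = out_dir / f"cnvr_{pop}.tsv"
                write_cnvrs(regions, path)
                outputs.append(path)
                path = out_dir / f"cnvr_filtered_{pop}.tsv"
                write_cnvrs(filtered_sets[pop], path)
                outputs.append(path)
            if len(filtered_sets) >= 2:
                sharing = compare_populations(filtered_sets, config.overlap_fraction)
                nr = sharing.non_redundant.copy()
                nr["start"] = nr["start"] - 1
                emit("cnvr_nonredundant.tsv", nr)
                venn = pd.DataFrame(
                    [
                        {"populations": ",".join(k), "n_regions": v}
                        for k, v in sorted(sharing.venn.items())
                    ]
                )
                emit("venn_counts.tsv", venn)
            summaries = summarize(calls, cnvr_sets, genome, pop_sizes)
            emit("summary.tsv", _summary_frame(summaries))
            for pop, s in summaries.items():
                emit(f"per_chromosome_{pop}.tsv", s.per_chromosome)
            stages.append({"name": "cnvr", "status": "completed"})

    if "annotate" in wanted:
        with _stage_errors("annotate"):
            if config.genes is not None and sharing is not None:
                genes = read_table(config.genes)
                annot = annotate_cnvrs(sharing.non_redundant, genes)
                if config.qtl is not None:
                    annot = attach_qtl(annot, read_table(config.qtl))
                emit("annotation.tsv", annot)
                stages.append({"name": "annotate", "status": "completed"})
            else:
                stages.append({"name": "annotate", "status": "skipped"})

    if "pca" in wanted:
        with _stage_errors("pca"):
            if sharing is not None and len(sharing.non_redundant) >= 2:
                states = code_cnv_states(
                    calls, sharing.non_redundant, samples=list(lrr.columns)
                )
                emit("cnv_states.tsv", states, index=True)
                result = pca(states)
                emit("cnv_pca_scores.tsv", result.scores, index=True)
                emit(
                    "cnv_pca_variance.tsv",
                    pd.DataFrame(
                        {
                            "component": result.scores.columns,
                            "explained_variance_ratio": result.explained_variance_ratio,
                        }
                    ),
                )
                if plot:
                    _scatter(
                        result.scores, populations, out_dir / "cnv_pca.png", "CNV-state PCA"
                    )
                stages.append({"name": "pca", "status": "completed"})
            else:
                stages.append({"name": "pca", "status": "skipped"})

    if "fst" in wanted:
        with _stage_errors("fst"):
            if config.genotypes is not None:
                genotypes = read_matrix(config.genotypes)
                geno_pops = populations.loc[genotypes.index]
                snp_pca = pca(genotypes)
                emit("snp_pca_scores.tsv", snp_pca.scores, index=True)
                fst = pairwise_fst(genotypes, geno_pops)
                emit("fst.tsv", fst)
                if plot:
                    _scatter(
                        snp_pca.scores, geno_pops, out_dir / "snp_pca.png", "SNP PCA"
                    )
                stages.append({"name": "fst", "status": "completed"})
            else:
                stages.append({"name": "fst", "status": "skipped"})

    manifest = {
        "parameters": {
            "seed": config.seed,
            "frequency_fraction": config.frequency_fraction,
            "overlap_fraction": config.overlap_fraction,
            "loss_threshold": config.loss_threshold,
            "gain_threshold": config.gain_threshold,
            "genome_length": config.genome_length,
            "segmentation": dataclasses.asdict(config.segmentation),
            "qc": dataclasses.asdict(config.qc),
        },
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("marker_map", "lrr", "qc_metadata", "populations",
                         "genes", "qtl", "genotypes")
            if getattr(config, name) is not None
        },
        "stages": stages,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _scatter(scores: pd.DataFrame, populations: pd.Series, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pops = populations.loc[scores.index]
    for pop in pd.unique(pops):
        mask = (pops == pop).to_numpy()
        ax.scatter(
            scores.iloc[mask, 0], scores.iloc[mask, 1], label=str(pop), s=14, alpha=0.8
        )
    ax.set_xlabel(scores.columns[0])
    ax.set_ylabel(scores.columns[1] if scores.shape[1] > 1 else "")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
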