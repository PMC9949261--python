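"""End-to-end run orchestration: demux -> fit -> factors -> normalize -> metrics.

Clonotype assembly itself is external (the pipeline consumes assembler
tabular exports); everything else in the post-merge analysis chain runs
here.  Every artifact is a TSV with a provenance header (seed, version,
factor source), and a run-summary TSV is always produced.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .demux import demux_fastq
from .io import (
    read_clonotype_table,
    read_design,
    read_st_counts,
    write_clonotype_table,
    write_panel_fit,
    write_scaling_factors,
    write_st_counts,
)
from .metrics import summarize_repertoire
from .nb import fit_panel
from .normalize import batch_scaling_factors, nb_scaling_factors, normalize_clonotypes
from .panel import STCountMatrix

__all__ = ["RunConfig", "PipelineError", "pipeline_run"]

logger = logging.getLogger("otsp")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``st_fastq`` (merged reads to demultiplex) or
    ``st_counts`` (a pre-quantified ST count TSV) must be given.
    """

    design: str
    clonotypes: str
    out_prefix: str
    st_fastq: str | None = None
    st_counts: str | None = None
    normalization: str = "nb_mean"  # nb_mean | batch_mean
    seed: int = 0
    hyperexpanded_threshold: float = 0.01
    barcode_max_dist: int = 1
    column_map: Mapping[str, str] | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if (self.st_fastq is None) == (self.st_counts is None):
            raise ValueError("provide exactly one of st_fastq or st_counts")
        if self.normalization not in ("nb_mean", "batch_mean"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for name in ("design", "clonotypes", "st_fastq", "st_counts"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} path does not exist: {value}")
        Path(self.out_prefix).parent.mkdir(parents=True, exist_ok=True)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def pipeline_run(config: RunConfig) -> dict[str, Path]:
    """Run the full post-merge pipeline; returns the output paths."""
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    config.validate()
    prefix = Path(config.out_prefix)
    header = [f"otsp {__version__}", f"seed {config.seed}",
              f"normalization {config.normalization}"]
    outputs: dict[str, Path] = {}
    summary_rows: list[dict] = []

    design = _stage("design")(read_design)(config.design)

    if config.st_fastq is not None:
        logger.info("demultiplexing %s", config.st_fastq)
        non_st_path = prefix.with_name(prefix.name + ".non_st.fastq")
        counts_vec, _non_st, demux_summary = _stage("demux")(demux_fastq)(
            config.st_fastq, design, max_dist=config.barcode_max_dist,
            non_st_out=non_st_path,
        )
        matrix = STCountMatrix(panel=design.panel,
                               counts=counts_vec[:, None],
                               sample_ids=("sample1",),
                               batch_id=prefix.name, design=design)
        outputs["non_st_fastq"] = non_st_path
        summary_rows.append({"stage": "demux", "key": "n_reads_total",
                             "value": demux_summary.n_reads_total})
        summary_rows.append({"stage": "demux", "key": "n_st_flagged",
                             "value": demux_summary.n_st_flagged})
        summary_rows.append({"stage": "demux", "key": "n_st_assigned",
                             "value": demux_summary.n_st_assigned})
        summary_rows.append({"stage": "demux", "key": "n_st_ambiguous",
                             "value": demux_summary.n_st_ambiguous})
        summary_rows.append({"stage": "demux", "key": "n_non_st",
                             "value": demux_summary.n_non_st})
    else:
        logger.info("loading ST counts from %s", config.st_counts)
        matrix = _stage("st_counts")(read_st_counts)(
            config.st_counts, panel=design.panel)

    counts_path = prefix.with_name(prefix.name + ".st_counts.tsv")
    write_st_counts(matrix, counts_path, header)
    outputs["st_counts"] = counts_path
    summary_rows.append({"stage": "st_counts", "key": "n_samples",
                         "value": matrix.n_samples})
    summary_rows.append({"stage": "st_counts", "key": "total_st_reads",
                         "value": int(matrix.counts.sum())})

    if config.normalization == "nb_mean":
        if matrix.n_samples < 2:
            logger.warning(
                "single sample: NB dispersions are not estimable; "
                "factors reduce to the batch means")
            sf = nb_scaling_factors(matrix.row_means(), panel=matrix.panel)
        else:
            fit = _stage("fit")(fit_panel)(matrix)
            fit_path = prefix.with_name(prefix.name + ".fit.tsv")
            write_panel_fit(fit, fit_path)
            outputs["fit"] = fit_path
            summary_rows.append({"stage": "fit", "key": "common_dispersion",
                                 "value": fit.common_dispersion})
            summary_rows.append({"stage": "fit", "key": "m_bar",
                                 "value": fit.m_bar})
            sf = nb_scaling_factors(fit)
    else:
        sf = _stage("factors")(batch_scaling_factors)(matrix)
    sf_path = prefix.with_name(prefix.name + ".factors.tsv")
    write_scaling_factors(sf, sf_path, header)
    outputs["factors"] = sf_path

    logger.info("normalizing clonotypes from %s", config.clonotypes)
    table = _stage("clonotypes")(read_clonotype_table)(
        config.clonotypes, column_map=config.column_map, panel=design.panel)
    normalized = _stage("normalize")(normalize_clonotypes)(table, sf)
    clones_path = prefix.with_name(prefix.name + ".normalized_clones.tsv")
    write_clonotype_table(normalized, clones_path, header)
    outputs["normalized_clones"] = clones_path

    metric_frames = []
    for use_norm, label in ((False, "raw"), (True, "normalized")):
        summary = _stage("metrics")(summarize_repertoire)(
            normalized, use_normalized=use_norm,
            threshold=config.hyperexpanded_threshold)
        row = {"counts": label, **summary.to_dict()}
        metric_frames.append(row)
        for key, value in summary.to_dict().items():
            summary_rows.append({"stage": f"metrics_{label}", "key": key,
                                 "value": value})
    metrics_path = prefix.with_name(prefix.name + ".metrics.tsv")
    with open(metrics_path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        pd.DataFrame(metric_frames).to_csv(fh, sep="\t", index=False)
    outputs["metrics"] = metrics_path

    run_summary_path = prefix.with_name(prefix.name + ".run_summary.tsv")
    with open(run_summary_path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        pd.DataFrame(summary_rows).to_csv(fh, sep="\t", index=False)
    outputs["run_summary"] = run_summary_path
    logger.info("pipeline complete: %d outputs under %s", len(outputs), prefix)
    return outputs
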