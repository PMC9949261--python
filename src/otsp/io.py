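"""TSV/YAML readers and writers for panel designs, counts and factors.

All TSV outputs carry explicit ``v_name``/``j_name`` columns (files are
index-convention-free) and may start with ``#``-prefixed provenance
header lines, which every reader skips.  Every writer round-trips
losslessly through its reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .nb import NBPanelFit
from .normalize import ScalingFactorSet
from .panel import (
    ClonotypeTable,
    PanelError,
    PrimerPanel,
    STCountMatrix,
    STDesign,
)

__all__ = [
    "write_design",
    "read_design",
    "write_st_counts",
    "read_st_counts",
    "write_clonotype_table",
    "read_clonotype_table",
    "write_scaling_factors",
    "read_scaling_factors",
    "write_panel_fit",
    "read_panel_fit",
]

#: Accepted aliases for clonotype-table columns (assembler export headers).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "cloneId": "clone_id",
    "cloneCount": "raw_count",
    "count": "raw_count",
    "nSeqCDR3": "cdr3_nt",
    "cdr3nt": "cdr3_nt",
    "aaSeqCDR3": "cdr3_aa",
    "cdr3aa": "cdr3_aa",
    "v": "v_name",
    "bestVGene": "v_name",
    "j": "j_name",
    "bestJGene": "j_name",
}


def _write_tsv(frame: pd.DataFrame, path, header_lines: Sequence[str] = ()):
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_design(design: STDesign, path) -> None:
    doc = {
        "v_names": list(design.panel.v_names),
        "j_names": list(design.panel.j_names),
        "universal_barcode": design.universal_barcode,
        "specific_barcodes": list(design.specific_barcodes),
        "template_length": design.template_length,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_design(path) -> STDesign:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        panel = PrimerPanel(tuple(doc["v_names"]), tuple(doc["j_names"]))
        return STDesign(
            panel=panel,
            universal_barcode=doc["universal_barcode"],
            specific_barcodes=tuple(doc["specific_barcodes"]),
            template_length=int(doc.get("template_length", 200)),
        )
    except KeyError as exc:
        raise PanelError(f"design file missing key: {exc}") from exc


def write_st_counts(matrix: STCountMatrix, path,
                    header_lines: Sequence[str] = ()) -> None:
    _write_tsv(matrix.to_frame(), path, header_lines)


def read_st_counts(path, panel: PrimerPanel | None = None,
                   batch_id: str | None = None,
                   concentration: float | None = None) -> STCountMatrix:
    df = _read_tsv(path)
    for col in ("v_name", "j_name"):
        if col not in df.columns:
            raise PanelError(f"ST count file missing column {col!r}")
    if panel is None:
        panel = PrimerPanel(
            tuple(dict.fromkeys(df["v_name"].astype(str))),
            tuple(dict.fromkeys(df["j_name"].astype(str))),
        )
    sample_cols = [c for c in df.columns if c not in ("v_name", "j_name")]
    if not sample_cols:
        raise PanelError("ST count file has no sample columns")
    counts = np.zeros((panel.n_pairs, len(sample_cols)), dtype=np.int64)
    seen = np.zeros(panel.n_pairs, dtype=bool)
    for _, row in df.iterrows():
        i = panel.pair_index(row["v_name"], row["j_name"])
        counts[i] = [row[c] for c in sample_cols]
        seen[i] = True
    if not seen.all():
        missing = [panel.pair_name(i) for i in np.nonzero(~seen)[0][:5]]
        raise PanelError(f"ST count file missing primer pairs, e.g. {missing}")
    return STCountMatrix(panel=panel, counts=counts,
                         sample_ids=tuple(sample_cols),
                         batch_id=batch_id or Path(path).stem,
                         concentration=concentration)


def write_clonotype_table(table: ClonotypeTable, path,
                          header_lines: Sequence[str] = ()) -> None:
    _write_tsv(table.frame, path, header_lines)


def read_clonotype_table(path, column_map: Mapping[str, str] | None = None,
                         panel: PrimerPanel | None = None) -> ClonotypeTable:
    """Read a clonotype TSV, accepting common assembler export headers.

    ``column_map`` maps file column names to the canonical ones
    (``cdr3_nt, v_name, j_name, raw_count, ...``) and extends the
    built-in aliases.  Missing mandatory columns and malformed rows are
    reported with names / line numbers.
    """
    df = _read_tsv(path)
    mapping = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        mapping.update(column_map)
    df = df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})
    missing = [c for c in ("cdr3_nt", "v_name", "j_name", "raw_count")
               if c not in df.columns]
    if missing:
        raise PanelError(
            f"clonotype file {Path(path).name} missing mandatory "
            f"column(s): {missing}"
        )
    return ClonotypeTable(df, panel=panel)


def write_scaling_factors(sf: ScalingFactorSet, path,
                          header_lines: Sequence[str] = ()) -> None:
    _write_tsv(sf.to_frame(), path, header_lines)


def read_scaling_factors(path, panel: PrimerPanel | None = None
                         ) -> ScalingFactorSet:
    df = _read_tsv(path)
    for col in ("v_name", "j_name", "factor"):
        if col not in df.columns:
            raise PanelError(f"scaling-factor file missing column {col!r}")
    if panel is None:
        panel = PrimerPanel(
            tuple(dict.fromkeys(df["v_name"].astype(str))),
            tuple(dict.fromkeys(df["j_name"].astype(str))),
        )
    factors = np.full(panel.n_pairs, np.nan)
    for _, row in df.iterrows():
        factors[panel.pair_index(row["v_name"], row["j_name"])] = row["factor"]
    kind = str(df["kind"].iloc[0]) if "kind" in df.columns else "nb_mean"
    return ScalingFactorSet(panel=panel, factors=factors, kind=kind,
                            provenance=(Path(path).stem,))


def write_panel_fit(fit: NBPanelFit, path) -> None:
    header = [
        f"common_dispersion\t{fit.common_dispersion!r}",
        f"m_bar\t{fit.m_bar!r}",
        f"n_samples\t{fit.n_samples}",
        f"batch_ids\t{','.join(fit.batch_ids)}",
    ]
    _write_tsv(fit.to_frame(), path, header)


def read_panel_fit(path, panel: PrimerPanel | None = None) -> NBPanelFit:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").rstrip("\n").partition("\t")
            meta[key] = value
    df = _read_tsv(path)
    if panel is None:
        panel = PrimerPanel(
            tuple(dict.fromkeys(df["v_name"].astype(str))),
            tuple(dict.fromkeys(df["j_name"].astype(str))),
        )
    means = np.zeros(panel.n_pairs)
    disps = np.full(panel.n_pairs, np.nan)
    for _, row in df.iterrows():
        i = panel.pair_index(row["v_name"], row["j_name"])
        means[i] = row["m_hat"]
        disps[i] = row["d_hat"]
    return NBPanelFit(
        panel=panel, means=means, dispersions=disps,
        common_dispersion=float(meta.get("common_dispersion", "nan")),
        m_bar=float(meta.get("m_bar", "nan")),
        n_samples=int(meta.get("n_samples", 0)),
        batch_ids=tuple(filter(None, meta.get("batch_ids", "").split(","))),
    )
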