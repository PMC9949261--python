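"""Primer-panel domain model for multiplex TCRβ amplification.

A multiplex TCRβ PCR uses a panel of V-segment forward primers and
J-segment reverse primers; every (V, J) combination is one *primer pair*
with its own amplification efficiency.  The default panel has 20 V and
13 J primers, hence 260 pairs, and one equimolar synthetic template (ST)
per pair carrying a 16-bp pair-specific barcode flanked by a 9-bp barcode
common to all STs.

All pair-indexed vectors in this package use the canonical flat index

    i = v_index * n_j + j_index        (0-based)

so that index 0 is (V1, J1) and index ``n_pairs - 1`` is the last (V, J)
combination.  TSV files always carry explicit ``v_name``/``j_name``
columns so files stay index-convention-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelError",
    "DesignError",
    "UnknownPrimerError",
    "PrimerPanel",
    "STDesign",
    "STCountMatrix",
    "ClonotypeTable",
    "pair_index",
    "clonotype_primer_totals",
]


class PanelError(ValueError):
    """Invalid primer panel or panel-indexed data."""


class DesignError(ValueError):
    """Synthetic-template design violates a barcode constraint."""


class UnknownPrimerError(KeyError):
    """A V or J name does not resolve against the panel."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it plain
        return self.args[0] if self.args else ""


def _clean_names(names: Sequence[str], kind: str) -> tuple[str, ...]:
    cleaned = tuple(str(n).strip() for n in names)
    if not cleaned:
        raise PanelError(f"{kind} primer list must be non-empty")
    if any(not n for n in cleaned):
        raise PanelError(f"{kind} primer names must be non-blank")
    if len(set(cleaned)) != len(cleaned):
        dupes = sorted({n for n in cleaned if cleaned.count(n) > 1})
        raise PanelError(f"duplicate {kind} primer names: {dupes}")
    return cleaned


@dataclass(frozen=True)
class PrimerPanel:
    """Ordered V and J primer names defining the pair-index space."""

    v_names: tuple[str, ...]
    j_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "v_names", _clean_names(self.v_names, "V"))
        object.__setattr__(self, "j_names", _clean_names(self.j_names, "J"))

    @classmethod
    def default(cls) -> "PrimerPanel":
        """The 20 V x 13 J panel (260 primer pairs)."""
        return cls(
            v_names=tuple(f"V{i}" for i in range(1, 21)),
            j_names=tuple(f"J{i}" for i in range(1, 14)),
        )

    @property
    def n_v(self) -> int:
        return len(self.v_names)

    @property
    def n_j(self) -> int:
        return len(self.j_names)

    @property
    def n_pairs(self) -> int:
        return self.n_v * self.n_j

    @cached_property
    def _v_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.v_names)}

    @cached_property
    def _j_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.j_names)}

    def pair_index(self, v_name: str, j_name: str) -> int:
        """Flat 0-based index of primer pair (v_name, j_name)."""
        v = str(v_name).strip()
        j = str(j_name).strip()
        try:
            vi = self._v_index[v]
        except KeyError:
            raise UnknownPrimerError(f"unknown V primer name: {v!r}") from None
        try:
            ji = self._j_index[j]
        except KeyError:
            raise UnknownPrimerError(f"unknown J primer name: {j!r}") from None
        return vi * self.n_j + ji

    def pair_name(self, index: int) -> tuple[str, str]:
        """Inverse of :meth:`pair_index`."""
        idx = int(index)
        if not 0 <= idx < self.n_pairs:
            raise PanelError(
                f"pair index {idx} out of range 0..{self.n_pairs - 1}"
            )
        return self.v_names[idx // self.n_j], self.j_names[idx % self.n_j]

    def iter_pairs(self) -> Iterator[tuple[int, str, str]]:
        for i in range(self.n_pairs):
            v, j = self.pair_name(i)
            yield i, v, j

    def pair_frame(self) -> pd.DataFrame:
        """Two-column frame (v_name, j_name) in pair-index order."""
        rows = [(v, j) for _, v, j in self.iter_pairs()]
        return pd.DataFrame(rows, columns=["v_name", "j_name"])


def pair_index(panel: PrimerPanel, v_name: str, j_name: str) -> int:
    """Canonical pair index of (v_name, j_name); see :class:`PrimerPanel`."""
    return panel.pair_index(v_name, j_name)


_DNA = set("ACGT")


def _check_dna(seq: str, what: str) -> str:
    s = str(seq).strip().upper()
    if not s or set(s) - _DNA:
        raise DesignError(f"{what} must be a non-empty ACGT string, got {seq!r}")
    return s


@dataclass(frozen=True)
class STDesign:
    """Synthetic-template design: panel plus the barcode scheme.

    One 200-bp template per primer pair; each carries the 9-bp universal
    barcode (flags a read as ST) next to a 16-bp pair-specific barcode
    (identifies which ST).  Barcode assignment downstream tolerates one
    mismatch or indel, which is guaranteed unambiguous when all specific
    barcodes are at pairwise edit distance >= 3.
    """

    panel: PrimerPanel
    universal_barcode: str
    specific_barcodes: tuple[str, ...]
    template_length: int = 200

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "universal_barcode", _check_dna(self.universal_barcode, "universal barcode")
        )
        object.__setattr__(
            self,
            "specific_barcodes",
            tuple(_check_dna(b, "specific barcode") for b in self.specific_barcodes),
        )
        if len(self.specific_barcodes) != self.panel.n_pairs:
            raise DesignError(
                f"need {self.panel.n_pairs} specific barcodes "
                f"(one per primer pair), got {len(self.specific_barcodes)}"
            )
        lengths = {len(b) for b in self.specific_barcodes}
        if len(lengths) != 1:
            raise DesignError("specific barcodes must all have the same length")
        if self.template_length < len(self.universal_barcode) + len(self.specific_barcodes[0]):
            raise DesignError("template_length too short to hold both barcodes")

    @property
    def n_templates(self) -> int:
        return self.panel.n_pairs

    def validate_distances(self, min_dist: int = 3) -> None:
        """Check the barcode edit-distance invariants.

        Every pair of specific barcodes must be at Levenshtein distance
        >= ``min_dist``, and the universal barcode must be at distance
        >= ``min_dist`` from every window of every specific barcode (so a
        specific barcode can never be mistaken for the universal flag at
        the one-error search tolerance).
        """
        import edlib

        k = min_dist - 1
        bcs = self.specific_barcodes
        for a_idx in range(len(bcs)):
            a = bcs[a_idx]
            hit = edlib.align(self.universal_barcode, a, mode="HW", task="distance", k=k)
            if hit["editDistance"] != -1:
                raise DesignError(
                    f"specific barcode {a_idx} contains a window within "
                    f"distance {hit['editDistance']} of the universal barcode"
                )
            for b_idx in range(a_idx + 1, len(bcs)):
                d = edlib.align(a, bcs[b_idx], task="distance", k=k)["editDistance"]
                if d != -1:
                    raise DesignError(
                        f"specific barcodes {a_idx} and {b_idx} are at edit "
                        f"distance {d} < {min_dist}"
                    )


@dataclass
class STCountMatrix:
    """ST read counts C_ij: one row per primer pair, one column per sample."""

    panel: PrimerPanel
    counts: np.ndarray
    sample_ids: tuple[str, ...] = ()
    batch_id: str = "batch"
    concentration: float | None = None
    design: STDesign | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise PanelError("counts must be a 2-D (pairs x samples) array")
        if counts.shape[0] != self.panel.n_pairs:
            raise PanelError(
                f"counts has {counts.shape[0]} rows; panel defines "
                f"{self.panel.n_pairs} primer pairs"
            )
        if counts.shape[1] < 1:
            raise PanelError("need at least one sample column")
        if np.any(counts < 0):
            raise PanelError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise PanelError("counts must be integers")
        self.counts = counts.astype(np.int64)
        if not self.sample_ids:
            self.sample_ids = tuple(f"s{j + 1}" for j in range(counts.shape[1]))
        else:
            self.sample_ids = tuple(str(s) for s in self.sample_ids)
        if len(self.sample_ids) != counts.shape[1]:
            raise PanelError("sample_ids length does not match column count")
        if self.concentration is not None and self.concentration <= 0:
            raise PanelError("concentration must be positive")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def row_means(self) -> np.ndarray:
        return self.counts.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        out = self.panel.pair_frame()
        for j, sid in enumerate(self.sample_ids):
            out[sid] = self.counts[:, j]
        return out


_CLONE_REQUIRED = ("cdr3_nt", "v_name", "j_name", "raw_count")
_CLONE_COLUMNS = ("clone_id", "cdr3_nt", "cdr3_aa", "v_name", "j_name",
                  "raw_count", "normalized_count")


class ClonotypeTable:
    """Clonotype records: CDR3 nucleotide sequence, V/J names, counts.

    Wraps a :class:`pandas.DataFrame` with columns ``clone_id, cdr3_nt,
    cdr3_aa, v_name, j_name, raw_count, normalized_count`` (the tabular
    shape exported by clonotype assemblers).  ``normalized_count`` is NaN
    until normalization fills it.
    """

    def __init__(self, frame: pd.DataFrame, panel: PrimerPanel | None = None):
        df = frame.copy()
        missing = [c for c in _CLONE_REQUIRED if c not in df.columns]
        if missing:
            raise PanelError(f"clonotype table missing required columns: {missing}")
        if "clone_id" not in df.columns:
            df["clone_id"] = [f"clone{i + 1}" for i in range(len(df))]
        if "cdr3_aa" not in df.columns:
            df["cdr3_aa"] = pd.NA
        if "normalized_count" not in df.columns:
            df["normalized_count"] = np.nan
        df["v_name"] = df["v_name"].astype(str).str.strip()
        df["j_name"] = df["j_name"].astype(str).str.strip()
        counts = pd.to_numeric(df["raw_count"], errors="coerce")
        bad = df.index[counts.isna() | (counts < 0)].tolist()
        if bad:
            raise PanelError(f"non-numeric or negative raw_count in rows {bad}")
        df["raw_count"] = counts.astype(np.int64)
        if len(df) and df["raw_count"].sum() <= 0:
            raise PanelError("non-empty clonotype table must have positive total count")
        self._frame = df.loc[:, list(_CLONE_COLUMNS)].reset_index(drop=True)
        if panel is not None:
            self.pair_indices(panel)  # raises on unresolvable names

    @classmethod
    def from_records(cls, records: Sequence[dict], panel: PrimerPanel | None = None
                     ) -> "ClonotypeTable":
        return cls(pd.DataFrame.from_records(records), panel=panel)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def total_raw(self) -> int:
        return int(self._frame["raw_count"].sum())

    @property
    def has_normalized(self) -> bool:
        return bool(self._frame["normalized_count"].notna().all()) and len(self) > 0

    def pair_indices(self, panel: PrimerPanel) -> np.ndarray:
        """Pair index per record; raises listing unresolvable records."""
        idx = np.empty(len(self._frame), dtype=np.int64)
        bad: list[tuple[int, str, str]] = []
        for pos, (v, j) in enumerate(
            zip(self._frame["v_name"], self._frame["j_name"])
        ):
            try:
                idx[pos] = panel.pair_index(v, j)
            except UnknownPrimerError:
                bad.append((pos, v, j))
        if bad:
            raise UnknownPrimerError(
                "clonotype records with V/J names not in the panel "
                f"(row, v, j): {bad[:10]}{' ...' if len(bad) > 10 else ''}"
            )
        return idx

    def counts(self, use_normalized: bool = False) -> np.ndarray:
        if use_normalized:
            if not self.has_normalized:
                raise PanelError("normalized counts requested but not present")
            return self._frame["normalized_count"].to_numpy(dtype=float)
        return self._frame["raw_count"].to_numpy(dtype=float)

    def frequencies(self, use_normalized: bool = False) -> np.ndarray:
        c = self.counts(use_normalized)
        total = c.sum()
        if total <= 0:
            raise PanelError("cannot form frequencies from zero total count")
        return c / total

    def with_normalized(self, values: np.ndarray) -> "ClonotypeTable":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self._frame),):
            raise PanelError("normalized values length does not match table")
        if np.any(values < 0):
            raise PanelError("normalized counts must be non-negative")
        df = self._frame.copy()
        df["normalized_count"] = values
        return ClonotypeTable(df)


def clonotype_primer_totals(table: ClonotypeTable, panel: PrimerPanel) -> np.ndarray:
    """Primer-pair totals C_i: total clonotype count amplified by pair i.

    Conserves the table's total read count exactly:
    ``totals.sum() == table.total_raw``.
    """
    if len(table) == 0:
        return np.zeros(panel.n_pairs, dtype=np.int64)
    idx = table.pair_indices(panel)
    raw = table.frame["raw_count"].to_numpy()
    return np.bincount(idx, weights=raw, minlength=panel.n_pairs).astype(np.int64)
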