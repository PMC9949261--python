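"""Repertoire summary metrics over (normalized) clonotype frequencies.

Shannon diversity is reported in nats by default (base-2 via ``base``);
clonality is the normalized-entropy complement 1 - H/ln(R), 0 for a
perfectly even repertoire and 1 for a monoclonal one.  Hyperexpanded
fraction sums the frequencies of clones above a frequency threshold
(default 0.01).  Cross-replicate dropout tabulation keys clones by the
exact (cdr3_nt, v_name, j_name) triple.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import ClonotypeTable

__all__ = [
    "RepertoireSummary",
    "to_frequencies",
    "shannon_diversity",
    "clonality",
    "hyperexpanded_fraction",
    "dominant_clone_proportion",
    "dropout_table",
    "summarize_repertoire",
]

_FREQ_TOL = 1e-9


def to_frequencies(counts: Sequence[float]) -> np.ndarray:
    """Counts to relative frequencies; errors on a zero-sum vector."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("cannot form frequencies from a zero-sum vector")
    return c / total


def _check_probs(p: Sequence[float]) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty probability vector")
    if np.any(p < 0) or abs(p.sum() - 1.0) > _FREQ_TOL:
        raise ValueError("probabilities must be non-negative and sum to 1")
    return p


def shannon_diversity(p: Sequence[float], base: float | None = None) -> float:
    """H = -sum p ln p (nats), with 0 ln 0 = 0; ``base=2`` for bits."""
    p = _check_probs(p)
    pos = p[p > 0]
    h = float(-(pos * np.log(pos)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def clonality(p: Sequence[float]) -> float:
    """1 - H/ln(R): 0 = even repertoire, 1 = monoclonal."""
    p = _check_probs(p)
    r = len(p)
    if r == 1:
        warnings.warn("single-clone repertoire: clonality defined as 1",
                      stacklevel=2)
        return 1.0
    value = 1.0 - shannon_diversity(p) / math.log(r)
    return min(1.0, max(0.0, value))  # clip float round-off to [0, 1]


def hyperexpanded_fraction(p: Sequence[float], threshold: float = 0.01) -> float:
    """Summed frequency of clones with frequency > threshold."""
    p = _check_probs(p)
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return float(p[p > threshold].sum())


def dominant_clone_proportion(table: ClonotypeTable,
                              use_normalized: bool = False) -> float:
    """Frequency of the most abundant clone (ties pick either)."""
    if len(table) == 0:
        raise ValueError("empty clonotype table")
    return float(table.frequencies(use_normalized).max())


_CLONE_KEY = ["cdr3_nt", "v_name", "j_name"]


def dropout_table(replicates: Sequence[ClonotypeTable],
                  top_fraction: float | None = None) -> pd.Series:
    """Distinct clones detected in exactly k of n replicates, k = 1..n.

    With ``top_fraction`` given, only the union of each replicate's most
    frequent fraction of clonotypes (by raw count) is tabulated — their
    presence is still scored against the full replicate tables, so the
    result measures dropout of clones that are abundant somewhere.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    n = len(replicates)
    member_sets = []
    for rep in replicates:
        keys = set(map(tuple, rep.frame[_CLONE_KEY].itertuples(index=False)))
        member_sets.append(keys)

    if top_fraction is None:
        universe = set().union(*member_sets)
    else:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        universe = set()
        for rep in replicates:
            df = rep.frame.sort_values("raw_count", ascending=False,
                                       kind="stable")
            k_top = max(1, math.ceil(top_fraction * len(df)))
            universe |= set(map(tuple,
                                df.head(k_top)[_CLONE_KEY].itertuples(index=False)))

    counts = np.zeros(n + 1, dtype=np.int64)
    for key in universe:
        counts[sum(key in s for s in member_sets)] += 1
    return pd.Series(counts[1:], index=pd.RangeIndex(1, n + 1, name="k"),
                     name="n_clones")


@dataclass(frozen=True)
class RepertoireSummary:
    n_clones: int
    shannon_H: float
    clonality: float
    max_clonal_frequency: float
    hyperexpanded_fraction: float
    hyperexpanded_threshold: float

    def to_dict(self) -> dict:
        return {
            "n_clones": self.n_clones,
            "shannon_H": self.shannon_H,
            "clonality": self.clonality,
            "max_clonal_frequency": self.max_clonal_frequency,
            "hyperexpanded_fraction": self.hyperexpanded_fraction,
            "hyperexpanded_threshold": self.hyperexpanded_threshold,
        }


def summarize_repertoire(table: ClonotypeTable, use_normalized: bool = False,
                         threshold: float = 0.01) -> RepertoireSummary:
    """All repertoire metrics for one sample's clonotype table."""
    p = table.frequencies(use_normalized)
    return RepertoireSummary(
        n_clones=len(table),
        shannon_H=shannon_diversity(p),
        clonality=clonality(p),
        max_clonal_frequency=float(p.max()),
        hyperexpanded_fraction=hyperexpanded_fraction(p, threshold),
        hyperexpanded_threshold=threshold,
    )
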