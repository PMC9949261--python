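"""Separate ST reads from clonotype reads and quantify the templates.

Merged reads are scanned for the 9-bp universal barcode; reads carrying it
(allowing one mismatch or indel, i.e. Levenshtein distance <= 1) are
flagged as synthetic-template reads and removed from downstream clonotype
analysis.  Flagged reads are then assigned to one of the templates by the
16-bp pair-specific barcode at the same tolerance.  Flagged reads without
a unique specific-barcode match (a tie at minimal distance, or no match at
all) are counted as ambiguous and dropped — never fractionally allocated.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import edlib
import numpy as np

from .panel import STDesign
from .simulate import FastqRead

__all__ = [
    "NOT_ST",
    "AMBIGUOUS",
    "DemuxSummary",
    "find_barcode",
    "assign_st",
    "demux_fastq",
    "parse_fastq",
    "write_fastq",
]

#: Sentinels returned by :func:`assign_st`.
NOT_ST = "NOT_ST"
AMBIGUOUS = "AMBIGUOUS"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FastqFormatError(ValueError):
    """Malformed FASTQ record."""


@dataclass
class DemuxSummary:
    """Read-level accounting for one demultiplexing run.

    Invariants: ``n_st_assigned + n_st_ambiguous == n_st_flagged`` and
    ``n_st_flagged + n_non_st == n_reads_total``; the per-template counts
    sum to ``n_st_assigned``.
    """

    n_reads_total: int
    n_st_flagged: int
    n_st_assigned: int
    n_st_ambiguous: int
    n_non_st: int
    template_counts: np.ndarray

    def __post_init__(self) -> None:
        assert self.n_st_assigned + self.n_st_ambiguous == self.n_st_flagged
        assert self.n_st_flagged + self.n_non_st == self.n_reads_total
        assert int(self.template_counts.sum()) == self.n_st_assigned


def _window_min_distances(read: str, barcode: str) -> np.ndarray:
    """dist[s] = min Levenshtein distance of barcode to read windows starting at s.

    Semi-global DP run on the reversed strings: the classic infix DP is
    free at the window *start*; reversing both strings turns per-end
    minima into per-start minima.  The horizontal (gap-in-barcode) pass is
    a running minimum of ``cand[j] - j``.
    """
    t = np.frombuffer(read[::-1].encode(), dtype=np.uint8)
    p = np.frombuffer(barcode[::-1].encode(), dtype=np.uint8)
    n = len(t)
    j_idx = np.arange(n + 1)
    prev = np.zeros(n + 1)
    for i in range(1, len(p) + 1):
        sub = prev[:-1] + (t != p[i - 1])      # diagonal: match/mismatch
        cand = np.minimum(prev[1:] + 1, sub)   # vertical: skip barcode char
        w = np.concatenate(([float(i)], cand))
        prev = np.minimum.accumulate(w - j_idx) + j_idx
    # window of reversed read ending at j <=> window of read starting at n - j
    return prev[::-1][:n]


def find_barcode(read: str, barcode: str, max_dist: int = 1
                 ) -> tuple[int, int] | None:
    """Best-matching read offset for ``barcode`` within ``max_dist`` errors.

    Returns ``(position, distance)`` for the window with the globally
    minimal Levenshtein distance to the barcode (ties between
    equal-distance windows resolve to the leftmost offset), or ``None``
    when no window is within ``max_dist``.  An exact occurrence is always
    reported at its own offset with distance 0.
    """
    if not read or not barcode:
        raise ValueError("read and barcode must be non-empty")
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    dist = _window_min_distances(read.upper(), barcode.upper())
    s = int(dist.argmin())  # argmin takes the leftmost minimum
    if dist[s] > max_dist:
        return None
    return s, int(dist[s])


def assign_st(read: str, design: STDesign, max_dist: int = 1,
              search_revcomp: bool = True):
    """Assign a read to a template index, ``AMBIGUOUS``, or ``NOT_ST``.

    The universal barcode is searched in the read (and, by default, its
    reverse complement; the better-scoring orientation wins, forward on
    ties).  Reads without a universal hit are ``NOT_ST``.  Otherwise the
    oriented read is scanned against every specific barcode with edlib's
    infix mode; a unique minimal-distance hit within ``max_dist`` gives
    the template index, anything else is ``AMBIGUOUS``.
    """
    read = str(read).strip().upper()
    if not read:
        return NOT_ST
    uni = design.universal_barcode
    fwd = find_barcode(read, uni, max_dist)
    oriented = read
    if search_revcomp:
        rc = revcomp(read)
        rev = find_barcode(rc, uni, max_dist)
        if fwd is None and rev is not None:
            oriented = rc
        elif fwd is not None and rev is not None and rev[1] < fwd[1]:
            oriented = rc
        elif fwd is None and rev is None:
            return NOT_ST
    elif fwd is None:
        return NOT_ST

    best_dist = max_dist + 1
    best_idx = -1
    n_best = 0
    for i, bc in enumerate(design.specific_barcodes):
        d = edlib.align(bc, oriented, mode="HW", task="distance",
                        k=max_dist)["editDistance"]
        if d == -1:
            continue
        if d < best_dist:
            best_dist, best_idx, n_best = d, i, 1
        elif d == best_dist:
            n_best += 1
    if n_best == 1:
        return best_idx
    return AMBIGUOUS


def parse_fastq(source) -> Iterator[FastqRead]:
    """Yield records from a FASTQ path/handle (gzip by .gz suffix).

    Raises :class:`FastqFormatError` naming the record number on
    malformed input.
    """
    own = False
    if isinstance(source, (str, Path)):
        path = Path(source)
        handle: IO[str] = (
            io.TextIOWrapper(gzip.open(path, "rb"))
            if path.suffix == ".gz"
            else open(path)
        )
        own = True
    else:
        handle = source
    try:
        record = 0
        while True:
            header = handle.readline()
            if not header:
                break
            if header.strip() == "":
                continue
            record += 1
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual:
                raise FastqFormatError(f"truncated FASTQ record {record}")
            header, seq, plus, qual = (s.rstrip("\n") for s in (header, seq, plus, qual))
            if not header.startswith("@") or not plus.startswith("+"):
                raise FastqFormatError(f"malformed FASTQ record {record}")
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"sequence/quality length mismatch in record {record}"
                )
            yield FastqRead(header[1:].split()[0], seq, qual)
    finally:
        if own:
            handle.close()


def write_fastq(reads: Iterable[FastqRead], dest) -> None:
    own = False
    if isinstance(dest, (str, Path)):
        path = Path(dest)
        handle = (
            io.TextIOWrapper(gzip.open(path, "wb"))
            if path.suffix == ".gz"
            else open(path, "w")
        )
        own = True
    else:
        handle = dest
    try:
        for r in reads:
            handle.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")
    finally:
        if own:
            handle.close()


def demux_fastq(reads, design: STDesign, max_dist: int = 1,
                search_revcomp: bool = True, non_st_out=None
                ) -> tuple[np.ndarray, list[FastqRead], DemuxSummary]:
    """Partition reads into per-template ST counts and a non-ST stream.

    ``reads`` may be a FASTQ path/handle or an iterable of
    :class:`FastqRead`.  Every input read lands in exactly one tally; the
    non-ST reads pass through unmodified (written to ``non_st_out`` if
    given, and always returned) for downstream clonotype assembly.
    """
    if isinstance(reads, (str, Path)) or hasattr(reads, "readline"):
        reads = parse_fastq(reads)

    counts = np.zeros(design.n_templates, dtype=np.int64)
    non_st: list[FastqRead] = []
    total = flagged = ambiguous = 0
    for r in reads:
        total += 1
        result = assign_st(r.seq, design, max_dist=max_dist,
                           search_revcomp=search_revcomp)
        if result is NOT_ST:
            non_st.append(r)
        elif result is AMBIGUOUS:
            flagged += 1
            ambiguous += 1
        else:
            flagged += 1
            counts[result] += 1
    if non_st_out is not None:
        write_fastq(non_st, non_st_out)
    summary = DemuxSummary(
        n_reads_total=total,
        n_st_flagged=flagged,
        n_st_assigned=flagged - ambiguous,
        n_st_ambiguous=ambiguous,
        n_non_st=total - flagged,
        template_counts=counts,
    )
    return counts, non_st, summary
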