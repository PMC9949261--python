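"""Seeded generators for ST counts, biased repertoires, and FASTQ fixtures.

The generative model mirrors the measurement process: each primer pair i
amplifies with its own efficiency, so an equimolar template mix yields
counts with pair-specific means m_i; replicate-to-replicate variability is
negative binomial with a common dispersion d,

    E C = m,   var C = m + d m**2 ,

sampled as a gamma-Poisson mixture (gamma shape 1/d, scale m*d), which
reproduces that variance exactly; d = 0 short-circuits to Poisson.

Defaults emulate an ST-only sequencing batch: per-template grand mean 5000
reads, log-means spread uniformly over 4 natural-log units (~55-fold
between the weakest and strongest primer pair), d = 0.125.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .panel import (
    ClonotypeTable,
    DesignError,
    PanelError,
    PrimerPanel,
    STCountMatrix,
    STDesign,
)

__all__ = [
    "BiasModel",
    "sample_nb",
    "simulate_st_counts",
    "simulate_repertoire",
    "generate_fixture_fastq",
    "make_st_design",
    "FastqRead",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class FastqRead(NamedTuple):
    """One FASTQ record (quality is a constant placeholder)."""

    id: str
    seq: str
    qual: str


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_nb(mean, dispersion: float, size, rng) -> np.ndarray:
    """Draw NB counts with E=mean, var = mean + dispersion*mean**2."""
    rng = _as_rng(rng)
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("NB mean must be strictly positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.broadcast_to(mean * dispersion, size), size=size)
    return rng.poisson(lam)


@dataclass
class BiasModel:
    """Per-pair amplification efficiencies plus NB dispersion.

    ``st_means`` are the separable (V x J) efficiencies in pair-index
    order; an optional ``interaction`` matrix (|V| x |J|, multiplicative,
    geometric-mean 1 per row/column for identifiability in spirit) layers
    pair-specific dependence on top of the separable effects.
    """

    panel: PrimerPanel
    st_means: np.ndarray
    dispersion: float = 0.125
    interaction: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.st_means, dtype=float)
        if m.shape != (self.panel.n_pairs,):
            raise PanelError(
                f"st_means must have length {self.panel.n_pairs}, got {m.shape}"
            )
        if np.any(m <= 0):
            raise ValueError("all ST means must be strictly positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        self.st_means = m
        if self.interaction is not None:
            inter = np.asarray(self.interaction, dtype=float)
            if inter.shape != (self.panel.n_v, self.panel.n_j):
                raise PanelError("interaction must be |V| x |J|")
            if np.any(inter <= 0):
                raise ValueError("interaction factors must be positive")
            self.interaction = inter

    @property
    def effective_means(self) -> np.ndarray:
        """st_means with the interaction layer applied."""
        if self.interaction is None:
            return self.st_means
        return self.st_means * self.interaction.reshape(-1)

    @classmethod
    def separable(
        cls,
        panel: PrimerPanel,
        seed,
        mean_level: float = 5000.0,
        log_spread: float = 4.0,
        dispersion: float = 0.125,
        interaction: np.ndarray | None = None,
    ) -> "BiasModel":
        """Random separable bias: log-mean = V effect + J effect.

        V and J effects are uniform, scaled so the total log-mean range is
        ``log_spread`` natural-log units; means are recentred so their
        arithmetic mean equals ``mean_level``.
        """
        rng = _as_rng(seed)
        v_eff = rng.uniform(-0.5, 0.5, size=panel.n_v) * log_spread
        j_eff = rng.uniform(-0.5, 0.5, size=panel.n_j) * log_spread
        # each of the two uniform(-s/2, s/2) effects contributes half the
        # spread so the summed range is ~log_spread
        log_m = 0.5 * (v_eff[:, None] + j_eff[None, :]).reshape(-1)
        m = np.exp(log_m)
        m *= mean_level / m.mean()
        return cls(panel=panel, st_means=m, dispersion=dispersion,
                   interaction=interaction)

    @classmethod
    def uniform(cls, panel: PrimerPanel, mean_level: float = 5000.0,
                dispersion: float = 0.125) -> "BiasModel":
        """Bias-free model: every primer pair has the same mean."""
        return cls(panel=panel,
                   st_means=np.full(panel.n_pairs, float(mean_level)),
                   dispersion=dispersion)


def simulate_st_counts(model: BiasModel, n_samples: int, seed,
                       batch_id: str = "sim",
                       concentration: float | None = None) -> STCountMatrix:
    """Draw an ST count matrix: C_ij ~ NB(m_i, d), independent over (i, j)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _as_rng(seed)
    m = model.effective_means
    if concentration is not None:
        m = m * concentration
    counts = sample_nb(m[:, None], model.dispersion,
                       size=(model.panel.n_pairs, n_samples), rng=rng)
    return STCountMatrix(panel=model.panel, counts=counts,
                         sample_ids=tuple(f"{batch_id}_s{j + 1}" for j in range(n_samples)),
                         batch_id=batch_id, concentration=concentration)


def _random_cdr3(rng: np.random.Generator, length: int = 36) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def simulate_repertoire(
    clone_freqs: Sequence[float],
    vj_assignment: Sequence[int],
    model: BiasModel,
    depth: int,
    seed,
    drop_unobserved: bool = True,
) -> ClonotypeTable:
    """Sample a clonotype table distorted by amplification bias.

    Clone c with true frequency f_c on primer pair p(c) has expected raw
    count ``depth * f_c m_{p(c)} / sum_c f_c m_{p(c)}`` (so total depth is
    conserved in expectation), with NB noise at the model's dispersion.
    Clones sampled at zero count are dropped by default, mirroring
    assembler output in which undetected clones are simply absent.
    """
    f = np.asarray(clone_freqs, dtype=float)
    if f.ndim != 1 or len(f) == 0:
        raise ValueError("clone_freqs must be a non-empty 1-D vector")
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("clone_freqs must be non-negative and sum to 1 (tol 1e-9)")
    pair_idx = np.asarray(vj_assignment, dtype=np.int64)
    if pair_idx.shape != f.shape:
        raise ValueError("vj_assignment must match clone_freqs in length")
    if np.any(pair_idx < 0) or np.any(pair_idx >= model.panel.n_pairs):
        raise PanelError("vj_assignment contains out-of-range pair indices")
    if depth <= 0:
        raise ValueError("depth must be positive")

    rng = _as_rng(seed)
    m = model.effective_means[pair_idx]
    w = f * m
    mu = depth * w / w.sum()
    raw = np.zeros(len(f), dtype=np.int64)
    pos = mu > 0
    raw[pos] = sample_nb(mu[pos], model.dispersion, size=int(pos.sum()), rng=rng)

    records = []
    seen: set[str] = set()
    for c in range(len(f)):
        cdr3 = _random_cdr3(rng)
        while cdr3 in seen:
            cdr3 = _random_cdr3(rng)
        seen.add(cdr3)
        v, j = model.panel.pair_name(int(pair_idx[c]))
        records.append({
            "clone_id": f"clone{c + 1}",
            "cdr3_nt": cdr3,
            "v_name": v,
            "j_name": j,
            "raw_count": int(raw[c]),
        })
    df = pd.DataFrame.from_records(records)
    if drop_unobserved:
        df = df[df["raw_count"] > 0].reset_index(drop=True)
    return ClonotypeTable(df, panel=model.panel)


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < error_rate
    n = int(hit.sum())
    if n:
        # substitute with a different base
        for pos in np.nonzero(hit)[0]:
            choices = _BASES[_BASES != arr[pos]]
            arr[pos] = rng.choice(choices)
    return arr.tobytes().decode(), n


def generate_fixture_fastq(
    design: STDesign,
    st_counts: Sequence[int],
    clonotype_reads: Sequence[str] = (),
    error_rate: float = 0.0,
    seed=0,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Build merged-read fixtures with a per-read truth table.

    Each ST read embeds the universal barcode immediately followed by the
    template's specific barcode at a randomized offset, padded with random
    sequence to ``design.template_length``.  Clonotype reads are emitted
    as given.  Uniform per-base substitutions are applied at
    ``error_rate``; the truth table records each read's origin so demux
    output can be scored exactly.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    st_counts = np.asarray(st_counts, dtype=np.int64)
    if st_counts.shape != (design.n_templates,):
        raise PanelError(
            f"st_counts must have length {design.n_templates}, got {st_counts.shape}"
        )
    if np.any(st_counts < 0):
        raise ValueError("st_counts must be non-negative")

    rng = _as_rng(seed)
    uni = design.universal_barcode
    reads: list[FastqRead] = []
    truth_rows: list[dict] = []

    for i in range(design.n_templates):
        spec = design.specific_barcodes[i]
        core = uni + spec
        pad_total = design.template_length - len(core)
        for k in range(int(st_counts[i])):
            left = int(rng.integers(0, pad_total + 1))
            seq = (
                bytes(_BASES[rng.integers(0, 4, size=left)]).decode()
                + core
                + bytes(_BASES[rng.integers(0, 4, size=pad_total - left)]).decode()
            )
            seq, n_err = _mutate(seq, error_rate, rng)
            rid = f"st{i}_{k}"
            reads.append(FastqRead(rid, seq, "I" * len(seq)))
            truth_rows.append({"read_id": rid, "kind": "st",
                               "template_index": i, "n_errors": n_err})

    for k, seq in enumerate(clonotype_reads):
        seq = str(seq).strip().upper()
        seq, n_err = _mutate(seq, error_rate, rng)
        rid = f"clone_read{k}"
        reads.append(FastqRead(rid, seq, "I" * len(seq)))
        truth_rows.append({"read_id": rid, "kind": "clonotype",
                           "template_index": -1, "n_errors": n_err})

    order = rng.permutation(len(reads))
    reads = [reads[o] for o in order]
    truth = pd.DataFrame.from_records([truth_rows[o] for o in order])
    if truth.empty:
        truth = pd.DataFrame(columns=["read_id", "kind", "template_index", "n_errors"])
    return reads, truth


def make_st_design(
    panel: PrimerPanel,
    seed,
    specific_length: int = 16,
    universal_length: int = 9,
    template_length: int = 200,
    min_dist: int = 3,
    max_tries: int = 200,
) -> STDesign:
    """Random barcode design satisfying the distance invariants.

    Rejection-samples specific barcodes until all are at pairwise edit
    distance >= ``min_dist`` and none contains a window within
    ``min_dist - 1`` of the universal barcode.
    """
    import edlib

    rng = _as_rng(seed)
    k = min_dist - 1

    def rand_bc(length: int) -> str:
        return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()

    universal = rand_bc(universal_length)
    accepted: list[str] = []
    for _ in range(panel.n_pairs):
        for _try in range(max_tries):
            cand = rand_bc(specific_length)
            if edlib.align(universal, cand, mode="HW", task="distance",
                           k=k)["editDistance"] != -1:
                continue
            if any(
                edlib.align(cand, prev, task="distance", k=k)["editDistance"] != -1
                for prev in accepted
            ):
                continue
            accepted.append(cand)
            break
        else:
            raise DesignError(
                "could not sample barcodes satisfying the distance "
                "constraints; try longer barcodes or a smaller panel"
            )
    return STDesign(panel=panel, universal_barcode=universal,
                    specific_barcodes=tuple(accepted),
                    template_length=template_length)
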