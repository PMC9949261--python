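"""Scaling factors and their application to primer-pair and clonotype counts.

Two flavours of per-primer-pair scaling factor, both averaging to 1:

* batch-mean: ``SF_i = C_i. / C..`` — the template's batch mean over the
  batch mean of all template means; distribution-free.
* NB-mean: ``m_i / m_bar`` from a fitted NB panel (or pooled combined
  estimates) — identical to batch-mean factors on a single batch, since
  the NB mean MLE *is* the arithmetic mean, but usable on samples
  sequenced without spike-ins.

Normalization divides each primer-pair total by its factor,
``C'_i = C_i / SF_i``, and redistributes within a pair proportionally:
a clonotype holding proportion p of its pair's total keeps proportion p
of the normalized total (equivalently, every clone count is divided by
its pair's factor).  Normalized counts are real-valued, never re-rounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .nb import NBPanelFit
from .panel import ClonotypeTable, PanelError, PrimerPanel, STCountMatrix

__all__ = [
    "ScalingFactorSet",
    "SpikeInNormalizer",
    "batch_scaling_factors",
    "nb_scaling_factors",
    "normalize_primer_totals",
    "normalize_clonotypes",
    "spread_report",
    "SpreadReport",
]


@dataclass
class ScalingFactorSet:
    """Per-primer-pair scaling factors with unit mean.

    Templates that yielded no reads have *no* factor (NaN), not a zero:
    normalizing a pair that carries clonotype counts but lacks a factor
    is a hard error, never a silent pass-through.
    """

    panel: PrimerPanel
    factors: np.ndarray
    kind: str = "batch_mean"  # batch_mean | nb_mean
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if f.shape != (self.panel.n_pairs,):
            raise PanelError(
                f"factors must have length {self.panel.n_pairs}, got {f.shape}"
            )
        ok = np.isfinite(f)
        if not ok.any():
            raise PanelError("no finite scaling factors")
        if np.any(f[ok] <= 0):
            raise PanelError("scaling factors must be strictly positive")
        if self.kind not in ("batch_mean", "nb_mean"):
            raise PanelError(f"unknown factor kind {self.kind!r}")
        self.factors = f

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.factors)

    def to_frame(self) -> pd.DataFrame:
        out = self.panel.pair_frame()
        out["factor"] = self.factors
        out["kind"] = self.kind
        return out


class SpikeInNormalizer(TransformerMixin, BaseEstimator):
    """Amplification-bias normalizer in scikit-learn transformer form.

    ``fit`` learns per-template scaling factors from spike-in counts
    ``X`` of shape ``(n_samples, n_templates)``: each column mean divided
    by the grand mean of the (non-zero) column means.  ``transform``
    divides count columns by their factor — applicable to the spike-in
    matrix itself or to primer-pair totals laid out on the same template
    axis.  ``batch_mean`` and ``nb_mean`` factors coincide numerically on
    a single batch (the NB mean MLE is the arithmetic mean); the ``kind``
    parameter records which interpretation is intended.

    Attributes
    ----------
    scaling_factors_ : ndarray of shape (n_templates,)
        Unit-mean factors; NaN for all-zero columns.
    """

    def __init__(self, kind: str = "nb_mean"):
        self.kind = kind

    def fit(self, X, y=None):
        if self.kind not in ("batch_mean", "nb_mean"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        X = check_array(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("counts must be non-negative")
        means = X.mean(axis=0)
        nonzero = means > 0
        if not nonzero.any():
            raise ValueError("all-zero count matrix")
        if not nonzero.all():
            warnings.warn(
                f"{int((~nonzero).sum())} all-zero template column(s) "
                "receive no scaling factor", stacklevel=2,
            )
        grand = means[nonzero].mean()
        sf = np.where(nonzero, means / grand, np.nan)
        self.n_features_in_ = X.shape[1]
        self.means_ = means
        self.scaling_factors_ = sf
        return self

    def transform(self, X):
        check_is_fitted(self, "scaling_factors_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of templates than fit")
        sf = self.scaling_factors_
        missing = ~np.isfinite(sf)
        if missing.any() and np.any(X[:, missing] != 0):
            raise ValueError(
                "non-zero counts on templates without a scaling factor"
            )
        out = np.array(X, dtype=float)
        cols = ~missing
        out[:, cols] = out[:, cols] / sf[cols]
        out[:, missing] = 0.0
        return out

    def inverse_transform(self, X):
        check_is_fitted(self, "scaling_factors_")
        X = check_array(X, dtype=float)
        sf = np.where(np.isfinite(self.scaling_factors_),
                      self.scaling_factors_, 1.0)
        return X * sf


def batch_scaling_factors(matrix: STCountMatrix) -> ScalingFactorSet:
    """Batch-mean factors SF_i = C_i. / C.. from one ST count matrix."""
    est = SpikeInNormalizer(kind="batch_mean").fit(matrix.counts.T)
    return ScalingFactorSet(panel=matrix.panel, factors=est.scaling_factors_,
                            kind="batch_mean", provenance=(matrix.batch_id,))


def nb_scaling_factors(fit: NBPanelFit | np.ndarray,
                       panel: PrimerPanel | None = None) -> ScalingFactorSet:
    """NB-mean factors m_i/m_bar from a panel fit or a combined-means vector."""
    if isinstance(fit, NBPanelFit):
        return ScalingFactorSet(panel=fit.panel, factors=fit.relative_means,
                                kind="nb_mean", provenance=fit.batch_ids)
    if panel is None:
        raise PanelError("panel required when passing a raw means vector")
    means = np.asarray(fit, dtype=float)
    if means.shape != (panel.n_pairs,):
        raise PanelError("means vector length does not match the panel")
    nonzero = np.isfinite(means) & (means > 0)
    if not nonzero.any():
        raise PanelError("no positive means")
    rel = np.where(nonzero, means / means[nonzero].mean(), np.nan)
    return ScalingFactorSet(panel=panel, factors=rel, kind="nb_mean",
                            provenance=("combined",))


def normalize_primer_totals(totals: Sequence[float], sf: ScalingFactorSet
                            ) -> np.ndarray:
    """C'_i = C_i / SF_i; zero totals stay zero, missing factors hard-error."""
    totals = np.asarray(totals, dtype=float)
    if totals.shape != (sf.panel.n_pairs,):
        raise PanelError("totals length does not match the panel")
    bad = sf.missing & (totals != 0)
    if bad.any():
        names = [sf.panel.pair_name(i) for i in np.nonzero(bad)[0][:10]]
        raise PanelError(
            f"non-zero totals on primer pairs without a scaling factor: {names}"
        )
    out = np.zeros_like(totals)
    ok = ~sf.missing
    out[ok] = totals[ok] / sf.factors[ok]
    return out


def normalize_clonotypes(table: ClonotypeTable, sf: ScalingFactorSet
                         ) -> ClonotypeTable:
    """Fill ``normalized_count`` by proportional within-pair redistribution.

    A clone holding proportion p of its primer-pair total C_i is assigned
    p * C'_i = raw / SF_i, so within-pair proportions are exactly
    preserved while pairs shift relative to each other by factor ratios.
    """
    idx = table.pair_indices(sf.panel)
    if len(table) == 0:
        return table
    factors = sf.factors[idx]
    raw = table.frame["raw_count"].to_numpy(dtype=float)
    bad = ~np.isfinite(factors) & (raw != 0)
    if bad.any():
        rows = np.nonzero(bad)[0][:10].tolist()
        raise PanelError(
            f"clonotype rows on primer pairs without a scaling factor: {rows}"
        )
    normalized = np.where(np.isfinite(factors), raw / factors, 0.0)
    return table.with_normalized(normalized)


@dataclass
class SpreadReport:
    """Within-sample template-to-template spread before/after normalization.

    ``per_sample`` has one row per sample with the Q3/Q1 fold ratio
    (type-7 quantiles) and CV across templates, raw and normalized.  The
    IQR contrast compares (on the natural-log relative-frequency scale)
    the median across samples of template-to-template IQR — amplification
    bias — against the median across templates of sample-to-sample IQR —
    replicate noise; equimolar spike-ins with strong primer bias give a
    large ratio.
    """

    per_sample: pd.DataFrame
    st_to_st_iqr: float
    sample_to_sample_iqr: float

    @property
    def iqr_contrast(self) -> float:
        return self.st_to_st_iqr / self.sample_to_sample_iqr


def _qratio(x: np.ndarray) -> np.ndarray:
    q1, q3 = np.nanquantile(x, [0.25, 0.75], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return q3 / q1


def spread_report(matrix: STCountMatrix, sf: ScalingFactorSet) -> SpreadReport:
    """Per-sample spread statistics of ST counts, raw vs normalized."""
    if sf.panel != matrix.panel:
        raise PanelError("factors and matrix must share the panel")
    raw = matrix.counts.astype(float)
    norm = np.empty_like(raw)
    for j in range(matrix.n_samples):
        norm[:, j] = normalize_primer_totals(raw[:, j], sf)
    keep = ~sf.missing
    raw_k, norm_k = raw[keep], norm[keep]
    per_sample = pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "qratio_raw": _qratio(raw_k),
        "qratio_normalized": _qratio(norm_k),
        "cv_raw": raw_k.std(axis=0, ddof=1) / raw_k.mean(axis=0),
        "cv_normalized": norm_k.std(axis=0, ddof=1) / norm_k.mean(axis=0),
    })
    # Fig-1B-style contrast on log relative frequencies (zeros masked)
    freqs = raw / raw.sum(axis=0, keepdims=True)
    logf = np.full_like(freqs, np.nan)
    np.log(freqs, out=logf, where=freqs > 0)
    q1s, q3s = np.nanquantile(logf[keep], [0.25, 0.75], axis=0)
    st_to_st = float(np.median(q3s - q1s))
    q1t, q3t = np.nanquantile(logf[keep], [0.25, 0.75], axis=1)
    sample_to_sample = float(np.median(q3t - q1t))
    return SpreadReport(per_sample=per_sample, st_to_st_iqr=st_to_st,
                        sample_to_sample_iqr=sample_to_sample)
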