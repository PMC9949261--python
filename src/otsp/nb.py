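"""Negative-binomial modeling of synthetic-template counts.

Replicate counts for a fixed template i across a batch are modeled as
NB(m_i, d) with mean m_i and a common dispersion d, in the mean-dispersion
parameterization

    E C = m ,   var C = m + d m**2 ,

so d = 0 is Poisson and overdispersion is measured relative to Poisson.
The MLE of m_i is the arithmetic mean of the template's counts; d is
estimated per template by maximizing the profile log-likelihood in d with
m fixed at its MLE, and the panel-wide common dispersion is the *median*
of the per-template estimates.  The template-specific means, rescaled by
their average m_bar, are exactly the NB-mean scaling factors m_i/m_bar
used for normalization (see :mod:`otsp.normalize`).

Libraries parameterizing the NB by a shape r are related by r = 1/d; that
conversion stays behind this module's contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .panel import PanelError, PrimerPanel, STCountMatrix
from .simulate import sample_nb, _as_rng

__all__ = [
    "NBFitResult",
    "NBPanelFit",
    "NegativeBinomialPanelModel",
    "fit_nb_single",
    "fit_panel",
    "mean_variance_table",
    "pool_batches",
    "independence_spread_bound",
    "IndependenceBound",
    "scaling_factor_stability",
    "nb_loglik",
]

_D_MAX = 10.0
_D_TOL = 1e-8


def nb_loglik(counts: np.ndarray, m: float, d: float) -> float:
    """NB log-likelihood at mean m, dispersion d (d = 0 -> Poisson)."""
    counts = np.asarray(counts, dtype=float)
    if m <= 0:
        raise ValueError("mean must be positive")
    if d < 0:
        raise ValueError("dispersion must be >= 0")
    if d == 0:
        return float(np.sum(counts * np.log(m) - m - gammaln(counts + 1)))
    r = 1.0 / d
    return float(np.sum(
        gammaln(counts + r) - gammaln(r) - gammaln(counts + 1)
        + r * np.log(r / (r + m)) + counts * np.log(m / (r + m))
    ))


def _fit_dispersion(counts: np.ndarray, m: float,
                    d_max: float = _D_MAX, tol: float = _D_TOL
                    ) -> tuple[float, float]:
    """Profile-likelihood MLE of d given m; returns (d_hat, loglik).

    The profile likelihood is maximized on (0, d_max] with a bounded
    scalar optimizer; under-dispersed data clip to the Poisson boundary
    d = 0.
    """
    res = minimize_scalar(
        lambda d: -nb_loglik(counts, m, d),
        bounds=(tol, d_max), method="bounded",
        options={"xatol": tol},
    )
    ll_poisson = nb_loglik(counts, m, 0.0)
    if ll_poisson >= -res.fun - 1e-12:
        return 0.0, ll_poisson
    return float(res.x), float(-res.fun)


@dataclass(frozen=True)
class NBFitResult:
    """Single-template fit: m_hat is exactly the arithmetic mean."""

    m_hat: float
    d_hat: float
    n: int
    loglik: float


def fit_nb_single(counts: Sequence[int], d_max: float = _D_MAX,
                  tol: float = _D_TOL) -> NBFitResult:
    """ML fit of NB(m, d) to one template's replicate counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("need a 1-D vector of at least 2 counts")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    m = float(counts.mean())
    if m == 0:
        raise ValueError("degenerate input: all counts are zero")
    d_hat, ll = _fit_dispersion(counts, m, d_max=d_max, tol=tol)
    return NBFitResult(m_hat=m, d_hat=d_hat, n=len(counts), loglik=ll)


class NegativeBinomialPanelModel(BaseEstimator):
    """Per-template NB fits over a panel of spike-in templates.

    scikit-learn-style estimator: ``X`` has shape ``(n_samples,
    n_templates)`` — rows are sequencing replicates, columns are
    templates.  Each column gets its own mean (its arithmetic average,
    the NB MLE) and profile-ML dispersion; the panel-wide common
    dispersion is the median of the per-column estimates.

    Parameters
    ----------
    d_max : float
        Upper bound of the dispersion search interval.
    tol : float
        Absolute tolerance of the bounded scalar optimizer.

    Attributes
    ----------
    means_ : ndarray of shape (n_templates,)
        Per-template mean estimates (column means).
    dispersions_ : ndarray of shape (n_templates,)
        Per-template dispersion MLEs; NaN for all-zero columns.
    common_dispersion_ : float
        Median of the per-template dispersions (all-zero columns excluded).
    mean_of_means_ : float
        m_bar, the average of the per-template means over non-zero columns.
    scaling_factors_ : ndarray of shape (n_templates,)
        m_i / m_bar; NaN for all-zero columns (no factor, not zero).
    """

    def __init__(self, d_max: float = _D_MAX, tol: float = _D_TOL):
        self.d_max = d_max
        self.tol = tol

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        if np.any(X < 0):
            raise ValueError("counts must be non-negative")
        n_samples, n_templates = X.shape
        means = X.mean(axis=0)
        disps = np.full(n_templates, np.nan)
        logliks = np.full(n_templates, np.nan)
        zero = means == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} all-zero template column(s) excluded "
                "from the dispersion median and from m_bar",
                stacklevel=2,
            )
        for i in np.nonzero(~zero)[0]:
            disps[i], logliks[i] = _fit_dispersion(
                X[:, i], means[i], d_max=self.d_max, tol=self.tol
            )
        if zero.all():
            raise ValueError("all template columns are zero")
        self.n_features_in_ = n_templates
        self.n_samples_ = n_samples
        self.means_ = means
        self.dispersions_ = disps
        self.logliks_ = logliks
        self.common_dispersion_ = float(np.median(disps[~zero]))
        self.mean_of_means_ = float(means[~zero].mean())
        sf = means / self.mean_of_means_
        sf[zero] = np.nan
        self.scaling_factors_ = sf
        return self

    def score(self, X, y=None) -> float:
        """Mean per-observation log-likelihood at the fitted parameters."""
        check_is_fitted(self, "means_")
        X = check_array(X, dtype=float)
        total = 0.0
        n = 0
        for i in range(X.shape[1]):
            if np.isnan(self.dispersions_[i]):
                continue
            total += nb_loglik(X[:, i], self.means_[i], self.common_dispersion_)
            n += X.shape[0]
        return total / max(n, 1)


@dataclass
class NBPanelFit:
    """Panel-level NB fit in pair-index order (domain wrapper).

    ``means`` holds m_hat_i (0 for excluded all-zero templates, which
    carry no scaling factor), ``dispersions`` holds d_hat_i (NaN where
    excluded), ``common_dispersion`` their median, and ``m_bar`` the mean
    of the non-excluded means.
    """

    panel: PrimerPanel
    means: np.ndarray
    dispersions: np.ndarray
    common_dispersion: float
    m_bar: float
    n_samples: int
    batch_ids: tuple[str, ...] = ()
    logliks: np.ndarray | None = None

    @property
    def excluded(self) -> np.ndarray:
        """Boolean mask of all-zero templates (no mean, no factor)."""
        return self.means == 0

    @property
    def relative_means(self) -> np.ndarray:
        """m_i / m_bar; NaN for excluded templates."""
        rel = self.means / self.m_bar
        rel[self.excluded] = np.nan
        return rel

    def to_frame(self) -> pd.DataFrame:
        out = self.panel.pair_frame()
        out["m_hat"] = self.means
        out["d_hat"] = self.dispersions
        return out


def fit_panel(matrix: STCountMatrix, d_max: float = _D_MAX,
              tol: float = _D_TOL) -> NBPanelFit:
    """Fit one NB per template row of an ST count matrix."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to fit dispersions")
    est = NegativeBinomialPanelModel(d_max=d_max, tol=tol).fit(matrix.counts.T)
    return NBPanelFit(
        panel=matrix.panel,
        means=est.means_,
        dispersions=est.dispersions_,
        common_dispersion=est.common_dispersion_,
        m_bar=est.mean_of_means_,
        n_samples=matrix.n_samples,
        batch_ids=(matrix.batch_id,),
        logliks=est.logliks_,
    )


def mean_variance_table(matrix: STCountMatrix, d: float) -> pd.DataFrame:
    """Empirical mean/variance per template with the model line v = m + d m^2.

    Sorted by the empirical mean; plot on log-log scales, where the model
    line approaches slope 2 for large m (log v ~ log d + 2 log m).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples for a variance")
    m_hat = matrix.counts.mean(axis=1)
    v_hat = matrix.counts.var(axis=1, ddof=1)
    out = matrix.panel.pair_frame()
    out["m_hat"] = m_hat
    out["v_hat"] = v_hat
    out["v_model"] = m_hat + d * m_hat**2
    return out.sort_values("m_hat", kind="stable").reset_index(drop=True)


def pool_batches(batches: Sequence[STCountMatrix]) -> np.ndarray:
    """Combined relative mean estimates across batches ("combined estimates").

    Each batch's per-template mean vector is divided by its own grand
    mean — removing the batch's overall spike-in concentration — then the
    relative vectors are averaged with weights proportional to batch
    sample counts and rescaled to unit mean.  The result is the pooled
    m_i/m_bar scaling-factor vector; a single batch reduces to that
    batch's own relative means, and multiplying any batch by a positive
    constant leaves the output unchanged.
    """
    if not batches:
        raise ValueError("need at least one batch")
    panel = batches[0].panel
    for b in batches[1:]:
        if b.panel != panel:
            raise PanelError("all batches must share the same primer panel")
    acc = np.zeros(panel.n_pairs)
    total_w = 0.0
    for b in batches:
        means = b.row_means()
        grand = means.mean()
        if grand <= 0:
            raise ValueError(f"batch {b.batch_id!r} has zero grand mean")
        acc += b.n_samples * (means / grand)
        total_w += b.n_samples
    combined = acc / total_w
    return combined / combined.mean()


@dataclass(frozen=True)
class IndependenceBound:
    """Monte-Carlo floor on post-normalization spread under independence.

    Per replicate, an n_st x n_samples matrix of *independent* equimolar
    NB(m, d) counts is normalized with NB-mean factors estimated from the
    replicate itself; ``qratio`` and ``cv`` hold, per replicate, the
    median across samples of the within-sample Q3/Q1 fold and coefficient
    of variation.  Observed spreads below this floor indicate dependence
    between templates.
    """

    qratio: np.ndarray
    cv: np.ndarray

    @property
    def qratio_mean(self) -> float:
        return float(self.qratio.mean())

    @property
    def qratio_se(self) -> float:
        return float(self.qratio.std(ddof=1) / np.sqrt(len(self.qratio)))

    @property
    def cv_mean(self) -> float:
        return float(self.cv.mean())

    @property
    def cv_se(self) -> float:
        return float(self.cv.std(ddof=1) / np.sqrt(len(self.cv)))

    def summary(self) -> dict[str, float]:
        return {
            "qratio_mean": self.qratio_mean, "qratio_se": self.qratio_se,
            "cv_mean": self.cv_mean, "cv_se": self.cv_se,
            "n_rep": len(self.qratio),
        }


def independence_spread_bound(m: float, d: float, n_st: int, n_samples: int,
                              n_rep: int, seed) -> IndependenceBound:
    """Simulate the spread floor for independent equimolar NB templates."""
    if m <= 0 or n_st < 2 or n_samples < 2 or n_rep < 2:
        raise ValueError("m must be positive and n_st, n_samples, n_rep >= 2")
    if d < 0:
        raise ValueError("dispersion must be >= 0")
    rng = _as_rng(seed)
    qratio = np.empty(n_rep)
    cv = np.empty(n_rep)
    for r in range(n_rep):
        X = sample_nb(m, d, size=(n_st, n_samples), rng=rng).astype(float)
        means = X.mean(axis=1)
        grand = means.mean()
        factors = np.where(means > 0, means / grand, np.nan)
        norm = X / factors[:, None]
        q1, q3 = np.nanquantile(norm, [0.25, 0.75], axis=0)
        with np.errstate(divide="ignore"):
            qratio[r] = float(np.median(q3 / q1))
        cv[r] = float(np.median(np.nanstd(norm, axis=0, ddof=1)
                                / np.nanmean(norm, axis=0)))
    return IndependenceBound(qratio=qratio, cv=cv)


def scaling_factor_stability(fit_a: NBPanelFit, fit_b: NBPanelFit) -> float:
    """Pearson correlation of log relative means between two panel fits.

    Computed on the natural-log scale, so it is invariant to overall
    spike-in concentration differences between the experiments.
    Templates with zero mean in either fit are excluded with a warning.
    """
    if fit_a.panel != fit_b.panel:
        raise PanelError("fits must share the same primer panel")
    ok = ~(fit_a.excluded | fit_b.excluded)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} template(s) with zero mean excluded from the "
            "stability correlation", stacklevel=2,
        )
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared non-zero templates")
    la = np.log(fit_a.relative_means[ok])
    lb = np.log(fit_b.relative_means[ok])
    return float(np.corrcoef(la, lb)[0, 1])
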