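"""Hybrid-index concordance: per-locus deviation from equal introgression.

Each individual's hybrid index HI is the fraction of its scored allele
copies derived from the klauberi taxon (diploid loci contribute 2 copies,
the mitochondrial marker 1). Partitioning the copies by locus gives
individual x locus hybrid indices HI_loc; if every locus introgresses
equally these scatter around the diagonal HI_loc = HI. Barton's
concordance model expresses systematic deviation as

    HI_loc = HI + He * [alpha + beta * (2 HI - 1)],    He = 2 HI (1 - HI)

where alpha (directionality) shifts a locus toward one genetic background
and beta (abruptness) makes its transition steeper or shallower than the
genome-wide expectation. Both vanish at HI = 0 and HI = 1, so parental
individuals carry no information about them.

Fitting is by binomial maximum likelihood on the per-individual K-copy
counts at the focal locus, with the predicted proportion clamped into
(0, 1); a likelihood-ratio G-test against alpha = beta = 0 (df = 2) gives
the concordance verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cline import LRTResult
from .io import GenotypeDataset

PRED_CLAMP = 1e-6


def concordance_prediction(hi, alpha: float, beta: float):
    """Expected per-locus hybrid index given genome-wide HI and (alpha, beta)."""
    hi = np.asarray(hi, dtype=float)
    he = 2.0 * hi * (1.0 - hi)
    return np.clip(hi + he * (alpha + beta * (2.0 * hi - 1.0)), PRED_CLAMP, 1.0 - PRED_CLAMP)


def hybrid_index(
    dataset: GenotypeDataset, loci: str | list[str] = "all"
) -> pd.DataFrame:
    """Per-individual hybrid index table.

    Returns columns ``id``, ``HI``, ``copies`` plus ``HI_<locus>`` /
    ``k_<locus>`` / ``n_<locus>`` per selected locus. Missing loci are
    excluded from numerator and denominator; individuals with no scored
    copies get HI = NaN.
    """
    if isinstance(loci, str):
        if loci == "all":
            selected = [l.name for l in dataset.loci]
        elif loci == "nuclear":
            selected = [l.name for l in dataset.nuclear_loci]
        else:
            selected = [loci]
    else:
        selected = list(loci)
    by_name = {l.name: l for l in dataset.loci}
    unknown = [s for s in selected if s not in by_name]
    if unknown:
        raise ValueError(f"unknown loci {unknown}")

    out = pd.DataFrame({"id": dataset.table["id"]})
    k_total = np.zeros(len(out))
    n_total = np.zeros(len(out))
    for name in selected:
        loc = by_name[name]
        if loc.role == "mitochondrial":
            k = dataset.mito_k().to_numpy()
            n = np.where(np.isnan(k), 0.0, 1.0)
        else:
            k = dataset.table[name].astype(float).to_numpy()
            n = np.where(np.isnan(k), 0.0, 2.0)
        k = np.nan_to_num(k)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"HI_{name}"] = np.where(n > 0, k / np.maximum(n, 1), np.nan)
        out[f"k_{name}"] = np.where(n > 0, k, np.nan)
        out[f"n_{name}"] = np.where(n > 0, n, np.nan)
        k_total += k
        n_total += n
    with np.errstate(invalid="ignore", divide="ignore"):
        out["HI"] = np.where(n_total > 0, k_total / np.maximum(n_total, 1), np.nan)
    out["copies"] = n_total
    return out


class ConcordanceModel(BaseEstimator):
    """Binomial-ML fit of Barton's (alpha, beta) concordance parameters.

    ``fit(X, y, sample_weight)``: X is the genome-wide hybrid index (one
    feature), y the K-copy count at the focal locus, ``sample_weight`` the
    copies scored there (2 nuclear, 1 mitochondrial).
    """

    def __init__(self, min_individuals: int = 10):
        self.min_individuals = min_individuals

    def _nll(self, params, hi, k, n):
        p = concordance_prediction(hi, *params)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    def fit(self, X, y=None, sample_weight=None):
        hi = np.asarray(X, dtype=float)
        if hi.ndim == 2:
            hi = hi[:, 0]
        k = np.asarray(y, dtype=float).ravel()
        n = (
            np.full(hi.size, 2.0)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float).ravel()
        )
        ok = ~(np.isnan(hi) | np.isnan(k) | np.isnan(n))
        hi, k, n = hi[ok], k[ok], n[ok]
        if hi.size < self.min_individuals:
            raise ValueError(
                f"need >= {self.min_individuals} individuals with HI and the locus scored"
            )
        if np.allclose(k, 0) or np.allclose(k, n):
            raise ValueError("focal locus is monomorphic in the sample")

        best = None
        for start in ((0.0, 0.0), (0.5, -1.0), (-0.5, 1.0), (0.0, 1.0)):
            res = optimize.minimize(
                self._nll,
                x0=start,
                args=(hi, k, n),
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("concordance optimizer failed to converge")
        self.alpha_ = float(best.x[0])
        self.beta_ = float(best.x[1])
        self.loglik_ = -float(best.fun)
        self.null_loglik_ = -self._nll((0.0, 0.0), hi, k, n)
        G = max(2.0 * (self.loglik_ - self.null_loglik_), 0.0)
        self.lrt_ = LRTResult(G=G, df=2, p=float(stats.chi2.sf(G, 2)))
        self.n_individuals_ = int(hi.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        hi = np.asarray(X, dtype=float)
        if hi.ndim == 2:
            hi = hi[:, 0]
        return concordance_prediction(hi, self.alpha_, self.beta_)


@dataclass
class ConcordanceFit:
    """Per-locus concordance parameters and the equal-introgression G-test."""

    locus: str
    alpha: float
    beta: float
    loglik: float
    lrt: LRTResult
    n_individuals: int


def fit_concordance(
    dataset: GenotypeDataset,
    locus: str,
    *,
    leave_one_out: bool = False,
    min_individuals: int = 10,
) -> ConcordanceFit:
    """Fit (alpha, beta) for one locus against the all-locus hybrid index.

    By default the regressor HI includes the focal locus; ``leave_one_out``
    recomputes HI from the remaining loci instead.
    """
    hi_all = hybrid_index(dataset, "all")
    if leave_one_out:
        rest = [l.name for l in dataset.loci if l.name != locus]
        hi = hybrid_index(dataset, rest)["HI"].to_numpy()
    else:
        hi = hi_all["HI"].to_numpy()
    k = hi_all[f"k_{locus}"].to_numpy()
    n = hi_all[f"n_{locus}"].to_numpy()
    est = ConcordanceModel(min_individuals=min_individuals).fit(hi, k, sample_weight=n)
    return ConcordanceFit(
        locus=locus,
        alpha=est.alpha_,
        beta=est.beta_,
        loglik=est.loglik_,
        lrt=est.lrt_,
        n_individuals=est.n_individuals_,
    )
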