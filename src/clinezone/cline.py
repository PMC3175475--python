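"""Parametric sigmoid (tanh) cline fitting by maximum likelihood.

The allele-frequency cline is ``p(x) = (1 + tanh[2 (x - c) / w]) / 2`` with
center ``c`` (position of the 0.5 crossing) and width ``w`` (inverse of the
maximum slope: dp/dx at the center is exactly 1/w). Observations are
per-individual binomial counts of K alleles (n = 2 for diploid nuclear
loci, n = 1 for a haploid mitochondrial marker); the binomial coefficient
is parameter-free and omitted from all log-likelihoods.

Uncertainty is summarized by profile likelihoods and two-unit support
limits (the parameter interval within 2 log-likelihood units of the
maximum, analogous to a 95% confidence interval). Coincidence (shared
center) and concordance (shared width) across loci are tested with
likelihood-ratio tests: G = 2*dLL against a chi-square with df equal to the
parameter difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

P_CLAMP = 1e-12
_LL_TOL = 1e-8


def tanh_p(x, c: float, w: float):
    """Cline frequency ``(1 + tanh[2(x - c)/w]) / 2``; strictly increasing in x."""
    if w <= 0:
        raise ValueError("cline width w must be > 0")
    return 0.5 * (1.0 + np.tanh(2.0 * (np.asarray(x, dtype=float) - c) / w))


def cline_loglik(c: float, w: float, x, k, n) -> float:
    """Binomial log-likelihood of K-allele counts under a tanh cline.

    ``sum_i [k_i ln p_i + (n_i - k_i) ln(1 - p_i)]`` with p clamped to
    ``[1e-12, 1 - 1e-12]``; the binomial coefficient is omitted.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if x.size == 0:
        raise ValueError("empty observations")
    p = np.clip(tanh_p(x, c, w), P_CLAMP, 1.0 - P_CLAMP)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


@dataclass
class LRTResult:
    """Likelihood-ratio test: G = 2*dLL against chi-square upper tail."""

    G: float
    df: int
    p: float


@dataclass
class ProfileCurve:
    """Profile log-likelihood along one parameter (nuisance re-optimized)."""

    parameter: str
    values: np.ndarray
    loglik: np.ndarray


@dataclass
class ClineFit:
    """Fitted tanh cline for one locus or a shared locus set."""

    loci: tuple[str, ...]
    center: float
    width: float
    loglik: float
    support_center: tuple[float, float] | None = None
    support_width: tuple[float, float] | None = None
    profile_center: ProfileCurve | None = None
    profile_width: ProfileCurve | None = None
    n_obs: int = 0


def _validate_obs(x, k, n):
    x = np.asarray(x, dtype=float).ravel()
    k = np.asarray(k, dtype=float).ravel()
    n = np.asarray(n, dtype=float).ravel()
    if not (x.size == k.size == n.size):
        raise ValueError("positions, successes and trials must have equal length")
    if x.size == 0:
        raise ValueError("empty observations")
    if np.any((n != 1) & (n != 2)):
        raise ValueError("trials per observation must be 1 or 2")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("successes must lie in [0, n]")
    return x, k, n


class TanhClineFitter(RegressorMixin, BaseEstimator):
    """Maximum-likelihood tanh-cline estimator.

    scikit-learn conventions: ``fit(X, y, sample_weight)`` where X is the
    transect position (one feature), y the observed K-allele proportion and
    ``sample_weight`` the allele-copy count per observation (1 or 2, default
    2). ``predict`` returns the fitted cline frequency.

    Parameters
    ----------
    w_min : float
        Lower bound on width during optimization (km).
    w_max : float or None
        Upper bound on width; defaults to the position span of the data.
    compute_support : bool
        If True (default) compute two-unit support limits for c and w by
        profile likelihood + bisection, plus coarse profile curves.
    n_profile : int
        Grid size of the stored profile curves.
    """

    def __init__(
        self,
        w_min: float = 1e-3,
        w_max: float | None = None,
        compute_support: bool = True,
        n_profile: int = 41,
    ):
        self.w_min = w_min
        self.w_max = w_max
        self.compute_support = compute_support
        self.n_profile = n_profile

    # -- likelihood machinery -------------------------------------------------
    def _nll(self, c, w, x, k, n):
        return -cline_loglik(c, w, x, k, n)

    def fit(self, X, y=None, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must have exactly one feature (transect position)")
            X = X[:, 0]
        if y is None:
            raise ValueError("y (observed K-allele proportion) is required")
        y = np.asarray(y, dtype=float).ravel()
        n = (
            np.full(X.size, 2.0)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float).ravel()
        )
        k = y * n
        x, k, n = _validate_obs(X, k, n)
        if np.allclose(k, 0) or np.allclose(k, n):
            raise ValueError("monomorphic data: no cline to fit")

        span = float(x.max() - x.min())
        if span <= 0:
            raise ValueError("all observations at a single position")
        w_hi = self.w_max if self.w_max is not None else max(span, 10 * self.w_min)
        w_lo = self.w_min
        c_lo, c_hi = x.min() - span, x.max() + span
        bounds = [(c_lo, c_hi), (np.log(w_lo), np.log(w_hi))]

        def nll_vec(theta):
            c, logw = theta
            return self._nll(c, float(np.exp(logw)), x, k, n)

        q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
        w0 = max(min(span / 4.0, w_hi), w_lo)
        starts = [
            (q50, w0),
            (q25, w0),
            (q75, w0),
            (q50, max(min(0.5 * w0, w_hi), w_lo)),
            (q50, max(min(2.0 * w0, w_hi), w_lo)),
        ]
        best = None
        for c0, ws in starts:
            res = optimize.minimize(
                nll_vec,
                x0=[c0, np.log(ws)],
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": _LL_TOL, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("cline optimizer failed to converge")

        self.center_ = float(best.x[0])
        self.width_ = float(np.exp(best.x[1]))
        self.loglik_ = -float(best.fun)
        self.n_obs_ = int(x.size)
        self._x, self._k, self._n = x, k, n
        self._bounds = (c_lo, c_hi, w_lo, w_hi)
        if self.compute_support:
            self._profile_and_support()
        else:
            self.support_center_ = None
            self.support_width_ = None
            self.profile_center_ = None
            self.profile_width_ = None
        return self

    # profile of one parameter with the other re-optimized (1-D bounded search)
    def _profile_ll(self, param: str, value: float) -> float:
        x, k, n = self._x, self._k, self._n
        c_lo, c_hi, w_lo, w_hi = self._bounds
        if param == "center":
            f = lambda logw: self._nll(value, float(np.exp(logw)), x, k, n)
            lo, hi = np.log(w_lo), np.log(w_hi)
            x0 = np.clip(np.log(self.width_), lo, hi)
        else:
            f = lambda c: self._nll(float(c), value, x, k, n)
            lo, hi = c_lo, c_hi
            x0 = np.clip(self.center_, lo, hi)
        res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        # polish around the joint MLE too; bounded Brent can stop short
        return -min(float(res.fun), float(f(x0)))

    def _support_edge(self, param: str, mle: float, target: float,
                      direction: int, bound: float) -> float:
        """Bisection for the position where the profile crosses max - 2."""
        g = lambda v: self._profile_ll(param, v) - target
        step = max(abs(mle) * 0.05, self.width_ * 0.1, 1e-4)
        v = mle
        for _ in range(60):
            nxt = v + direction * step
            if (direction > 0 and nxt >= bound) or (direction < 0 and nxt <= bound):
                nxt = bound
            if g(nxt) < 0:
                return float(optimize.brentq(g, min(v, nxt), max(v, nxt), xtol=1e-6))
            v = nxt
            if v == bound:
                return float(bound)
            step *= 1.8
        return float(v)

    def _profile_and_support(self) -> None:
        c_lo, c_hi, w_lo, w_hi = self._bounds
        target = self.loglik_ - 2.0
        sc = (
            self._support_edge("center", self.center_, target, -1, c_lo),
            self._support_edge("center", self.center_, target, +1, c_hi),
        )
        sw = (
            self._support_edge("width", self.width_, target, -1, w_lo),
            self._support_edge("width", self.width_, target, +1, w_hi),
        )
        self.support_center_ = sc
        self.support_width_ = sw
        m = self.n_profile
        cgrid = np.linspace(sc[0] - 0.25 * (sc[1] - sc[0]),
                            sc[1] + 0.25 * (sc[1] - sc[0]), m)
        wgrid = np.linspace(max(w_lo, sw[0] - 0.25 * (sw[1] - sw[0])),
                            sw[1] + 0.25 * (sw[1] - sw[0]), m)
        self.profile_center_ = ProfileCurve(
            "center", cgrid, np.array([self._profile_ll("center", v) for v in cgrid])
        )
        self.profile_width_ = ProfileCurve(
            "width", wgrid, np.array([self._profile_ll("width", v) for v in wgrid])
        )

    def predict(self, X):
        check_is_fitted(self, "center_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return tanh_p(X, self.center_, self.width_)

    def to_fit(self, loci: Sequence[str] = ()) -> ClineFit:
        check_is_fitted(self, "center_")
        return ClineFit(
            loci=tuple(loci),
            center=self.center_,
            width=self.width_,
            loglik=self.loglik_,
            support_center=self.support_center_,
            support_width=self.support_width_,
            profile_center=self.profile_center_,
            profile_width=self.profile_width_,
            n_obs=self.n_obs_,
        )


Observations = tuple[np.ndarray, np.ndarray, np.ndarray]  # (x, k, n)


def fit_cline(
    observations: Mapping[str, Observations] | Observations,
    share: Sequence[str] | None = None,
    *,
    compute_support: bool = True,
    w_max: float | None = None,
) -> ClineFit:
    """Fit one tanh cline to one locus or to a pooled (shared) locus subset.

    ``observations`` is either a single ``(x, k, n)`` triple or a mapping
    ``locus -> (x, k, n)``; ``share`` selects the loci pooled into the fit
    (default: all).
    """
    if isinstance(observations, Mapping):
        names = list(share) if share is not None else list(observations)
        xs, ks, ns = zip(*(observations[name] for name in names))
        x = np.concatenate([np.asarray(a, float).ravel() for a in xs])
        k = np.concatenate([np.asarray(a, float).ravel() for a in ks])
        n = np.concatenate([np.asarray(a, float).ravel() for a in ns])
    else:
        names = list(share) if share is not None else []
        x, k, n = (np.asarray(a, float).ravel() for a in observations)
    est = TanhClineFitter(compute_support=compute_support, w_max=w_max)
    est.fit(x.reshape(-1, 1), k / n, sample_weight=n)
    return est.to_fit(loci=names)


@dataclass
class SharedClineTest:
    """Shared-parameter fit plus the LRT against fully independent clines."""

    shared: str
    shared_fit: ClineFit
    per_locus_free: dict[str, ClineFit]
    per_locus_constrained: dict[str, ClineFit]
    lrt: LRTResult


def _multifit_nll(theta, obs_list, shared):
    # theta layout: shared 'center' -> [c, logw_1..logw_L]
    #               shared 'width'  -> [logw, c_1..c_L]
    if shared == "center":
        c = theta[0]
        return sum(
            -cline_loglik(c, float(np.exp(lw)), *ob)
            for lw, ob in zip(theta[1:], obs_list)
        )
    w = float(np.exp(theta[0]))
    return sum(-cline_loglik(float(c), w, *ob) for c, ob in zip(theta[1:], obs_list))


def fit_shared_and_test(
    observations: Mapping[str, Observations],
    shared: str = "center",
    *,
    compute_support: bool = False,
) -> SharedClineTest:
    """Coincidence/concordance test: shared center, width or both across loci.

    The free model fits independent ``(c, w)`` per locus; the constrained
    model shares the named parameter(s). ``G = 2 (LL_free - LL_shared)`` with
    ``df = (n_loci - 1) * n_shared_parameters`` and an upper-tail chi-square
    p-value.
    """
    if shared not in {"center", "width", "both"}:
        raise ValueError("shared must be 'center', 'width' or 'both'")
    usable: dict[str, Observations] = {}
    for name, (x, k, n) in observations.items():
        x, k, n = (np.asarray(a, float).ravel() for a in (x, k, n))
        if x.size == 0 or np.allclose(k, 0) or np.allclose(k, n):
            warnings.warn(f"locus {name} has no usable cline data; excluded")
            continue
        usable[name] = (x, k, n)
    if len(usable) < 2:
        raise ValueError("need at least 2 loci with data for a shared-parameter test")
    names = list(usable)

    free: dict[str, ClineFit] = {
        name: fit_cline(usable[name], share=[name], compute_support=False)
        for name in names
    }
    ll_free = sum(f.loglik for f in free.values())

    if shared == "both":
        shared_fit = fit_cline(usable, share=names, compute_support=compute_support)
        constrained = {
            name: ClineFit(
                loci=(name,),
                center=shared_fit.center,
                width=shared_fit.width,
                loglik=cline_loglik(shared_fit.center, shared_fit.width, *usable[name]),
            )
            for name in names
        }
        ll_shared = shared_fit.loglik
        n_shared_params = 2
    else:
        obs_list = [usable[name] for name in names]
        pooled = fit_cline(usable, share=names, compute_support=False)
        if shared == "center":
            x0 = np.concatenate(
                [[pooled.center], [np.log(free[n_].width) for n_ in names]]
            )
            alt = np.concatenate(
                [
                    [float(np.mean([free[n_].center for n_ in names]))],
                    [np.log(free[n_].width) for n_ in names],
                ]
            )
        else:
            x0 = np.concatenate(
                [[np.log(pooled.width)], [free[n_].center for n_ in names]]
            )
            alt = np.concatenate(
                [
                    [float(np.mean([np.log(free[n_].width) for n_ in names]))],
                    [free[n_].center for n_ in names],
                ]
            )
        best = None
        for start in (x0, alt):
            res = optimize.minimize(
                _multifit_nll,
                x0=start,
                args=(obs_list, shared),
                method="L-BFGS-B",
                options={"ftol": _LL_TOL, "gtol": 1e-10, "maxiter": 1000},
            )
            if best is None or res.fun < best.fun:
                best = res
        ll_shared = -float(best.fun)
        n_shared_params = 1
        constrained = {}
        if shared == "center":
            c_hat = float(best.x[0])
            for i, name in enumerate(names):
                w_i = float(np.exp(best.x[1 + i]))
                constrained[name] = ClineFit(
                    (name,), c_hat, w_i, cline_loglik(c_hat, w_i, *usable[name])
                )
            shared_fit = ClineFit(tuple(names), c_hat, float("nan"), ll_shared)
        else:
            w_hat = float(np.exp(best.x[0]))
            for i, name in enumerate(names):
                c_i = float(best.x[1 + i])
                constrained[name] = ClineFit(
                    (name,), c_i, w_hat, cline_loglik(c_i, w_hat, *usable[name])
                )
            shared_fit = ClineFit(tuple(names), float("nan"), w_hat, ll_shared)

    G = 2.0 * (ll_free - ll_shared)
    if G < -1e-4:
        warnings.warn(f"shared fit beat the free fit by {-G/2:.2e} log-units")
    G = max(G, 0.0)
    df = (len(names) - 1) * n_shared_params
    return SharedClineTest(
        shared=shared,
        shared_fit=shared_fit,
        per_locus_free=free,
        per_locus_constrained=constrained,
        lrt=LRTResult(G=G, df=df, p=float(stats.chi2.sf(G, df))),
    )
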