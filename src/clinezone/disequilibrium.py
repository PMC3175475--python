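"""Maximum-likelihood disequilibrium estimates in a sliding spatial window.

Three components, each bounded in [-0.25, 0.25] for diagnostic biallelic
markers and positive when K alleles co-occur:

* within-locus: heterozygote deficit, the single-diploid-locus analog of D
  (``D_within = P(KK) - p^2``, the plug-in ML estimate);
* between nuclear loci: gametic D with double-heterozygote phase resolved
  by an EM algorithm on haplotype frequencies under random union of
  gametes;
* cytonuclear: association between the haploid mitochondrial state and a
  random nuclear allele copy, which has a closed-form ML estimate (no
  phase ambiguity).

The window scan averages each component over loci/pairs inside a window
slid along the transect (defaults: 200 m windows moved in 100 m steps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .transect import ProjectedDataset

EM_TOL = 1e-10
EM_MAX_ITER = 10_000


def d_bounds(p_a: float, p_b: float) -> tuple[float, float]:
    """Feasible range of D at allele frequencies (p_a, p_b)."""
    lo = -min(p_a * p_b, (1 - p_a) * (1 - p_b))
    hi = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    return lo, hi


@dataclass
class DEstimate:
    """One ML disequilibrium estimate with its context."""

    D: float
    p_a: float
    p_b: float
    loglik: float
    converged: bool = True
    degenerate: bool = False


def het_deficit_ml(counts) -> DEstimate:
    """ML heterozygote deficit from genotype counts ``(n_KK, n_KE, n_EE)``.

    ML genotype frequencies are the observed proportions, so
    ``D_within = n_KK/N - p^2`` with ``p = (2 n_KK + n_KE) / 2N``.
    """
    n_kk, n_ke, n_ee = (float(c) for c in counts)
    N = n_kk + n_ke + n_ee
    if N < 1:
        raise ValueError("need at least one individual")
    p = (2 * n_kk + n_ke) / (2 * N)
    d = n_kk / N - p * p
    freqs = np.array([n_kk, n_ke, n_ee]) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.sum(np.where(freqs > 0, np.array([n_kk, n_ke, n_ee]) * np.log(freqs), 0.0)))
    return DEstimate(D=d, p_a=p, p_b=p, loglik=ll)


def _haplotype_genotype_probs(h: np.ndarray) -> np.ndarray:
    """3x3 genotype probabilities from haplotype freqs (h_EE, h_EK, h_KE, h_KK).

    Index convention: h[a*2 + b] where a, b are the K indicators at loci A, B;
    genotype cell (i, j) = K-copy counts at A and B.
    """
    h_ee, h_ek, h_ke, h_kk = h
    P = np.empty((3, 3))
    P[0, 0] = h_ee**2
    P[0, 1] = 2 * h_ee * h_ek
    P[0, 2] = h_ek**2
    P[1, 0] = 2 * h_ee * h_ke
    P[1, 1] = 2 * (h_ee * h_kk + h_ek * h_ke)
    P[1, 2] = 2 * h_ek * h_kk
    P[2, 0] = h_ke**2
    P[2, 1] = 2 * h_ke * h_kk
    P[2, 2] = h_kk**2
    return P


def _table_loglik(table: np.ndarray, h: np.ndarray) -> float:
    P = _haplotype_genotype_probs(h)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(np.maximum(P, 1e-300)), 0.0)
    return float(terms.sum())


def _em_from_start(table: np.ndarray, h0: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Run EM on haplotype frequencies; loglik is non-decreasing by construction."""
    N2 = 2.0 * table.sum()
    n = table
    h = h0.copy()
    ll_prev = _table_loglik(n, h)
    converged = False
    for _ in range(EM_MAX_ITER):
        h_ee, h_ek, h_ke, h_kk = h
        denom = h_ee * h_kk + h_ek * h_ke
        c = 0.5 if denom <= 0 else (h_ee * h_kk) / denom  # P(coupling | double het)
        n_kk = 2 * n[2, 2] + n[2, 1] + n[1, 2] + c * n[1, 1]
        n_ke = 2 * n[2, 0] + n[2, 1] + n[1, 0] + (1 - c) * n[1, 1]
        n_ek = 2 * n[0, 2] + n[0, 1] + n[1, 2] + (1 - c) * n[1, 1]
        n_ee = 2 * n[0, 0] + n[0, 1] + n[1, 0] + c * n[1, 1]
        h = np.array([n_ee, n_ek, n_ke, n_kk]) / N2
        ll = _table_loglik(n, h)
        if ll < ll_prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        if ll - ll_prev < EM_TOL:
            converged = True
            break
        ll_prev = ll
    return h, _table_loglik(n, h), converged


def pairwise_D_ml(table) -> DEstimate:
    """ML gametic D from a 3x3 two-locus diploid genotype table.

    Rows/columns are K-copy counts (0, 1, 2) at loci A and B. Phase of
    double heterozygotes is resolved by EM on the four haplotype
    frequencies under random union of gametes; multiple starts spanning
    positive and negative D guard against the saddle at D = 0. A loglik tie
    between maxima at +/-D (within 1e-6) returns 0 with ``degenerate=True``.
    """
    n = np.asarray(table, dtype=float)
    if n.shape != (3, 3) or n.sum() < 1 or np.any(n < 0):
        raise ValueError("table must be a non-negative 3x3 with >= 1 individual")
    N2 = 2.0 * n.sum()
    p_a = (2 * n[2, :].sum() + n[1, :].sum()) / N2
    p_b = (2 * n[:, 2].sum() + n[:, 1].sum()) / N2
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic locus: D undefined")

    lo, hi = d_bounds(p_a, p_b)
    offsets = [0.0, 0.02, -0.02, 0.1, -0.1, 0.2, -0.2, 0.24, -0.24]
    fits = []
    for d0 in offsets:
        d0 = float(np.clip(d0, lo + 1e-6, hi - 1e-6)) if lo < hi else 0.0
        h0 = np.array(
            [
                (1 - p_a) * (1 - p_b) + d0,
                (1 - p_a) * p_b - d0,
                p_a * (1 - p_b) - d0,
                p_a * p_b + d0,
            ]
        )
        if np.any(h0 < 0):
            continue
        h0 = np.maximum(h0, 1e-12)
        h0 /= h0.sum()
        fits.append(_em_from_start(n, h0))
    h_best, ll_best, conv = max(fits, key=lambda f: f[1])
    D = h_best[3] - (h_best[2] + h_best[3]) * (h_best[1] + h_best[3])
    # twin-maximum degeneracy: a tied optimum with opposite-signed D
    degenerate = False
    for h, ll, _ in fits:
        d_alt = h[3] - (h[2] + h[3]) * (h[1] + h[3])
        if abs(ll - ll_best) < 1e-6 and d_alt * D < -1e-8 and abs(abs(d_alt) - abs(D)) < 1e-4:
            degenerate = True
            D = 0.0
            break
    p_a_hat = h_best[2] + h_best[3]
    p_b_hat = h_best[1] + h_best[3]
    return DEstimate(
        D=float(D), p_a=float(p_a_hat), p_b=float(p_b_hat),
        loglik=ll_best, converged=conv, degenerate=degenerate,
    )


def cytonuclear_D_ml(table) -> DEstimate:
    """ML cytonuclear D from a 2x3 (mito x nuclear genotype) count table.

    Rows: mito E, K. Columns: nuclear K-copy count 0, 1, 2. Each individual
    is one mito copy paired with two nuclear copies; the ML estimate is the
    closed form ``D = P(K, K) - p_mt * p_nuc`` with
    ``P(K, K) = [2 n(K, KK) + n(K, KE)] / 2N``.
    """
    n = np.asarray(table, dtype=float)
    if n.shape != (2, 3) or n.sum() < 1 or np.any(n < 0):
        raise ValueError("table must be a non-negative 2x3 with >= 1 individual")
    N = n.sum()
    p_mt = n[1, :].sum() / N
    p_nuc = (2 * n[:, 2].sum() + n[:, 1].sum()) / (2 * N)
    if p_mt in (0.0, 1.0) or p_nuc in (0.0, 1.0):
        raise ValueError("monomorphic marker: D undefined")
    p_joint = (2 * n[1, 2] + n[1, 1]) / (2 * N)
    D = p_joint - p_mt * p_nuc
    # loglik under the fitted (conditional binomial) model
    ll = 0.0
    for m in (0, 1):
        nm = n[m, :].sum()
        if nm == 0:
            continue
        p_k_given_m = (2 * n[m, 2] + n[m, 1]) / (2 * nm)
        probs = np.array(
            [
                (1 - p_k_given_m) ** 2,
                2 * p_k_given_m * (1 - p_k_given_m),
                p_k_given_m**2,
            ]
        ) * (nm / N)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll += float(
                np.sum(np.where(n[m, :] > 0, n[m, :] * np.log(np.maximum(probs, 1e-300)), 0.0))
            )
    return DEstimate(D=float(D), p_a=float(p_mt), p_b=float(p_nuc), loglik=ll)


@dataclass
class DWindowRecord:
    """Sliding-window averages of the three disequilibrium components."""

    center: float
    n_within: int
    n_between: int
    n_cyto: int
    D_within: float
    D_between: float
    D_cytonuclear: float


def _genotype_counts(k: np.ndarray) -> tuple[float, float, float]:
    return (float(np.sum(k == 2)), float(np.sum(k == 1)), float(np.sum(k == 0)))


def ld_scan(
    projected: ProjectedDataset,
    window: float = 0.2,
    step: float = 0.1,
    min_n: int = 5,
) -> pd.DataFrame:
    """Sliding-window ML disequilibria along the transect.

    Window centers run from ``min position + window/2`` to
    ``max position - window/2`` in increments of ``step``; membership is
    half-open on the right. Components with fewer than ``min_n`` complete
    individuals in a window are NaN. Returns one row per window with
    columns matching :class:`DWindowRecord`.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    x = np.asarray(projected.position, dtype=float)
    ds = projected.base
    nuc_names = [l.name for l in ds.nuclear_loci]
    kmat = ds.table[nuc_names].astype(float).to_numpy()
    mito = ds.mito_k().to_numpy() if ds.mito_locus is not None else None

    lo, hi = x.min() + window / 2, x.max() - window / 2
    if hi < lo:
        warnings.warn("transect shorter than one window; empty scan")
        return pd.DataFrame(
            columns=["center", "n_within", "n_between", "n_cyto",
                     "D_within", "D_between", "D_cytonuclear"]
        )
    centers = lo + step * np.arange(int(np.floor((hi - lo) / step + 1e-9)) + 1)

    records = []
    for c in centers:
        inside = (x >= c - window / 2) & (x < c + window / 2)
        kw = kmat[inside]
        mw = mito[inside] if mito is not None else None

        within_vals, n_within = [], 0
        for j in range(kw.shape[1]):
            col = kw[:, j]
            col = col[~np.isnan(col)]
            if col.size >= min_n and 0 < col.mean() / 2 < 1:
                est = het_deficit_ml(_genotype_counts(col))
                _assert_bounds(est)
                within_vals.append(est.D)
                n_within = max(n_within, col.size)

        between_vals, n_between = [], 0
        for a, b in combinations(range(kw.shape[1]), 2):
            pair = kw[:, [a, b]]
            pair = pair[~np.isnan(pair).any(axis=1)]
            if pair.shape[0] < min_n:
                continue
            tab = np.zeros((3, 3))
            for ka, kb in pair:
                tab[int(ka), int(kb)] += 1
            pa = (2 * tab[2].sum() + tab[1].sum()) / (2 * tab.sum())
            pb = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / (2 * tab.sum())
            if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                continue
            est = pairwise_D_ml(tab)
            _assert_bounds(est)
            between_vals.append(est.D)
            n_between = max(n_between, pair.shape[0])

        cyto_vals, n_cyto = [], 0
        if mw is not None:
            for j in range(kw.shape[1]):
                both = ~(np.isnan(kw[:, j]) | np.isnan(mw))
                if both.sum() < min_n:
                    continue
                tab = np.zeros((2, 3))
                for m, kn in zip(mw[both], kw[both, j]):
                    tab[int(m), int(kn)] += 1
                if tab[1].sum() in (0.0, tab.sum()):
                    continue
                if (2 * tab[:, 2].sum() + tab[:, 1].sum()) in (0.0, 2 * tab.sum()):
                    continue
                est = cytonuclear_D_ml(tab)
                _assert_bounds(est)
                cyto_vals.append(est.D)
                n_cyto = max(n_cyto, int(both.sum()))

        records.append(
            DWindowRecord(
                center=float(c),
                n_within=n_within,
                n_between=n_between,
                n_cyto=n_cyto,
                D_within=float(np.mean(within_vals)) if within_vals else np.nan,
                D_between=float(np.mean(between_vals)) if between_vals else np.nan,
                D_cytonuclear=float(np.mean(cyto_vals)) if cyto_vals else np.nan,
            )
        )
    out = pd.DataFrame([r.__dict__ for r in records])
    if out[["D_within", "D_between", "D_cytonuclear"]].isna().all().all():
        warnings.warn("no window met the minimum sample size for any component")
    return out


def _assert_bounds(est: DEstimate) -> None:
    lo, hi = d_bounds(est.p_a, est.p_b)
    if not (lo - 1e-9 <= est.D <= hi + 1e-9):
        raise AssertionError(
            f"D={est.D} violates allele-frequency bounds ({lo}, {hi})"
        )
    if not -0.25 - 1e-9 <= est.D <= 0.25 + 1e-9:
        raise AssertionError(f"D={est.D} outside [-0.25, 0.25]")
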