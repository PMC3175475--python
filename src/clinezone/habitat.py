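"""Genotype-habitat association tests and the habitat-and-cline model.

The contact zone sits on an ecotone: vegetation series and elevation are
both confounded with transect position. Two questions are addressed:

* do hybrid/parental classes associate with vegetation series or differ in
  elevation? (Pearson chi-square on the contingency table; one-way ANOVA
  on elevation);
* does letting the cline respond to habitat improve on geography alone?
  The "cline-only" model is the shared tanh cline; the "habitat-and-cline"
  model shifts the cline center by ``delta`` for individuals in the MWP
  vegetation series (or linearly in centered elevation), adding one
  parameter, and the two are compared by a likelihood-ratio test. The
  richer model is accepted only on a significant likelihood gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cline import LRTResult, ClineFit, fit_cline
from .io import GenotypeDataset
from .transect import ProjectedDataset


@dataclass
class AssociationTest:
    statistic: float
    df: int
    p: float
    table: pd.DataFrame
    low_expected: bool


def habitat_association_test(classes, vegetation) -> AssociationTest:
    """Pearson chi-square association between class labels and vegetation."""
    df_in = pd.DataFrame({"cls": pd.Series(classes), "veg": pd.Series(vegetation)}).dropna()
    table = pd.crosstab(df_in["cls"], df_in["veg"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 levels on each margin after dropping missing")
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    low = bool((expected < 5).any())
    if low:
        warnings.warn("some expected counts < 5; chi-square approximation is rough")
    return AssociationTest(
        statistic=float(chi2), df=int(dof), p=float(p), table=table, low_expected=low
    )


@dataclass
class HabitatClineFit:
    """Habitat-and-cline fit with the LRT against the cline-only model."""

    covariate: str
    cline_only: ClineFit
    center: float
    width: float
    effect: float  # delta (km, MWP center offset) or gamma (km per meter)
    loglik: float
    lrt: LRTResult
    n_individuals: int


def fit_habitat_cline_and_test(
    projected: ProjectedDataset,
    covariate: str = "vegetation",
    loci: str = "all",
    *,
    width_effect: bool = False,
) -> HabitatClineFit:
    """Compare the habitat-and-cline model to the cline-only model by LRT.

    The habitat model replaces the shared center c with
    ``c + delta * 1[veg == MWP]`` (or ``c + gamma * (elev - mean elev)``),
    one added parameter; ``width_effect`` instead scales log-width. Both
    models are fitted by ML on the same individuals (those with the
    covariate observed, which must cover >= 90% of the dataset).
    """
    ds = projected.base
    if covariate == "vegetation":
        cov = ds.table["vegetation"].map({"MMW": 0.0, "MWP": 1.0}).astype(float).to_numpy()
    elif covariate == "elevation":
        cov = pd.to_numeric(ds.table["elevation"], errors="coerce").to_numpy()
    else:
        raise ValueError("covariate must be 'vegetation' or 'elevation'")
    have = ~np.isnan(cov)
    coverage = have.mean()
    if coverage < 0.9:
        raise ValueError(
            f"covariate {covariate} observed for only {coverage:.0%} of individuals"
        )
    if have.sum() and np.nanstd(cov) == 0:
        raise ValueError(f"covariate {covariate} is constant: effect unidentifiable")
    if not have.all():
        warnings.warn(f"dropping {int((~have).sum())} individuals without {covariate}")
    if covariate == "elevation":
        cov = cov - np.nanmean(cov[have])

    from .transect import _locus_observations

    raw = _locus_observations(ds, loci)
    xs, ks, ns, cs = [], [], [], []
    for name, (k, n, mask) in raw.items():
        keep = mask & have
        xs.append(projected.position[keep])
        ks.append(k[keep])
        ns.append(n[keep])
        cs.append(cov[keep])
    x = np.concatenate(xs)
    k = np.concatenate(ks)
    n = np.concatenate(ns)
    z = np.concatenate(cs)

    base = fit_cline((x, k, n), compute_support=False)

    def nll(theta):
        c0, logw, eff = theta
        if width_effect:
            w_i = np.exp(logw + eff * z)
            p = 0.5 * (1.0 + np.tanh(2.0 * (x - c0) / w_i))
        else:
            p = 0.5 * (1.0 + np.tanh(2.0 * (x - (c0 + eff * z)) / np.exp(logw)))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    scale = 1.0 if covariate == "vegetation" else 1.0 / max(np.std(z), 1e-9)
    best = None
    for eff0 in (0.0, 0.2 * scale, -0.2 * scale):
        res = optimize.minimize(
            nll,
            x0=[base.center, np.log(base.width), eff0],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    ll_hab = -float(best.fun)
    # nesting: the habitat model contains cline-only at effect = 0
    ll_hab = max(ll_hab, base.loglik)
    G = max(2.0 * (ll_hab - base.loglik), 0.0)
    lrt = LRTResult(G=G, df=1, p=float(stats.chi2.sf(G, 1)))
    return HabitatClineFit(
        covariate=covariate,
        cline_only=base,
        center=float(best.x[0]),
        width=float(np.exp(best.x[1])),
        effect=float(best.x[2]),
        loglik=ll_hab,
        lrt=lrt,
        n_individuals=int(have.sum()),
    )


@dataclass
class ElevationSummary:
    per_class: pd.DataFrame  # index: class; columns: n, mean, min, max
    F: float
    df: tuple[int, int]
    p: float
    n_missing: int


def elevation_summary(dataset: GenotypeDataset, classes=None) -> ElevationSummary:
    """Per-class elevation descriptives and the one-way ANOVA omnibus F."""
    elev = pd.to_numeric(dataset.table["elevation"], errors="coerce")
    cls = pd.Series(
        classes if classes is not None else dataset.table["phenotype"]
    ).reset_index(drop=True)
    df_in = pd.DataFrame({"cls": cls, "elev": elev.reset_index(drop=True)})
    n_missing = int(df_in["elev"].isna().sum() + df_in["cls"].isna().sum())
    df_in = df_in.dropna()
    if n_missing:
        warnings.warn(f"dropped {n_missing} individuals with missing class/elevation")
    per_class = df_in.groupby("cls")["elev"].agg(n="count", mean="mean", min="min", max="max")
    groups = [g["elev"].to_numpy() for _, g in df_in.groupby("cls") if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 classes with >= 2 individuals each for the F test")
    F, p = stats.f_oneway(*groups)
    k = len(groups)
    N = sum(len(g) for g in groups)
    return ElevationSummary(
        per_class=per_class, F=float(F), df=(k - 1, N - k), p=float(p), n_missing=n_missing
    )
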