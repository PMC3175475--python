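"""Transect projection, monotone (PAVA) maximum-likelihood clines, and the
maximum-likelihood transect heading.

Sampling coordinates are mapped to a local planar frame with an
equirectangular projection (adequate well below kilometre-scale error for a
study area a few km across), then collapsed onto a 1-D axis:
``position = east*sin(heading) + north*cos(heading)`` with the compass
heading in degrees. The model-free monotone cline for a locus is the
isotonic (pool-adjacent-violators) fit of allele frequency against
position under binomial weighting; the best-fit transect heading maximizes
the summed monotone-cline log-likelihood over loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .io import GenotypeDataset

EARTH_RADIUS_KM = 6371.0088


@dataclass
class ProjectedDataset:
    """A dataset collapsed onto a 1-D transect at a fixed compass heading."""

    base: GenotypeDataset
    heading: float
    origin: tuple[float, float]  # (lat0, lon0)
    position: np.ndarray  # km per individual, same order as base.table


@dataclass
class MonotoneCline:
    """Isotonic ML cline: non-decreasing (or non-increasing) frequencies."""

    position: np.ndarray  # distinct sorted positions (ties pooled)
    frequency: np.ndarray  # fitted frequencies in [0, 1]
    weight: np.ndarray  # allele copies per pooled position
    loglik: float
    direction: str  # "increasing" | "decreasing"


def planar_coordinates(
    lat: np.ndarray, lon: np.ndarray, origin: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular local projection: (east, north) in km about origin."""
    lat0, lon0 = origin
    east = EARTH_RADIUS_KM * np.cos(np.deg2rad(lat0)) * np.deg2rad(
        np.asarray(lon, float) - lon0
    )
    north = EARTH_RADIUS_KM * np.deg2rad(np.asarray(lat, float) - lat0)
    return east, north


def project_positions(
    dataset: GenotypeDataset,
    heading: float,
    origin: tuple[float, float] | str = "centroid",
) -> ProjectedDataset:
    """Project individuals onto the 1-D transect axis at ``heading`` degrees.

    Default origin is the centroid of the coordinates, so positions are
    centered. ``position(heading + 180) == -position(heading)``.
    """
    lat = pd.to_numeric(dataset.table["lat"], errors="coerce").to_numpy()
    lon = pd.to_numeric(dataset.table["lon"], errors="coerce").to_numpy()
    bad = np.isnan(lat) | np.isnan(lon)
    if bad.any():
        ids = list(dataset.table.loc[bad, "id"])
        raise ValueError(f"individuals without coordinates: {ids[:10]}")
    if origin == "centroid":
        origin = (float(lat.mean()), float(lon.mean()))
    east, north = planar_coordinates(lat, lon, origin)
    theta = np.deg2rad(heading % 360.0)
    position = east * np.sin(theta) + north * np.cos(theta)
    return ProjectedDataset(
        base=dataset, heading=heading % 360.0, origin=origin, position=position
    )


def _binom_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    """Binomial loglik with the 0*ln(0) := 0 convention (coefficient omitted)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(p), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log1p(-p), 0.0)
    return float(np.sum(t1 + t2))


def pava_fit(
    positions, k, n, direction: str = "increasing"
) -> MonotoneCline:
    """Binomial-ML monotone cline by pool-adjacent-violators.

    Ties in position are pooled first; the isotonic fit of ``k/n`` with
    weights ``n`` maximizes the binomial likelihood over all monotone
    frequency sequences (the weighted-mean pooling is the ML solution for
    any Bregman likelihood, the binomial included).
    """
    if direction not in {"increasing", "decreasing"}:
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    x = np.asarray(positions, dtype=float).ravel()
    k = np.asarray(k, dtype=float).ravel()
    n = np.asarray(n, dtype=float).ravel()
    ok = ~(np.isnan(x) | np.isnan(k) | np.isnan(n))
    x, k, n = x[ok], k[ok], n[ok]
    if x.size == 0:
        raise ValueError("locus has no scored observations")
    order = np.argsort(x, kind="stable")
    x, k, n = x[order], k[order], n[order]
    # pool exact ties in position
    xu, inv = np.unique(x, return_inverse=True)
    ku = np.bincount(inv, weights=k)
    nu = np.bincount(inv, weights=n)
    y = ku / nu
    res = optimize.isotonic_regression(y, weights=nu, increasing=(direction == "increasing"))
    p = np.clip(np.asarray(res.x, dtype=float), 0.0, 1.0)
    return MonotoneCline(
        position=xu,
        frequency=p,
        weight=nu,
        loglik=_binom_loglik(ku, nu, p),
        direction=direction,
    )


def _locus_observations(dataset: GenotypeDataset, loci: str = "all"):
    """(k, n, mask) per selected locus, in table row order."""
    out = {}
    for loc in dataset.loci:
        if loci == "nuclear" and loc.role != "nuclear":
            continue
        if loci == "mito" and loc.role != "mitochondrial":
            continue
        if loc.role == "mitochondrial":
            k = dataset.mito_k().to_numpy()
            n = np.ones_like(k)
        else:
            k = dataset.table[loc.name].astype(float).to_numpy()
            n = np.full_like(k, 2.0)
        mask = ~np.isnan(k)
        out[loc.name] = (k, n, mask)
    if not out:
        raise ValueError(f"no loci selected by {loci!r}")
    return out


@dataclass
class OrientationResult:
    """ML transect heading with two-unit support limits and loglik profile."""

    heading: float
    support: tuple[float, float]
    loglik: float
    profile: pd.DataFrame  # columns: heading, loglik
    directions_agree: bool
    per_locus_direction: dict[str, str]


class TransectOrientation(BaseEstimator):
    """Maximum-likelihood transect heading via per-locus monotone clines.

    For each heading on a grid over [0, 360), individuals are projected,
    each locus gets the better of an increasing or decreasing isotonic
    cline, and log-likelihoods are summed over loci. The reported heading
    follows the convention that K-allele frequency increases along the
    positive axis; the support set is every heading within 2 log-units of
    the maximum (on the half-turn containing the MLE, since headings 180
    degrees apart index the same transect).

    Parameters
    ----------
    grid_step : float
        Heading grid step in degrees; must divide 360.
    loci : {"all", "nuclear", "mito"}
        Which loci contribute to the likelihood.
    refine : bool
        Golden-section refinement within +/- 2 grid steps of the argmax.
    """

    def __init__(self, grid_step: float = 1.0, loci: str = "all", refine: bool = True):
        self.grid_step = grid_step
        self.loci = loci
        self.refine = refine

    def fit(self, X: GenotypeDataset, y=None):
        if not isinstance(X, GenotypeDataset):
            raise TypeError("TransectOrientation.fit expects a GenotypeDataset")
        if 360.0 % self.grid_step != 0:
            raise ValueError("grid_step must divide 360")
        lat = pd.to_numeric(X.table["lat"]).to_numpy()
        lon = pd.to_numeric(X.table["lon"]).to_numpy()
        if len(set(zip(lat, lon))) < 3:
            raise ValueError("need at least 3 distinct sampling positions")
        obs = _locus_observations(X, self.loci)

        def total_ll(heading: float) -> tuple[float, dict[str, str]]:
            proj = project_positions(X, heading)
            ll = 0.0
            dirs: dict[str, str] = {}
            for name, (k, n, mask) in obs.items():
                inc = pava_fit(proj.position[mask], k[mask], n[mask], "increasing")
                dec = pava_fit(proj.position[mask], k[mask], n[mask], "decreasing")
                if inc.loglik >= dec.loglik:
                    ll += inc.loglik
                    dirs[name] = "increasing"
                else:
                    ll += dec.loglik
                    dirs[name] = "decreasing"
            return ll, dirs

        grid = np.arange(0.0, 360.0, self.grid_step)
        lls = np.array([total_ll(h)[0] for h in grid])
        i_best = int(np.argmax(lls))
        h_best = float(grid[i_best])

        if self.refine:
            span = 2.0 * self.grid_step
            res = optimize.minimize_scalar(
                lambda h: -total_ll(h % 360.0)[0],
                bracket=None,
                bounds=(h_best - span, h_best + span),
                method="bounded",
                options={"xatol": 1e-3},
            )
            if -res.fun >= lls[i_best]:
                h_best = float(res.x % 360.0)
        ll_best, dirs = total_ll(h_best)

        # convention: K frequency increases along +axis (majority of loci)
        n_inc = sum(d == "increasing" for d in dirs.values())
        if n_inc * 2 < len(dirs):
            h_best = (h_best + 180.0) % 360.0
            ll_best, dirs = total_ll(h_best)

        # support set: contiguous run of grid headings around the MLE that stay
        # within 2 log-units of the maximum (the profile is 180-degree periodic,
        # so only the half-turn containing the MLE is scanned)
        ok = lls >= ll_best - 2.0
        m = len(grid)
        i0 = int(np.argmin(np.abs((grid - h_best + 180.0) % 360.0 - 180.0)))
        lo_steps = hi_steps = 0
        while lo_steps < m // 4 and ok[(i0 - lo_steps - 1) % m]:
            lo_steps += 1
        while hi_steps < m // 4 and ok[(i0 + hi_steps + 1) % m]:
            hi_steps += 1
        lo = min(float(grid[i0]) - lo_steps * self.grid_step, h_best)
        hi = max(float(grid[i0]) + hi_steps * self.grid_step, h_best)
        self.heading_ = h_best
        self.support_ = (lo % 360.0, hi % 360.0)
        self.loglik_ = ll_best
        self.profile_ = pd.DataFrame({"heading": grid, "loglik": lls})
        self.per_locus_direction_ = dirs
        self.directions_agree_ = len(set(dirs.values())) == 1
        return self

    def result(self) -> OrientationResult:
        return OrientationResult(
            heading=self.heading_,
            support=self.support_,
            loglik=self.loglik_,
            profile=self.profile_,
            directions_agree=self.directions_agree_,
            per_locus_direction=self.per_locus_direction_,
        )


def fit_orientation(
    dataset: GenotypeDataset,
    grid: float = 1.0,
    loci: str = "all",
    refine: bool = True,
) -> OrientationResult:
    """ML transect heading + two-unit support limits + heading profile."""
    est = TransectOrientation(grid_step=grid, loci=loci, refine=refine).fit(dataset)
    return est.result()


def cline_observations(
    projected: ProjectedDataset, loci: str = "all"
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-locus ``(x, k, n)`` observation triples from a projected dataset.

    Orientation: if the selected loci's K frequency decreases along the
    axis, callers should flip the heading first; this function performs no
    flipping.
    """
    obs = _locus_observations(projected.base, loci)
    out = {}
    for name, (k, n, mask) in obs.items():
        out[name] = (projected.position[mask], k[mask], n[mask])
    return out
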