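"""Synthetic hybrid-zone datasets with known ground truth.

The generator emulates a narrow two-taxon contact zone sampled on a small
rectangular strip: tanh allele-frequency clines at a handful of diagnostic
markers, a mitochondrial cline offset toward one flank, genetic
disequilibrium injected by dispersal of unrecombined parental individuals
into the zone (the tension-zone mechanism), strongly asymmetric mtDNA in
mixed-ancestry individuals, and habitat covariates (vegetation series,
elevation) confounded with transect position.

Defaults mirror the study conditions of the salamander contact the package
models: 335 individuals on a 3.5 x 1.75 km strip, three diploid nuclear
loci plus one haploid mitochondrial marker, cline widths around 0.72-0.80
km, an mtDNA center shifted ~0.105 km toward the eschscholtzii side, and
~90% of mixed-ancestry individuals carrying the klauberi mitotype.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .cline import tanh_p
from .io import GenotypeDataset, Locus

EARTH_RADIUS_KM = 6371.0088


def _default_centers() -> dict[str, float]:
    return {"ND4": -0.105, "CXCR4": 0.0, "SLC8A3": 0.0, "RAG1": 0.0}


def _default_widths() -> dict[str, float]:
    return {"ND4": 0.718, "CXCR4": 0.770, "SLC8A3": 0.799, "RAG1": 0.725}


@dataclass
class SimConfig:
    """Ground-truth parameters of a simulated hybrid zone.

    Lengths are in km along the transect axis (positive direction = the
    klauberi side, i.e. K-allele frequency increases with position).
    ``mix_amplitude`` is the peak probability that a sampled individual is an
    unrecombined parental immigrant; the probability decays as
    ``exp(-|x - mix_center_km| / mix_scale_km)``, which jointly injects
    heterozygote deficit, inter-locus D and cytonuclear D around
    ``mix_center_km``. ``mt_asymmetry`` is the probability that a
    mixed-ancestry individual carries the K mitotype regardless of position.
    """

    n: int = 335
    strip: tuple[float, float] = (3.5, 1.75)
    heading_true: float = 207.0
    center_per_locus: dict[str, float] = field(default_factory=_default_centers)
    width_per_locus: dict[str, float] = field(default_factory=_default_widths)
    mito_locus: str | None = "ND4"
    mix_amplitude: float = 0.7
    mix_center_km: float = -0.15
    mix_scale_km: float = 0.5
    mt_asymmetry: float | None = 0.9
    veg_boundary: float = 0.0
    veg_blur_km: float = 0.15
    elev_base: float = 1420.0
    elev_slope: float = 60.0
    elev_noise_sd: float = 60.0
    origin_lat: float = 33.34
    origin_lon: float = -116.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, w in self.width_per_locus.items():
            if w <= 0:
                raise ValueError(f"width for {name} must be > 0")
        for p, label in (
            (self.mix_amplitude, "mix_amplitude"),
            (self.mt_asymmetry, "mt_asymmetry"),
        ):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1]")
        if self.mix_scale_km <= 0 or self.veg_blur_km <= 0:
            raise ValueError("scales must be positive")
        if set(self.center_per_locus) != set(self.width_per_locus):
            raise ValueError("center_per_locus and width_per_locus must name the same loci")
        if self.mito_locus is not None and self.mito_locus not in self.center_per_locus:
            raise ValueError(f"mito locus {self.mito_locus!r} has no cline parameters")

    @property
    def nuclear_names(self) -> list[str]:
        return [n for n in self.center_per_locus if n != self.mito_locus]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if f.name == "strip" else v
        return cls(**kwargs)


def sample_genotype_at(
    x: float | np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw genotype fields for individuals at transect position(s) ``x``.

    With probability ``m(x) = mix_amplitude * exp(-|x - mix_center| / mix_scale)``
    an individual is a pure parental at every marker (all-K with the local
    consensus-cline probability, else all-E); otherwise each allele copy is
    drawn independently from its locus's tanh cline (HWE, linkage
    equilibrium), except that the mitotype of mixed-ancestry draws is K with
    probability ``mt_asymmetry``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n = x.size
    nuc = cfg.nuclear_names
    consensus_c = float(np.mean([cfg.center_per_locus[l] for l in nuc]))
    consensus_w = float(np.mean([cfg.width_per_locus[l] for l in nuc]))

    m = cfg.mix_amplitude * np.exp(-np.abs(x - cfg.mix_center_km) / cfg.mix_scale_km)
    is_parental = rng.random(n) < m
    parental_is_k = rng.random(n) < tanh_p(x, consensus_c, consensus_w)

    out: dict[str, np.ndarray] = {}
    for name in nuc:
        p = tanh_p(x, cfg.center_per_locus[name], cfg.width_per_locus[name])
        k = rng.binomial(2, p).astype(float)
        k[is_parental] = np.where(parental_is_k[is_parental], 2.0, 0.0)
        out[name] = k
    if cfg.mito_locus is not None:
        p_mt = tanh_p(
            x, cfg.center_per_locus[cfg.mito_locus], cfg.width_per_locus[cfg.mito_locus]
        )
        mito_k = rng.random(n) < p_mt
        # asymmetric maternal inheritance applies to individuals of genuinely
        # mixed ancestry (nuclear genotype carries alleles of both taxa);
        # pure-genotype draws keep the mitochondrial cline itself
        if cfg.mt_asymmetry is not None:
            total_k = np.sum([out[name] for name in nuc], axis=0)
            mixed = (~is_parental) & (total_k > 0) & (total_k < 2 * len(nuc))
            mito_k[mixed] = rng.random(int(mixed.sum())) < cfg.mt_asymmetry
        mito_k[is_parental] = parental_is_k[is_parental]
        out["mito"] = np.where(mito_k, "K", "E")
    return out


def simulate_zone(cfg: SimConfig) -> GenotypeDataset:
    """Simulate a full dataset: positions, genotypes, habitat, coordinates.

    Positions are uniform on the strip, the strip is rotated so the cline
    axis has compass heading ``heading_true``, and lat/lon are recovered by
    inverting the local equirectangular projection about the configured
    origin. Byte-identical output for identical config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    L, W = cfg.strip
    u = rng.uniform(-L / 2, L / 2, cfg.n)  # along cline axis
    v = rng.uniform(-W / 2, W / 2, cfg.n)  # across

    theta = np.deg2rad(cfg.heading_true)
    east = u * np.sin(theta) + v * np.cos(theta)
    north = u * np.cos(theta) - v * np.sin(theta)
    lat0 = np.deg2rad(cfg.origin_lat)
    lat = cfg.origin_lat + np.rad2deg(north / EARTH_RADIUS_KM)
    lon = cfg.origin_lon + np.rad2deg(east / (EARTH_RADIUS_KM * np.cos(lat0)))

    geno = sample_genotype_at(u, cfg, rng)

    p_mwp = 1.0 / (1.0 + np.exp(-(u - cfg.veg_boundary) / cfg.veg_blur_km))
    vegetation = np.where(rng.random(cfg.n) < p_mwp, "MWP", "MMW")
    elevation = cfg.elev_base + cfg.elev_slope * u + rng.normal(0, cfg.elev_noise_sd, cfg.n)
    elevation = np.clip(np.round(elevation, 1), 0.0, None)

    nuc = cfg.nuclear_names
    kmat = np.column_stack([geno[name] for name in nuc])
    total_k = kmat.sum(axis=1) + (
        (geno["mito"] == "K").astype(float) if cfg.mito_locus else 0.0
    )
    copies = 2 * len(nuc) + (1 if cfg.mito_locus else 0)
    phenotype = np.where(
        total_k == 0, "eschscholtzii", np.where(total_k == copies, "klauberi", "hybrid")
    )

    table = pd.DataFrame(
        {
            "id": [f"sim{idx:04d}" for idx in range(cfg.n)],
            "lat": np.round(lat, 8),
            "lon": np.round(lon, 8),
            "elevation": elevation,
            "vegetation": vegetation,
            "phenotype": phenotype,
            "external_class": phenotype,
        }
    )
    loci: list[Locus] = []
    if cfg.mito_locus is not None:
        loci.append(Locus(cfg.mito_locus, 1, "mitochondrial"))
        table["mito"] = geno["mito"]
    for name in nuc:
        loci.append(Locus(name, 2, "nuclear"))
        table[name] = geno[name]
    return GenotypeDataset(
        loci=loci, table=table, provenance=f"simulate_zone(seed={cfg.seed})"
    )
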