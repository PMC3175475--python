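"""End-to-end orchestration: one configuration in, a result bundle out.

Stages: (1) load or simulate the dataset; (2) fit or fix the transect
heading; (3) per-locus, nuclear-consensus and all-locus tanh clines with
support limits, plus coincidence (shared-center) and concordance
(shared-width) LRTs; (4) Barton's (alpha, beta) per locus; (5) sliding-
window disequilibria; (6) hybrid classification; (7) habitat association
and habitat-and-cline tests with elevation summaries. Every stage's output
is written to the run directory and listed, with a SHA-256 checksum, in a
machine-readable manifest. Output is a pure function of (input, config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as czio
from .classify import classify_by_q, genotype_class_posterior, CLASSES
from .cline import fit_cline, fit_shared_and_test
from .concordance import fit_concordance, hybrid_index
from .disequilibrium import ld_scan
from .habitat import elevation_summary, fit_habitat_cline_and_test, habitat_association_test
from .io import GenotypeDataset, read_individual_table, write_individual_table
from .simulate import SimConfig, simulate_zone
from .transect import fit_orientation, project_positions, cline_observations

RESULT_FILES = (
    "dataset.tsv",
    "orientation.json",
    "cline_fits.tsv",
    "coincidence_tests.json",
    "concordance.tsv",
    "ld_windows.tsv",
    "classifications.tsv",
    "habitat.json",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` / ``sim`` must be set. ``heading`` is
    either the string ``"fit"`` (estimate by ML) or a fixed compass heading
    in degrees. Window and step are in meters, as conventionally quoted;
    they are converted to km internally.
    """

    outdir: str | Path
    input_path: str | Path | None = None
    sim: SimConfig | None = None
    schema: dict | str | None = None
    heading: float | str = "fit"
    window_m: float = 200.0
    step_m: float = 100.0
    min_n: int = 5
    threshold_mode: str = "printed"
    q_source: str = "hybrid-index"  # or "column"
    covariates: tuple[str, ...] = ("vegetation", "elevation")
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("exactly one of input_path / sim must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim = raw["sim"]
            if "strip" in sim:
                sim["strip"] = tuple(sim["strip"])
            raw["sim"] = SimConfig(**sim)
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


def _round12(obj: Any) -> Any:
    return czio._jsonable(obj)


def _write_json(payload: Any, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(_round12(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _clinefit_row(name: str, fit, alpha=None, beta=None) -> dict:
    return {
        "locus": name,
        "n_obs": fit.n_obs,
        "center": fit.center,
        "center_lo": fit.support_center[0] if fit.support_center else np.nan,
        "center_hi": fit.support_center[1] if fit.support_center else np.nan,
        "width": fit.width,
        "width_lo": fit.support_width[0] if fit.support_width else np.nan,
        "width_hi": fit.support_width[1] if fit.support_width else np.nan,
        "loglik": fit.loglik,
        "alpha": np.nan if alpha is None else alpha,
        "beta": np.nan if beta is None else beta,
    }


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the manifest dict (also written to disk).

    Any stage failure raises with the stage name; outputs of completed
    stages are preserved in the run directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if config.sim is not None:
            dataset = simulate_zone(config.sim)
        else:
            dataset = read_individual_table(config.input_path, config.schema)
        write_individual_table(dataset, outdir / "dataset.tsv")

        stage = "orientation"
        if config.heading == "fit":
            orient = fit_orientation(dataset, grid=1.0)
            heading = orient.heading
            orientation_payload = {
                "heading": orient.heading,
                "support": list(orient.support),
                "loglik": orient.loglik,
                "directions_agree": orient.directions_agree,
                "per_locus_direction": orient.per_locus_direction,
                "fitted": True,
            }
        else:
            heading = float(config.heading)
            orientation_payload = {"heading": heading, "fitted": False}
        _write_json(orientation_payload, outdir / "orientation.json")

        stage = "cline_fits"
        projected = project_positions(dataset, heading)
        obs = cline_observations(projected, "all")
        nuclear_names = [l.name for l in dataset.nuclear_loci]
        rows = []
        per_locus = {}
        for name in obs:
            per_locus[name] = fit_cline(obs[name], share=[name])
        all_fit = fit_cline(obs, share=list(obs))
        nuc_fit = (
            fit_cline(obs, share=nuclear_names) if len(nuclear_names) > 1 else None
        )

        stage = "concordance"
        conc = {}
        for name in obs:
            try:
                conc[name] = fit_concordance(dataset, name)
            except ValueError:
                conc[name] = None
        rows.append(_clinefit_row("all_loci", all_fit))
        if nuc_fit is not None:
            rows.append(_clinefit_row("all_nuclear", nuc_fit))
        for name in obs:
            c = conc[name]
            rows.append(
                _clinefit_row(
                    name,
                    per_locus[name],
                    alpha=None if c is None else c.alpha,
                    beta=None if c is None else c.beta,
                )
            )
        czio.write_results(pd.DataFrame(rows), outdir / "cline_fits.tsv", "tsv")
        conc_rows = [
            {
                "locus": name,
                "alpha": c.alpha,
                "beta": c.beta,
                "loglik": c.loglik,
                "G": c.lrt.G,
                "df": c.lrt.df,
                "p": c.lrt.p,
                "n_individuals": c.n_individuals,
            }
            for name, c in conc.items()
            if c is not None
        ]
        czio.write_results(pd.DataFrame(conc_rows), outdir / "concordance.tsv", "tsv")

        stage = "coincidence_tests"
        tests = {}
        for shared in ("center", "width"):
            t = fit_shared_and_test(obs, shared)
            tests[f"shared_{shared}"] = {
                "G": t.lrt.G,
                "df": t.lrt.df,
                "p": t.lrt.p,
                "shared_value": t.shared_fit.center
                if shared == "center"
                else t.shared_fit.width,
                "loci": list(t.shared_fit.loci),
            }
        if dataset.mito_locus is not None and len(nuclear_names) >= 1 and nuc_fit:
            mt_fit = per_locus[dataset.mito_locus.name]
            tests["mt_vs_nuclear_center_offset_km"] = mt_fit.center - nuc_fit.center
        _write_json(tests, outdir / "coincidence_tests.json")

        stage = "classification"
        hi = hybrid_index(dataset, "nuclear")
        kmat = dataset.k_counts().to_numpy()
        cls_rows = []
        ext = dataset.table["external_class"]
        for i, ind_id in enumerate(dataset.table["id"]):
            if config.q_source == "column" and pd.notna(ext.iloc[i]):
                q_val = ext.iloc[i]
                q = None
            else:
                q = hi["HI"].iloc[i]
            row: dict[str, Any] = {"id": ind_id}
            if q is not None and not np.isnan(q):
                qc = classify_by_q(q, len(nuclear_names), config.threshold_mode)
                row["q"] = qc.q
                row["q_class"] = qc.label
            else:
                row["q"] = np.nan
                row["q_class"] = str(ext.iloc[i]) if pd.notna(ext.iloc[i]) else "missing"
            try:
                post = genotype_class_posterior(kmat[i])
                for c in CLASSES:
                    row[f"p_{c}"] = post.probabilities[c]
                row["map_class"] = post.map_class()
            except ValueError:
                row["map_class"] = "missing"
            cls_rows.append(row)
        czio.write_results(pd.DataFrame(cls_rows), outdir / "classifications.tsv", "tsv")

        stage = "ld_scan"
        ld = ld_scan(
            projected,
            window=config.window_m / 1000.0,
            step=config.step_m / 1000.0,
            min_n=config.min_n,
        )
        czio.write_results(ld, outdir / "ld_windows.tsv", "tsv")

        stage = "habitat"
        habitat_payload: dict[str, Any] = {}
        cls_series = pd.DataFrame(cls_rows)["q_class"]
        try:
            assoc = habitat_association_test(cls_series, dataset.table["vegetation"])
            habitat_payload["association"] = {
                "statistic": assoc.statistic,
                "df": assoc.df,
                "p": assoc.p,
                "low_expected": assoc.low_expected,
            }
        except ValueError as exc:
            habitat_payload["association"] = {"error": str(exc)}
        for cov in config.covariates:
            try:
                fitc = fit_habitat_cline_and_test(projected, cov)
                habitat_payload[f"cline_{cov}"] = {
                    "effect": fitc.effect,
                    "loglik": fitc.loglik,
                    "cline_only_loglik": fitc.cline_only.loglik,
                    "G": fitc.lrt.G,
                    "df": fitc.lrt.df,
                    "p": fitc.lrt.p,
                }
            except ValueError as exc:
                habitat_payload[f"cline_{cov}"] = {"error": str(exc)}
        try:
            elev = elevation_summary(dataset, cls_series)
            habitat_payload["elevation"] = {
                "per_class": elev.per_class.reset_index().to_dict(orient="records"),
                "F": elev.F,
                "df": list(elev.df),
                "p": elev.p,
            }
        except ValueError as exc:
            habitat_payload["elevation"] = {"error": str(exc)}
        _write_json(habitat_payload, outdir / "habitat.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    manifest = {
        "config": _round12(
            {
                **{
                    k: (str(v) if isinstance(v, Path) else v)
                    for k, v in dataclasses.asdict(config).items()
                    if k != "sim"
                },
                "sim": dataclasses.asdict(config.sim) if config.sim else None,
            }
        ),
        "files": {
            name: {"sha256": _sha256(outdir / name), "bytes": (outdir / name).stat().st_size}
            for name in RESULT_FILES
            if (outdir / name).exists()
        },
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
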