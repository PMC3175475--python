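"""Reading, validating and writing per-individual genotype tables and result records.

The canonical input is a tab-separated table with one row per individual:
geographic coordinates, elevation, a vegetation-series label, a field
phenotype class, optional external classification labels, one haploid
mitochondrial marker column and two allele columns per diploid nuclear
locus. Alleles are coded ``E`` / ``K`` for the two parental taxa; ``-9``
marks missing data. Column names are mapped through a schema dict (or YAML
file) so differently labelled tables can be adapted.

Internally each diploid genotype is collapsed to a count of K alleles
(0, 1, 2 or missing), which is sufficient for every downstream analysis of
diagnostic markers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("clinezone")

VALID_ALLELES = {"E", "K"}
MISSING_CODES = {"-9", "", "NA", "NAN"}

#: column layout written by :func:`write_individual_table` and produced by the
#: simulator; doubles as the default read schema.
DEFAULT_SCHEMA: dict[str, Any] = {
    "id": "id",
    "lat": "latitude",
    "lon": "longitude",
    "elevation": "elevation",
    "vegetation": "vegetation",
    "phenotype": "phenotype",
    "external_class": "external_class",
    "mito": {"locus": "ND4", "column": "ND4"},
    "nuclear": [
        {"locus": "CXCR4", "alleles": ["CXCR4_1", "CXCR4_2"]},
        {"locus": "SLC8A3", "alleles": ["SLC8A3_1", "SLC8A3_2"]},
        {"locus": "RAG1", "alleles": ["RAG1_1", "RAG1_2"]},
    ],
}


class SchemaError(ValueError):
    """A required column is absent or the schema itself is malformed."""


class RowError(ValueError):
    """A row-level validation failure, carrying the offending individual id."""


@dataclass(frozen=True)
class Locus:
    """A diagnostic marker: diploid nuclear or haploid mitochondrial."""

    name: str
    ploidy: int
    role: str  # "nuclear" | "mitochondrial"

    def __post_init__(self) -> None:
        if self.role == "mitochondrial" and self.ploidy != 1:
            raise ValueError(f"mitochondrial locus {self.name} must have ploidy 1")
        if self.role == "nuclear" and self.ploidy != 2:
            raise ValueError(f"nuclear locus {self.name} must have ploidy 2")
        if self.role not in {"nuclear", "mitochondrial"}:
            raise ValueError(f"unknown locus role {self.role!r}")


#: canonical per-individual columns preceding the genotype columns
META_COLUMNS = ["id", "lat", "lon", "elevation", "vegetation", "phenotype", "external_class"]


@dataclass
class GenotypeDataset:
    """Individuals with coordinates, habitat covariates and diagnostic genotypes.

    ``table`` holds one row per individual with the :data:`META_COLUMNS`, a
    ``mito`` column (``"E"``/``"K"``/NaN) when a mitochondrial locus is
    present, and one float column per nuclear locus containing the K-allele
    count (0, 1, 2 or NaN).
    """

    loci: list[Locus]
    table: pd.DataFrame
    provenance: str = ""
    elevation_range: tuple[float, float] = (0.0, 5000.0)

    def __post_init__(self) -> None:
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        if not self.nuclear_loci:
            raise ValueError("dataset needs at least one nuclear locus")
        if sum(loc.role == "mitochondrial" for loc in self.loci) > 1:
            raise ValueError("at most one mitochondrial locus")
        missing = [c for c in META_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"table lacks columns {missing}")
        for loc in self.nuclear_loci:
            if loc.name not in self.table.columns:
                raise SchemaError(f"table lacks genotype column for locus {loc.name}")
        if self.mito_locus is not None and "mito" not in self.table.columns:
            raise SchemaError("table lacks 'mito' column for the mitochondrial locus")
        ids = self.table["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise RowError(f"duplicate individual id {dup!r}")
        elev = pd.to_numeric(self.table["elevation"], errors="coerce")
        lo, hi = self.elevation_range
        bad = elev.dropna()[(elev.dropna() < lo) | (elev.dropna() > hi)]
        if len(bad):
            raise RowError(
                f"elevation outside plausible range {self.elevation_range}: "
                f"ids {list(self.table.loc[bad.index, 'id'])[:5]}"
            )

    @property
    def nuclear_loci(self) -> list[Locus]:
        return [loc for loc in self.loci if loc.role == "nuclear"]

    @property
    def mito_locus(self) -> Locus | None:
        for loc in self.loci:
            if loc.role == "mitochondrial":
                return loc
        return None

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    def k_counts(self) -> pd.DataFrame:
        """K-allele counts per nuclear locus (columns ordered as ``loci``)."""
        return self.table[[loc.name for loc in self.nuclear_loci]].astype(float)

    def mito_k(self) -> pd.Series:
        """Mitochondrial K indicator (1.0 for K, 0.0 for E, NaN missing)."""
        if self.mito_locus is None:
            raise ValueError("dataset has no mitochondrial locus")
        return self.table["mito"].map({"K": 1.0, "E": 0.0}).astype(float)

    def n_complete(self) -> int:
        """Individuals scored at every nuclear locus and (if present) mtDNA."""
        ok = self.k_counts().notna().all(axis=1)
        if self.mito_locus is not None:
            ok &= self.table["mito"].isin(["E", "K"])
        return int(ok.sum())

    def equals(self, other: "GenotypeDataset") -> bool:
        if [dataclasses.astuple(l) for l in self.loci] != [
            dataclasses.astuple(l) for l in other.loci
        ]:
            return False
        a, b = self.table.reset_index(drop=True), other.table.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                if not np.allclose(
                    x.astype(float), y.astype(float), rtol=0, atol=1e-9, equal_nan=True
                ):
                    return False
            elif not (x.fillna("\0") == y.fillna("\0")).all():
                return False
        return True


def _canon_allele(raw: Any) -> str | None:
    """Canonicalize one allele code; None means missing. Unknown codes -> None + warning."""
    s = str(raw).strip().upper()
    if s in MISSING_CODES or s == "NONE":
        return None
    if s not in VALID_ALLELES:
        logger.warning("unassignable allele code %r coerced to missing", raw)
        return None
    return s


def load_schema(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        schema = source
    else:
        with open(source) as fh:
            schema = yaml.safe_load(fh)
    for key in ("id", "lat", "lon", "nuclear"):
        if key not in schema:
            raise SchemaError(f"schema is missing required key {key!r}")
    return schema


def read_individual_table(
    path: str | Path,
    schema: str | Path | dict | None = None,
    *,
    elevation_range: tuple[float, float] = (0.0, 5000.0),
) -> GenotypeDataset:
    """Read a delimited per-individual genotype table into a :class:`GenotypeDataset`.

    Each pair of nuclear allele columns is collapsed to a K-allele count; any
    allele coded ``-9``, or any code outside {E, K}, makes that locus missing
    for that individual. Row order is preserved.
    """
    schema = load_schema(DEFAULT_SCHEMA if schema is None else schema)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def col(key: str, optional: bool = False) -> str | None:
        name = schema.get(key)
        if name is None:
            if optional:
                return None
            raise SchemaError(f"schema does not name the {key!r} column")
        if name not in raw.columns:
            if optional:
                return None
            raise SchemaError(f"required column {name!r} absent from {path}")
        return name

    out = pd.DataFrame()
    out["id"] = raw[col("id")].astype(str)
    if out["id"].duplicated().any():
        dup = out["id"][out["id"].duplicated()].iloc[0]
        raise RowError(f"duplicate individual id {dup!r}")
    for key in ("lat", "lon"):
        c = col(key)
        vals = pd.to_numeric(raw[c], errors="coerce")
        bad = vals.isna() & ~raw[c].str.strip().str.upper().isin(MISSING_CODES)
        if bad.any():
            raise RowError(
                f"non-numeric {key} for id {out['id'][bad].iloc[0]!r}"
            )
        if vals.isna().any():
            raise RowError(
                f"missing {key} for id {out['id'][vals.isna()].iloc[0]!r}"
            )
        out[key] = vals
    c = col("elevation", optional=True)
    out["elevation"] = (
        pd.to_numeric(raw[c].replace(list(MISSING_CODES), np.nan), errors="coerce")
        if c
        else np.nan
    )
    for key, valid in (
        ("vegetation", {"MMW", "MWP"}),
        ("phenotype", {"eschscholtzii", "klauberi", "hybrid"}),
    ):
        c = col(key, optional=True)
        if c:
            vals = raw[c].str.strip()
            out[key] = vals.where(vals.isin(valid), np.nan)
        else:
            out[key] = np.nan
    c = col("external_class", optional=True)
    if c:
        vals = raw[c].str.strip()
        out["external_class"] = vals.where(~vals.str.upper().isin(MISSING_CODES), np.nan)
    else:
        out["external_class"] = np.nan

    loci: list[Locus] = []
    mito_cfg = schema.get("mito")
    if mito_cfg:
        mcol = mito_cfg["column"]
        if mcol not in raw.columns:
            raise SchemaError(f"required column {mcol!r} absent from {path}")
        loci.append(Locus(mito_cfg.get("locus", mcol), 1, "mitochondrial"))
        out["mito"] = raw[mcol].map(lambda a: _canon_allele(a) or np.nan)
    for nuc in schema["nuclear"]:
        name = nuc["locus"]
        c1, c2 = nuc["alleles"]
        for c in (c1, c2):
            if c not in raw.columns:
                raise SchemaError(f"required column {c!r} absent from {path}")
        loci.append(Locus(name, 2, "nuclear"))
        a1 = raw[c1].map(_canon_allele)
        a2 = raw[c2].map(_canon_allele)
        count = (a1 == "K").astype(float) + (a2 == "K").astype(float)
        count[a1.isna() | a2.isna()] = np.nan
        out[name] = count

    # order loci mito-last in table columns but keep declaration order in `loci`
    return GenotypeDataset(
        loci=loci,
        table=out,
        provenance=f"read from {path}",
        elevation_range=elevation_range,
    )


def write_individual_table(dataset: GenotypeDataset, path: str | Path) -> Path:
    """Write a dataset back to the two-allele-columns-per-locus TSV layout."""
    path = Path(path)
    t = dataset.table
    out = pd.DataFrame()
    out["id"] = t["id"]
    out["latitude"] = t["lat"].map(lambda v: _fmt_real(v))
    out["longitude"] = t["lon"].map(lambda v: _fmt_real(v))
    out["elevation"] = t["elevation"].map(lambda v: "-9" if pd.isna(v) else _fmt_real(v))
    for key in ("vegetation", "phenotype", "external_class"):
        out[key] = t[key].fillna("-9")
    if dataset.mito_locus is not None:
        out[dataset.mito_locus.name] = t["mito"].fillna("-9")
    for loc in dataset.nuclear_loci:
        k = t[loc.name]
        out[f"{loc.name}_1"] = np.where(k.isna(), "-9", np.where(k >= 1, "K", "E"))
        out[f"{loc.name}_2"] = np.where(k.isna(), "-9", np.where(k >= 2, "K", "E"))
    out.to_csv(path, sep="\t", index=False)
    return path


def schema_for(dataset: GenotypeDataset) -> dict:
    """Schema matching :func:`write_individual_table` output for this dataset."""
    sch: dict[str, Any] = {
        "id": "id",
        "lat": "latitude",
        "lon": "longitude",
        "elevation": "elevation",
        "vegetation": "vegetation",
        "phenotype": "phenotype",
        "external_class": "external_class",
        "nuclear": [
            {"locus": loc.name, "alleles": [f"{loc.name}_1", f"{loc.name}_2"]}
            for loc in dataset.nuclear_loci
        ],
    }
    if dataset.mito_locus is not None:
        sch["mito"] = {"locus": dataset.mito_locus.name, "column": dataset.mito_locus.name}
    return sch


def _fmt_real(v: float) -> str:
    """Format a real to 12 significant digits (round-trip safe at that precision)."""
    return format(float(v), ".12g")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else float(_fmt_real(v))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return [_jsonable(rec) for rec in obj.to_dict(orient="records")]
    if obj is None or isinstance(obj, (str, bool)):
        return obj
    return str(obj)


def write_results(results: Any, path: str | Path, format: str = "tsv") -> Path:
    """Write a non-empty set of result records as TSV or JSON.

    Round-trip safe: labels and integers exactly, reals to 12 significant
    digits. ``results`` may be a DataFrame, a dataclass, or a sequence of
    dataclasses/dicts.
    """
    path = Path(path)
    if results is None:
        raise ValueError("empty result set")
    if isinstance(results, pd.DataFrame):
        if results.empty:
            raise ValueError("empty result set")
        records = results
    elif dataclasses.is_dataclass(results) and not isinstance(results, type):
        records = pd.DataFrame([_jsonable(results)])
    else:
        seq = list(results)
        if not seq:
            raise ValueError("empty result set")
        records = pd.DataFrame([_jsonable(r) for r in seq])
    if format == "tsv":
        records.to_csv(path, sep="\t", index=False, float_format="%.12g")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(records), fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_results(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown format {format!r}")
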