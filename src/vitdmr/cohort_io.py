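"""Cohort table and results I/O with a fixed column contract.

Cohorts travel as tab-separated text with a header, "." as the missing
token, and genotypes stored as integer raising-allele dosages; a JSON
sidecar records the generating preset and seed.  Genotypes can also be
ingested from biallelic VCF (GT fields), with the raising allele
resolved against REF/ALT per site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, SchemaError

__all__ = [
    "CohortFileSchema",
    "schema_for_cohort",
    "read_cohort",
    "write_cohort",
    "read_vcf_dosages",
    "write_results",
    "RESULTS_SCHEMA_VERSION",
]

RESULTS_SCHEMA_VERSION = "1.0"
DELIMITER = "\t"
MISSING_TOKEN = "."

BASE_COVARIATES = [
    "age", "sex", "current_smoker", "current_drinker", "day_of_year",
    "season", "region", "sbp", "low_physical_activity", "bmi",
]
LIPID_COLUMNS = ["tc", "ldl", "hdl", "tg", "apoa", "apob"]


@dataclass
class CohortFileSchema:
    """Ordered column contract for a cohort TSV."""

    snp_ids: list[str]
    endpoints: list[str]
    lipids: list[str] = field(default_factory=lambda: list(LIPID_COLUMNS))
    delimiter: str = DELIMITER
    missing_token: str = MISSING_TOKEN

    @property
    def columns(self) -> list[str]:
        cols = ["subject_id"]
        cols += [f"dosage_{s}" for s in self.snp_ids]
        cols += ["exposure_25ohd"]
        cols += BASE_COVARIATES
        for ep in self.endpoints:
            cols += [f"time_{ep}", f"event_{ep}"]
        cols += self.lipids
        return cols


def schema_for_cohort(cohort: pd.DataFrame) -> CohortFileSchema:
    """Infer the schema from a simulated cohort's columns."""
    snps = [c[len("dosage_"):] for c in cohort.columns if c.startswith("dosage_")]
    eps = [c[len("time_"):] for c in cohort.columns if c.startswith("time_")]
    lipids = [c for c in LIPID_COLUMNS if c in cohort.columns]
    return CohortFileSchema(snp_ids=snps, endpoints=eps, lipids=lipids)


def write_cohort(
    cohort: pd.DataFrame, path, schema: CohortFileSchema | None = None
) -> Path:
    """Write the analysis view of a cohort (drops ``latent_u``) plus a
    provenance sidecar recording preset and seed when available."""
    path = Path(path)
    schema = schema or schema_for_cohort(cohort)
    missing = [c for c in schema.columns if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort lacks required column(s): {missing}")
    out = cohort[schema.columns]
    out.to_csv(path, sep=schema.delimiter, index=False, na_rep=schema.missing_token)
    meta = cohort.attrs.get("scenario")
    if meta is not None:
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    return path


def _check_numeric(df: pd.DataFrame, col: str) -> pd.Series:
    raw = df[col]
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(f"non-numeric cell in column {col!r}, row {row}")
    if num.isna().any():
        row = int(num.isna().idxmax())
        raise SchemaError(f"missing value in column {col!r}, row {row}")
    return num


def read_cohort(path, schema: CohortFileSchema) -> pd.DataFrame:
    """Read and validate a cohort TSV against its schema.

    Dosages must be integral in {0,1,2}, follow-up times positive and
    event flags 0/1; any violation raises SchemaError naming the row and
    column, and no partially validated table is returned.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=schema.delimiter, na_values=[schema.missing_token],
        keep_default_na=False, dtype=str,
    )
    for col in schema.columns:
        n = (df.columns == col).sum()
        if n == 0:
            raise SchemaError(f"missing required column {col!r}")
        if n > 1:
            raise SchemaError(f"duplicated column {col!r}")
    out = pd.DataFrame(index=df.index)
    for col in schema.columns:
        num = _check_numeric(df, col)
        if col.startswith("dosage_"):
            if not np.isin(num.to_numpy(), [0.0, 1.0, 2.0]).all():
                row = int(num.index[~num.isin([0.0, 1.0, 2.0])][0])
                raise SchemaError(f"dosage outside {{0,1,2}} in {col!r}, row {row}")
            out[col] = num.astype(np.int8)
        elif col.startswith("time_"):
            if (num <= 0).any():
                row = int(num.index[num <= 0][0])
                raise SchemaError(f"nonpositive follow-up in {col!r}, row {row}")
            out[col] = num.astype(float)
        elif col.startswith("event_"):
            if not num.isin([0.0, 1.0]).all():
                row = int(num.index[~num.isin([0.0, 1.0])][0])
                raise SchemaError(f"event flag not 0/1 in {col!r}, row {row}")
            out[col] = num.astype(np.int8)
        elif col in ("subject_id", "sex", "current_smoker", "current_drinker",
                     "season", "region", "low_physical_activity", "day_of_year"):
            out[col] = num.astype(np.int64)
        else:
            out[col] = num.astype(float)
    return out


def read_vcf_dosages(path, snp_ids: list[str], raising_alleles: list[str]) -> pd.DataFrame:
    """Raising-allele dosages from a biallelic VCF (GT fields).

    The raising allele may be REF or ALT; orientation is resolved per
    site.  Multiallelic sites, absent sites, and raising alleles not
    among REF/ALT are errors.
    """
    from cyvcf2 import VCF

    if len(snp_ids) != len(raising_alleles):
        raise InvalidParameterError("one raising allele per SNP id required")
    wanted = dict(zip(snp_ids, raising_alleles))
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    found: dict[str, np.ndarray] = {}
    for variant in vcf:
        vid = variant.ID
        if vid not in wanted:
            continue
        if len(variant.ALT) != 1:
            raise SchemaError(f"site {vid} is not biallelic")
        raising = wanted[vid]
        alt_dosage = np.array(
            [a + b for a, b, *_ in variant.genotypes], dtype=np.int8
        )
        if raising == variant.ALT[0]:
            found[vid] = alt_dosage
        elif raising == variant.REF:
            found[vid] = (2 - alt_dosage).astype(np.int8)
        else:
            raise SchemaError(
                f"raising allele {raising!r} for {vid} is neither "
                f"REF={variant.REF} nor ALT={variant.ALT[0]}"
            )
    missing = [s for s in snp_ids if s not in found]
    if missing:
        raise SchemaError(f"site(s) absent from VCF: {missing}")
    return pd.DataFrame({s: found[s] for s in snp_ids}, index=samples)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {"_type": "table", "records": _to_jsonable(obj.to_dict("records"))}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    return obj


def write_results(report: dict, path, format: str = "json") -> Path:
    """Serialise a (possibly nested) report of estimates.

    JSON output is schema-versioned and keeps full float precision;
    TSV output flattens nested keys into a two-column key/value table
    with >= 6 significant digits.
    """
    path = Path(path)
    if format == "json":
        doc = {"schema_version": RESULTS_SCHEMA_VERSION, "report": _to_jsonable(report)}
        path.write_text(json.dumps(doc, indent=2, allow_nan=True) + "\n")
    elif format == "tsv":
        rows = []

        def flatten(prefix, obj):
            if isinstance(obj, dict):
                for k, v in obj.items():
                    flatten(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (list, tuple, np.ndarray)):
                for i, v in enumerate(obj):
                    flatten(f"{prefix}[{i}]", v)
            elif isinstance(obj, pd.DataFrame):
                flatten(prefix, _to_jsonable(obj))
            elif isinstance(obj, float) or isinstance(obj, np.floating):
                rows.append((prefix, f"{float(obj):.6g}"))
            else:
                rows.append((prefix, str(obj)))

        flatten("", _to_jsonable(report))
        lines = ["key\tvalue"] + [f"{k}\t{v}" for k, v in rows]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise InvalidParameterError(f"unknown results format {format!r}")
    return path


def read_results(path) -> dict:
    """Inverse of the JSON writer (used for round-trip checks)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != RESULTS_SCHEMA_VERSION:
        raise SchemaError("unsupported results schema version")
    return doc["report"]
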