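"""Readers and writers: phenotype tables, GRM formats, fit reports.

Phenotype tables are long-format CSV/TSV (one row per subject x visit).
Relatedness matrices travel either as a square CSV (first row and column
are subject IDs) or as a GCTA-style text pair: ``<prefix>.grm.id`` with
family and individual ID columns, and ``<prefix>.grm`` with 1-based
lower-triangle triplets (i, j, n_snps, relatedness). Fit reports are
written as JSON plus a TSV with one row per effect.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import VarianceComponentFit
from .relatedness import RelatednessMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TableSchema",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_grm",
    "write_grm",
    "write_fit_report",
    "read_fit_report",
]

NA_CODES = ["NA", "NaN", "nan", ""]


@dataclass(frozen=True)
class TableSchema:
    """Required columns and parsing conventions for a phenotype table."""

    required: tuple[str, ...] = ("subject_id", "family_id", "visit")
    delimiter: str | None = None  # None = infer from extension
    na_codes: tuple[str, ...] = tuple(NA_CODES)


def _delimiter_for(path: str, schema: TableSchema) -> str:
    if schema.delimiter:
        return schema.delimiter
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_phenotype_table(path, schema: TableSchema | None = None) -> pd.DataFrame:
    """Read and validate a long-format phenotype table.

    Missing-value codes become NaN (never 0); duplicate (subject, visit)
    rows are an error listing the offenders.
    """
    schema = schema or TableSchema()
    df = pd.read_csv(
        path,
        sep=_delimiter_for(path, schema),
        na_values=list(schema.na_codes),
        keep_default_na=False,
        dtype={c: str for c in ("subject_id", "family_id")},
    )
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    dup_mask = df.duplicated(subset=["subject_id", "visit"], keep=False)
    if dup_mask.any():
        offenders = (
            df.loc[dup_mask, ["subject_id", "visit"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValueError(f"{path}: duplicated (subject, visit) rows: {offenders}")
    logger.info("read %d observation rows from %s", len(df), path)
    return df


def write_phenotype_table(df: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_grm(path_or_prefix, source: str | None = None) -> RelatednessMatrix:
    """Read a relatedness matrix (square CSV or GCTA-style prefix).

    ``source`` forces the label; by default a matrix whose entries all sit
    on the kinship grid {0, 0.5, 1} with unit diagonal is labeled
    "kinship", anything else "snp".
    """
    p = str(path_or_prefix)
    if os.path.exists(p) and not os.path.isdir(p):
        ids, V = _read_square_csv(p)
    elif os.path.exists(p + ".grm") and os.path.exists(p + ".grm.id"):
        ids, V = _read_gcta(p)
    else:
        raise FileNotFoundError(
            f"no GRM at {p!r}: expected a square CSV file or the pair "
            f"{p}.grm + {p}.grm.id"
        )
    if source is None:
        on_grid = np.isin(V, (0.0, 0.5, 1.0)).all() and (np.diag(V) == 1.0).all()
        source = "kinship" if on_grid else "snp"
    return RelatednessMatrix(ids=ids, values=V, source=source)


def _read_square_csv(path):
    raw = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in raw.columns]
    row_ids = [str(i) for i in raw.index]
    if ids != row_ids:
        raise ValueError(f"{path}: row and column subject IDs differ")
    V = raw.to_numpy(dtype=float)
    if not np.allclose(V, V.T, atol=1e-8, rtol=0):
        raise ValueError(f"{path}: square CSV GRM asymmetric beyond 1e-8")
    return ids, (V + V.T) / 2.0


def _read_gcta(prefix):
    id_df = pd.read_csv(
        prefix + ".grm.id", sep=r"\s+", header=None, dtype=str
    )
    if id_df.shape[1] < 2:
        raise ValueError(f"{prefix}.grm.id: expected two whitespace columns")
    ids = id_df.iloc[:, 1].tolist()
    n = len(ids)
    V = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    trip = pd.read_csv(prefix + ".grm", sep=r"\s+", header=None)
    if trip.shape[1] != 4:
        raise ValueError(f"{prefix}.grm: expected 4 columns (i, j, n_snps, value)")
    for i, j, _, val in trip.itertuples(index=False):
        i, j = int(i), int(j)
        if not (1 <= j <= i <= n):
            raise ValueError(
                f"{prefix}.grm: index pair ({i}, {j}) out of range for "
                f"{n} subjects (1-based lower triangle expected)"
            )
        V[i - 1, j - 1] = V[j - 1, i - 1] = float(val)
        seen[i - 1, j - 1] = True
    if not seen[np.tril_indices(n)].all():
        logger.warning("%s.grm: %d lower-triangle entries absent, taken as 0",
                       prefix, int((~seen[np.tril_indices(n)]).sum()))
    return ids, V


def write_grm(grm: RelatednessMatrix, path_or_prefix, fmt: str = "csv") -> None:
    """Write a GRM as a square CSV (fmt="csv") or GCTA pair (fmt="gcta")."""
    p = str(path_or_prefix)
    if fmt == "csv":
        pd.DataFrame(grm.values, index=grm.ids, columns=grm.ids).to_csv(p)
    elif fmt == "gcta":
        with open(p + ".grm.id", "w") as fh:
            for s in grm.ids:
                fh.write(f"{s}\t{s}\n")
        with open(p + ".grm", "w") as fh:
            for i in range(grm.n):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t0\t{grm.values[i, j]:.10g}\n")
    else:
        raise ValueError(f"fmt must be 'csv' or 'gcta', got {fmt!r}")


def intersect_with_grm(
    table: pd.DataFrame, grm: RelatednessMatrix
) -> tuple[pd.DataFrame, RelatednessMatrix]:
    """Restrict table and GRM to their common subjects (counts logged)."""
    tab_ids = set(table["subject_id"].astype(str))
    grm_ids = set(grm.ids)
    common = tab_ids & grm_ids
    if not common:
        raise ValueError("no subjects shared between phenotype table and GRM")
    if common != tab_ids or common != grm_ids:
        logger.warning(
            "subject intersection: %d in table, %d in GRM, %d shared",
            len(tab_ids), len(grm_ids), len(common),
        )
    table2 = table.loc[table["subject_id"].astype(str).isin(common)].copy()
    keep = [s for s in grm.ids if s in common]
    return table2, grm.subset(keep)


def fit_to_dict(fit: VarianceComponentFit) -> dict:
    return {
        "model": fit.model,
        "phenotype": fit.phenotype,
        "total_variance": fit.total_variance,
        "log_likelihood": fit.log_likelihood,
        "k": fit.k,
        "k_convention": fit.k_convention,
        "AIC": fit.aic,
        "ci_level": fit.ci_level,
        "n_obs": fit.n_obs,
        "n_families": fit.n_families,
        "fractions": fit.fractions,
        "ci": {e: list(v) for e, v in fit.ci.items()},
        "boundary_effects": list(fit.boundary_effects),
        "warnings": list(fit.warnings),
        "converged": fit.converged,
        "residual_checksum": fit.residual_checksum,
    }


def write_fit_report(fit: VarianceComponentFit, path_prefix) -> tuple[str, str]:
    """Write <prefix>.json and <prefix>.tsv; returns the two paths.

    The fraction sum-to-1 invariant is re-checked on write.
    """
    s = sum(fit.fractions.values())
    if abs(s - 1.0) > 1e-8:
        raise ValueError(f"refusing to write report: fractions sum to {s}")
    p = str(path_prefix)
    jpath, tpath = p + ".json", p + ".tsv"
    with open(jpath, "w") as fh:
        json.dump(fit_to_dict(fit), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(tpath, "w") as fh:
        fh.write(
            f"# model={fit.model}\tphenotype={fit.phenotype}\t"
            f"total_variance={fit.total_variance:.10g}\t"
            f"loglik={fit.log_likelihood:.10g}\tk={fit.k}\t"
            f"AIC={fit.aic:.10g}\tn_obs={fit.n_obs}\t"
            f"n_families={fit.n_families}\n"
        )
        fh.write("effect\tfraction\tci_low\tci_high\n")
        for e in fit.fractions:
            lo, hi = fit.ci.get(e, (float("nan"), float("nan")))
            fh.write(f"{e}\t{fit.fractions[e]:.10g}\t{lo:.10g}\t{hi:.10g}\n")
    return jpath, tpath


def read_fit_report(json_path) -> VarianceComponentFit:
    """Rehydrate a fit from its JSON report (without likelihood state)."""
    with open(json_path) as fh:
        d = json.load(fh)
    return VarianceComponentFit(
        model=d["model"],
        total_variance=d["total_variance"],
        fractions={e: float(v) for e, v in d["fractions"].items()},
        log_likelihood=d["log_likelihood"],
        k=d["k"],
        aic=d["AIC"],
        ci={e: tuple(v) for e, v in d["ci"].items()},
        ci_level=d["ci_level"],
        n_obs=d["n_obs"],
        n_families=d["n_families"],
        boundary_effects=tuple(d["boundary_effects"]),
        warnings=tuple(d["warnings"]),
        converged=d["converged"],
        residual_checksum=d["residual_checksum"],
        k_convention=d.get("k_convention", ""),
        phenotype=d.get("phenotype", ""),
    )
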