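"""Readers and writers for the plain-text formats the pipeline consumes.

All tables are UTF-8 TSV with a header row; gene sets travel as GMT.  Every
reader/writer pair is a lossless roundtrip on valid inputs, and readers never
silently drop rows: each exclusion (deduplication, filtering) is logged with
a count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DrugResponseTable,
    ExpressionMatrix,
    GeneSignature,
    MultiRegionCohort,
    MutationAnnotation,
    Scale,
    SurvivalTable,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file into one :class:`GeneSignature` per line.

    Duplicate genes within a line are removed preserving first occurrence
    (logged).  Raises on malformed lines (< 3 tab-separated fields) and on
    empty files.
    """
    path = Path(path)
    signatures: list[GeneSignature] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, provenance, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s:%d: removed %d duplicate genes from signature %s",
                    path, lineno, len(genes) - len(deduped), name,
                )
            signatures.append(GeneSignature(name=name, genes=tuple(deduped), provenance=provenance))
    if not signatures:
        raise ValueError(f"{path}: empty GMT file")
    return signatures


def write_gmt(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    """Write signatures as standard GMT (name, description, genes...)."""
    if not signatures:
        raise ValueError("cannot write an empty signature list")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.provenance or ".", *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression_tsv(
    path: str | Path,
    scale: Scale | str,
    cohort_row: str | None = None,
) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene ids, header sample ids).

    Duplicate gene ids are resolved by keeping the row with the maximum mean
    value across the cohort; the exclusions are logged.  Duplicate sample ids
    and non-numeric cells are errors.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) < len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    cohort = None
    if cohort_row is not None:
        if cohort_row not in df.index:
            raise ValueError(f"{path}: cohort row {cohort_row!r} not found")
        cohort = df.loc[cohort_row].astype(str)
        df = df.drop(index=cohort_row)
    non_numeric = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        where = f"gene {bad.index[0]!r}, sample {col!r}" if len(bad) else f"sample {col!r}"
        raise ValueError(f"{path}: non-numeric value at {where}")
    if df.index.has_duplicates:
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        kept = df.iloc[order][~df.index[order].duplicated(keep="first")]
        kept = kept.loc[df.index.unique()]  # restore original gene order
        logger.warning(
            "%s: %d duplicate gene-id rows resolved by maximum mean expression",
            path, len(df) - len(kept),
        )
        df = kept
    return ExpressionMatrix(values=df.astype(float), scale=Scale(scale), cohort=cohort)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(Path(path), sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Mutation tables


def read_mutation_tsv(
    path: str | Path, pathway_genes: Sequence[str] | None = None
) -> MutationAnnotation:
    """Read a minimal MAF-like TSV: sample, gene, altered(0/1), genotype."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str})
    required = {"sample", "gene", "altered"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: requires columns {sorted(required)}")
    if not set(pd.unique(df["altered"])) <= {0, 1}:
        raise ValueError(f"{path}: altered must be 0/1")
    if "genotype" in df.columns:
        df["genotype"] = df["genotype"].replace({".": pd.NA, "": pd.NA})
    return MutationAnnotation(
        table=df, pathway_genes=tuple(pathway_genes) if pathway_genes else None
    )


def write_mutation_tsv(mutations: MutationAnnotation, path: str | Path) -> None:
    out = mutations.table.copy()
    out["altered"] = out["altered"].astype(int)
    out["genotype"] = out["genotype"].fillna(".")
    out.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical / survival tables


def read_clinical_tsv(path: str | Path) -> SurvivalTable:
    """Read a clinical TSV: sample, time, event, plus covariate columns.

    Missing covariate values are kept as NA (flagged, never imputed).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="sample")
    if "time" not in df.columns or "event" not in df.columns:
        raise ValueError(f"{path}: requires 'time' and 'event' columns")
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0][0]
        raise ValueError(f"{path}: non-positive time for sample {bad!r}")
    if not set(pd.unique(df["event"])) <= {0, 1}:
        raise ValueError(f"{path}: event must be 0/1")
    n_missing = int(df.drop(columns=["time", "event"]).isna().sum().sum())
    if n_missing:
        logger.warning("%s: %d missing covariate values retained as NA", path, n_missing)
    return SurvivalTable(data=df)


def write_clinical_tsv(survival: SurvivalTable, path: str | Path) -> None:
    out = survival.data.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(Path(path), sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Drug response

def read_drug_response_tsv(
    values_path: str | Path, targets_path: str | Path | None = None
) -> DrugResponseTable:
    """Read a cell-line-by-drug response TSV plus an optional drug->category map.

    The target map is long-format TSV with columns ``drug`` and ``category``
    (one row per pair; a drug may carry zero or more categories).
    """
    values = pd.read_csv(Path(values_path), sep="\t", index_col=0)
    values.index.name = None
    values.columns.name = None
    target_map: dict[str, tuple[str, ...]] = {}
    if targets_path is not None:
        tm = pd.read_csv(Path(targets_path), sep="\t", dtype=str)
        if not {"drug", "category"} <= set(tm.columns):
            raise ValueError(f"{targets_path}: requires columns drug, category")
        for drug, grp in tm.groupby("drug", sort=False):
            target_map[drug] = tuple(grp["category"])
    return DrugResponseTable(values=values.astype(float), target_map=target_map)


def write_drug_response_tsv(
    table: DrugResponseTable, values_path: str | Path, targets_path: str | Path | None = None
) -> None:
    table.values.to_csv(Path(values_path), sep="\t", index_label="cell_line")
    if targets_path is not None:
        rows = [
            {"drug": d, "category": c}
            for d, cats in table.target_map.items()
            for c in cats
        ]
        pd.DataFrame(rows, columns=["drug", "category"]).to_csv(
            Path(targets_path), sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Multi-region cohort maps


def read_multiregion_tsv(path: str | Path) -> MultiRegionCohort:
    """Read a patient -> region-sample map (columns patient, sample)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if not {"patient", "sample"} <= set(df.columns):
        raise ValueError(f"{path}: requires columns patient, sample")
    regions = {p: tuple(grp["sample"]) for p, grp in df.groupby("patient", sort=False)}
    return MultiRegionCohort(regions=regions)


def write_multiregion_tsv(cohort: MultiRegionCohort, path: str | Path) -> None:
    rows = [{"patient": p, "sample": s} for p, ss in cohort.regions.items() for s in ss]
    pd.DataFrame(rows, columns=["patient", "sample"]).to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run manifests


def write_run_manifest(
    path: str | Path,
    command: str,
    inputs: Mapping[str, str] | None = None,
    parameters: Mapping[str, object] | None = None,
    seed: int | None = None,
) -> None:
    """Record what produced an output directory: inputs, parameters, seed."""
    from . import __version__

    manifest = {
        "command": command,
        "inputs": dict(inputs or {}),
        "parameters": {k: _jsonable(v) for k, v in (parameters or {}).items()},
        "seed": seed,
        "version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _jsonable(value: object) -> object:
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (tuple, set)):
        return list(value)
    if isinstance(value, Path):
        return str(value)
    return value
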