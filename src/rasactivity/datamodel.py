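"""Core typed containers shared by every stage of the pipeline.

The pipeline moves a small number of objects between stages: a gene-by-sample
expression matrix with an explicit normalization state, named gene signatures,
per-sample mutation annotations, activity groupings (the k=3 high/low split
used during signature derivation and the k=5 RAG stratification), survival
tables, drug-response tables and multi-region cohort maps.  All containers
validate their invariants on construction so that downstream code can assume
well-formed inputs.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ordered labels for the three-way split used during signature derivation
K3_LABELS = ("low", "unclassified", "high")


def rag_labels(k: int) -> tuple[str, ...]:
    """Ordered RAS-activity-group labels for a k-way stratification."""
    if k == 2:
        return ("low", "high")
    if k == 3:
        return K3_LABELS
    return tuple(f"RAG-{i}" for i in range(k))


class Scale(str, enum.Enum):
    """Normalization state of an expression matrix."""

    raw_counts = "raw_counts"
    vst_like = "vst_like"
    zscore = "zscore"


def _check_unique(ids: Sequence[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric matrix with an explicit normalization state.

    ``values`` is indexed by gene id (rows) and sample id (columns).  Raw
    counts must be non-negative and finite; transformed scales must be finite.
    ``cohort`` optionally maps each sample to a cohort label (used by the
    pan-cancer analysis).
    """

    values: pd.DataFrame
    scale: Scale
    cohort: pd.Series | None = None

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite values not allowed at scale {self.scale.value}")
        if self.scale is Scale.raw_counts and (arr < 0).any():
            raise ValueError("raw counts must be >= 0")
        if self.cohort is not None:
            missing = self.values.columns.difference(self.cohort.index)
            if len(missing):
                raise ValueError(f"cohort labels missing for samples: {list(missing)[:5]}")
            self.cohort = self.cohort.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.scale, self.cohort)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        cohort = self.cohort.loc[list(samples)] if self.cohort is not None else None
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.scale, cohort)


@dataclass
class GeneSignature:
    """Named, ordered gene set (up-regulated direction by convention).

    ``parents`` optionally records, per gene, which founder signatures
    contributed it to a merged meta-signature.
    """

    name: str
    genes: tuple[str, ...]
    direction: str = "up"
    provenance: str = ""
    parents: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        _check_unique(self.genes, f"genes in signature {self.name!r}")
        if self.direction != "up":
            raise ValueError("only up-regulated signatures are supported")

    def __len__(self) -> int:
        return len(self.genes)

    def present_in(self, expr: ExpressionMatrix) -> tuple[str, ...]:
        """Genes of this signature present in ``expr``; logs the missing ones."""
        present = tuple(g for g in self.genes if g in expr.gene_ids)
        n_missing = len(self.genes) - len(present)
        if n_missing:
            logger.warning(
                "signature %s: %d/%d genes absent from expression matrix",
                self.name, n_missing, len(self.genes),
            )
        return present


@dataclass
class MutationAnnotation:
    """Per-sample gene alteration calls with optional genotype strings.

    ``table`` holds one row per (sample, gene) pair with an ``altered``
    boolean and an optional ``genotype`` (e.g. an amino-acid change such as
    G12D).  Pairs absent from the table are treated as not altered, which
    conflates untested and wild-type -- a limitation of MAF-like inputs.
    ``pathway_genes`` optionally names the curated RAS-pathway gene set used
    for confounder exclusion and burden computation.
    """

    table: pd.DataFrame
    pathway_genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        required = {"sample", "gene", "altered"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"mutation table missing columns: {sorted(missing)}")
        tab = self.table.copy()
        if not set(pd.unique(tab["altered"])) <= {0, 1, True, False}:
            raise ValueError("altered must be 0/1")
        tab["altered"] = tab["altered"].astype(bool)
        if "genotype" not in tab.columns:
            tab["genotype"] = pd.NA
        bad = tab["genotype"].notna() & ~tab["altered"]
        if bad.any():
            raise ValueError(
                f"genotype present on {int(bad.sum())} non-altered rows (first: "
                f"{tab.loc[bad].iloc[0][['sample', 'gene']].tolist()})"
            )
        self.table = tab
        if self.pathway_genes is not None:
            self.pathway_genes = tuple(self.pathway_genes)

    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    def altered_mask(self, samples: Sequence[str], gene: str) -> pd.Series:
        """Boolean alteration status of ``gene`` for each of ``samples``."""
        sub = self.table[(self.table["gene"] == gene) & self.table["altered"]]
        altered = set(sub["sample"])
        return pd.Series([s in altered for s in samples], index=list(samples))

    def any_altered_mask(self, samples: Sequence[str], genes: Sequence[str]) -> pd.Series:
        sub = self.table[self.table["gene"].isin(list(genes)) & self.table["altered"]]
        altered = set(sub["sample"])
        return pd.Series([s in altered for s in samples], index=list(samples))

    def genotype_mask(self, samples: Sequence[str], gene: str, genotype: str) -> pd.Series:
        sub = self.table[
            (self.table["gene"] == gene)
            & self.table["altered"]
            & (self.table["genotype"] == genotype)
        ]
        carriers = set(sub["sample"])
        return pd.Series([s in carriers for s in samples], index=list(samples))

    def pathway_altered_other_than(
        self, samples: Sequence[str], allowed: str = "KRAS"
    ) -> pd.Series:
        """Samples with an alteration in a pathway gene other than ``allowed``."""
        if self.pathway_genes is None:
            raise ValueError("no pathway gene set attached")
        genes = [g for g in self.pathway_genes if g != allowed]
        return self.any_altered_mask(samples, genes)


@dataclass
class ActivityGrouping:
    """Per-sample activity-group labels plus the RAS index.

    Labels are an ordered categorical; order follows ascending per-group mean
    signature expression (low -> high for k=3, RAG-0 -> RAG-4 for k=5).  ``ri``
    is the per-sample mean signature-gene expression and ``group_mean_ri`` its
    per-group mean, ascending by construction.
    """

    labels: pd.Series
    ri: pd.Series
    group_mean_ri: pd.Series
    k: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not isinstance(self.labels.dtype, pd.CategoricalDtype):
            ordered = rag_labels(self.k)
            self.labels = pd.Series(
                pd.Categorical(self.labels, categories=ordered, ordered=True),
                index=self.labels.index,
            )
        if self.labels.isna().any():
            raise ValueError("every sample must carry exactly one label")
        if len(self.labels.cat.categories) != self.k:
            raise ValueError("label categories must match k")
        if not self.labels.index.equals(self.ri.index):
            raise ValueError("labels and RI must share a sample index")
        means = self.group_mean_ri.to_numpy()
        if not (np.diff(means) >= 0).all():
            raise ValueError("group mean RI must ascend with label order")

    @property
    def samples(self) -> pd.Index:
        return self.labels.index

    def samples_with(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


@dataclass
class SurvivalTable:
    """Per-sample survival times (days), event indicators and covariates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival table requires a {col!r} column")
        t = self.data["time"].to_numpy(dtype=float)
        if not np.isfinite(t).all() or (t <= 0).any():
            raise ValueError("survival times must be positive and finite")
        ev = pd.unique(self.data["event"])
        if not set(ev) <= {0, 1, True, False}:
            raise ValueError("event must be 0/1")
        self.data = self.data.assign(event=self.data["event"].astype(bool))
        _check_unique(self.data.index, "survival sample ids")
        _check_unique(self.data.columns, "covariate names")

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())


@dataclass
class DrugResponseTable:
    """Cell-line-by-drug response values (log IC50 or AUC; NaN allowed)."""

    values: pd.DataFrame  # cell lines x drugs
    target_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "cell line ids")
        _check_unique(self.values.columns, "drug ids")
        self.target_map = {d: tuple(c) for d, c in dict(self.target_map).items()}

    @property
    def drugs(self) -> pd.Index:
        return self.values.columns

    def categories_of(self, drug: str) -> tuple[str, ...]:
        return tuple(self.target_map.get(drug, ()))


@dataclass
class MultiRegionCohort:
    """Patient -> region-sample map, with optional per-gene variance classes.

    ``gene_variance`` may carry precomputed intra-/inter-tumour variance
    classifications (boolean columns ``low_intra`` and ``high_inter``) for the
    quadrant-enrichment analysis.
    """

    regions: Mapping[str, tuple[str, ...]]
    gene_variance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.regions = {p: tuple(r) for p, r in dict(self.regions).items()}
        all_samples: list[str] = []
        for patient, samples in self.regions.items():
            if len(samples) < 1:
                raise ValueError(f"patient {patient!r} has no regions")
            all_samples.extend(samples)
        _check_unique(all_samples, "region sample ids across patients")
        if self.gene_variance is not None:
            need = {"low_intra", "high_inter"}
            if not need <= set(self.gene_variance.columns):
                raise ValueError(f"gene_variance requires columns {sorted(need)}")

    @property
    def sample_ids(self) -> list[str]:
        return [s for samples in self.regions.values() for s in samples]

    def patient_of(self) -> pd.Series:
        pairs = {s: p for p, samples in self.regions.items() for s in samples}
        return pd.Series(pairs)
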