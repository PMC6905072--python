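"""Data containers and plain-text readers/writers.

Expression data travel as a genes x samples matrix of log2 intensities plus a
per-sample metadata table; lifespan assays travel as cumulative daily death
counts per (genotype, treatment); gene sets travel as GMT.  All formats are
tab-delimited text so that externally normalized microarray or RNA-seq data
can be dropped in without any binary tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("control", "heat", "recovery")
SPLITS = ("train", "test", "unassigned")

#: required columns of the sample-metadata table, in canonical order
META_COLUMNS = ("sample_id", "genotype", "treatment", "t_dev", "t_heat", "t_rec", "split")


class DataFormatError(ValueError):
    """Raised when an input file violates the interchange contract."""


@dataclass
class ExpressionDataset:
    """A log2 expression matrix (genes x samples) with per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene IDs), samples in columns (column labels =
        sample IDs), log2 intensity values.
    samples : pandas.DataFrame
        One row per sample, indexed by ``sample_id``, with columns
        ``genotype``, ``treatment`` (control/heat/recovery), ``t_dev`` (hours
        post age-synchronization), ``t_heat`` (hours at 35 C), ``t_rec``
        (hours of recovery at 20 C) and ``split`` (train/test/unassigned).
        Row order must match the column order of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.samples = pd.DataFrame(self.samples)
        if self.samples.index.name != "sample_id":
            if "sample_id" in self.samples.columns:
                self.samples = self.samples.set_index("sample_id")
            else:
                self.samples.index.name = "sample_id"
        validate_expression(self.values, self.samples)

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        """Restrict to ``gene_ids`` (kept in the given order)."""
        return ExpressionDataset(self.values.loc[list(gene_ids)], self.samples.copy())

    def subset_samples(self, mask) -> "ExpressionDataset":
        """Restrict to samples where ``mask`` (boolean per sample, or list of
        sample IDs) selects them."""
        arr = np.asarray(mask)
        if arr.dtype == bool:
            ids = self.sample_ids[arr]
        else:
            ids = pd.Index(arr)
        return ExpressionDataset(self.values[list(ids)], self.samples.loc[list(ids)].copy())

    def select(self, **conditions) -> "ExpressionDataset":
        """Restrict to samples whose metadata match all keyword conditions,
        e.g. ``select(treatment="heat", split="train")``.  A tuple/list value
        selects membership."""
        mask = np.ones(self.n_samples, dtype=bool)
        for key, val in conditions.items():
            col = self.samples[key]
            if isinstance(val, (tuple, list, set, frozenset)):
                mask &= col.isin(list(val)).to_numpy()
            else:
                mask &= (col == val).to_numpy()
        return self.subset_samples(mask)


def validate_expression(values: pd.DataFrame, samples: pd.DataFrame) -> None:
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise DataFormatError(f"duplicate gene ID {dup!r}")
    if values.columns.has_duplicates:
        dup = values.columns[values.columns.duplicated()][0]
        raise DataFormatError(f"duplicate sample ID {dup!r}")
    if list(values.columns) != list(samples.index):
        missing = [s for s in values.columns if s not in samples.index]
        if missing:
            raise DataFormatError(f"samples missing from metadata: {missing}")
        raise DataFormatError("metadata rows must match expression columns in order")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = values.columns[[not np.issubdtype(values[c].dtype, np.number) for c in values.columns]]
        raise DataFormatError(f"non-numeric expression values in columns {list(bad)}")
    if not np.isfinite(arr).all():
        g, s = np.argwhere(~np.isfinite(arr))[0]
        raise DataFormatError(
            f"non-finite expression value at gene {values.index[g]!r}, sample {values.columns[s]!r}"
        )
    missing_cols = [c for c in META_COLUMNS[1:] if c not in samples.columns]
    if missing_cols:
        raise DataFormatError(f"metadata missing required columns: {missing_cols}")
    bad_treat = set(samples["treatment"]) - set(TREATMENTS)
    if bad_treat:
        raise DataFormatError(f"unknown treatment labels: {sorted(bad_treat)}")
    bad_split = set(samples["split"]) - set(SPLITS)
    if bad_split:
        raise DataFormatError(f"unknown split labels: {sorted(bad_split)}")
    for sid, row in samples.iterrows():
        t, th, tr = row["treatment"], row["t_heat"], row["t_rec"]
        ok = (
            (t == "control" and th == 0 and tr == 0)
            or (t == "heat" and th > 0 and tr == 0)
            or (t == "recovery" and th > 0 and tr >= 0)
        )
        if not ok:
            raise DataFormatError(
                f"sample {sid!r}: treatment {t!r} inconsistent with t_heat={th}, t_rec={tr}"
            )


def read_expression(path, meta_path) -> ExpressionDataset:
    """Load a tab-delimited expression matrix (first column gene ID, header of
    sample IDs) together with its sample-metadata table."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad = values[pd.to_numeric(values[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise DataFormatError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r} in {path}"
            )
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "genotype": str})
    if "sample_id" not in meta.columns:
        raise DataFormatError(f"metadata file {meta_path} lacks a sample_id column")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise DataFormatError(f"duplicate sample ID {dup!r} in metadata")
    meta = meta.set_index("sample_id")
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise DataFormatError(f"samples missing from metadata: {missing}")
    meta = meta.loc[list(values.columns)]
    return ExpressionDataset(values, meta)


def write_expression(ds: ExpressionDataset, path, meta_path) -> None:
    out = ds.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
    ds.samples.reset_index().to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------

@dataclass
class SurvivalArm:
    """Event times for one (genotype, treatment) lifespan assay.

    ``event_times`` are integer days post age-synchronization (1-based);
    ``censored`` flags entries that are censoring times rather than deaths.
    """

    genotype: str
    treatment: str
    event_times: np.ndarray
    censored: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(len(self.event_times), dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if len(self.censored) != len(self.event_times):
            raise ValueError("censored flags must match event_times in length")
        if len(self.event_times) and self.event_times.min() < 1:
            raise ValueError("event days must be >= 1")

    @property
    def n_events(self) -> int:
        return int((~self.censored).sum())


@dataclass
class SurvivalTable:
    """Per-genotype, per-treatment lifespan assays keyed by (genotype, treatment)."""

    arms: dict = field(default_factory=dict)

    def add(self, arm: SurvivalArm) -> None:
        self.arms[(arm.genotype, arm.treatment)] = arm

    def get(self, genotype: str, treatment: str) -> SurvivalArm | None:
        return self.arms.get((genotype, treatment))

    def genotypes(self) -> list:
        return sorted({g for g, _ in self.arms})

    def __len__(self) -> int:
        return len(self.arms)


def read_survival_cumulative(path) -> SurvivalTable:
    """Load a lifespan table stored as cumulative death counts.

    Expected columns: ``genotype``, ``treatment``, then day columns (any names;
    column order is day order, day 1 first) holding non-decreasing cumulative
    numbers of dead animals.  Per-day deaths are recovered by first
    differences, and each death becomes one event time at that day.
    """
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str, "treatment": str})
    required = {"genotype", "treatment"}
    if not required.issubset(df.columns):
        raise DataFormatError(f"survival file {path} must have columns {sorted(required)}")
    day_cols = [c for c in df.columns if c not in required]
    if not day_cols:
        raise DataFormatError(f"survival file {path} has no day columns")
    table = SurvivalTable()
    for _, row in df.iterrows():
        cum = row[day_cols].to_numpy(dtype=float)
        if np.isnan(cum).any():
            cum = np.nan_to_num(cum, nan=0.0)
        deaths = np.diff(np.concatenate([[0.0], cum]))
        if (deaths < 0).any():
            day = int(np.argwhere(deaths < 0)[0][0]) + 1
            raise DataFormatError(
                f"decreasing cumulative death count for genotype {row['genotype']!r} at day {day}"
            )
        days = np.repeat(np.arange(1, len(cum) + 1), deaths.astype(int))
        if len(days) == 0:
            logger.warning(
                "survival row (%s, %s) has zero deaths; unusable for statistics",
                row["genotype"], row["treatment"],
            )
        table.add(SurvivalArm(str(row["genotype"]), str(row["treatment"]), days))
    return table


def write_survival_cumulative(table: SurvivalTable, path, n_days: int | None = None) -> None:
    if n_days is None:
        n_days = max(
            (int(a.event_times.max()) for a in table.arms.values() if len(a.event_times)),
            default=1,
        )
    rows = []
    for (genotype, treatment), arm in sorted(table.arms.items()):
        counts = np.zeros(n_days, dtype=int)
        for day in arm.event_times.astype(int):
            counts[day - 1] += 1
        rows.append([genotype, treatment] + list(np.cumsum(counts)))
    cols = ["genotype", "treatment"] + [f"X{d}" for d in range(1, n_days + 1)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets sharing the gene-ID namespace of the expression data."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(str(m) for m in members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gene_sets(path) -> GeneSetCollection:
    """Load a GMT file: per line, set name TAB description TAB member genes."""
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not any(p for p in parts[2:]):
                logger.warning("skipping empty gene set at %s line %d", path, lineno)
                continue
            name, desc = parts[0], parts[1]
            members = [p for p in parts[2:] if p]
            if len(members) != len(set(members)):
                logger.warning("gene set %r contains duplicated members; deduplicating", name)
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
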