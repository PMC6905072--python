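"""Low-expression filtering and per-gene standardization.

Every axis is inferred from a centered-and-scaled training subset; the same
training statistics are reused when any other sample is projected onto that
axis, so the Standardizer is a first-class, serializable object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_FILTER_THRESHOLD = 4.5
DEFAULT_MIN_GENE_OVERLAP = 0.9


def filter_low_expression(
    ds: ExpressionDataset, threshold: float = DEFAULT_FILTER_THRESHOLD
) -> ExpressionDataset:
    """Drop genes whose mean log2 intensity across all samples is <= threshold.

    Microarray log2 intensities are bimodal: a low mode of background-level
    probes and a high mode of genuinely expressed genes.  The default cutoff
    of 4.5 sits in the valley between the modes; retention requires a mean
    strictly greater than the threshold.
    """
    if not np.isfinite(threshold):
        if threshold == -np.inf:
            return ds.subset_genes(ds.gene_ids)
        raise ValueError("threshold must be finite or -inf")
    means = ds.values.mean(axis=1)
    keep = means > threshold
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError(f"no genes exceed the expression threshold {threshold}")
    logger.info(
        "expression filter at %.3g: retained %d genes, removed %d",
        threshold, n_keep, ds.n_genes - n_keep,
    )
    return ds.subset_genes(ds.gene_ids[keep.to_numpy()])


@dataclass
class Standardizer:
    """Per-gene location/scale fitted on one training subset.

    ``mean`` and ``sd`` are on the log2 scale; ``sd`` uses the n-1
    denominator.  Genes with zero variance in the training subset carry no
    directional information and are dropped at fit time.
    """

    gene_ids: pd.Index
    mean: np.ndarray
    sd: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.gene_ids) == len(self.mean) == len(self.sd)):
            raise ValueError("gene_ids, mean and sd must have equal length")
        if (self.sd <= 0).any():
            raise ValueError("standardizer sd must be strictly positive")

    def subset(self, gene_ids) -> "Standardizer":
        idx = self.gene_ids.get_indexer(pd.Index(gene_ids))
        if (idx < 0).any():
            raise KeyError("requested genes absent from standardizer")
        return Standardizer(self.gene_ids[idx], self.mean[idx], self.sd[idx], self.source_tag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd},
                            index=self.gene_ids.rename("gene_id"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source_tag: str = "") -> "Standardizer":
        return cls(df.index, df["mean"].to_numpy(), df["sd"].to_numpy(), source_tag)


def fit_standardizer(ds: ExpressionDataset, source_tag: str = "") -> Standardizer:
    """Fit per-gene mean and standard deviation (ddof=1) on a training subset."""
    if ds.n_samples < 2:
        raise ValueError("standardization requires at least 2 samples")
    mean = ds.values.mean(axis=1).to_numpy()
    sd = ds.values.std(axis=1, ddof=1).to_numpy()
    nonconst = sd > 0
    if not nonconst.all():
        dropped = list(ds.gene_ids[~nonconst])
        logger.warning("dropping %d zero-variance genes: %s", len(dropped), dropped[:10])
    if not nonconst.any():
        raise ValueError("all genes have zero variance in the training subset")
    return Standardizer(ds.gene_ids[nonconst], mean[nonconst], sd[nonconst], source_tag)


def apply_standardizer(
    ds: ExpressionDataset,
    st: Standardizer,
    min_gene_overlap: float = DEFAULT_MIN_GENE_OVERLAP,
) -> ExpressionDataset:
    """Standardize ``ds`` with training statistics ``st``.

    The output is restricted to the genes shared between the dataset and the
    standardizer, ordered as in the standardizer; each value becomes
    ``(x - mean) / sd``.  If the shared fraction of the standardizer's genes
    falls below ``min_gene_overlap`` the datasets are considered
    incompatible.
    """
    shared = st.gene_ids[st.gene_ids.isin(ds.gene_ids)]
    frac = len(shared) / len(st.gene_ids)
    if frac < min_gene_overlap:
        raise ValueError(
            f"dataset shares only {frac:.1%} of the standardizer's genes "
            f"(floor {min_gene_overlap:.0%})"
        )
    sub = st.subset(shared)
    vals = ds.values.loc[list(shared)]
    z = (vals.to_numpy() - sub.mean[:, None]) / sub.sd[:, None]
    return ExpressionDataset(pd.DataFrame(z, index=shared, columns=ds.sample_ids),
                             ds.samples.copy())
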