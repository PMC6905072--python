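"""Genotype-level resilience scores and the subset-SD variability analysis.

A genotype's resilience is read off the projection of its recovery samples on
a stress axis: the farther the score stays from the unperturbed baseline two
hours into recovery, the lower the transcriptional resilience.  The subset-SD
analysis asks whether the scatter of genotype-panel projections exceeds the
scatter of technical replicates of a single reference genotype, by comparing
the reference SD with the distribution of SDs of many random same-size
subsets of panel samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def score_resilience(proj: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-sample projection scores into per-genotype scores.

    Returns a table indexed by genotype with ``recovery_score`` and
    ``heat_score`` (arithmetic means of the replicate projections for the
    recovery and heat conditions; NaN when a genotype lacks that condition)
    plus the replicate counts ``n_recovery`` and ``n_heat``.
    """
    if len(proj) == 0:
        raise ValueError("projection table is empty")
    rows = {}
    for genotype, grp in proj.groupby("genotype", sort=True):
        rec = grp.loc[grp["treatment"] == "recovery", "score"]
        heat = grp.loc[grp["treatment"] == "heat", "score"]
        rows[genotype] = {
            "recovery_score": rec.mean() if len(rec) else np.nan,
            "heat_score": heat.mean() if len(heat) else np.nan,
            "n_recovery": len(rec),
            "n_heat": len(heat),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "genotype"
    return out


@dataclass
class SubsetSDReport:
    """Null distribution of subset SDs against a reference SD.

    ``reference_percentile`` is the percentage of subset SDs less than or
    equal to ``reference_sd``: a value near 0 means the reference (replicate)
    scatter is smaller than essentially any same-size draw from the panel,
    i.e. the axis resolves genotype differences beyond technical noise.
    """

    treatment: str
    n_subset: int
    n_reps: int
    sd_distribution: np.ndarray
    reference_sd: float
    reference_percentile: float


def subset_sd_distribution(
    proj: pd.DataFrame,
    n_subset: int,
    reference_sd: float,
    n_reps: int = 5000,
    seed: int | None = None,
    treatment: str | None = None,
) -> SubsetSDReport:
    """SDs of random same-size subsets of panel projections.

    ``proj`` is a projection table (optionally pre-filtered; ``treatment``
    filters it here).  Each of ``n_reps`` replicates draws ``n_subset``
    samples without replacement and records their SD (ddof=1).  Fully
    reproducible from ``seed``.
    """
    if treatment is not None:
        proj = proj[proj["treatment"] == treatment]
    pool = proj["score"].to_numpy(dtype=float)
    if n_subset < 2:
        raise ValueError("n_subset must be at least 2")
    if len(pool) < n_subset:
        raise ValueError(f"pool of {len(pool)} samples is smaller than n_subset={n_subset}")
    rng = np.random.default_rng(seed)
    sds = np.empty(n_reps)
    for i in range(n_reps):
        sds[i] = rng.choice(pool, size=n_subset, replace=False).std(ddof=1)
    percentile = 100.0 * float(np.mean(sds <= reference_sd))
    return SubsetSDReport(
        treatment=treatment or "all",
        n_subset=n_subset,
        n_reps=n_reps,
        sd_distribution=sds,
        reference_sd=float(reference_sd),
        reference_percentile=percentile,
    )
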