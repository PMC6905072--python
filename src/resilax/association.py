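"""Rank correlation, axis top-contributors, and gene-set overlap tests.

Links the short-timescale transcriptome scores to long-timescale phenotypes
(Spearman rank correlation with an exact permutation p-value at small n) and
characterizes an axis biologically through its strongest-loading genes and
their enrichment in user-supplied gene sets (hypergeometric upper tail,
Bonferroni-corrected).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .axes import Axis
from .datasets import GeneSetCollection

EXACT_PERMUTATION_MAX_N = 10


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    Pairs with missing values are dropped.  The two-sided p-value is exact
    (full enumeration of rank permutations) for n <= 10 and uses the
    t-distribution approximation for larger n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return CorrelationResult(rho=rho, p=p, n=n)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by enumerating all n! pairings of the y-ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return 1.0
    rx = (rx - rx.mean()) / sx
    n = len(rx)
    count = 0
    total = math.factorial(n)
    # chunked enumeration keeps memory bounded at n = 10
    chunk = []
    threshold = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 100_000:
            count += _count_extreme(np.array(chunk), rx, sy, threshold)
            chunk = []
    if chunk:
        count += _count_extreme(np.array(chunk), rx, sy, threshold)
    return count / total


def _count_extreme(perms: np.ndarray, rx: np.ndarray, sy: float, threshold: float) -> int:
    rhos = (perms - perms.mean(axis=1, keepdims=True)) @ rx / (len(rx) * sy)
    return int((np.abs(rhos) >= threshold).sum())


def top_contributors(axis: Axis, fraction: float = 0.05, tail: str = "abs") -> pd.DataFrame:
    """Genes contributing most to an axis.

    Genes are ranked by |loading| (``tail="abs"``, the default) or by signed
    loading (``"up"``/``"down"``); the top ceil(fraction * n) are returned
    with a ``direction`` label (``up`` for positive loadings, ``down`` for
    negative).  Ties at the cutoff are broken by gene-ID order.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if tail not in ("abs", "up", "down"):
        raise ValueError(f"unknown tail {tail!r}")
    df = pd.DataFrame({"gene_id": axis.gene_ids, "loading": axis.loadings})
    if tail == "abs":
        key = df["loading"].abs()
    elif tail == "up":
        key = df["loading"]
    else:
        key = -df["loading"]
    df = df.assign(_key=key).sort_values(["_key", "gene_id"], ascending=[False, True])
    n_top = math.ceil(fraction * len(df))
    out = df.head(n_top).drop(columns="_key").reset_index(drop=True)
    out["direction"] = np.where(out["loading"] > 0, "up", "down")
    return out


@dataclass
class EnrichmentRow:
    set_name: str
    set_size: int
    overlap: int
    p: float
    p_bonferroni: float
    passes_filter: bool


def _hypergeom_upper_tail(overlap: int, universe: int, set_size: int, query: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set_size, query)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, query))


def hypergeometric_enrichment(
    query, sets: GeneSetCollection, universe,
    alpha: float = 0.05, min_set_size: int = 4, min_overlap: int = 3,
) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of a query gene list in each gene set.

    Each set is intersected with the universe before testing; the Bonferroni
    multiplier is the number of sets tested.  A set passes the reporting
    filter when the Bonferroni-corrected p is below ``alpha``, the (universe-
    intersected) set has more than 3 members and the overlap exceeds 2 —
    i.e. the defaults encode p_bonf < 0.05, set size > 3, overlap > 2.
    """
    query = frozenset(str(g) for g in query)
    universe = frozenset(str(g) for g in universe)
    if not query:
        raise ValueError("query gene set is empty")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    n_tests = len(sets)
    rows = []
    for name, members in sorted(sets.items()):
        members = members & universe
        overlap = len(members & query)
        p = _hypergeom_upper_tail(overlap, len(universe), len(members), len(query))
        p_bonf = min(1.0, p * n_tests)
        rows.append(EnrichmentRow(
            set_name=name, set_size=len(members), overlap=overlap,
            p=p, p_bonferroni=p_bonf,
            passes_filter=(p_bonf < alpha)
            and (len(members) >= min_set_size) and (overlap >= min_overlap),
        ))
    return rows


def overlap_test(
    query, reference, universe, n_tests: int = 1,
    alpha: float = 0.001, min_overlap: int = 11,
) -> EnrichmentRow:
    """Hypergeometric overlap of two gene lists with the stricter filter used
    for external reference lists (eQTL targets, polymorphism-bearing genes):
    Bonferroni-corrected p < 0.001 and an overlap of more than 10 genes."""
    query = frozenset(str(g) for g in query)
    reference = frozenset(str(g) for g in reference) & frozenset(str(g) for g in universe)
    universe = frozenset(str(g) for g in universe)
    if not query:
        raise ValueError("query gene set is empty")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    overlap = len(query & reference)
    p = _hypergeom_upper_tail(overlap, len(universe), len(reference), len(query))
    p_bonf = min(1.0, p * n_tests)
    return EnrichmentRow(
        set_name="overlap", set_size=len(reference), overlap=overlap,
        p=p, p_bonferroni=p_bonf,
        passes_filter=(p_bonf < alpha) and (overlap >= min_overlap),
    )


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
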