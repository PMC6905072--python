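"""Lifespan statistics: thermotolerance ratio, logrank tests, FDR adjustment.

Thermotolerance is operationalized as the ratio of the mean lifespan of the
heat-stressed arm to the mean lifespan of the control arm of the same
genotype.  Whether heat stress significantly affected a genotype's survival
is decided by a two-sample logrank test with Benjamini-Hochberg correction
across genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import SurvivalTable

logger = logging.getLogger(__name__)


def thermotolerance(surv: SurvivalTable, direction: str = "heat_over_control") -> pd.DataFrame:
    """Per-genotype mean lifespans and their ratio.

    Returns a table indexed by genotype with ``mean_control``, ``mean_heat``,
    ``ratio`` and the arm sizes.  ``direction`` selects heat/control (the
    default) or control/heat.  Genotypes lacking one of the two arms are
    skipped with a warning; an arm that is present but recorded no deaths is
    an error, since its mean lifespan is undefined.
    """
    if direction not in ("heat_over_control", "control_over_heat"):
        raise ValueError(f"unknown ratio direction {direction!r}")
    rows = {}
    for genotype in surv.genotypes():
        ctrl = surv.get(genotype, "control")
        heat = surv.get(genotype, "heat")
        if ctrl is None or heat is None:
            logger.warning("genotype %s lacks a control or heat arm; skipped", genotype)
            continue
        for arm in (ctrl, heat):
            if arm.n_events == 0:
                raise ValueError(
                    f"arm ({genotype}, {arm.treatment}) has zero recorded deaths"
                )
        mc = float(ctrl.event_times[~ctrl.censored].mean())
        mh = float(heat.event_times[~heat.censored].mean())
        ratio = mh / mc if direction == "heat_over_control" else mc / mh
        rows[genotype] = {
            "mean_control": mc, "mean_heat": mh, "ratio": ratio,
            "n_control": len(ctrl.event_times), "n_heat": len(heat.event_times),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "genotype"
    return out


def logrank(times_a, times_b, censored_a=None, censored_b=None) -> tuple[float, float]:
    """Two-sample logrank test.

    At each distinct event time t, with d(t) pooled deaths, n(t) subjects at
    risk and n_a(t) of them in arm a: the observed deaths O_a(t) are compared
    with the expectation E_a(t) = n_a(t) d(t) / n(t) under the null, with the
    hypergeometric variance

        V(t) = d(t) (n_a/n) (1 - n_a/n) (n - d) / (n - 1).

    The statistic (sum O_a - sum E_a)^2 / sum V is chi-squared with 1 df.
    Ties are handled by the hypergeometric variance; censored times leave the
    risk set at their recorded time without contributing an event.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    cens_a = np.zeros(len(times_a), bool) if censored_a is None else np.asarray(censored_a, bool)
    cens_b = np.zeros(len(times_b), bool) if censored_b is None else np.asarray(censored_b, bool)
    times = np.concatenate([times_a, times_b])
    group_a = np.concatenate([np.ones(len(times_a), bool), np.zeros(len(times_b), bool)])
    event = ~np.concatenate([cens_a, cens_b])
    if not event.any():
        raise ValueError("logrank requires at least one observed event")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[event]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & group_a).sum())
        dead = event & (times == t)
        d = int(dead.sum())
        d_a = int((dead & group_a).sum())
        o_minus_e += d_a - n_a * d / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    statistic = o_minus_e**2 / var
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LogrankResult:
    genotype: str
    statistic: float
    p: float
    p_fdr: float = float("nan")
    significant: bool = False


def compare_genotypes(surv: SurvivalTable, alpha: float = 0.05) -> list[LogrankResult]:
    """Logrank control-vs-heat per genotype, BH-adjusted across genotypes."""
    results = []
    for genotype in surv.genotypes():
        ctrl = surv.get(genotype, "control")
        heat = surv.get(genotype, "heat")
        if ctrl is None or heat is None or ctrl.n_events == 0 or heat.n_events == 0:
            logger.warning("genotype %s lacks usable arms; skipped from logrank", genotype)
            continue
        stat, p = logrank(ctrl.event_times, heat.event_times, ctrl.censored, heat.censored)
        results.append(LogrankResult(genotype, stat, p))
    if results:
        adj = fdr_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.p_fdr = float(q)
            r.significant = bool(q < alpha)
    return results


def count_significant(results: list[LogrankResult], alpha: float = 0.05) -> tuple[int, int]:
    """Count genotypes significantly affected (FDR < alpha) and not."""
    n_sig = sum(1 for r in results if r.p_fdr < alpha)
    return n_sig, len(results) - n_sig


def results_frame(results: list[LogrankResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"genotype": r.genotype, "statistic": r.statistic, "p": r.p,
          "p_fdr": r.p_fdr, "significant": r.significant} for r in results]
    ).set_index("genotype") if results else pd.DataFrame(
        columns=["statistic", "p", "p_fdr", "significant"])
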