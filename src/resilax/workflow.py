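"""High-level assembly of the full resilience analysis.

Training subsets are chosen purely from sample metadata: the reference
strain's unperturbed ``train`` samples yield the developmental axis D and its
heat-stressed ``train`` samples the stress axis H; the genotype panel's
``train`` control and heat samples yield the genetic axes GD and GH.  Test
samples (recovery series, panel recovery, reference replicates) are never
used for axis inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .axes import Axis, derive_axis_pair, project
from .datasets import ExpressionDataset, SurvivalTable
from .preprocess import filter_low_expression
from .resilience import SubsetSDReport, score_resilience, subset_sd_distribution
from .survival import compare_genotypes, count_significant, results_frame, thermotolerance
from .association import spearman


def reference_axes(ds: ExpressionDataset, reference: str = "N2",
                   component_mode: str = "fixed_second") -> tuple[Axis, Axis]:
    """Developmental axis D and heat-stress axis H from the reference strain."""
    dev_train = ds.select(genotype=reference, treatment="control", split="train")
    heat_train = ds.select(genotype=reference, treatment="heat", split="train")
    return derive_axis_pair(
        dev_train, heat_train, names=("D", "H"),
        component_mode=component_mode, orientation="covariate",
    )


def genetic_axes(ds: ExpressionDataset, reference: str = "N2",
                 component_mode: str = "fixed_second") -> tuple[Axis, Axis]:
    """Genetic baseline axis GD and genetic heat-stress axis GH from the panel."""
    non_ref = (ds.samples["genotype"] != reference).to_numpy()
    panel = ds.subset_samples(non_ref)
    gd_train = panel.select(treatment="control", split="train")
    gh_train = panel.select(treatment="heat", split="train")
    return derive_axis_pair(
        gd_train, gh_train, names=("GD", "GH"),
        component_mode=component_mode, orientation="contrast",
    )


@dataclass
class StudyResults:
    """Everything the full pipeline computes on one expression + lifespan study."""

    axis_d: Axis
    axis_h: Axis
    axis_gd: Axis | None = None
    axis_gh: Axis | None = None
    projection_h: pd.DataFrame | None = None
    projection_d: pd.DataFrame | None = None
    projection_gh: pd.DataFrame | None = None
    resilience: pd.DataFrame | None = None
    thermo: pd.DataFrame | None = None
    logrank: pd.DataFrame | None = None
    subset_sd: SubsetSDReport | None = None
    summary: dict = field(default_factory=dict)


def analyze_study(
    ds: ExpressionDataset,
    survival: SurvivalTable | None = None,
    reference: str = "N2",
    filter_threshold: float = 4.5,
    alpha: float = 0.05,
    seed: int = 0,
    subset_sd_reps: int = 5000,
) -> StudyResults:
    """Run filter -> axes -> projections -> resilience -> survival -> link.

    ``summary`` collects the headline scalars: the H.D overlap check, the
    correlation between resilience (mean projection of a genotype's recovery
    samples on GH) and thermotolerance (heat/control mean-lifespan ratio),
    the count of genotypes significantly affected by heat stress, and the
    subset-SD percentile of the reference strain's replicate scatter.
    """
    kept = filter_low_expression(ds, filter_threshold)
    res = StudyResults(*reference_axes(kept, reference))
    res.summary["retained_gene_fraction"] = kept.n_genes / ds.n_genes
    res.summary["H_dot_D"] = res.axis_h.dot(res.axis_d)
    res.summary["H_confound_overlap"] = res.axis_h.confound_overlap
    res.projection_h = project(kept, res.axis_h)
    res.projection_d = project(kept, res.axis_d)

    has_panel = (kept.samples["genotype"] != reference).any()
    if has_panel:
        res.axis_gd, res.axis_gh = genetic_axes(kept, reference)
        res.summary["GH_dot_GD"] = res.axis_gh.dot(res.axis_gd)
        res.projection_gh = project(kept, res.axis_gh)
        panel_proj = res.projection_gh[res.projection_gh["genotype"] != reference]
        res.resilience = score_resilience(panel_proj)

        # genotype scatter vs replicate scatter of the reference strain,
        # compared within the heat condition (one array per genotype, several
        # replicate arrays of the reference)
        panel_duration = panel_proj.loc[panel_proj["treatment"] == "heat", "t_heat"].mode()
        panel_duration = float(panel_duration.iloc[0]) if len(panel_duration) else np.nan
        ref_heat = res.projection_gh[
            (res.projection_gh["genotype"] == reference)
            & (res.projection_gh["treatment"] == "heat")
            & (res.projection_gh["t_heat"] == panel_duration)
        ]["score"]
        if len(ref_heat) >= 2:
            res.subset_sd = subset_sd_distribution(
                panel_proj, n_subset=len(ref_heat),
                reference_sd=float(ref_heat.std(ddof=1)),
                n_reps=subset_sd_reps, seed=seed, treatment="heat",
            )
            res.summary["subset_sd_reference_percentile"] = (
                res.subset_sd.reference_percentile)

    if survival is not None:
        res.thermo = thermotolerance(survival)
        results = compare_genotypes(survival, alpha=alpha)
        res.logrank = results_frame(results)
        n_sig, n_not = count_significant(results, alpha)
        res.summary["n_significant"] = n_sig
        res.summary["n_not_significant"] = n_not
        if res.resilience is not None:
            joined = res.resilience.join(res.thermo[["ratio"]], how="inner").dropna(
                subset=["recovery_score", "ratio"])
            if len(joined) >= 3:
                corr = spearman(joined["recovery_score"], joined["ratio"])
                res.summary["resilience_thermotolerance_rho"] = corr.rho
                res.summary["resilience_thermotolerance_p"] = corr.p
                res.summary["resilience_thermotolerance_n"] = corr.n
    return res
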