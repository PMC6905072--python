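"""Synthetic expression time series and linked lifespan data.

The generator emulates the statistical structure the analysis assumes for
age-synchronized *C. elegans* populations measured on two-color microarrays:

* a bimodal distribution of mean log2 intensity (a low background mode and a
  high expressed mode),
* a smooth developmental expression trend shared by all samples,
* a saturating stress-dose response shared across genotypes, with a mild
  per-genotype modulation of its magnitude,
* genotype-specific baseline offsets along a one-dimensional latent trait,
* genotype-specific recovery rates that slow with accumulated stress dose,
* a dominant technical array-to-array direction (the usual first principal
  component of microarray compendia), and
* lifespan ratios after heat stress that increase with the recovery rate.

The latent *effective dose* u accumulates during heat exposure as
``u(t) = u_sat (1 - exp(-t/tau))`` and decays during recovery as
``u_end * exp(-rho_eff * t_rec)`` with ``rho_eff = rho0 * exp(-lambda *
u_end)``: longer exposure both raises the dose and slows its decay, so
mildly stressed populations relax back to baseline while severely stressed
ones stay displaced.

Expression of gene g in sample s:

    x_gs = m_g + a_g * t~_s + b_g * u_s * (1 + gamma * z_k(s))
           + c_g * z_k(s) + g_g * w_s + eps_gs

with t~ the globally standardized developmental age, z_k the genotype latent
trait, w_s the per-array technical factor and eps Gaussian noise.  All
planted parameters are returned as ground truth for parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datasets import ExpressionDataset, SurvivalArm, SurvivalTable


@dataclass
class SimConfig:
    """Study-design and effect-size parameters of the simulated experiment.

    Defaults describe a desk-scale version of a microarray compendium: one
    reference strain measured in dense developmental, heat-stress and
    recovery time series, plus a 40-genotype panel measured in a
    control/heat/recovery design, with matched lifespan assays of ~31 worms
    per arm.
    """

    n_genes: int = 2000
    n_genotypes: int = 40

    # baseline log2 intensity: mixture of background and expressed modes
    low_expression_fraction: float = 0.3
    baseline_low_mean: float = 3.0
    baseline_low_sd: float = 0.5
    baseline_high_mean: float = 8.0
    baseline_high_sd: float = 1.5

    # per-gene loadings
    dev_loading_sd: float = 0.4        # a_g ~ N(0, 0.4)
    stress_loading_mean: float = 0.1   # b_g ~ N(0.1, 0.5): asymmetric, more up
    stress_loading_sd: float = 0.5
    genotype_loading_sd: float = 0.3   # c_g ~ N(0, 0.3)
    array_effect_sd: float = 1.0       # g_g ~ N(0, 1.0): technical direction
    noise_sd: float = 0.25             # eps, log2 units

    # effective-dose dynamics
    u_sat: float = 1.0
    tau: float = 2.0                   # hours at 35 C to reach ~63% of u_sat
    recovery_rate_log_mean: float = float(np.log(0.5))  # rho0 ~ LogNormal
    recovery_rate_log_sd: float = 0.4
    dose_slowing: float = 1.5          # lambda: recovery slows with dose
    stress_sensitivity: float = 0.35   # gamma: genotype modulation of stress response
    # genotypes vary along one intrinsic thermotolerance trait: strong
    # transcriptional responders (high z) are also slow recoverers
    trait_coupling: float = 0.8

    # development arrests at 35 C and restarts slowly afterwards; the
    # expression trend follows physiological (not wall-clock) age
    dev_rate_heat: float = 0.05
    dev_rate_recovery: float = 0.5

    # sampling design (hours)
    heat_start: float = 46.0           # developmental age at stress onset
    dev_grid: tuple = tuple(np.arange(44.0, 59.0, 1.0))
    dev_replicates: int = 2
    heat_grid: tuple = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0)
    heat_replicates: int = 3
    heat_train_replicates: int = 2
    recovery_design: tuple = (
        (2.0, (0.0, 1.0, 2.0, 3.0, 4.0, 6.0)),
        (3.0, (0.0, 1.0, 2.0, 3.0, 4.0)),
        (4.0, (0.0, 1.0, 2.0, 3.0, 4.0)),
        (6.0, (0.0, 1.0, 2.0, 3.0, 4.0)),
    )
    panel_heat_duration: float = 2.0
    panel_recovery_times: tuple = (2.0, 3.0, 4.0, 6.0)
    reference_genotype: str = "N2"
    n_replicates_reference: int = 3

    # lifespan model
    control_lifespan_mean: float = 17.0  # days
    lifespan_sd: float = 2.5
    n_worms: int = 31
    ratio_base: float = 0.45
    ratio_span: float = 0.5
    ratio_noise_sd: float = 0.05

    seed: int = 42


@dataclass
class SyntheticTruth:
    """Planted parameters for parameter-recovery tests.

    ``samples``: per-sample effective dose ``u`` (indexed by sample_id).
    ``genotypes``: per-genotype latent trait ``z``, recovery rate ``rho0``
    and (once survival is simulated) true lifespan ratio ``lifespan_ratio``.
    """

    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    genotypes: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_dose(t_heat: float, t_rec: float, rho0: float, cfg: SimConfig) -> float:
    """Effective stress dose after ``t_heat`` hours at 35 C and ``t_rec``
    hours of recovery, for a genotype with base recovery rate ``rho0``."""
    if t_heat < 0 or t_rec < 0:
        raise ValueError("times must be non-negative")
    u_end = cfg.u_sat * (1.0 - np.exp(-t_heat / cfg.tau))
    if t_rec <= 0:
        return float(u_end)
    rho_eff = rho0 * np.exp(-cfg.dose_slowing * u_end)
    return float(u_end * np.exp(-rho_eff * t_rec))


def _panel_genotypes(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_genotypes))
    return [f"RIL{str(i + 1).zfill(width)}" for i in range(cfg.n_genotypes)]


def _sample_plan(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic sample sheet: metadata for every simulated array."""
    rows = []

    def add(prefix, genotype, treatment, t_dev, t_heat, t_rec, split):
        rows.append({
            "sample_id": f"{prefix}_{len(rows):03d}", "genotype": genotype,
            "treatment": treatment, "t_dev": float(t_dev),
            "t_heat": float(t_heat), "t_rec": float(t_rec), "split": split,
        })

    ref = cfg.reference_genotype
    # unperturbed developmental series; replicate arrays split train/test
    dev_points = sorted(list(cfg.dev_grid) * cfg.dev_replicates)
    for i, t in enumerate(dev_points):
        add("dev", ref, "control", t, 0.0, 0.0, "train" if i % 2 == 0 else "test")
    # heat-stress series (0 h points are unstressed controls at stress onset)
    for rep in range(cfg.heat_replicates):
        for t in cfg.heat_grid:
            treatment = "heat" if t > 0 else "control"
            add("heat", ref, treatment, cfg.heat_start + t, t, 0.0,
                "train" if rep < cfg.heat_train_replicates else "test")
    # recovery series after graded stress durations (never used for training)
    for dur, recs in cfg.recovery_design:
        for tr in recs:
            add("rec", ref, "recovery", cfg.heat_start + dur + tr, dur, tr, "test")
    # genotype panel: control / heat / short recovery series per line
    dur = cfg.panel_heat_duration
    for genotype in _panel_genotypes(cfg):
        add("panel", genotype, "control", cfg.heat_start + dur, 0.0, 0.0, "train")
        add("panel", genotype, "heat", cfg.heat_start + dur, dur, 0.0, "train")
        for tr in cfg.panel_recovery_times:
            add("panel", genotype, "recovery", cfg.heat_start + dur + tr, dur, tr, "test")
    # reference-strain replicates inside the panel design (for replicate SD)
    for rep in range(cfg.n_replicates_reference):
        add("panelref", ref, "control", cfg.heat_start + dur, 0.0, 0.0, "test")
        add("panelref", ref, "heat", cfg.heat_start + dur, dur, 0.0, "test")
        for tr in cfg.panel_recovery_times:
            add("panelref", ref, "recovery", cfg.heat_start + dur + tr, dur, tr, "test")
    return pd.DataFrame(rows)


def simulate_expression(cfg: SimConfig, seed: int | None = None
                        ) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate the expression compendium; returns (dataset, truth).

    Deterministic given the seed (``cfg.seed`` unless overridden).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    plan = _sample_plan(cfg)
    if len(plan) == 0:
        raise ValueError("empty sampling grid")

    # per-gene parameters
    n = cfg.n_genes
    is_low = rng.random(n) < cfg.low_expression_fraction
    m = np.where(
        is_low,
        rng.normal(cfg.baseline_low_mean, cfg.baseline_low_sd, n),
        rng.normal(cfg.baseline_high_mean, cfg.baseline_high_sd, n),
    )
    a = rng.normal(0.0, cfg.dev_loading_sd, n)
    b = rng.normal(cfg.stress_loading_mean, cfg.stress_loading_sd, n)
    c = rng.normal(0.0, cfg.genotype_loading_sd, n)
    g = rng.normal(0.0, cfg.array_effect_sd, n)

    # per-genotype parameters; the reference strain sits at the trait origin
    # with the distribution-median recovery rate.  The recovery rate shares
    # the latent trait with the stress-response magnitude (strong responders
    # recover slowly), plus an independent component.
    genos = [cfg.reference_genotype] + _panel_genotypes(cfg)
    z = np.concatenate([[0.0], rng.normal(0.0, 1.0, cfg.n_genotypes)])
    r = cfg.trait_coupling
    xi = -r * z[1:] + np.sqrt(1.0 - r**2) * rng.normal(0.0, 1.0, cfg.n_genotypes)
    rho0 = np.concatenate([
        [np.exp(cfg.recovery_rate_log_mean)],
        np.exp(cfg.recovery_rate_log_mean + cfg.recovery_rate_log_sd * xi),
    ])
    geno_idx = {name: i for i, name in enumerate(genos)}

    # per-sample latent quantities
    k = plan["genotype"].map(geno_idx).to_numpy()
    u = np.array([
        simulate_dose(th, tr, rho0[ki], cfg)
        for th, tr, ki in zip(plan["t_heat"], plan["t_rec"], k)
    ])
    t_dev = plan["t_dev"].to_numpy()
    # physiological age: wall-clock before stress onset, slowed during heat
    # exposure and early recovery
    t_heat_arr = plan["t_heat"].to_numpy()
    t_rec_arr = plan["t_rec"].to_numpy()
    onset = t_dev - t_heat_arr - t_rec_arr
    t_phys = onset + cfg.dev_rate_heat * t_heat_arr + cfg.dev_rate_recovery * t_rec_arr
    # the developmental trend is scaled to the unperturbed developmental
    # series, the reference for what one unit of developmental change means
    dev_mask = plan["sample_id"].str.startswith("dev_").to_numpy()
    anchor = t_phys[dev_mask] if dev_mask.any() else t_phys
    t_tilde = (t_phys - anchor.mean()) / anchor.std()
    w = rng.normal(0.0, 1.0, len(plan))

    x = (
        m[:, None]
        + np.outer(a, t_tilde)
        + np.outer(b, u * (1.0 + cfg.stress_sensitivity * z[k]))
        + np.outer(c, z[k])
        + np.outer(g, w)
        + rng.normal(0.0, cfg.noise_sd, (n, len(plan)))
    )

    gene_ids = pd.Index([f"gene{str(i + 1).zfill(5)}" for i in range(n)], name="gene_id")
    values = pd.DataFrame(x, index=gene_ids, columns=plan["sample_id"])
    ds = ExpressionDataset(values, plan.set_index("sample_id"))

    truth = SyntheticTruth(
        samples=pd.DataFrame(
            {"u": u, "t_phys": t_phys, "genotype": plan["genotype"].to_numpy(),
             "t_dev": t_dev, "t_heat": plan["t_heat"].to_numpy(),
             "t_rec": plan["t_rec"].to_numpy()},
            index=plan["sample_id"].rename("sample_id"),
        ),
        genotypes=pd.DataFrame(
            {"z": z, "rho0": rho0},
            index=pd.Index(genos, name="genotype"),
        ),
    )
    return ds, truth


def true_lifespan_ratio(rho0: np.ndarray, cfg: SimConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Planted heat/control lifespan ratio: a monotone map of the recovery
    rate through the lognormal CDF, plus assay noise, clipped to (0, 1.1]."""
    quantile = norm.cdf(
        (np.log(rho0) - cfg.recovery_rate_log_mean) / cfg.recovery_rate_log_sd
    )
    r = cfg.ratio_base + cfg.ratio_span * quantile
    r = r + rng.normal(0.0, cfg.ratio_noise_sd, len(rho0))
    return np.clip(r, 0.05, 1.1)


def simulate_survival(cfg: SimConfig, truth: SyntheticTruth,
                      seed: int | None = None) -> SurvivalTable:
    """Simulate per-genotype lifespan assays matched to the expression panel.

    Each genotype gets a control arm (lifespans ~ Normal(17, 2.5) days,
    truncated at >= 2) and a heat arm (mean scaled by the genotype's true
    lifespan ratio), ``n_worms`` animals per arm, recorded as integer days.
    Fills ``truth.genotypes['lifespan_ratio']`` as a side effect.
    """
    if truth.genotypes.empty:
        raise ValueError("truth must be populated by simulate_expression first")
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    rho0 = truth.genotypes["rho0"].to_numpy()
    ratios = true_lifespan_ratio(rho0, cfg, rng)
    truth.genotypes["lifespan_ratio"] = ratios

    table = SurvivalTable()
    for genotype, ratio in zip(truth.genotypes.index, ratios):
        ctrl = rng.normal(cfg.control_lifespan_mean, cfg.lifespan_sd, cfg.n_worms)
        heat = rng.normal(cfg.control_lifespan_mean * ratio, cfg.lifespan_sd, cfg.n_worms)
        ctrl = np.maximum(np.round(np.maximum(ctrl, 2.0)), 1).astype(int)
        heat = np.maximum(np.round(np.maximum(heat, 2.0)), 1).astype(int)
        table.add(SurvivalArm(genotype, "control", ctrl))
        table.add(SurvivalArm(genotype, "heat", heat))
    return table


@dataclass
class SimulatedStudy:
    """One complete simulated study: expression, lifespans, ground truth."""

    dataset: ExpressionDataset
    survival: SurvivalTable
    truth: SyntheticTruth
    config: SimConfig


def simulate_study(cfg: SimConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Convenience wrapper running expression and survival simulation."""
    cfg = cfg if cfg is not None else SimConfig()
    ds, truth = simulate_expression(cfg, seed=seed)
    surv = simulate_survival(cfg, truth, seed=seed)
    return SimulatedStudy(dataset=ds, survival=surv, truth=truth, config=cfg)
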