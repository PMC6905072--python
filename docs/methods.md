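# Methods

## Model and procedure

The pipeline treats a gene-expression compendium as a cloud of samples in
gene space and summarizes biologically meaningful variation by unit loading
vectors ("axes").  Four axes are inferred, each from its own training
subset, each by the same recipe: center and scale every gene using the
training subset's statistics (mean, SD with the n−1 denominator; zero-
variance genes dropped), take the second principal component (SVD of the
standardized samples×genes matrix), orient its sign against a biological
covariate, and — for the two stress axes — remove the corresponding
confound axis by a single Gram–Schmidt step with re-normalization.

| axis | training subset | confound removed | orientation |
|------|-----------------|------------------|-------------|
| D    | reference strain, unperturbed, `split=train` | — | *d* increases with age |
| H    | reference strain, heat-stressed, `split=train` | D | *h* increases with exposure time |
| GD   | genotype panel, control, `split=train` | — | control-vs-heat contrast (usually uninformative; logged) |
| GH   | genotype panel, heat, `split=train` | GD | mean *gh*(heat) > mean *gh*(control) |

The *second* component is the default (`fixed_second`) because in microarray
compendia the first component is dominated by technical array-to-array
variation; `max_association` is available as a data-driven alternative and
warns when the two disagree.

**Why orthogonalize.**  Heat-stressed worms keep developing (slowly), so the
raw stress component Ĥ mixes stress response with developmental drift.
Defining H = (Ĥ − (Ĥ·D)D)/‖·‖ removes the developmental direction; the
overlap scalar (Ĥ·D) is kept as provenance.

**Which coordinates the scalar product uses.**  A loading vector describes a
direction of expression change only relative to a per-gene scale, and D and
Ĥ are fitted in differently scaled spaces.  Before the scalar product, the
confound's loadings are re-expressed in the candidate's standardized
coordinates (`w · sd_confound / sd_candidate` over the shared genes,
re-normalized).  Orthogonality therefore holds exactly in the space in
which H projects samples — the property that makes unperturbed samples'
*h* flat.  With equal scales this reduces to the naive dot product.
`Axis.dot(other)` evaluates in `self`'s coordinates and is mildly
asymmetric; tests always use `stress.dot(confound)`.

**Projection.**  `project(ds, axis)` standardizes raw samples with the
axis's *training* statistics (never re-fitted), restricts to the shared
genes (error below a 90% overlap floor), re-normalizes the loadings over the
intersection, and dots.  The training-set mean profile scores exactly 0.

**Resilience and its link to survival.**  A genotype's resilience score is
the arithmetic mean of its recovery-array projections on GH (one number per
genotype; reduces to the single array when only one exists).
Thermotolerance is mean(heat lifespan)/mean(control lifespan); the reverse
ratio is available via `direction=`.  Per-genotype control-vs-heat logrank
tests use the standard O−E/hypergeometric-variance statistic with the tie
correction, all deaths treated as observed events (cumulative-death tables
record no censoring; flags are supported), chi-squared with 1 df, BH-FDR
across genotypes at α = 0.05.  The headline association is the Spearman
rank correlation between resilience score and thermotolerance ratio, with
an exact permutation p-value for n ≤ 10 and the t approximation above.

**Enrichment.**  Top contributors are the ⌈5%⌉ of genes with largest
|loading| (ties broken by gene ID and logged; `tail=up/down` restricts to a
signed tail).  Enrichment of a query list in a gene set is the upper-tail
hypergeometric probability, Bonferroni-corrected by the number of sets
tested; reported sets must satisfy p_bonf < 0.05, set size > 3, overlap > 2.
Overlap tests against external reference lists (e.g. eQTL-target or
polymorphism lists) use the stricter p_bonf < 0.001 and overlap > 10.  The
universe is the set of genes surviving the expression filter in the axis's
training compendium — only those genes could have contributed.

## Tunable parameters

| parameter | default | units | why |
|-----------|---------|-------|-----|
| `filter.threshold` | 4.5 | log2 intensity | valley between the background and expressed modes of the bimodal intensity distribution; retention requires mean strictly greater |
| `standardize.min_gene_overlap` | 0.9 | fraction | guards against projecting datasets that share too few genes with an axis |
| component selection | `fixed_second` | — | technical variation is PC1 in these compendia |
| orientation threshold | 0.05 | \|rho\| | below this the sign is left unchanged with a warning |
| logrank α | 0.05 | — | FDR level for "significantly affected" |
| enrichment fraction | 0.05 | — | top-contributor share |

## What the generator emulates

`simulate_expression` draws gene baselines from a 30/70 mixture of
Normal(3, 0.5) and Normal(8, 1.5) log2 intensity; loadings a_g ~ N(0, 0.4)
(development), b_g ~ N(0.1, 0.5) (stress; the positive shift plants the
asymmetric, mostly-upregulated loading distribution), c_g ~ N(0, 0.3)
(genotype baseline), g_g ~ N(0, 1) (technical array direction); residual
noise SD 0.25 log2 units.  Expression is

    x_gs = m_g + a_g t̃_s + b_g u_s (1 + γ z_k) + c_g z_k + g_g w_s + ε ,

with w_s ~ N(0,1) per array and γ = 0.35 a genotype modulation of the
shared stress response.

*Effective dose.*  u accumulates as u_sat(1 − e^(−t/τ)) (τ = 2 h, u_sat = 1)
and decays in recovery as u_end e^(−ρ_eff t_rec) with
ρ_eff = ρ₀ e^(−λ u_end), λ = 1.5: longer exposure both raises the dose and
slows its clearance, so 2 h populations relax back while 6 h populations
stay displaced.  Genotype recovery rates are lognormal
(median 0.5 h⁻¹, log-SD 0.4).

*One intrinsic thermotolerance trait.*  Genotypes vary along a single
latent trait z_k ~ N(0,1) that shifts baseline expression (c_g z_k), scales
the stress response (1 + γ z_k), and — with coupling 0.8 on the log scale —
lowers the recovery rate: strong transcriptional responders are slow
recoverers.  The true lifespan ratio is a monotone map of ρ₀ through its
distribution's CDF, r = 0.45 + 0.5·Φ(·) plus Normal(0, 0.05) assay noise,
clipped to (0, 1.1]; survival arms draw 31 integer-day lifespans per arm
from Normal(17, 2.5) days (control) and Normal(17·r, 2.5) (heat), truncated
at 2 days.

*Physiological age.*  Development nearly arrests at 35 °C (rate 0.05 of
normal) and restarts at half speed during recovery; the developmental trend
follows this physiological age, scaled so that one unit corresponds to the
spread of the unperturbed developmental series.  This matches the empirical
observation that developmental expression changes during stress are small,
and it is what makes the developmental confound in the heat set *removable*.

*Sampling design* (default): an unperturbed series of 30 arrays (44–58 h
post-synchronization, duplicate arrays each hour, alternating train/test);
a heat series of 7 durations (0–6 h at 35 °C) × 3 replicates (2 train);
recovery series after 2/3/4/6 h of stress sampled hourly (never trained
on); and a 40-genotype panel with one control, one heat (2 h) and four
recovery arrays (2–6 h) per genotype, plus 3 replicate arrays of the
reference strain per condition for the replicate-SD comparison.

**What it does not emulate** — probe-level noise, dye bias, batch structure
beyond one rank-1 technical direction, real gene identities, multi-locus
genetic architecture (the trait is one-dimensional by design), censored
survival, or inter-assay lifespan drift.  Passing tests therefore show that
the *method* recovers planted structure of this form at realistic
signal-to-noise; they do not certify performance on data whose confounds
are higher-rank or nonlinear.

## Numerical choices

PCA via `numpy.linalg.svd` on the exactly re-centered standardized matrix
(deterministic; sign fixed by orientation, so a repeated run is
bit-identical).  Orthogonality and unit-norm tolerances are 1e-9; a
residual norm below 1e-8 after confound removal raises "axis degenerate".
Zero-variance genes are dropped, not given SD 1.  Ties in loadings are
broken by gene ID; midranks handle ties in all rank correlations.  Subset-SD
resampling draws without replacement with a seeded `numpy` generator; the
reference percentile is the fraction of subset SDs ≤ the reference SD.
Exact Spearman p-values enumerate all n! pairings in chunks (n ≤ 10).
All randomness flows from explicit seeds; the simulation's survival stream
is offset from the expression stream so the two stages are independently
reproducible.

## Problem sizes

The shipped analyses run the generator's default scale — 2000 genes, 330
arrays, 41 genotypes × 62 worms — which preserves the structure of the
motivating study at roughly half its gene count and panel size; axis
inference there is sample-limited, not gene-limited, so conclusions about
recoverability transfer.  The statistical oracles use 100 paired logrank
datasets, 2000 null simulations, exhaustive hypergeometric enumeration to
universe size 25, and exact permutation Spearman at n ≤ 5.

## Known limitations

GD has no natural orientation covariate (its control-vs-heat contrast is
near zero by construction); its sign is reported but arbitrary.  GH
estimation quality degrades when the panel's baseline genetic variation
dwarfs its stress-response variation — the renormalization after removing
GD amplifies estimation noise by 1/√(1−overlap²), visible as seed-to-seed
variation in the resilience correlations.  The subset-SD percentile is a
noisy statistic when the reference strain has few replicate arrays (an SD
on 5 df is wide); with the default 6 replicates it cleanly separates
genotype signal from replicate noise only when the variance ratio is well
above the F-distribution's resolution.  Exact permutation p-values are
enumerated, so n = 10 costs ~3.6 M permutations.
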