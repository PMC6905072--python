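# resilax

Stress-response axes and transcriptome-resilience scoring for heat-stressed
*C. elegans* gene-expression and lifespan data.

## The problem

A short heat shock reorganizes the expression of thousands of genes, and
populations differ heritably in how fast their transcriptome returns to its
unperturbed trajectory.  `resilax` condenses that high-dimensional response
into a handful of scalar scores and asks whether *transcriptome resilience*
measured hours after a mild stress predicts *thermotolerance* measured as
lifespan weeks later.  It is written for quantitative biologists working
with bulk expression time series (microarray or RNA-seq, supplied as
normalized log2 matrices) plus per-genotype survival assays.

## The method

All axes are unit loading vectors over genes, inferred by PCA on separately
centered-and-scaled training subsets:

* **D** (developmental axis): the second principal component of unperturbed,
  age-synchronized samples (the first is typically technical array-to-array
  variation).  Its projection *d* tracks transcriptional age.
* **H** (heat-stress axis): the second principal component of heat-stressed
  samples, Ĥ, with the developmental direction removed by one Gram–Schmidt
  step and re-normalized,

      H = ( Ĥ − (Ĥ·D) D ) / ‖ Ĥ − (Ĥ·D) D ‖ ,

  the scalar product taken after expressing D in Ĥ's standardized
  coordinates.  The projection *h* of any sample rises with heat-exposure
  duration, saturates, and decays during recovery.
* **GD / GH** (genetic axes): the same construction across a genotype panel —
  baseline genetic variation (GD) from control arrays, genotype differences
  in the stress response (GH) from heat arrays orthogonalized against GD.

A genotype's **resilience score** is the mean projection of its recovery
arrays on GH: the larger the score, the farther its transcriptome remains
from the unperturbed state.  **Thermotolerance** is the ratio of mean
lifespan after heat stress to mean lifespan in control conditions; whether a
line is significantly affected is decided by a two-sample logrank test with
Benjamini–Hochberg correction across the panel.  Axes are characterized by
their top |loading| contributors and hypergeometric gene-set enrichment.

A first-class synthetic-data generator (`resilax.simulate`) produces
expression compendia and linked lifespan tables with this exact planted
structure (saturating stress dose, dose-dependent recovery slowing, one
latent thermotolerance trait per genotype, bimodal intensities, a dominant
technical direction), so every stage is testable without downloads.

## Worked example

```bash
python examples/02_axes_and_projection.py
```

prints, for the default simulated study (2000 genes, 40 genotypes, seed 42):

```
D: component 2, 25.4% of training variance
H: component 2, confound overlap (H-hat . D) = +0.059
H . D = -1.84e-17  (orthogonal by construction)

h vs heat duration (reference strain): Spearman rho = 0.96
-> h rises with exposure time: a single scalar tracks the stress state
h vs age in unperturbed samples: rho = +0.17
-> flat: the developmental confound was removed
recovery after 2 h stress: displacement  18.0 ->   5.6
recovery after 6 h stress: displacement  23.4 ->  18.1
-> mild stress relaxes back toward baseline; severe stress stays displaced
```

The stress score *h* tracks the latent dose almost perfectly while staying
flat in unperturbed worms; after a mild (2 h) stress the transcriptome
relaxes most of the way back to baseline within 6 h, while after a severe
(6 h) stress it stays displaced.  `examples/04_survival_and_thermotolerance.py`
closes the loop:

```
Spearman(resilience score, thermotolerance): rho = -0.83, p = 5e-11
-> negative: genotypes whose transcriptome recovers fast lose less lifespan
```

The other examples cover simulation and filtering (01), genetic axes and
the subset-SD variability analysis (03), and top contributors plus gene-set
enrichment (05).

A thin CLI mirrors the library (`resilax simulate | filter | derive-axes |
project | score | subset-sd | survival | correlate | enrich | run`); see
`resilax --help`.

## Real data

The pipeline consumes plain TSV (expression matrix + sample metadata with
`genotype`, `treatment`, `t_dev`, `t_heat`, `t_rec`, `split` columns),
cumulative-death lifespan tables, and GMT gene sets, so externally
normalized public datasets can be run through `resilax run --config`
unchanged.  Probe-level normalization and annotation retrieval are out of
scope.
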