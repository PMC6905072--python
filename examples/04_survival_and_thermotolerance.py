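"""Lifespan statistics and the resilience-thermotolerance link.

Thermotolerance is the ratio of a genotype's mean lifespan after heat stress
to its mean lifespan in control conditions.  Per-genotype logrank tests
(BH-FDR across the panel) count how many lines heat stress significantly
affected; rank-correlating thermotolerance with the GH resilience score
tests whether short-term transcriptome recovery predicts long-term survival.
"""

import resilax as rx
from resilax.workflow import analyze_study

study = rx.simulate_study(seed=42)
results = analyze_study(study.dataset, study.survival, seed=42)

thermo = results.thermo
print(f"mean thermotolerance ratio (heat/control): {thermo['ratio'].mean():.2f}")
print(f"{results.summary['n_significant']} lines significantly affected by heat "
      f"stress (logrank, FDR < 0.05); "
      f"{results.summary['n_not_significant']} not")

rho = results.summary["resilience_thermotolerance_rho"]
p = results.summary["resilience_thermotolerance_p"]
print(f"\nSpearman(resilience score, thermotolerance): rho = {rho:.2f}, p = {p:.2g}")
print("-> negative: genotypes whose transcriptome recovers fast lose less lifespan")
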