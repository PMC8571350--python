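"""Simulate an admixed cohort with pedigree structure and noisy sequencing.

Builds a two-ancestry admixed panel (mean African fraction 0.823), grafts
relatives onto it, emulates ~15x sequencing, and prints what the generator
produced. The printed admixture mean should sit near 0.823 and the genotype
error rate should reflect intermediate coverage.
"""

import numpy as np

import panelqc as pq

sim = pq.simulate_panel(
    pq.CohortSpec(n_samples=200, n_variants=4000, chrom_length=4_000_000, seed=1)
)
print(f"panel: {sim.panel.n_samples} samples x {sim.panel.n_variants} variants")
print(f"mean realized African ancestry fraction: {sim.african_fraction.mean():.3f}")

ped = pq.simulate_pedigree(sim.panel, pq.PedigreeSpec(seed=2))
print(f"with relatives: {ped.panel.n_samples} samples")
print("related pairs by type:")
print(ped.truth.groupby("relationship").size().to_string())

called = pq.simulate_sequencing(ped.panel, pq.SeqSimParams(mean_coverage=15), seed=3)
truth = ped.panel.genotypes()
called_mask = called.gt != pq.MISSING
err = ((called.gt != truth.gt) & called_mask).sum() / called_mask.sum()
print(f"called genotype error rate at 15x: {err:.4f} "
      f"(missing fraction {1 - called_mask.mean():.4f})")
# the error rate is the fraction of non-missing hard calls that disagree
# with the true genotypes; at 15x a fraction of a percent is expected
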