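"""Sample QC: coverage/contamination gates, kinship, relatedness pruning.

Simulates a cohort with known relatives, estimates pairwise kinship and
IBD0, classifies relationship degrees, and prunes the related samples the
way a reference panel is pruned (children first, then the lower-coverage
member of each remaining pair).
"""

import numpy as np

import panelqc as pq

sim = pq.simulate_panel(
    pq.CohortSpec(n_samples=40, n_variants=20_000, chrom_length=20_000_000, seed=1)
)
ped = pq.simulate_pedigree(
    sim.panel, pq.PedigreeSpec(n_trios=1, n_duos=3, n_sib_pairs=2,
                               n_cousin_pairs=2, seed=2)
)
gm = ped.panel.genotypes()

pairs = list(zip(ped.truth.sample1, ped.truth.sample2))
results = pq.pairwise_kinship(gm, pairs)
print("pair kinship/IBD0 vs pedigree truth:")
for res, rel in zip(results, ped.truth.relationship):
    print(f"  {res.pair[0]:>12} - {res.pair[1]:<12} {rel:<13} "
          f"phi={res.kinship:+.3f} ibd0={res.ibd0:.3f} -> {res.degree}")

# coverage metadata: relatives get slightly different coverages so pruning
# has a higher-quality member to keep
rng = np.random.default_rng(3)
meta = [pq.SampleMeta(s, 12 + 6 * rng.random(), 0.01) for s in gm.samples]
kept, removed = pq.prune_relatives(results, meta)
print(f"\npruning removed {len(removed)} samples: {removed}")
print("(each parent-child pair loses its child; each remaining pair keeps "
      "the higher-coverage member)")
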