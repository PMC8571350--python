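"""Per-sample benchmarking of a call set against a curated truth set.

Compares one sample's calls to its truth genotypes inside confident
regions, counting TP / FN / FP (split into genotype mismatches FP.gt,
allele mismatches FP.al and spurious calls) and deriving recall, precision
and F1 — the harmonic mean of the two.
"""

import panelqc as pq
from panelqc.containers import TruthSet

sim = pq.simulate_panel(
    pq.CohortSpec(n_samples=1, n_variants=5000, chrom_length=5_000_000, seed=21)
)
truth_matrix = sim.panel.genotypes()
called = pq.simulate_sequencing(sim.panel, pq.SeqSimParams(mean_coverage=12), seed=22)

truth = TruthSet(truth_matrix, [pq.Region("1", 0, 5_000_000)])
reports = pq.compare_sample(called, truth)
table = pq.report_table(reports, caller="simulated-12x")
print(table.to_string(index=False))
print("\nF1 = 2PR/(P+R); FP = FP.gt + FP.al + spurious calls")
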