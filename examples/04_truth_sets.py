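"""Truth-set curation: dual-caller WGS consensus and microarray probe QC.

The consensus recipe intersects two call sets, blanks disagreements and
low-GQ calls, drops high-missingness sites and masks excluded regions. The
array recipe applies probe-level filters (unique exact alignment, vendor
consistency, no common-variant overlap, non-overlapping probes).
"""

import numpy as np

import panelqc as pq
from panelqc.truthsets import PROBE_LENGTH, ProbeRecord

# --- dual-caller consensus on simulated calls ---
sim = pq.simulate_panel(
    pq.CohortSpec(n_samples=50, n_variants=2000, chrom_length=2_000_000, seed=9)
)
calls_a = pq.simulate_sequencing(sim.panel, pq.SeqSimParams(mean_coverage=15), seed=1)
calls_b = pq.simulate_sequencing(sim.panel, pq.SeqSimParams(mean_coverage=15), seed=2)
confident = [pq.Region("1", 0, 2_000_000)]
segdup = [pq.Region("1", 500_000, 600_000)]  # an excluded repeat-like track
ts = pq.consensus_wgs_truth(calls_a, calls_b, gq_min=20, max_missing=0.10,
                            confident=confident, exclude=segdup)
print(f"consensus truth: {ts.genotypes.n_variants}/{calls_a.n_variants} sites "
      f"retained after consensus + missingness + region masking")

# --- microarray probe curation against a synthetic reference ---
rng = np.random.default_rng(11)
ref = "".join(rng.choice(list("ACGT"), size=3000))
probes, keys = [], []
for i, start in enumerate(range(100, 1100, 100)):
    pos = start + 25
    base = ref[pos - 1]
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[base]
    key = pq.VariantKey("1", pos, base, alt)
    keys.append(key)
    probes.append(ProbeRecord(f"p{i}", ref[start:start + PROBE_LENGTH], "1", pos, key))
gt = np.tile([0, 1, 1, 2], (len(keys), 1)).T.astype(np.int16)
cohort = pq.GenotypeMatrix(["a", "b", "c", "d"], keys, gt)
truth = pq.curate_array_truth(
    array=cohort, probes=probes, reference={"1": ref},
    common_variants={}, cohort=cohort,
    db_call_rate={k: 0.99 for k in keys}, db_maf={k: 0.01 for k in keys},
)
print(f"array truth: {truth.genotypes.n_variants}/{len(probes)} probe sites "
      f"survive the probe-level filters")
print(f"confident regions cover {sum(r.length for r in truth.confident_regions)} bp")
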