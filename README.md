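# panelqc

Quality control, truth-set curation and imputation-accuracy evaluation for
sequencing-based genotype **imputation reference panels** — with a synthetic
admixed-cohort generator so that every stage is testable without access to
controlled sequencing data.

Building an imputation panel from intermediate-coverage (~15×) whole-genome
sequencing of an admixed cohort involves a chain of decisions that each need
quantitative checks: excluding low-quality samples, finding and pruning
close relatives, filtering unreliable variant sites, phasing in overlapping
genomic chunks and ligating them back together, and finally measuring how
well the panel imputes held-out truth genotypes. `panelqc` implements that
chain as a tested Python library for statistical geneticists and pipeline
engineers.

## What it computes

* **Sample QC & relatedness** — coverage/contamination gates (fail below 3×
  or above 5 % contamination); the allele-frequency-robust kinship estimator
  φ = (N_AaAa − 2·N_AA,aa)/(N_Aa,i + N_Aa,j) with IBD0 = N_AA,aa / 2Σp²q²;
  degree classification at the standard 2^(−k/2) bands; and clique pruning
  that removes children first, then the lower-coverage member of each
  remaining related pair.
* **Site filtration** — singleton removal, missingness, the exact
  conditional Hardy–Weinberg test (probability-ordered two-sided p), and the
  GQ-based expected-correct-genotype statistic mean(1 − 10^(−GQ/10)), with
  presets mirroring the two common panel recipes (`dvglx`: p ≥ 1e−20,
  missingness ≤ 20 %, expected-correct ≥ 60 %; `gatk`: missingness ≤ 10 %).
* **Truth sets** — dual-caller WGS consensus (intersect call sets, blank
  disagreements and GQ < 20, drop sites > 10 % missing, mask excluded
  regions) and microarray truth with probe-level filters (call-rate/MAF
  gates, unique exact 50-mer probe alignment consistent with vendor
  coordinates, no common-variant overlap in the probe footprint,
  non-overlapping probes).
* **Chunked phasing orchestration** — fixed-length (~10 Mbp, 400 kbp
  overlap) and fixed-marker-count chunk plans, and ligation of
  independently phased chunks by majority vote over overlap heterozygotes.
* **Imputation evaluation** — *aggregate R²*: the squared Pearson
  correlation between pooled imputed dosages and truth hard genotypes per
  alternate-allele-frequency bin, in a strict mode that imputes
  panel-missing variants as homozygous reference and a lenient
  intersect-only mode; overall genotype discordance and non-reference
  discordance (NRD); and panel completeness by truth allele count
  (AC = 1, 2, > 2; SNPs and indels separately).
* **Call benchmarking** — hap.py-style confusion counts in confident
  regions (TP, FN, FP split into FP.gt genotype mismatches, FP.al allele
  mismatches and spurious calls) and recall / precision / F1 (harmonic
  mean).
* **Synthetic cohorts** — Balding–Nichols two-ancestry divergence, Markov
  local-ancestry mosaics with Beta-distributed admixture (mean African
  fraction 0.823 by default), Mendelian pedigrees with crossovers,
  Poisson-depth/binomial-read genotype calling with calibrated GQ,
  microarray emulation, and dosages corrupted to chosen per-AF-bin R².

## Worked example

```python
import panelqc as pq

sim = pq.simulate_panel(pq.CohortSpec(n_samples=40, n_variants=20_000,
                                      chrom_length=20_000_000, seed=1))
ped = pq.simulate_pedigree(sim.panel, pq.PedigreeSpec(
    n_trios=1, n_duos=3, n_sib_pairs=2, n_cousin_pairs=2, seed=2))
gm = ped.panel.genotypes()
results = pq.pairwise_kinship(gm, list(zip(ped.truth.sample1, ped.truth.sample2)))
for res in results[:3]:
    print(res.pair, round(res.kinship, 3), round(res.ibd0, 3), res.degree)
```

prints (see `examples/02_sample_qc.py` for the full script):

```
('trio0_child', 'S0000') 0.249 0.0 parent_child
('trio0_child', 'S0001') 0.243 0.0 parent_child
('duo0_child', 'S0002') 0.246 0.0 parent_child
```

Each line is a sample pair with its estimated kinship coefficient (0.25 for
first-degree relatives), IBD0 proportion (near 0 for parent–child, near
0.25 for siblings) and the inferred relationship degree. The `examples/`
directory holds one short narrative script per capability: cohort
simulation, sample QC, site filters, truth curation, chunk ligation,
imputation evaluation and call benchmarking.

A thin CLI mirrors the library:

```bash
panelqc simulate --n-samples 100 --n-variants 5000 --seed 1 --out-prefix cohort
panelqc sampleqc --vcf cohort.called.vcf --meta meta.tsv --out-prefix qc
panelqc filter --vcf cohort.called.vcf --preset dvglx \
    --out-vcf filtered.vcf --report sites.tsv
```

## Documentation

`docs/methods.md` describes the statistical models, the defaults and their
units, what the synthetic generator does and does not emulate, and known
limitations.
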