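# spatialnb

Estimating the effective number of breeders (N̂b) in spatially structured
populations — and quantifying how badly the estimate degrades when the
sampling window outgrows the genetic neighbourhood.

Single-sample N̂b estimators are a staple of conservation genetics: sample
one cohort, genotype a few microsatellites, read off the effective number
of parents.  But pond-breeding amphibians and similar systems form
metapopulations with isolation by distance: every breeding patch is within
dispersal range of the next, yet mating is distance-limited.  Pooling
samples across patches then mixes genetically divergent individuals, and
the resulting *mixture LD* masquerades as drift, biasing the LD-based N̂b
downward — in the moor frog survey this package reproduces, the pooled
estimate (381) was nearly half the sum of patch-level estimates (677).
`spatialnb` implements the full analysis pipeline for this problem and a
spatially explicit simulator for validating every stage against known
truth.

## What is inside

| module | contents |
| --- | --- |
| `popdata_io` | genepop reader/writer, patch/clutch side tables, the `Dataset` data model |
| `synthpop` | forward-time metapopulation simulator (Gaussian dispersal, patch carrying capacities, polyandrous clutches, genotyping artifacts) with full pedigree truth |
| `marker_qc` | exact HWE tests (enumeration + Monte Carlo), null-allele EM, interlocus-LD permutation tests, Bonferroni-based locus filters |
| `sibship_nb` | pairwise-likelihood sibship reconstruction with clutch-maternity prior; dyad-frequency N̂b: `1/Nb = ((1+3α)/4)(Q_HS + 2Q_FS) − (α/2)(1/Nm + 1/Nf)` |
| `ld_nb` | bias-adjusted LD estimator: Burrows composite r² per allele pair, Pcrit screening, `E[r²]` correction, delete-one-locus jackknife CIs |
| `spatial_structure` | individual pairwise Moran's I + autocorrelogram, sPCA with global/local Monte Carlo tests, Weir–Cockerham θ with bootstrap CIs, Nei FIS, patch grouping |
| `window_meta` | buffer-window construction/dedup, per-window estimate profiles, breeding-window radius from the autocorrelogram, meta-N̂b = ΣN̂b/(1−FST), random breeding-window surveys, Wright's Nn = 4πσ²D |
| `cli_pipeline` | `spatialnb` command-line tool (simulate / qc / sibship / ldnb / spatial / windows / meta / run-all / report) and the end-to-end pipeline |

## Worked example

```python
import spatialnb as sn

# 1. published moor-frog survey: per-patch estimates and their aggregates
df = sn.example_patch_estimates()
table = sn.make_table1(df)
print(table[table.patch == "Sum"][["patch", "ld_nb", "sibship_nb"]].to_string(index=False))
meta = sn.meta_nb(df.ld_nb.dropna().to_numpy(), fst=0.0162, mode="island")
print(f"island meta-Nb = {meta.value:.0f}")

# 2. simulate the study system and estimate on the pooled sample
dataset, truth = sn.simulate_metapopulation(sn.SimConfig(seed=1))
est = sn.ld_nb(dataset, pcrit=0.02)
print(f"pooled LD Nb = {est.nb_point:.0f} (95% CI {est.ci_low:.0f}-{est.ci_high:.0f}), "
      f"true parents = {truth.n_parents(dataset.genotypes.individual_ids)}")
fst = sn.wc_fst(dataset, n_boot=100, pairwise=False)
ac = sn.autocorrelogram(dataset, n_perm=0)
d, r = sn.breeding_window_from_autocorr(ac)
print(f"global theta = {fst.theta:.4f}; breeding window radius = {r:.0f} m")
```

prints

```
patch  ld_nb sibship_nb
  Sum  676.9        670
island meta-Nb = 688
pooled LD Nb = 683 (95% CI 567-859), true parents = 1686
global theta = 0.0181; breeding window radius = 315 m
```

Reading: summing the survey's per-patch LD estimates gives 676.9 breeders;
correcting for among-patch structure with the island model
(Σ N̂b / (1 − FST), FST = 0.0162) raises it to 688.  On the simulated
metapopulation — weak structure (θ ≈ 0.018), isolation by distance with a
~315 m breeding-window radius — the pooled-sample LD estimate finds only
683 of the 1686 true parents of the cohort: mixture LD makes a single
pooled sample understate the metapopulation-wide N̂b more than twofold,
which is exactly why the window-wise analysis exists.

The same pipeline runs from the shell:

```bash
spatialnb run-all --seed 1 --outdir out/      # full report bundle
spatialnb ldnb genotypes.gen --per-patch      # per-patch LD Nb from genepop
spatialnb meta 16.1 31.8 24.6 --fst 0.0162    # island meta-Nb from locals
```

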