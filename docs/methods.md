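# Methods

`spatialnb` estimates the effective number of breeders (Nb) of a single
cohort in a spatially structured population — the setting of pond-breeding
amphibians such as the moor frog (*Rana arvalis*), where eggs are sampled
clutch-wise from discrete breeding patches inside an area small enough that
every patch is within individual dispersal range, yet large enough that
mating is distance-limited.  The package implements the two single-sample
estimators used in that setting (linkage-disequilibrium and
sibship/dyad-frequency), the spatial diagnostics that reveal when their
assumptions fail, the incremental sampling-window analysis that exposes the
failure, and a forward simulator that generates data with known truth.

## The estimators

**LD Nb.**  For unlinked loci, drift in a finite parent pool of effective
size Nb generates squared gametic correlations E[r²] ≈ 1/(3Nb) at
equilibrium.  We compute r² as the squared Pearson correlation of diploid
allele-dosage vectors (0/1/2) over the pairwise-complete individuals — the
Burrows composite convention, which needs no phase or HWE assumption; the
denominator p(1−p)(1+F) q(1−q)(1+G) equals the classical composite
normalisation.  Alleles with frequency below Pcrit (default 0.02) in the
pairwise-complete subset are dropped, not pooled.  Comparisons are weighted
by their sample size S_pair; the weighted mean r̂² minus the pure sampling
expectation

    E[r²] = 1/S + 3.19/S²                  (S ≥ 30)
    E[r²] = 0.0018 + 0.907/S + 4.44/S²     (S < 30)

leaves the drift component r²′, inverted through the second-order
random-mating correction

    Nb = (1/3 + √(1/9 − 2.76 r²′)) / (2 r²′)        (S ≥ 30)
    Nb = (0.308 + √(0.308² − 2.08 r²′)) / (2 r²′)   (S < 30).

A non-positive r²′ or negative discriminant is reported as Nb = ∞
("no detectable drift signal"), serialised as the literal `Inf` and
excluded from sums and curve fits.  The 95% CI is a delete-one-locus
jackknife on the weighted mean r̂² (Student-t with the jackknife variance,
df = loci − 1), mapped through the Nb transform so that a lower r² bound
below E[r²] propagates to an infinite upper Nb bound.  Jackknifing in r²
space rather than Nb space keeps the interval defined when some deletions
produce infinite estimates.

**Sibship Nb.**  With Q_FS and Q_HS the frequencies of full- and half-sib
dyads among all pairs in the sample, Nm/Nf the numbers of breeding
males/females, and α the within-individual deviation from HWE,

    1/Nb = ((1 + 3α)/4)(Q_HS + 2 Q_FS) − (α/2)(1/Nm + 1/Nf).

α defaults to 0 (random mating); the multilocus FIS can be plugged in.
With α = 0 and random-mating dyad frequencies the equation reduces exactly
to Nb = 4 Nm Nf/(Nm + Nf), which the tests verify for all Nm, Nf in
2..500.

**Sibship reconstruction.**  Full-likelihood partition annealing (COLONY
style) is deliberately not re-implemented.  Because the sampling design
genotypes at most two eggs per clutch and maternity is known (one clutch
per female per season), pairwise information is nearly sufficient: each
pair's genotypes are evaluated under the IBD-coefficient triples
FS (¼, ½, ¼), HS (½, ½, 0), U (1, 0, 0), multiplied across loci, with a
per-locus error mixture ((1−ε)² toward the relationship likelihood, the
rest toward independence; ε defaults to 1e-4).  Same-clutch pairs get the
prior {FS ½, HS ½, U 0}; others uniform.  Hard classification at the 0.90
posterior threshold: same-clutch pairs above it are FS, below it maternal
HS; cross-clutch pairs above it would imply a shared mother across
clutches, which the one-clutch-per-female rule forbids, so they are
demoted to paternal half sibs; cross-clutch pairs are HS only if the HS
posterior itself clears the threshold.  Families are connected components
of the FS graph (the transitive closure materially raises dyad recall for
families larger than two); fathers are connected components of the
paternal-sharing graph; mothers are clutches.  Accuracy is established by
simulation recovery, not assumed: ≥95% of true FS dyads at informative
panels, father counts with ~15% median error under two-father clutches at
13 loci × 8 alleles.  The residual upward bias in father counts (missed FS
calls split paternal families) is intrinsic to pairwise classification at
a 0.90 threshold and is documented rather than corrected.  CIs for sibship
Nb are clutch-level nonparametric bootstraps (500 reps, percentile).

## Spatial structure

*Pairwise Moran's I* between individuals uses within-individual allele
frequencies x ∈ {0, ½, 1}: I_ab = Σ z_a z_b / (mean_c Σ z_c²) with z the
column-centred x.  This normalisation makes the mean over ordered pairs
exactly −1/(n−1), the natural null.  The autocorrelogram uses 10 distance
classes at the deciles of the pairwise-distance distribution (same-patch
pairs, distance 0, fall in the first class), two-sided permutation tests of
individual locations, and linear interpolation between class means for the
zero-crossing distance.  Half the zero-crossing distance estimates the
breeding-window radius (≈ 2σ), which seeds the random-window survey.

*sPCA* eigen-decomposes (1/n) Xᵀ W_sym X with X the centred individual
allele-frequency matrix and W the row-normalised 0 < d ≤ 1 km
neighbourhood graph.  Each eigenvalue factors exactly into
var(score) × Moran's I(score) (asserted to 1e−8 in the tests), so extreme
positive eigenvalues capture global structure (clines, isolation by
distance) and extreme negative ones local structure.  The Monte Carlo
global/local tests use the max-positive and max-|negative| eigenvalue
under location permutations — a simplification of the published sPCA
randtest, calibrated by simulation.  Patch grouping averages the lagged
scores of the leading global axes (k−1 of them) plus the leading local
axis per patch and applies Ward clustering under a k-nearest-neighbour
contiguity constraint; k is always explicit, with a convex-hull/
breeding-window-area heuristic available as a default proposal.

*Differentiation.*  Weir–Cockerham θ by the moment formulas, multilocus as
the ratio of summed variance components a/(a+b+c); the tests cross-check
against an independent three-level ANOVA sums-of-squares oracle to 1e−10.
CIs are bias-corrected percentile bootstraps over loci.  FIS is Nei's
1 − ΣH_obs/ΣH_exp with unbiased gene diversities, pooled across loci.

## Marker QC

HWE uses the exact conditional test: the probability, under the
multivariate hypergeometric distribution of genotype tables given allele
counts, of tables at most as probable as the observed one.  Tables are
fully enumerated when the space is certainly small (n ≤ 15 and ≤ 4
alleles); otherwise Monte Carlo shuffling of the allele vector (default
1e5 draws, seeded), with the +1/(n+1) correction.  Null alleles are
estimated per locus by EM under HWE with one null allele; missing
genotypes are optionally treated as null homozygotes (flag), otherwise the
null/null class is handled as a truncated-multinomial phantom count so the
EM stays monotone in likelihood.  Interlocus LD is a permutation test of
the mean composite r² per locus pair, run per patch and combined across
patches by Fisher's method.  Retention mirrors standard microsatellite
practice: drop monomorphic/uncallable loci, loci failing
Bonferroni-corrected HWE (family-wise 5%, denominator = tests actually
performed) in more than m = 2 patches, or null frequency > 0.20 in more
than k = 1 patch.

## Windows and metapopulation Nb

Buffers of radius 100 m to 1 km (steps of 100 m) around every patch define
candidate windows; membership is by patch-centroid distance, duplicates by
patch-set equality collapse to the smallest radius (ties to the smallest
focal id — determinism where the choice is arbitrary), and one full window
holds all patches.  Per window: LD Nb (Pcrit 0.02), sibship Nb, inferred
parents Np, the census-based number of potential breeding adults
NA = Σ(counted clutches × target-species fraction)/female fraction (the
female fraction is the mean Nf/Np over windows, ≈ 0.48 in this system),
FIS, and the LD-Nb/NA ratio.  Windows under 6 individuals are skipped with
a reason; estimates without finite upper confidence limits are flagged and
excluded from curve analyses.  Meta-Nb estimators: Σ locals; the island
correction Σ locals/(1 − FST); and extrapolation local × k neighbourhoods,
with Wright's neighbourhood size Nn = 4πσ²D available for the
dispersal-based cross-check.  The random-window survey drops breeding-
window-sized buffers (radius 230 m by default) uniformly in the bounding
box, keeps those with ≥ 50 genotyped eggs in ≥ 2 patches, and estimates LD
Nb on 50 random samples, 10 replicates per buffer, counting non-finite
estimates rather than hiding them.

## The simulator

Forward-time, discrete non-overlapping generations — a deliberate
simplification for an iteroparous frog, justified because the target
quantity is the parents of one egg cohort.  Each patch holds a fixed
per-sex carrying capacity of adults.  Every season each female lays one
clutch at the nearest patch; her mates (1 + Poisson(λ), default λ = 0.5,
or a fixed count) are drawn with probability ∝ exp(−d²/2σ²) of the
male-female distance.  Eggs inherit Mendelian gametes, disperse from the
natal patch by a bivariate Gaussian of axial SD σ, and compete for the
recruitment slots of whichever patch they land nearest — so demes regulate
locally, gene flow is egg dispersal, and isolated demes neither swamp nor
starve each other.  Sex is Bernoulli(½) at birth; the ≈48:52 female:male
parent ratio of the real system emerges rather than being imposed.

Default study-scale conditions: 25 patches in a 2 km × 1 km extent, 40
adults of each sex per patch, σ = 115 m (breeding-window radius
2σ = 230 m), 13 loci × 8 alleles at initially uniform frequencies, 20
burn-in generations, ≤ 50 clutches sampled per patch with 2 eggs each.
These reproduce weak global differentiation (realised Weir–Cockerham θ ≈
0.015–0.018) and isolation by distance with positive autocorrelation
decaying to zero at roughly 500–650 m.  Genotyping artifacts are overlaid
on the sampled dataset: with probability ε a call is replaced by a random
patch-frequency genotype; a null allele of frequency ν turns one-null
heterozygotes into visible homozygotes and null/null calls into missing
data (observed missingness ν²).  Non-target-species clutches are simulated
as labels only — enough to exercise the species filter and the NA
correction, since they are never genotyped in the field workflow either.

What the generator does **not** emulate: overlapping generations and
age structure, genotyping error correlated within plates, allele-size
homoplasy and mutation, habitat-driven (non-Gaussian) dispersal, and
temporal variation in patch occupancy.  Passing tests therefore show the
estimators behave correctly under the stated spatial model, not that real
data meet that model.

## Fixed experiment conditions used in the checks

- *Panmictic recovery*: one patch, 25 + 25 adults, 6 burn-in generations,
  polyandry λ = 4 so that effectively all 50 adults parent the 100
  sampled eggs (25 clutches × 4 eggs) — median LD Nb over 20 replicates
  is compared with the 50-parent truth.  At the metapopulation default
  λ = 0.5 only ~45 of the 50 adults become parents, which would conflate
  estimator bias with unrealised parents.
- *Mixture-LD bias*: a 3 × 3 patch grid, 300 m spacing, 25 + 25 adults per
  patch, σ = 120 m, 15 generations — realised θ ≈ 0.013–0.021, the weak
  structure regime where pooling is most misleading.
- *Full-sib dyad recovery*: error-free data, single-father clutches of 8
  eggs at 13 loci × 12 alleles — family sizes large enough that the
  transitive closure of pairwise calls, not just single-pair power,
  determines recall.
- *Father-count recovery*: two-father clutches, 2 eggs genotyped, a male
  pool large enough (2000) that cross-clutch father sharing is negligible,
  13 loci × 8 alleles.
- *Wahlund*: two demes 4.8 km apart (no gene flow at σ = 80 m), 30
  generations of divergence.

Problem sizes throughout (patch counts, adults, replicate counts) are
chosen as the smallest that leave the qualitative contrasts with
comfortable statistical margin; all randomness flows through a single
seeded generator with stable per-stage labels, so adding a stage never
perturbs an earlier stream.

## Numerical choices and degenerate inputs

- Missing genotypes are explicit (all-zero genepop codes), never sentinel
  alleles; locus pairs use pairwise-complete cases with S_pair weights, no
  imputation — except pairwise Moran's I, which mean-imputes so its
  −1/(n−1) identity stays exact.
- Monomorphic loci: HWE p defined as 1.0 with a flag; LD comparisons with
  zero dosage variance error out; a dataset of clones is an error, not an
  estimate.
- EM convergence: max |Δfreq| < 1e-8 or 1e4 iterations.
- Permutation p-values use the (1 + exceedances)/(n + 1) form; two-sided
  class tests double the smaller tail and cap at 1.
- Window dedup ties, family orderings and CSV row orders are all given
  deterministic tie-breaks so reruns are byte-identical.

## Known limitations

- Pairwise sibship classification under-detects cross-clutch paternal half
  sibs (HS vs U is weakly identifiable at 13 microsatellites), so sibship
  Nb exceeds the true parent count when father sharing across clutches is
  common; the per-window curves remain monotone and rank-valid, which is
  what the window analysis consumes.
- The LD estimator inherits the known downward bias under sib-heavy
  sampling; the study design (≤ 2 eggs per clutch) limits, but does not
  remove, this.
- The island meta-Nb assumes the grouped units are internally panmictic;
  with isolation by distance inside groups it remains an approximation.
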