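# Methods

This note documents the models, the defaults and the design choices
behind `polyhap`, in the order the pipeline runs them.  It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Forward Wright–Fisher simulator (`synthetic_data`)

The generator emulates the study design the pipeline targets: a small
phased panel (default 22 diploids, 44 haplotypes) drawn from a
population that carries one strongly selected locus on top of standing
neutral variation, plus GWAS-like summary statistics and the covariates
used for null matching.

**Reproduction.**  Discrete generations; each offspring draws a parent
diploid with probability proportional to fitness and receives one
recombinant gamete per parent (selfing allowed).  Genotype fitness at
the selected site is (1+s)^(2h) for heterozygotes and (1+s)² for
homozygotes, which is multiplicative (genic) at the default dominance
h = 1/2 and therefore consistent with the deterministic update
p' = p(1+s)/(1+ps) used everywhere else; the closed-form logistic
p_t = p₀e^{st}/(1−p₀+p₀e^{st}) is the drift-free oracle the tests
check against.

**Recombination.**  Per-gamete crossover count ~ Poisson(total map
length in Morgans), breakpoints uniform on the genetic scale — the
simplest model consistent with a linear map.  The default map is
1 cM/Mb.

**Founders and polarization.**  Sites segregate from standing
variation: founder haplotypes are independent Bernoulli draws per site
with frequencies from a truncated neutral-like SFS (density ∝ 1/p on
[daf_min, daf_max]; a uniform option exists).  There is no recurrent
mutation after time 0, so ancestral(0)/derived(1) polarization is exact
by construction.  The real site-frequency spectrum of the emulated
panel is unknown at this scale, so the founder distribution is surfaced
in `SimConfig` rather than fixed.

**The sweep allele.**  By default it arises exactly once, on a single
haplotype, at onset (default s = 0.013, onset 100 generations before
present — the constants of the trajectory model).  Runs in which it is
lost, or in which it is observed fewer than `min_sample_carriers`
(default 6) times in the sampled panel, are resimulated with a fresh
stream up to a retry cap of 1,000 with the attempt count logged: the
fixture emulates the *ascertained* study situation of a known sweep
locus segregating at appreciable panel frequency.  Because a new
mutation under weak selection cannot reach appreciable frequency in
~100 generations, `initial_frequency` optionally starts the allele
from standing variation instead.

**What the generator does not emulate.**  Coalescent-depth LD (founders
are unlinked, so linkage structure only accumulates over the simulated
generations), mutation, genotyping error, ascertainment bias of real
GWAS panels, and population structure.  Passing tests therefore show
that the *methods* behave correctly under controlled haplotype
dynamics, not that real data meet these assumptions.

## EHH, iHH and iHS (`ehh_ihs`)

EHH at a signed offset is the fraction of carrier pairs identical from
the core through the offset, computed by refining carrier group labels
site by site outward; offset 0 is 1 by definition and the curve is
non-increasing outward on each side.  Extension stops independently per
side when EHH < 0.05 (the sub-threshold point is kept as the final
trapezoid edge) or at 1 Mb; both are configurable.  Curves that hit the
panel edge first are integrated to the edge and flagged — small
synthetic regions make edge hits common.  iHH is the trapezoidal
integral against cM from the map (physical-scale integration, in Mb,
is available behind a flag).  uiHS = ln(iHH_D/iHH_A) requires at least
two carriers of each allele; cores below DAF 0.05 are computed but
flagged low-frequency.

Standardization uses equal-width DAF bins on (0,1) — 25 by default,
equal-count quantile bins as an option for single-region scans — and
the sample (n−1) standard deviation; the denominator convention is
fixed so exact tests can assert per-bin mean 0 / SD 1 to 1e-12.  Bins
with fewer than two defined values or zero variance leave their records
unstandardizable (flagged, siHS = NaN).

## tiHS polygenic-adaptation test (`polyadapt`)

Effect sizes are polarized to the derived allele (sign inverted when
the reported effect allele is the ancestral allele); SNPs whose effect
allele matches neither panel allele are dropped with a log entry.  The
default statistic is tiHS = siHS · sign(β_derived); a weighted mode
tiHS = siHS · β_derived is retained behind a flag because both
definitions ("polarized by" and "weighted by" the GWAS effect) are in
circulation, and they differ.

Trait sets take GWAS-suggestive SNPs (strict P < 5 × 10⁻²) with a
defined siHS, minus an explicit exclusion list (the pipeline excludes
the known selected candidate so a single strong sweep cannot drive the
trait-level test).  Traits retaining fewer than a configurable floor
(default 10 at desk scale) are dropped with a log entry.

The null pool is every scanned SNP with a polarized GWAS effect, minus
the trait set and exclusions; each pool SNP contributes its *own* tiHS.
Matching is on joint bins of DAF, local recombination rate and
GERP-like score — deciles × terciles × terciles by default, fully
configurable, with quantile edges computed from the pool (the genome
studies use 5 × 3 × 3 over their ~1,400-SNP pools to keep every joint
bin populated).  Joint rather than marginal binning is the stricter
reading of covariate matching and is the default.  Each replicate
draws, for every trait SNP, one pool SNP uniformly from its joint bin
without replacement within the replicate; the replicate statistic is
the drawn set's mean tiHS.  The draw protocol (bin order, sequential
remapped uniform draws) is fixed and documented in the module docstring
so an independent re-implementation with the same seed reproduces the
replicate means exactly — the test suite contains that oracle.

P = (1 + r)/(N + 1) with r counting replicates whose |mean| ≥
|observed| (ties count toward r — conservative, consistent with the +1
correction).  Direction is Increasing when the observed mean exceeds
the replicate average, else Decreasing.  BH adjustment is step-up
across all tested traits; adjusted P < 0.05 is called significant.
The replicate count is configurable: the studies use 10⁴–10⁵;
paper-scale 10⁷ runs in the same chunked code path but is not needed
for the package's own checks.

## Wright–Fisher grid HMM (`wf_trajectory`)

The genealogy-based machinery used in the original analyses
(tree-sequence inference plus importance sampling of branch lengths)
needs data and tooling that cannot be reproduced at desk scale; the
package replaces it with a frequency-grid HMM that keeps the epoch
logic, the constants (Ne = 10,000, 28-year generations, epochs 0–50,
50–100, 100–150 with s = 0 beyond the last boundary) and the outputs
(trajectories, epoch-wise s, Z(t)).

The grid is 101 equally spaced frequencies with absorbing boundaries;
each one-generation operator places Binomial(2Ne, p') mass into bins
whose edges are midpoints between grid points, so rows sum to one
exactly and the neutral operator conserves expected frequency to within
half a grid cell.  The prior at the oldest time is uniform over the
grid (agnostic, configurable); the emission is Binomial(n, p) for the
present-day derived count.  A transition from generation t+1 to t uses
the epoch containing the *younger* generation t.

`estimate_epoch_s` maximizes the likelihood per epoch by grid search
(default grid ±0.05 in steps of 5 × 10⁻⁴).  Fully observed frequency
paths factor across epochs and are fit independently; a single
present-day count uses the HMM marginal likelihood with coordinate
ascent across epochs.  A flat surface (monomorphic observation, or an
epoch predating the allele) flags the estimate undefined rather than
returning a number.  A present-day count under the uniform ancient
prior is only weakly informative about s, which is why the pipeline
fits the simulated true path when one exists and why the recovery
study uses full paths.

Z(t) uses posterior-mean frequencies (a sampled-path mode is a
reasonable extension for credible bands but posterior means are the
default, and the only mode the identities are asserted on).  Effect
sizes are per derived-allele copy and Z(t) is on the allele-frequency
scale, not doubled: the sample mean of individual scores Σᵢβᵢgᵢ equals
2·Z(0), and a test pins that convention.  The horizon defaults to the
last epoch boundary (150 generations); beyond the last boundary s = 0.

The regression validation `ps_model_comparison` fits age-only, PS-only
and age+PS OLS models on age-defined subsets (default cutoffs none /
55 / 50 / 45 years, mirroring a 22-individual panel), reporting n,
adjusted R² and AIC; subsets under 4 individuals are skipped.

## Study conditions (`studies`)

Problem sizes were chosen once, for scientific realism at desk scale,
and are stated here as the package's own conditions:

* **Genome for the tiHS studies** — ten independent 4 Mb regions of 500
  diploids, 250 sites each, 60 generations of drift (per-region
  recombination rates jittered log-normally so the matching covariate
  varies), sampled to 22 diploids: ~2,100 scannable SNPs.
  Calibration: 12 random pseudo-traits at 10⁴ replicates, expecting
  raw P < 0.05 at the binomial 95% rate.  Power: a selected trait of
  100 causal SNPs whose trait-increasing derived alleles receive a −1
  siHS displacement (selection decreasing the trait, imposed at the
  summary-statistic level), tested with 11 null traits at 10⁵
  replicates over 20 runs.
* **Sweep-region studies** — a 20 Mb region at 1 cM/Mb in 5,000
  diploids, 250 array-density sites from common standing variation
  (founder DAF 0.2–0.8), s = 0.1 arising 70 generations ago,
  standardized genome-wide against a shared eight-region neutral
  reference.  The deep population keeps recent neutral coalescence
  (and hence spurious long-haplotype plateaus) rare.
* **Recovery study** — 50 full frequency paths per condition at
  Ne = 10,000: neutral from p₀ = 0.2, and s = 0.013 over 100
  generations from p₀ = 0.05.

## Known limitations

* The scan localizes a sweep to a region, not a site.  Under faithful
  hitchhiking dynamics the selected site's nearest linked neighbours
  carry almost the same haplotype signal, on both allele classes, and
  the exact regional argmax of |siHS| frequently lands on a hitchhiker;
  the selected site is a regional top-rank outlier far more reliably
  than it is the single maximum.  This is a property of the statistic,
  not of the implementation — the unit suite asserts the ranking
  property, and the acceptance suite reports the strict argmax rate.
* With 44 haplotypes the uiHS log-ratio is intrinsically noisy at low
  minor-allele counts; low-frequency cores are flagged rather than
  suppressed.
* The HMM stand-in conditions on far less data than genealogy-based
  trajectory inference; single-timepoint selection estimates are
  correspondingly diffuse.
* Empirical p-values are bounded below by 1/(N+1); BH adjustment is
  across the configured trait family only.
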