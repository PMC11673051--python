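# Methods

This note documents the statistical procedures, the synthetic-cohort
generator, and the numerical choices behind `bovintro`. Everything stated
here is computed by the test suite or `scripts/acceptance.py`; nothing is
quoted from external results.

## Data model

All analyses operate on a `HaplotypePanel`: a phased haplotype matrix over
{0, 1, missing} with strictly increasing 0-based positions on a single
contig. Haplotypes 2i and 2i+1 form diploid sample i. Coordinates are
0-based half-open everywhere inside the package and become 1-based only at
the VCF boundary, which prevents off-by-one errors in windowing. Missing
alleles are excluded from every frequency denominator (VCFtools
convention).

## Diversity and structure

- **θπ** per site is 2·c0·c1/(n(n−1)) over called alleles; a window's value
  is the sum over its SNPs divided by the window size in bp (VCFtools
  `--window-pi` semantics). Default windows are 50 kb with a 20 kb step.
- **Heterozygosity and F.** Ho is the mean observed heterozygote fraction
  over sites segregating within the population; He is the mean unbiased
  expected heterozygosity 2p(1−p)·n/(n−1) (n = called alleles). The
  unbiased correction is a package choice; the definition F = 1 − Ho/He
  leaves it open. A per-sample F is also reported, but the population
  aggregate is the primary value since sites fixed within the population
  contribute zero to both Ho and He and cancel from the ratio.
- **ROH** follows the PLINK sliding-window heuristic: windows of 50 SNPs
  are homozygosity-compatible with ≤ 1 heterozygous call; a SNP is inside
  a run if > 5% of its overlapping windows are compatible; maximal runs
  are trimmed to homozygous end SNPs and kept at ≥ 500 kb and ≥ 50 SNPs.
  All thresholds are keyword parameters. Run edges are only defined up to
  a few SNPs by this heuristic (as with PLINK); tests assert exact bounds
  only on fixtures with heterozygous flanks, and recall on implanted
  megabase runs.
- **LD pruning** reproduces the `--indep-pairwise 50 10 0.1` greedy pass on
  genotype-dosage r² (not EM haplotype r²). The later-position SNP of an
  offending pair is removed — a deterministic tie-break — and passes repeat
  until stable, which makes pruning idempotent.
- **p-distance** between diploids is the proportion of compared positions
  with unequal dosage (pairwise deletion); between haplotypes, unequal
  alleles. NJ trees use the Saitou–Nei algorithm (via scikit-bio) with
  negative branch lengths clamped to zero.
- **PCA** mean-imputes missing dosages per site, centres by 2p̂ and scales
  by √(p̂(1−p̂)) (Patterson normalisation); explained-variance fractions
  are eigenvalue shares.

## Selection scans

- **Tajima's D** uses the standard a1…e2 constants with n = the
  population's haplotype count; windows without a segregating site are
  flagged NaN, never zero.
- **F_ST** uses the Weir & Cockerham (1984) per-site variance components
  a, b, c with the window (and genome) value Σa / Σ(a+b+c) — the weighted
  estimator VCFtools reports. Negative values are legitimate and kept.
- **XP-EHH.** For each core SNP the extended haplotype homozygosity of
  each population (probability two random haplotypes are identical over
  the extending span) is integrated over bp by the trapezoid rule, both
  directions. Extension stops when the *pooled* EHH falls below 0.05, at a
  1 Mb extension cap, or at an inter-SNP gap over 200 kb (selscan-style
  defaults; the tool's flags are not published for this design, so the
  defaults are adopted and exposed). Because both integrals share one
  support, swapping populations negates the raw score ln(iHH_A/iHH_B)
  exactly. Scores are z-normalised genome-wide (not per chromosome —
  configurable), and a window's statistic is the mean normalised score of
  its cores.
- **Candidates.** "Significant" windows are the 0.5% empirical tail of the
  genome-wide distribution (low tail for θπ and Tajima's D, high for F_ST
  and XP-EHH), with ties at the cut included; no parametric p-values are
  computed. Regions supported by ≥ 2 methods (bp overlap, sweep-line
  merge) are candidate regions; genes overlap by ≥ 1 bp under half-open
  semantics. A composite-likelihood-ratio scan is deliberately not
  implemented; the within-population arm is the θπ tail plus Tajima's D.

## Introgression

- **Patterson's D** is computed from population allele frequencies:
  ABBA = (1−p1)p2p3(1−pO), BABA = p1(1−p2)p3(1−pO),
  D = Σ(ABBA−BABA)/Σ(ABBA+BABA). The standard error is a delete-one
  jackknife over contiguous bp blocks (default 5 Mb, set to 500 kb on the
  10 Mb synthetic contig to give 20 blocks — the minimum the function
  accepts); Z = D/SE.
- **U statistic.** A site counts toward U_{control,target,donor}(w, x, y)
  when p_donor ≥ y, p_control < w and p_target > x — strict/non-strict
  exactly as the verbal pattern "fixed in the donor, under 1% in the
  control, over 50% in the target". Defaults w = 0.01, x = 0.5, y = 1.0;
  the alternative parameterisation (0.01, 0.2, 1.0) is available through
  `UThresholds` since published labels and execution patterns for this
  statistic disagree. Counts are windowed (50 kb / 20 kb).
- **Local ancestry** is a transparent stand-in for CRF/random-forest
  classifiers (RFMix-class tools): each non-overlapping window of 20 SNPs
  on each target haplotype is assigned the reference panel whose *closest
  haplotype* has the smallest mean per-site Hamming distance, and only
  when the runner-up panel is at least 0.1 further away; otherwise the
  window stays unassigned and breaks tracts. The nearest-haplotype rule
  matches the copying process that generates introgressed tracts; the
  margin plays the role of a posterior threshold. With ~20 kb windows and
  the default cohort's donor-private substitution density (~1 per 10 kb),
  an assignment needs roughly two diagnostic sites of separation, which
  keeps the zero-gene-flow false-positive share near 10⁻³ while recovering
  implanted fractions of 2–12% within ±0.02 (both properties are asserted
  by the acceptance tests). Tract bp bounds are midpointed between
  boundary SNPs.
- **ILS filter.** A tract of length m that merely reflects shared
  ancestral polymorphism has length distribution with survival
  P(≥ m) = e^(−m/L)(1 + m/L), the Gamma(shape 2, rate 1/L) tail with
  L = 1/(r·t). Defaults r = 1e−8 crossovers/bp/generation and t = 300,000
  generations (≈ 1.8 Myr at a 6-year generation interval, a standard
  cattle–banteng/gaur divergence scale); both are explicit `IlsModel`
  fields because the source analyses do not print them. Tracts with
  P_ILS < α = 0.05 are retained; P_ILS is recorded on discarded tracts
  too.
- **Ratios.** A sample's donor share is total tract bp over both
  haplotypes divided by 2 × callable length; population min/mean/max are
  reported.
- **Region confirmation** extracts a candidate region's haplotypes from
  all panels, builds an NJ tree on haplotype p-distances rooted next to an
  outgroup haplotype, and reports which target haplotypes fall inside the
  minimal clade spanning the donor haplotypes.

## The synthetic cohort

The generator is a haplotype-mosaic model chosen over a full coalescent:
it produces LD, haplotype sharing, tract structure and — crucially — exact
truth labels with simple, auditable code (msprime remains available as an
external cross-validation oracle).

1. **Founders**: Poisson(μ·L) unlinked biallelic sites (μ = 5e−4/bp,
   L = 10 Mb by default, ≈ 5,000 ancestral SNPs), each with a uniform
   random frequency, kept polymorphic among 30 founder haplotypes.
2. **Lineage pools**: each lineage (indicine, taurine, banteng, gaur,
   outgroup) redraws site frequencies from the Balding–Nichols
   distribution at divergence F (0.1 / 0.3 / 0.5 / 0.5 / 0.7) and
   re-samples the pool, then gains *private fixed substitutions* at
   divergence-scaled densities (2e−5 / 5e−5 / 1e−4 / 1e−4 / 2e−4 per bp).
   These private sites are what real local-ancestry and U-statistic
   analyses key on; without them, frequency drift of shared polymorphism
   alone cannot separate lineages at window scale.
3. **Populations** are crossover mosaics of their lineage pool
   (Poisson(r·L·g) breakpoints per haplotype; recipient and control both
   draw from the indicine pool, which gives them realistic within-lineage
   haplotype sharing and a pairwise F_ST of a few percent). Cohort sizes
   mirror the real design: 16 recipient, 7 control, 10 taurine, 8 banteng,
   5 gaur, 2 outgroup diploids.
4. **Implants**: neutral donor tracts with exponential lengths (mean
   100 kb ≈ 1/(r·t_admix) for an admixture pulse ~1,000 generations ago)
   are copied from donor-panel haplotypes until the implanted share hits
   the target fraction to within 0.005 (the last tract is trimmed, so the
   realised share is essentially exact); default fractions 6.5% banteng
   and 5.5% gaur, the middle of the per-sample ranges reported for real
   East Asian indicine herds. Optional implants: one adaptive donor
   haplotype at a chosen carrier frequency in a fixed region, and a hard
   sweep (one core haplotype copied into a carrier fraction).

Everything is a pure function of (inputs, seed); identical seeds give
bit-identical output, which the determinism test checks at byte level
through VCF export.

**What the simulator does not emulate**: demographic history (growth,
bottlenecks, migration), mutation since admixture inside implanted tracts,
sequencing error, unphased or missing genotypes, recombination-rate
variation, and multi-chromosome genomes. Passing tests therefore
demonstrate correctness of the statistics and the detectability of clean
signals at desk scale — not performance on real resequencing data, where
phasing error and reference bias matter.

## Problem sizes and tolerances

Tests and the acceptance script run on a 10 Mb single-contig cohort
(~10,000 SNPs including lineage-private sites, 500 windows at 50 kb /
20 kb) — the package's chosen desk scale. Oracle-equivalence checks use
≤ 1,000-site fixtures at 1e−8 relative tolerance (exact integer equality
for U counts and LD-prune survivor sets). Calibration checks use 20 seeds
(D statistic: |Z| < 3 without gene flow, Z > 3 with a 6% pulse, in ≥ 18 of
20), 10 seeds for fraction recovery (±0.02 absolute, correct dose
ordering) and 20 replicates for sweep power (≥ 2 of 3 methods at the 0.5%
tail in ≥ 90%). Degenerate inputs (no informative sites, S = 0 windows,
all-missing sites, He = 0) yield flagged NaN results or explicit errors,
never silent zeros.
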