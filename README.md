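# bovintro

Selection scans and adaptive-introgression detection for bovine
resequencing panels — with a truth-tracked haplotype simulator so every
stage of the pipeline can be validated offline against known ground truth.

East Asian indicine cattle carry genomic tracts acquired from wild Asian
bovines (banteng, *Bos javanicus*, and gaur, *Bos gaurus*) through ancient
hybridisation; some of these tracts rose to high frequency because they
help with heat, humidity and disease. Detecting them from a multi-breed
VCF takes a stack of statistics that this package implements end to end:

- **Diversity & structure** — windowed nucleotide diversity θπ, observed /
  expected heterozygosity with inbreeding *F* = 1 − Ho/He, PLINK-style runs
  of homozygosity, LD decay, p-distance matrices, neighbor-joining trees,
  Patterson-normalised PCA, PLINK-style LD pruning.
- **Selection scans** — windowed Tajima's *D*, Weir–Cockerham *F*_ST
  (weighted window ratio Σa / Σ(a+b+c)), XP-EHH (ln(iHH_A/iHH_B),
  z-normalised genome-wide), empirical-tail candidate windows and
  multi-method candidate regions with gene overlap.
- **Introgression** — Patterson's D = Σ(ABBA−BABA) / Σ(ABBA+BABA) with a
  delete-one block jackknife; the windowed U statistic
  U_{control,target,donor}(w, x, y) counting sites fixed in the donor
  (p ≥ y), rare in the control (p < w) and common in the target (p > x);
  a window-based minimum-Hamming local-ancestry classifier; an
  incomplete-lineage-sorting filter P_ILS(m) = e^(−m/L)(1 + m/L) with
  L = 1/(r·t); per-sample introgression ratios; and haplotype/NJ-tree
  confirmation of candidate regions.
- **Simulator** — a haplotype-mosaic cohort generator (ancestral founders →
  Balding–Nichols lineage pools with private fixed substitutions →
  crossover-mosaic populations) that implants neutral and adaptive donor
  tracts and hard sweeps, emitting VCF + population map + truth BED.

Input is a phased multi-sample VCF plus a `sample<TAB>population` map;
all analyses are plain Python functions over a shared `HaplotypePanel`
container.

## Worked example

`examples/04_introgression.py` simulates the default cohort (10 Mb contig,
16 recipient + 7 control + 10 taurine + 8 banteng + 5 gaur + 2 outgroup
diploids, 6.5% banteng and 5.5% gaur tracts implanted, plus one adaptive
banteng haplotype at 60% frequency in 7.00–7.04 Mb) and runs the stack:

```
Patterson's D = 0.151 +- 0.013 (Z = 11.2, 20 blocks)
U-stat peak: 1:7000000-7050000 with 3 sites (adaptive region implanted at 7000000-7040000)

recovered banteng share: 5.907% (range 3.026%-9.574%; truth 6.738%)
recovered gaur share:    4.759%

region 7.00-7.04 Mb: 62% of recipient haplotypes nest inside the banteng clade
```

Z ≫ 3 confirms gene flow between the recipient and banteng; the U-statistic
peak lands exactly on the implanted adaptive region; the local-ancestry +
ILS pipeline recovers the per-sample donor shares close to the implanted
truth; and in the region tree 62% of recipient haplotypes nest with
banteng — matching the 60% implanted carrier frequency. The other examples
cover cohort simulation/export (`01`), diversity and structure (`02`) and
the three-method sweep scan (`03`).

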