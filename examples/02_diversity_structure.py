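"""Diversity and structure statistics on the simulated cohort.

Windowed nucleotide diversity, heterozygosity-based inbreeding F, runs of
homozygosity, PCA and a breed-level NJ tree from p-distances.
"""
import numpy as np

import bovintro as bi

panels, popmap, _ = bi.simulate_cohort(bi.CohortConfig(), seed=1)
comb = bi.merge_panels(panels)

print("per-population diversity (Ho, He, F = 1 - Ho/He, segregating sites):")
for pop, s in bi.het_and_f(comb, popmap).items():
    print(f"  {pop:<10} Ho={s.ho:.3f} He={s.he:.3f} F={s.f:+.3f} S={s.n_snps}")

pi = bi.pi_windows(comb, popmap, bi.RECIPIENT)
print(f"\nrecipient mean windowed pi: {np.mean([w.value for w in pi]):.3e} per bp "
      f"({len(pi)} windows of 50 kb, 20 kb step)")

res = bi.pca(bi.merge_panels({k: panels[k] for k in (bi.RECIPIENT, bi.CONTROL, bi.TAURINE)}))
print(f"PCA explained variance: PC1 {res.explained[0]:.1%}, PC2 {res.explained[1]:.1%}")
# PC1 separates taurine from the two indicine groups, as in real cattle panels.

d = bi.p_distance(comb.take_samples(
    [panels[p].sample_ids[0] for p in (bi.RECIPIENT, bi.CONTROL, bi.TAURINE, bi.BANTENG, bi.GAUR, bi.OUTGROUP)]
))
print("\nNJ tree of one sample per population (p-distance):")
print(" ", bi.nj_tree(d))
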