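"""Simulate the synthetic bovine cohort and export VCF + popmap + truth BED.

The cohort mirrors the real study design: 16 recipient (Xiangnan-like East
Asian indicine) cattle, an Indian-indicine control, taurine cattle, the two
wild donors (banteng, gaur) and a deep outgroup, with banteng/gaur tracts
implanted into the recipient at known genome fractions.
"""
from pathlib import Path

import bovintro as bi

cfg = bi.CohortConfig()
panels, popmap, truth = bi.simulate_cohort(cfg, seed=1)

out = Path("scratch/example_cohort")
paths = bi.export_cohort(panels, truth, out)

print(f"contig: {cfg.seq_length/1e6:.0f} Mb, {panels[bi.RECIPIENT].n_sites} SNPs")
for name, panel in panels.items():
    print(f"  {name:<10} {panel.n_samples:>3} diploids")
print(f"implanted tracts: {len(truth.tracts)}")
for donor in (bi.BANTENG, bi.GAUR):
    share = sum(t.end - t.start for t in truth.tracts if t.donor == donor)
    share /= panels[bi.RECIPIENT].n_haplotypes * cfg.seq_length
    print(f"  true {donor} genome share in recipient: {share:.3%}")
print("files:", ", ".join(str(p) for p in paths.values()))
# The true donor shares are the ground truth later examples try to recover.
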