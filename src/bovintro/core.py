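"""Site filtering, LD pruning and per-population allele frequencies."""
from __future__ import annotations

import logging

import numpy as np

from .panel import MISSING, HaplotypePanel, PopulationMap, SiteFrequencies

logger = logging.getLogger(__name__)


def site_filter(panel: HaplotypePanel, max_missing: float = 1.0, min_maf: float = 0.0) -> HaplotypePanel:
    """Keep sites with missing-allele fraction <= max_missing and MAF >= min_maf.

    MAF is computed over called alleles only; with ``min_maf`` = 0 the MAF
    condition is vacuous (sites with no calls are still subject to the
    missingness threshold).  Original coordinates are preserved.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    a = panel.alleles
    called = a != MISSING
    n_called = called.sum(axis=0)
    missing_frac = 1.0 - n_called / a.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, (a == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
        maf = np.minimum(p, 1.0 - p)
    keep = missing_frac <= max_missing
    if min_maf > 0:
        keep &= ~np.isnan(maf) & (maf >= min_maf)
    if not keep.any():
        logger.warning("site_filter removed every site (max_missing=%s, min_maf=%s)", max_missing, min_maf)
    return panel.take_sites(keep)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    panel: HaplotypePanel,
    snp_window: int = 50,
    snp_step: int = 10,
    r2_threshold: float = 0.1,
) -> HaplotypePanel:
    """PLINK ``--indep-pairwise``-style greedy dosage-r2 pruning.

    Within each window of ``snp_window`` surviving SNPs (advanced by
    ``snp_step``), for every pair with r2 > threshold the later-position
    SNP is removed; passes repeat until no further removal.  Deterministic
    and idempotent.
    """
    if panel.n_sites < 2:
        return panel
    dos = panel.dosage()
    keep = np.ones(panel.n_sites, dtype=bool)
    changed = True
    while changed:
        changed = False
        alive = np.flatnonzero(keep)
        start = 0
        while start < alive.size:
            window = alive[start : start + snp_window]
            for ai in range(len(window)):
                i = window[ai]
                if not keep[i]:
                    continue
                for aj in range(ai + 1, len(window)):
                    j = window[aj]
                    if not keep[j]:
                        continue
                    if _pairwise_r2(dos[:, i], dos[:, j]) > r2_threshold:
                        keep[j] = False  # later position removed
                        changed = True
            start += snp_step
    return panel.take_sites(keep)


def allele_freqs(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    outgroup: str | None = None,
) -> SiteFrequencies:
    """Per-population alternate (or derived) allele frequencies.

    Missing alleles are excluded from denominators.  With ``outgroup``,
    sites are polarized so the outgroup major allele is ancestral: where
    the outgroup alt frequency exceeds 1/2 every population's frequency is
    complemented.  Ties and outgroup-uncallable sites keep alt as derived
    and are flagged.
    """
    popmap.check_panel(panel)
    pops = popmap.populations()
    p: dict[str, np.ndarray] = {}
    n: dict[str, np.ndarray] = {}
    for pop in pops:
        rows = popmap.haplotype_rows(panel, pop)
        a = panel.alleles[rows]
        called = a != MISSING
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(n_called > 0, (a == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
        p[pop] = freq
        n[pop] = n_called

    flip = tie = None
    polarized = False
    if outgroup is not None:
        if outgroup not in p:
            raise KeyError(f"outgroup population {outgroup!r} not in population map")
        po = p[outgroup]
        flip = ~np.isnan(po) & (po > 0.5)
        tie = np.isnan(po) | (po == 0.5)
        for pop in pops:
            p[pop] = np.where(flip, 1.0 - p[pop], p[pop])
        polarized = True

    return SiteFrequencies(
        chrom=panel.chrom,
        positions=panel.positions.copy(),
        p=p,
        n=n,
        polarized=polarized,
        polarize_flip=flip,
        polarize_tie=tie,
    )
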