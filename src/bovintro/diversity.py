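"""Diversity and population-structure statistics.

Windowed nucleotide diversity, heterozygosity and inbreeding F, runs of
homozygosity, LD decay, p-distance matrices, neighbor-joining trees and
Patterson-normalized PCA.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .panel import MISSING, HaplotypePanel, PopulationMap, WindowSpec, WindowStat, make_windows

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def _per_site_pi(alleles: np.ndarray) -> np.ndarray:
    """Per-site pi = 2*c0*c1 / (n*(n-1)) over called alleles; NaN when n < 2."""
    called = alleles != MISSING
    n = called.sum(axis=0)
    c1 = (alleles == 1).sum(axis=0)
    c0 = n - c1
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * c0 * c1 / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi


def pi_windows(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    population: str,
    spec: WindowSpec = WindowSpec(),
) -> list[WindowStat]:
    """Windowed nucleotide diversity per bp (VCFtools --window-pi semantics).

    The window value is the sum of per-site pi over SNPs in the window
    divided by the window size in bp; sites with fewer than two called
    alleles are skipped.
    """
    rows = popmap.haplotype_rows(panel, population)
    pi = _per_site_pi(panel.alleles[rows])
    out = []
    for start, end in make_windows(panel.contig_length, spec):
        lo = np.searchsorted(panel.positions, start)
        hi = np.searchsorted(panel.positions, end)
        vals = pi[lo:hi]
        ok = ~np.isnan(vals)
        out.append(
            WindowStat(panel.chrom, start, end, "pi", float(vals[ok].sum()) / spec.size, int(ok.sum()))
        )
    return out


# ---------------------------------------------------------------------------
# heterozygosity and inbreeding
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    population: str
    ho: float
    he: float
    f: float  # 1 - Ho/He; NaN when He == 0
    n_snps: int
    per_sample_f: dict[str, float] = field(default_factory=dict)


def het_and_f(panel: HaplotypePanel, popmap: PopulationMap) -> dict[str, DiversitySummary]:
    """Observed/expected heterozygosity and F = 1 - Ho/He per population.

    Ho is the mean observed heterozygote fraction across sites segregating
    within the population; He is the mean unbiased expected heterozygosity
    2p(1-p) * n/(n-1).  A per-sample F (each sample's heterozygote fraction
    against the population He) is also reported; the population aggregate
    is the primary value.
    """
    popmap.check_panel(panel)
    out: dict[str, DiversitySummary] = {}
    for pop in popmap.populations():
        samples = popmap.samples(pop)
        rows = popmap.haplotype_rows(panel, pop)
        a = panel.alleles[rows]
        called = a != MISSING
        n = called.sum(axis=0)
        c1 = (a == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = c1 / n
        seg = (n >= 2) & (c1 > 0) & (c1 < n)
        n_snps = int(seg.sum())
        if n_snps == 0:
            out[pop] = DiversitySummary(pop, np.nan, np.nan, np.nan, 0)
            continue
        he_site = 2.0 * p[seg] * (1.0 - p[seg]) * n[seg] / (n[seg] - 1.0)
        he = float(he_site.mean())

        g0 = a[0::2][:, seg]
        g1 = a[1::2][:, seg]
        gt_called = (g0 != MISSING) & (g1 != MISSING)
        het = (g0 != g1) & gt_called
        ho_site = np.where(gt_called.sum(axis=0) > 0, het.sum(axis=0) / np.maximum(gt_called.sum(axis=0), 1), np.nan)
        ho = float(np.nanmean(ho_site))
        f = 1.0 - ho / he if he > 0 else np.nan
        if he == 0:
            logger.warning("He = 0 for population %s; F undefined", pop)
        per_sample = {}
        for i, s in enumerate(samples):
            ok = gt_called[i]
            ho_i = float(het[i, ok].mean()) if ok.any() else np.nan
            per_sample[s] = 1.0 - ho_i / he if he > 0 else np.nan
        out[pop] = DiversitySummary(pop, ho, he, f, n_snps, per_sample)
    return out


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RohSegment:
    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int


def roh_detect(
    panel: HaplotypePanel,
    sample: str,
    window_snps: int = 50,
    max_het_per_window: int = 1,
    min_len_kb: float = 500.0,
    min_snps: int = 50,
    window_threshold: float = 0.05,
) -> list[RohSegment]:
    """PLINK-style run-of-homozygosity scan for one sample.

    A sliding window of ``window_snps`` SNPs is homozygosity-compatible if
    it contains at most ``max_het_per_window`` heterozygous calls; a SNP is
    inside a run if the fraction of overlapping compatible windows exceeds
    ``window_threshold``.  Maximal runs are trimmed to homozygous end SNPs
    and reported when they meet the length and SNP-count minima.
    """
    h0, h1 = panel.haplotype_indices(sample)
    a0, a1 = panel.alleles[h0], panel.alleles[h1]
    called = (a0 != MISSING) & (a1 != MISSING)
    het = called & (a0 != a1)
    n_sites = panel.n_sites
    if n_sites < window_snps:
        return []

    het_c = np.concatenate(([0], np.cumsum(het)))
    n_windows = n_sites - window_snps + 1
    starts = np.arange(n_windows)
    compatible = (het_c[starts + window_snps] - het_c[starts]) <= max_het_per_window
    comp_c = np.concatenate(([0], np.cumsum(compatible)))

    idx = np.arange(n_sites)
    w_lo = np.maximum(idx - window_snps + 1, 0)
    w_hi = np.minimum(idx, n_windows - 1)
    n_over = (w_hi - w_lo + 1).clip(min=0)
    n_comp = comp_c[w_hi + 1] - comp_c[w_lo]
    in_run = np.zeros(n_sites, dtype=bool)
    ok = n_over > 0
    in_run[ok] = n_comp[ok] / n_over[ok] > window_threshold

    segments: list[RohSegment] = []
    hom = called & ~het
    i = 0
    while i < n_sites:
        if not in_run[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_sites and in_run[j + 1]:
            j += 1
        lo, hi = i, j
        while lo <= hi and not hom[lo]:
            lo += 1
        while hi >= lo and not hom[hi]:
            hi -= 1
        if lo <= hi:
            start = int(panel.positions[lo])
            end = int(panel.positions[hi]) + 1
            n_run = hi - lo + 1
            if end - start >= min_len_kb * 1000 and n_run >= min_snps:
                segments.append(RohSegment(sample, panel.chrom, start, end, n_run))
        i = j + 1
    return segments


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    population: str,
    max_dist: int = 500_000,
    bin_width: int = 50_000,
) -> dict[int, float]:
    """Mean dosage r2 by physical-distance bin within one population.

    Returns {bin start bp: mean r2} over all site pairs closer than
    ``max_dist``; sites monomorphic within the population are excluded.
    """
    samples = popmap.samples(population)
    sub = panel.take_samples(samples)
    dos = sub.dosage()
    col_mean = np.nanmean(dos, axis=0)
    filled = np.where(np.isnan(dos), col_mean, dos)
    sd = filled.std(axis=0)
    poly = sd > 0
    Z = (filled[:, poly] - filled[:, poly].mean(axis=0)) / sd[poly]
    pos = panel.positions[poly]
    n = Z.shape[0]

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i in range(len(pos) - 1):
        hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
        if hi <= i + 1:
            continue
        r = Z[:, i] @ Z[:, i + 1 : hi] / n
        d = pos[i + 1 : hi] - pos[i]
        for b in np.unique(d // bin_width):
            m = d // bin_width == b
            key = int(b) * bin_width
            sums[key] = sums.get(key, 0.0) + float((r[m] ** 2).sum())
            counts[key] = counts.get(key, 0) + int(m.sum())
    return {k: sums[k] / counts[k] for k in sorted(sums)}


# ---------------------------------------------------------------------------
# p-distance / NJ / PCA
# ---------------------------------------------------------------------------

@dataclass
class PDistanceMatrix:
    matrix: np.ndarray
    labels: list[str]
    n_compared: np.ndarray  # comparable positions per pair (0 => flagged)


def p_distance_rows(rows: np.ndarray, labels: list[str]) -> PDistanceMatrix:
    """Proportion of differing called positions between rows (pairwise deletion)."""
    X = np.asarray(rows, dtype=float)
    X[np.asarray(rows) == MISSING] = np.nan
    k = X.shape[0]
    dm = np.zeros((k, k))
    nc = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~np.isnan(X[i]) & ~np.isnan(X[j])
            nc[i, j] = nc[j, i] = ok.sum()
            if nc[i, j] == 0:
                dm[i, j] = dm[j, i] = np.nan
                logger.warning("no comparable positions between %s and %s", labels[i], labels[j])
            else:
                d = float((X[i, ok] != X[j, ok]).mean())
                dm[i, j] = dm[j, i] = d
    return PDistanceMatrix(dm, list(labels), nc)


def p_distance(panel: HaplotypePanel) -> PDistanceMatrix:
    """Diploid p-distance between samples: proportion of sites with unequal dosage."""
    dos = panel.dosage()
    dos = np.where(np.isnan(dos), MISSING, dos)
    return p_distance_rows(dos, list(panel.sample_ids))


def nj_tree(d: PDistanceMatrix) -> str:
    """Unrooted Saitou–Nei neighbor-joining tree as a Newick string.

    Negative branch lengths are clamped to zero.  Raises on NaN distances.
    """
    if np.isnan(d.matrix).any():
        raise ValueError("distance matrix contains NaN; cannot build NJ tree")
    if len(d.labels) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    dm = _SkbioDM(d.matrix, d.labels)
    tree = _skbio_nj(dm, neg_as_zero=True)
    return str(tree).strip()


@dataclass
class PcaResult:
    scores: np.ndarray  # (n_samples, n_components)
    explained: np.ndarray  # variance fractions, non-increasing
    sample_ids: list[str]


def pca(panel: HaplotypePanel, n_components: int = 10) -> PcaResult:
    """PCA of the dosage matrix with Patterson normalization.

    Dosages are mean-imputed per site, centered by 2*p_hat and scaled by
    sqrt(p_hat*(1-p_hat)); monomorphic sites are dropped.  Explained
    variance fractions are eigenvalue shares of the sample covariance.
    """
    dos = panel.dosage()
    col_mean = np.nanmean(dos, axis=0)
    filled = np.where(np.isnan(dos), col_mean, dos)
    p_hat = filled.mean(axis=0) / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites for PCA")
    X = (filled[:, poly] - 2 * p_hat[poly]) / np.sqrt(p_hat[poly] * (1 - p_hat[poly]))
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    lam = s**2
    explained = lam / lam.sum()
    k = min(n_components, len(s))
    return PcaResult(u[:, :k] * s[:k], explained[:k], list(panel.sample_ids))
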