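"""Selection scans: windowed Tajima's D, Weir–Cockerham F_ST, XP-EHH,
empirical-tail candidate windows, multi-method intersection and gene overlap.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import GeneRecord
from .panel import (
    MISSING,
    HaplotypePanel,
    PopulationMap,
    WindowSpec,
    WindowStat,
    make_windows,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants for n sequences."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_windows(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    population: str,
    spec: WindowSpec = WindowSpec(),
) -> list[WindowStat]:
    """Windowed Tajima's D for one population.

    Uses the population haplotype count n for the constants; per-site
    pairwise differences are computed over called alleles.  Windows with
    no segregating site are NaN-flagged.
    """
    rows = popmap.haplotype_rows(panel, population)
    n = len(rows)
    if n < 4:
        raise ValueError(f"Tajima's D needs >= 4 haplotypes, population {population!r} has {n}")
    const = tajima_constants(n)
    a = panel.alleles[rows]
    called = a != MISSING
    nc = called.sum(axis=0)
    c1 = (a == 1).sum(axis=0)
    c0 = nc - c1
    seg = (nc >= 2) & (c1 > 0) & (c1 < nc)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(seg, 2.0 * c0 * c1 / (nc * (nc - 1.0)), 0.0)

    out = []
    for start, end in make_windows(panel.contig_length, spec):
        lo = np.searchsorted(panel.positions, start)
        hi = np.searchsorted(panel.positions, end)
        S = int(seg[lo:hi].sum())
        if S == 0:
            out.append(WindowStat(panel.chrom, start, end, "tajd", float("nan"), 0))
            continue
        pi_sum = float(pi_site[lo:hi].sum())
        var = const["e1"] * S + const["e2"] * S * (S - 1)
        d = (pi_sum - S / const["a1"]) / math.sqrt(var)
        out.append(WindowStat(panel.chrom, start, end, "tajd", d, S))
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(panel: HaplotypePanel, popmap: PopulationMap, pops: tuple[str, str]):
    """Per-site Weir & Cockerham (1984) a, b, c variance components (r = 2)."""
    r = 2
    n_i, p_i, h_i = [], [], []
    for pop in pops:
        samples = popmap.samples(pop)
        sub = panel.take_samples(samples)
        g0, g1 = sub.alleles[0::2], sub.alleles[1::2]
        gt_ok = (g0 != MISSING) & (g1 != MISSING)
        ni = gt_ok.sum(axis=0).astype(float)
        alt = np.where(gt_ok, (g0 == 1).astype(int) + (g1 == 1).astype(int), 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = alt.sum(axis=0) / (2 * ni)
            hi = (np.where(gt_ok, (g0 != g1), False)).sum(axis=0) / ni
        n_i.append(ni)
        p_i.append(pi)
        h_i.append(hi)
    n_i = np.array(n_i)
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    usable = (n_i > 0).all(axis=0)
    n_bar = n_i.mean(axis=0)
    usable &= n_bar > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        nc = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        a = (n_bar / nc) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    # monomorphic-across-both sites contribute 0/0; drop them from sums
    usable &= ~((p_bar <= 0) | (p_bar >= 1)) | (h_bar > 0)
    return a, b, c, usable


def fst_windows(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    pops: tuple[str, str],
    spec: WindowSpec = WindowSpec(),
) -> list[WindowStat]:
    """Windowed weighted Weir–Cockerham F_ST: sum(a) / sum(a+b+c) per window.

    Negative window values are legitimate; windows with no usable site are
    NaN-flagged.
    """
    a, b, c, usable = _wc_components(panel, popmap, pops)
    out = []
    for start, end in make_windows(panel.contig_length, spec):
        lo = np.searchsorted(panel.positions, start)
        hi = np.searchsorted(panel.positions, end)
        u = usable[lo:hi]
        if not u.any():
            out.append(WindowStat(panel.chrom, start, end, "fst", float("nan"), 0))
            continue
        num = float(a[lo:hi][u].sum())
        den = float((a + b + c)[lo:hi][u].sum())
        val = num / den if den != 0 else float("nan")
        out.append(WindowStat(panel.chrom, start, end, "fst", val, int(u.sum())))
    return out


def fst_global(panel: HaplotypePanel, popmap: PopulationMap, pops: tuple[str, str]) -> float:
    """Genome-wide weighted Weir–Cockerham F_ST."""
    a, b, c, usable = _wc_components(panel, popmap, pops)
    den = float((a + b + c)[usable].sum())
    return float(a[usable].sum()) / den if den != 0 else float("nan")


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

def _ihh_pair(
    stacked: np.ndarray,
    n_a: int,
    positions: np.ndarray,
    core: int,
    cutoff: float,
    max_extend: int,
    max_gap: int,
) -> tuple[float, float]:
    """Integrated EHH for two stacked populations around one core site.

    ``stacked`` holds population A's haplotypes in the first ``n_a`` rows.
    Haplotype-identity groups over the extending span are refined site by
    site for the pooled sample; each population's EHH is the pooled
    grouping restricted to its rows (identity is the same relation).
    Extension stops (each direction independently) when the pooled EHH
    drops below ``cutoff``, the extension exceeds ``max_extend`` bp or an
    inter-SNP gap exceeds ``max_gap`` bp; both integrals share the same
    support, which makes the score antisymmetric under A<->B exactly.
    """
    n = stacked.shape[0]
    n_b = n - n_a
    den_a = n_a * (n_a - 1)
    den_b = n_b * (n_b - 1)
    den_p = n * (n - 1)
    ihh_a = ihh_b = 0.0
    for direction in (-1, 1):
        groups = np.zeros(n, dtype=np.int64)
        n_groups = 1
        ehh_a = ehh_b = 1.0
        pos_prev = positions[core]
        j = core
        while True:
            j += direction
            if j < 0 or j >= len(positions):
                break
            step = abs(int(positions[j]) - int(pos_prev))
            if step > max_gap or abs(int(positions[j]) - int(positions[core])) > max_extend:
                break
            col = stacked[:, j]
            key = groups * 3 + np.where(col == MISSING, 2, col)
            counts = np.bincount(key, minlength=3 * n_groups)
            counts_a = np.bincount(key[:n_a], minlength=len(counts))
            counts_b = counts - counts_a
            live = np.flatnonzero(counts)
            groups = np.searchsorted(live, key)
            n_groups = len(live)
            new_a = float((counts_a * (counts_a - 1)).sum()) / den_a
            new_b = float((counts_b * (counts_b - 1)).sum()) / den_b
            ihh_a += 0.5 * (ehh_a + new_a) * step
            ihh_b += 0.5 * (ehh_b + new_b) * step
            ehh_a, ehh_b = new_a, new_b
            pos_prev = positions[j]
            ehh_p = float((counts * (counts - 1)).sum()) / den_p
            if ehh_p < cutoff:
                break
    return ihh_a, ihh_b


@dataclass
class XpehhResult:
    windows: list[WindowStat]
    core_positions: np.ndarray
    raw_scores: np.ndarray
    norm_scores: np.ndarray
    n_skipped: int


def xpehh_scan(
    hapA: HaplotypePanel,
    hapB: HaplotypePanel,
    spec: WindowSpec = WindowSpec(),
    ehh_cutoff: float = 0.05,
    max_extend: int = 1_000_000,
    max_gap: int = 200_000,
) -> XpehhResult:
    """Cross-population EHH scan of phased panels A vs B (selscan-style).

    Per core SNP the raw score is ln(iHH_A / iHH_B) with trapezoidal
    integration over bp; scores are z-normalized genome-wide, and each
    window reports the mean normalized score of the cores inside it.
    Positive values indicate longer haplotype homozygosity in A.
    """
    if not np.array_equal(hapA.positions, hapB.positions):
        raise ValueError("panels must share the site map")
    stacked = np.vstack([hapA.alleles, hapB.alleles])
    n_a = hapA.n_haplotypes
    pos = hapA.positions
    raw = np.full(len(pos), np.nan)
    n_skipped = 0
    for core in range(len(pos)):
        ihh_a, ihh_b = _ihh_pair(stacked, n_a, pos, core, ehh_cutoff, max_extend, max_gap)
        if ihh_a <= 0 or ihh_b <= 0:
            n_skipped += 1
            continue
        raw[core] = math.log(ihh_a / ihh_b)
    ok = ~np.isnan(raw)
    if ok.sum() < 2:
        raise ValueError("too few scorable cores for XP-EHH normalization")
    mu, sd = raw[ok].mean(), raw[ok].std()
    norm = (raw - mu) / sd if sd > 0 else raw - mu

    windows = []
    for start, end in make_windows(hapA.contig_length, spec):
        lo = np.searchsorted(pos, start)
        hi = np.searchsorted(pos, end)
        vals = norm[lo:hi]
        good = ~np.isnan(vals)
        val = float(vals[good].mean()) if good.any() else float("nan")
        windows.append(WindowStat(hapA.chrom, start, end, "xpehh", val, int(good.sum())))
    return XpehhResult(windows, pos[ok], raw, norm, n_skipped)


# ---------------------------------------------------------------------------
# candidate machinery
# ---------------------------------------------------------------------------

def empirical_candidates(
    stats: list[WindowStat],
    tail_fraction: float = 0.005,
    direction: str = "high",
) -> list[WindowStat]:
    """Windows in the empirical tail (ties at the cut included).

    ``direction`` 'low' selects the smallest values (pi tail), 'high' the
    largest.  Windows with undefined values are excluded from ranking.
    Returns an empty list (with a warning) when there are too few windows
    for the tail to contain one window.
    """
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    defined = [w for w in stats if not math.isnan(w.value)]
    k = int(len(defined) * tail_fraction)
    if k < 1:
        logger.warning(
            "only %d defined windows; tail %g holds no window", len(defined), tail_fraction
        )
        return []
    vals = np.array([w.value for w in defined])
    order = np.argsort(vals, kind="stable")
    if direction == "high":
        order = order[::-1]
    cut = vals[order[k - 1]]
    if direction == "low":
        chosen = [w for w in defined if w.value <= cut]
    else:
        chosen = [w for w in defined if w.value >= cut]
    n = len(defined)
    for r, i in enumerate(order):
        defined[i].rank = (r + 1) / n  # tail quantile in the scan direction
    return chosen


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    methods: frozenset[str]
    genes: tuple[str, ...] = ()


def intersect_methods(
    candidates: dict[str, list[WindowStat]],
    min_methods: int = 2,
) -> list[CandidateRegion]:
    """Regions supported by >= min_methods candidate sets (bp overlap).

    Candidate windows of each method are merged, a sweep line finds the bp
    segments covered by enough distinct methods, and adjacent surviving
    segments are merged into maximal regions carrying the union of their
    supporting-method sets.
    """
    if len(candidates) < 2:
        raise ValueError("need candidate sets from at least two methods")
    chroms = {w.chrom for ws in candidates.values() for w in ws}
    regions: list[CandidateRegion] = []
    for chrom in sorted(chroms):
        merged: dict[str, list[tuple[int, int]]] = {}
        for method, ws in candidates.items():
            ivals = sorted((w.start, w.end) for w in ws if w.chrom == chrom)
            out: list[tuple[int, int]] = []
            for s, e in ivals:
                if out and s <= out[-1][1]:
                    out[-1] = (out[-1][0], max(out[-1][1], e))
                else:
                    out.append((s, e))
            merged[method] = out
        points = sorted({p for iv in merged.values() for s, e in iv for p in (s, e)})
        kept: list[tuple[int, int, set[str]]] = []
        for s, e in zip(points[:-1], points[1:]):
            support = {m for m, iv in merged.items() if any(a < e and s < b for a, b in iv)}
            if len(support) >= min_methods:
                if kept and kept[-1][1] == s:
                    kept[-1] = (kept[-1][0], e, kept[-1][2] | support)
                else:
                    kept.append((s, e, support))
        regions += [CandidateRegion(chrom, s, e, frozenset(sup)) for s, e, sup in kept]
    return regions


def genes_in_regions(
    regions: list[CandidateRegion],
    genes: list[GeneRecord],
) -> list[CandidateRegion]:
    """Attach gene names overlapping each region by >= 1 bp (half-open)."""
    out = []
    for r in regions:
        hits = tuple(
            g.name
            for g in genes
            if g.chrom == r.chrom and g.start < r.end and r.start < g.end
        )
        out.append(CandidateRegion(r.chrom, r.start, r.end, r.methods, hits))
    return out
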