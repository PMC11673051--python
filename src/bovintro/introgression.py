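"""Adaptive-introgression stack.

Patterson's D (ABBA-BABA) with a delete-one block jackknife, the windowed
U statistic for donor-fixed alleles, a transparent minimum-Hamming local
ancestry classifier (a stand-in for CRF-based tools such as RFMix, with a
margin rule instead of a posterior), an incomplete-lineage-sorting tract
length filter, per-sample introgression ratios, and haplotype/NJ-tree
confirmation of candidate regions.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .diversity import p_distance_rows
from .panel import (
    MISSING,
    HaplotypePanel,
    PopulationMap,
    SiteFrequencies,
    WindowSpec,
    WindowStat,
    make_windows,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Patterson's D
# ---------------------------------------------------------------------------

@dataclass
class DStatResult:
    d: float
    abba: float
    baba: float
    se: float
    z: float
    n_blocks: int
    block_size: int
    n_sites: int
    populations: tuple[str, str, str, str]


def patterson_d(
    freqs: SiteFrequencies,
    pops: tuple[str, str, str, str],
    block_size: int = 5_000_000,
    min_blocks: int = 20,
) -> DStatResult:
    """ABBA-BABA D for the tree ((P1,P2),P3),O from population frequencies.

    Per site ABBA = (1-p1)*p2*p3*(1-pO) and BABA = p1*(1-p2)*p3*(1-pO);
    D = sum(ABBA-BABA)/sum(ABBA+BABA).  The standard error comes from a
    delete-one jackknife over contiguous bp blocks, Z = D/SE.
    """
    p1, p2, p3, po = (freqs.p[p] for p in pops)
    ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(po))
    abba = (1 - p1[ok]) * p2[ok] * p3[ok] * (1 - po[ok])
    baba = p1[ok] * (1 - p2[ok]) * p3[ok] * (1 - po[ok])
    num = abba - baba
    den = abba + baba
    total_den = float(den.sum())
    if total_den == 0:
        logger.warning("no informative ABBA/BABA sites; D undefined")
        return DStatResult(float("nan"), 0.0, 0.0, float("nan"), float("nan"), 0, block_size, 0, pops)
    d = float(num.sum()) / total_den

    block_ids = freqs.positions[ok] // block_size
    blocks = np.unique(block_ids)
    if len(blocks) < min_blocks:
        raise ValueError(
            f"{len(blocks)} jackknife blocks of {block_size} bp; need >= {min_blocks} "
            "(reduce block_size)"
        )
    d_jack = []
    for b in blocks:
        m = block_ids != b
        den_b = float(den[m].sum())
        if den_b > 0:
            d_jack.append(float(num[m].sum()) / den_b)
    d_jack = np.array(d_jack)
    nb = len(d_jack)
    if nb >= 2:
        se = math.sqrt((nb - 1) / nb * ((d_jack - d_jack.mean()) ** 2).sum())
    else:
        se = float("nan")
    z = d / se if se > 0 else float("nan")
    return DStatResult(d, float(abba.sum()), float(baba.sum()), se, z, nb, block_size, int(ok.sum()), pops)


# ---------------------------------------------------------------------------
# U statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UThresholds:
    """U_{control,target,donor}(w, x, y) frequency thresholds.

    Counted sites have donor frequency >= y, control frequency < w and
    target frequency > x.  Defaults encode "fixed in the donor, < 1% in
    the control, > 50% in the target".
    """

    w: float = 0.01
    x: float = 0.5
    y: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.w < self.x <= self.y <= 1):
            raise ValueError(f"need 0 <= w < x <= y <= 1, got w={self.w} x={self.x} y={self.y}")


def u_stat_windows(
    freqs: SiteFrequencies,
    pops: tuple[str, str, str],
    thresholds: UThresholds = UThresholds(),
    spec: WindowSpec = WindowSpec(),
    contig_length: int | None = None,
) -> list[WindowStat]:
    """Windowed count of sites matching the U-statistic frequency pattern.

    ``pops`` is (control, target, donor).  Sites with an undefined
    frequency in any of the three panels are skipped (counted per window
    in ``n_sites``: the number of evaluable sites).
    """
    control, target, donor = pops
    pc, pt, pdn = freqs.p[control], freqs.p[target], freqs.p[donor]
    defined = ~(np.isnan(pc) | np.isnan(pt) | np.isnan(pdn))
    hit = defined & (pdn >= thresholds.y) & (pc < thresholds.w) & (pt > thresholds.x)
    if contig_length is None:
        contig_length = int(freqs.positions[-1]) + 1 if freqs.n_sites else 1
    out = []
    for start, end in make_windows(contig_length, spec):
        lo = np.searchsorted(freqs.positions, start)
        hi = np.searchsorted(freqs.positions, end)
        out.append(
            WindowStat(
                freqs.chrom, start, end, "u_count",
                float(hit[lo:hi].sum()), int(defined[lo:hi].sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# local ancestry
# ---------------------------------------------------------------------------

@dataclass
class AncestryTract:
    sample: str
    haplotype_index: int
    chrom: str
    start: int
    end: int
    donor: str
    margin: float  # mean (runner-up - best) distance over merged windows
    p_ils: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _window_bounds(positions: np.ndarray, contig_length: int, lo: int, hi: int) -> tuple[int, int]:
    """bp bounds of site-index window [lo, hi), midpointed between boundary SNPs."""
    start = 0 if lo == 0 else int((positions[lo - 1] + positions[lo]) // 2)
    end = contig_length if hi >= len(positions) else int((positions[hi - 1] + positions[hi]) // 2)
    return start, end


def local_ancestry(
    target: HaplotypePanel,
    references: dict[str, HaplotypePanel],
    window_snps: int = 20,
    margin: float = 0.1,
) -> list[AncestryTract]:
    """Window-based nearest-reference-haplotype ancestry assignment.

    Each non-overlapping window of ``window_snps`` sites on each target
    haplotype is assigned the reference panel whose closest haplotype has
    the minimum mean per-site Hamming distance, but only when the
    runner-up panel is at least ``margin`` further away; otherwise the
    window is unassigned.  Consecutive same-label windows merge into
    tracts whose bp bounds are midpointed between boundary SNPs.
    """
    for label, ref in references.items():
        if not np.array_equal(ref.positions, target.positions):
            raise ValueError(f"reference panel {label!r} does not share the site map")
        if ref.n_haplotypes < 2:
            raise ValueError(f"reference panel {label!r} needs >= 2 haplotypes")
    labels = list(references)
    n_sites = target.n_sites
    edges = list(range(0, n_sites, window_snps)) + [n_sites]
    n_win = len(edges) - 1

    T = target.alleles
    assign = np.full((target.n_haplotypes, n_win), -1, dtype=int)
    margins = np.zeros((target.n_haplotypes, n_win))
    for w in range(n_win):
        lo, hi = edges[w], edges[w + 1]
        tb = T[:, lo:hi]
        t_ok = tb != MISSING
        dists = np.full((target.n_haplotypes, len(labels)), np.inf)
        for k, label in enumerate(labels):
            rb = references[label].alleles[:, lo:hi]
            r_ok = rb != MISSING
            both = t_ok[:, None, :] & r_ok[None, :, :]
            mism = both & (tb[:, None, :] != rb[None, :, :])
            ncmp = both.sum(axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(ncmp > 0, mism.sum(axis=2) / np.maximum(ncmp, 1), np.inf)
            dists[:, k] = d.min(axis=1)
        order = np.argsort(dists, axis=1)
        best = order[:, 0]
        dbest = dists[np.arange(len(best)), best]
        drunner = dists[np.arange(len(best)), order[:, 1]]
        gap = drunner - dbest
        ok = np.isfinite(dbest) & (gap >= margin)
        assign[ok, w] = best[ok]
        margins[:, w] = np.where(np.isfinite(gap), gap, 0.0)

    tracts: list[AncestryTract] = []
    for h in range(target.n_haplotypes):
        sample = target.sample_ids[h // 2] if target.sample_ids else str(h)
        w = 0
        while w < n_win:
            lab = assign[h, w]
            if lab < 0:
                w += 1
                continue
            w2 = w
            while w2 + 1 < n_win and assign[h, w2 + 1] == lab:
                w2 += 1
            start, end = _window_bounds(
                target.positions, target.contig_length, edges[w], edges[w2 + 1]
            )
            tracts.append(
                AncestryTract(
                    sample, h % 2, target.chrom, start, end,
                    labels[lab], float(margins[h, w : w2 + 1].mean()),
                )
            )
            w = w2 + 1
    return tracts


# ---------------------------------------------------------------------------
# ILS probability filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IlsModel:
    """Expected length of a shared-ancestral (ILS) tract.

    Under recombination rate ``r`` per bp per generation and ``t``
    generations since donor/recipient divergence, an ILS tract has
    expected length L = 1/(r*t); introgressed tracts are much longer.
    """

    r: float = 1e-8
    t: float = 300_000.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.r <= 0 or self.t <= 0:
            raise ValueError("r and t must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def expected_length(self) -> float:
        return 1.0 / (self.r * self.t)


def ils_probability(m: float, model: IlsModel) -> float:
    """Probability that an ILS tract is at least ``m`` bp long.

    Survival of a Gamma(shape=2, rate=1/L) tract-length law with
    L = 1/(r*t): P = exp(-m/L) * (1 + m/L); monotone decreasing in m.
    """
    if m <= 0:
        raise ValueError(f"tract length must be positive, got {m}")
    x = m / model.expected_length
    return math.exp(-x) * (1.0 + x)


def filter_tracts(tracts: list[AncestryTract], model: IlsModel = IlsModel()) -> list[AncestryTract]:
    """Keep tracts too long to be plausibly ILS (P_ILS < alpha).

    P_ILS is recorded on every tract, including the discarded ones.
    """
    kept = []
    for t in tracts:
        t.p_ils = ils_probability(t.length, model)
        if t.p_ils < model.alpha:
            kept.append(t)
    n_drop = len(tracts) - len(kept)
    if n_drop:
        logger.info("ILS filter removed %d of %d tracts (alpha=%g)", n_drop, len(tracts), model.alpha)
    return kept


# ---------------------------------------------------------------------------
# introgression ratios
# ---------------------------------------------------------------------------

def introgression_ratio(
    tracts: list[AncestryTract],
    samples: list[str],
    callable_length: int,
    donors: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample donor genome share and a population min/mean/max summary.

    The share is total tract bp over both haplotypes divided by twice the
    callable genome length.
    """
    if callable_length <= 0:
        raise ValueError("callable_length must be positive")
    if donors is None:
        donors = sorted({t.donor for t in tracts})
    per = pd.DataFrame(0.0, index=list(samples), columns=list(donors))
    for t in tracts:
        if t.sample in per.index and t.donor in per.columns:
            per.loc[t.sample, t.donor] += t.length
    per /= 2.0 * callable_length
    summary = per.agg(["min", "mean", "max"])
    return per, summary


# ---------------------------------------------------------------------------
# region confirmation
# ---------------------------------------------------------------------------

@dataclass
class RegionConfirmResult:
    newick: str
    hap_labels: list[str]  # clustering order for haplotype-matrix display
    target_in_donor_clade: dict[str, bool]
    fraction_nested: float


def region_confirm(
    region: tuple[int, int],
    panels: dict[str, HaplotypePanel],
    target: str,
    donors: list[str],
    outgroup: str,
    min_snps: int = 5,
) -> RegionConfirmResult:
    """Haplotype p-distance NJ tree of a candidate region.

    Extracts the region's haplotypes from every panel, builds an NJ tree
    on haplotype p-distances, roots it at an outgroup haplotype, and
    reports which target haplotypes fall inside the minimal clade
    spanning all donor haplotypes.
    """
    start, end = region
    rows = []
    labels = []
    pop_of = {}
    for pop, panel in panels.items():
        sub = panel.take_region(start, end)
        for h in range(sub.n_haplotypes):
            sample = sub.sample_ids[h // 2] if sub.sample_ids else str(h)
            lab = f"{pop}.{sample}.{h % 2}"
            labels.append(lab)
            pop_of[lab] = pop
            rows.append(sub.alleles[h])
    n_snps = len(rows[0]) if rows else 0
    if n_snps < min_snps:
        raise ValueError(f"region has {n_snps} SNPs; need >= {min_snps}")

    dm = p_distance_rows(np.array(rows), labels)
    tree = _skbio_nj(_SkbioDM(dm.matrix, labels), neg_as_zero=True)

    # display order: single-linkage leaves of the distance matrix
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import squareform
    order = leaves_list(linkage(squareform(dm.matrix, checks=False), method="average"))
    ordered_labels = [labels[i] for i in order]

    out_label = next(l for l in labels if pop_of[l] == outgroup)
    out_tip = tree.find(out_label)
    rooted = tree.root_at(out_tip.parent) if out_tip.parent is not None else tree
    donor_tips = [rooted.find(l) for l in labels if pop_of[l] in donors]
    target_labels = [l for l in labels if pop_of[l] == target]
    if donor_tips:
        clade = rooted.lca(donor_tips) if len(donor_tips) > 1 else donor_tips[0].parent
        clade_set = {t.name for t in clade.tips()}
    else:
        clade_set = set()
    nested = {l: l in clade_set for l in target_labels}
    frac = sum(nested.values()) / len(nested) if nested else 0.0
    return RegionConfirmResult(str(rooted).strip(), ordered_labels, nested, frac)
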