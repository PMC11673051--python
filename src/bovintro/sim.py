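"""Truth-tracked multi-population haplotype simulator.

The generator is a haplotype-mosaic model, not a coalescent.  An
ancestral founder pool of unlinked biallelic sites is drifted into
lineage pools with a Balding–Nichols frequency draw; each lineage also
accumulates private fixed substitutions at a divergence-scaled density
(the signal real local-ancestry and U-statistic methods key on).  Each
descendant haplotype is then a crossover mosaic of its lineage pool,
which creates within-population linkage disequilibrium and haplotype
sharing.  Introgression is implanted by overwriting recipient haplotype
intervals with donor-panel haplotypes — either as random neutral tracts
or as one high-frequency adaptive haplotype in a chosen region — with
every implanted tract recorded in a TruthSet, so downstream detectors
can be scored against exact ground truth.

All randomness flows from explicit integer seeds; identical seeds give
bit-identical panels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import io as _io
from .panel import HaplotypePanel, PopulationMap


@dataclass(frozen=True)
class FounderPool:
    """Ancestral haplotype pool: unlinked sites at uniform random frequencies."""

    n_founders: int = 30
    seq_length: int = 10_000_000
    mut_rate_per_bp: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.seq_length <= 0:
            raise ValueError("seq_length must be > 0")
        if self.mut_rate_per_bp < 0:
            raise ValueError("mut_rate_per_bp must be >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """One descendant population.

    ``drift_F`` is the Balding–Nichols divergence of the population's site
    frequencies from the founder frequencies; ``private_mut_rate`` adds
    per-haplotype allele flips at existing segregating sites (the site map
    is shared across populations, so new sites are never created).
    """

    name: str
    n_diploids: int
    drift_F: float = 0.0
    private_mut_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_diploids < 1:
            raise ValueError("n_diploids must be >= 1")
        if not (0 <= self.drift_F < 1):
            raise ValueError("drift_F must lie in [0, 1)")


@dataclass(frozen=True)
class TruthTract:
    sample: str
    haplotype_index: int  # 0 or 1 within the sample
    chrom: str
    start: int  # 0-based half-open bp
    end: int
    donor: str


@dataclass
class TruthSet:
    """Simulator-emitted ground truth: introgressed tracts and sweep regions."""

    tracts: list[TruthTract] = field(default_factory=list)
    sweep_regions: list[tuple[str, int, int]] = field(default_factory=list)

    def total_tract_length(self) -> int:
        return sum(t.end - t.start for t in self.tracts)

    def genome_fraction(self, n_haplotypes: int, contig_length: int) -> float:
        return self.total_tract_length() / (n_haplotypes * contig_length)

    def sample_fraction(self, sample: str, contig_length: int, donor: str | None = None) -> float:
        """Diploid donor share: tract bp on both haplotypes / (2 * contig length)."""
        tot = sum(
            t.end - t.start
            for t in self.tracts
            if t.sample == sample and (donor is None or t.donor == donor)
        )
        return tot / (2 * contig_length)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.tracts:
                fh.write(
                    f"{t.chrom}\t{t.start}\t{t.end}\t{t.sample}|{t.haplotype_index}\t{t.donor}\t.\n"
                )
            for chrom, start, end in self.sweep_regions:
                fh.write(f"{chrom}\t{start}\t{end}\tsweep\tsweep\t.\n")


def make_founders(pool: FounderPool) -> HaplotypePanel:
    """Draw the founder haplotype pool.

    The number of segregating sites is Poisson(mut_rate * length); each
    site gets a uniform random frequency and a derived-allele count drawn
    from the matching binomial truncated to keep the site polymorphic
    among the founders.
    """
    rng = np.random.default_rng(pool.seed)
    n_sites = int(rng.poisson(pool.mut_rate_per_bp * pool.seq_length))
    n_sites = min(n_sites, pool.seq_length)
    positions = np.sort(rng.choice(pool.seq_length, size=n_sites, replace=False))
    alleles = np.zeros((pool.n_founders, n_sites), dtype=np.int8)
    freqs = rng.uniform(0.05, 0.95, size=n_sites)
    for j in range(n_sites):
        k = 0
        while not (0 < k < pool.n_founders):
            k = rng.binomial(pool.n_founders, freqs[j])
        carriers = rng.choice(pool.n_founders, size=k, replace=False)
        alleles[carriers, j] = 1
    return HaplotypePanel(
        alleles, positions, chrom="1", sample_ids=None, contig_length=pool.seq_length
    )


def drift_pool(founders: HaplotypePanel, F: float, seed: int = 0) -> HaplotypePanel:
    """Balding–Nichols drift of the pool: per-site Beta frequency draw, re-sampled haplotypes."""
    if not (0 < F < 1):
        raise ValueError("F must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = founders.alleles.mean(axis=0).clip(1e-6, 1 - 1e-6)
    p_drift = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
    alleles = (rng.random(founders.alleles.shape) < p_drift).astype(np.int8)
    return HaplotypePanel(
        alleles, founders.positions.copy(), founders.chrom, None, founders.contig_length
    )


def descend_population(
    founders: HaplotypePanel,
    spec: PopulationSpec,
    recomb_rate: float = 1e-8,
    generations: int = 200,
    seed: int = 0,
) -> HaplotypePanel:
    """Descend a diploid population from a haplotype pool.

    Optional drift first (Balding–Nichols frequency draw, pool re-sampled
    at the drifted frequencies), then each output haplotype is a crossover
    mosaic of the pool with Poisson(recomb_rate * L * generations)
    breakpoints, plus Poisson(private_mut_rate * L) private allele flips.
    """
    if founders.n_haplotypes == 0 or founders.n_sites == 0:
        raise ValueError("founder panel is empty")
    rng = np.random.default_rng(seed)
    L = founders.contig_length
    n_sites = founders.n_sites
    base = founders.alleles
    if spec.drift_F > 0:
        base = drift_pool(founders, spec.drift_F, seed=rng.integers(2**31)).alleles

    n_hap = 2 * spec.n_diploids
    out = np.empty((n_hap, n_sites), dtype=np.int8)
    mean_x = recomb_rate * L * generations
    for h in range(n_hap):
        n_break = int(rng.poisson(mean_x))
        if n_break == 0:
            out[h] = base[rng.integers(founders.n_haplotypes)]
        else:
            breaks = np.sort(rng.integers(0, L, size=n_break))
            bounds = np.concatenate(([0], breaks, [L]))
            sources = rng.integers(0, founders.n_haplotypes, size=len(bounds) - 1)
            seg_of_site = np.searchsorted(bounds, founders.positions, side="right") - 1
            out[h] = base[sources[seg_of_site], np.arange(n_sites)]
        if spec.private_mut_rate > 0:
            n_mut = int(rng.poisson(spec.private_mut_rate * L))
            if n_mut:
                idx = rng.integers(0, n_sites, size=min(n_mut, n_sites))
                out[h, idx] = 1 - out[h, idx]

    sample_ids = [f"{spec.name}_{i}" for i in range(spec.n_diploids)]
    return HaplotypePanel(out, founders.positions.copy(), founders.chrom, sample_ids, L)


def implant_introgression(
    recipient: HaplotypePanel,
    donor: HaplotypePanel,
    fraction: float,
    tract_len_mean: float = 100_000,
    seed: int = 0,
    donor_label: str = "donor",
    truth: TruthSet | None = None,
) -> tuple[HaplotypePanel, TruthSet]:
    """Overwrite recipient haplotypes with neutral donor tracts of known location.

    Tract lengths are exponential with mean ``tract_len_mean``; tracts are
    added (never overlapping a previous truth tract on one haplotype)
    until the implanted share of the recipient genome equals ``fraction``
    to within 0.005 — the last tract is trimmed, so the realised share is
    essentially exact.  Returns a modified copy and the TruthSet.
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if not np.array_equal(recipient.positions, donor.positions):
        raise ValueError("recipient and donor must share the site map")
    rng = np.random.default_rng(seed)
    out = recipient.copy()
    truth = truth if truth is not None else TruthSet()
    L = recipient.contig_length
    n_hap = recipient.n_haplotypes
    target = fraction * n_hap * L
    implanted = 0.0
    occupied: dict[int, list[tuple[int, int]]] = {h: [] for h in range(n_hap)}
    for t in truth.tracts:  # existing tracts (any donor) block placement
        if out.sample_ids and t.sample in out.sample_ids:
            h = 2 * out.sample_ids.index(t.sample) + t.haplotype_index
            occupied[h].append((t.start, t.end))

    max_tries = 100_000
    tries = 0
    while implanted < target - 1 and tries < max_tries:
        tries += 1
        h = int(rng.integers(n_hap))
        length = max(1, int(rng.exponential(tract_len_mean)))
        length = min(length, int(target - implanted) + 1, L)
        start = int(rng.integers(0, L - length + 1))
        end = start + length
        if any(s < end and start < e for s, e in occupied[h]):
            continue
        occupied[h].append((start, end))
        d = int(rng.integers(donor.n_haplotypes))
        lo = np.searchsorted(out.positions, start)
        hi = np.searchsorted(out.positions, end)
        out.alleles[h, lo:hi] = donor.alleles[d, lo:hi]
        sample = out.sample_ids[h // 2] if out.sample_ids else str(h)
        truth.tracts.append(TruthTract(sample, h % 2, out.chrom, start, end, donor_label))
        implanted += length
    return out, truth


def implant_adaptive_introgression(
    recipient: HaplotypePanel,
    donor: HaplotypePanel,
    region: tuple[int, int],
    carrier_fraction: float,
    seed: int = 0,
    donor_label: str = "donor",
    truth: TruthSet | None = None,
) -> tuple[HaplotypePanel, TruthSet]:
    """Sweep one donor haplotype to high frequency over ``region``.

    Emulates adaptive introgression: a single donor haplotype's segment is
    copied into ``carrier_fraction`` of recipient haplotypes, each carrier
    recorded as a truth tract.
    """
    start, end = region
    if not (0 <= start < end <= recipient.contig_length):
        raise ValueError(f"region {region} outside contig")
    if not (0 < carrier_fraction <= 1):
        raise ValueError("carrier_fraction must lie in (0, 1]")
    if not np.array_equal(recipient.positions, donor.positions):
        raise ValueError("recipient and donor must share the site map")
    rng = np.random.default_rng(seed)
    out = recipient.copy()
    truth = truth if truth is not None else TruthSet()
    lo = np.searchsorted(out.positions, start)
    hi = np.searchsorted(out.positions, end)
    d = int(rng.integers(donor.n_haplotypes))
    n_carriers = int(round(carrier_fraction * out.n_haplotypes))
    carriers = rng.choice(out.n_haplotypes, size=n_carriers, replace=False)
    out.alleles[np.ix_(carriers, np.arange(lo, hi))] = donor.alleles[d, lo:hi]
    for h in sorted(int(c) for c in carriers):
        sample = out.sample_ids[h // 2] if out.sample_ids else str(h)
        truth.tracts.append(TruthTract(sample, h % 2, out.chrom, start, end, donor_label))
    return out, truth


def implant_sweep(
    panel: HaplotypePanel,
    region: tuple[int, int],
    carrier_fraction: float,
    seed: int = 0,
    truth: TruthSet | None = None,
) -> tuple[HaplotypePanel, TruthSet]:
    """Copy one core haplotype over ``region`` into a fraction of haplotypes."""
    start, end = region
    if not (0 <= start < end <= panel.contig_length):
        raise ValueError(f"region {region} outside contig [0, {panel.contig_length})")
    if not (0 < carrier_fraction <= 1):
        raise ValueError("carrier_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = panel.copy()
    truth = truth if truth is not None else TruthSet()
    lo = np.searchsorted(out.positions, start)
    hi = np.searchsorted(out.positions, end)
    core_hap = int(rng.integers(out.n_haplotypes))
    core = out.alleles[core_hap, lo:hi].copy()
    n_carriers = int(round(carrier_fraction * out.n_haplotypes))
    carriers = rng.choice(out.n_haplotypes, size=n_carriers, replace=False)
    out.alleles[np.ix_(carriers, np.arange(lo, hi))] = core
    truth.sweep_regions.append((out.chrom, start, end))
    return out, truth


# ---------------------------------------------------------------------------
# study cohort
# ---------------------------------------------------------------------------

#: canonical population labels of the synthetic cohort
RECIPIENT, CONTROL, TAURINE, BANTENG, GAUR, OUTGROUP = (
    "xiangnan", "indicine", "taurine", "banteng", "gaur", "outgroup",
)

@dataclass(frozen=True)
class CohortConfig:
    """Conditions of the synthetic bovine study cohort.

    Mirrors the real panel design: an East-Asian indicine recipient herd
    and an Indian-indicine control sharing one indicine lineage pool, a
    taurine group, the two wild donors (banteng, gaur) and a deep
    outgroup (buffalo-like), on a single 10 Mb contig.  Each lineage pool
    is a Balding–Nichols drift of the ancestral founders plus private
    fixed substitutions at a divergence-scaled density; populations are
    crossover mosaics of their pool.
    """

    seq_length: int = 10_000_000
    mut_rate_per_bp: float = 5e-4
    n_founders: int = 30
    recomb_rate: float = 1e-8
    generations_domestic: int = 200
    generations_wild: int = 500
    n_recipient: int = 16
    n_control: int = 7
    n_taurine: int = 10
    n_banteng: int = 8
    n_gaur: int = 5
    n_outgroup: int = 2
    drift_indicine: float = 0.1
    drift_taurine: float = 0.3
    drift_wild: float = 0.5
    drift_outgroup: float = 0.7
    private_rate_indicine: float = 2e-5
    private_rate_taurine: float = 5e-5
    private_rate_wild: float = 1e-4
    private_rate_outgroup: float = 2e-4
    banteng_fraction: float = 0.065
    gaur_fraction: float = 0.055
    tract_len_mean: float = 100_000
    sweep_region: tuple[int, int] | None = None
    sweep_carrier_fraction: float = 0.9
    adaptive_region: tuple[int, int] | None = None
    adaptive_carrier_fraction: float = 0.6
    adaptive_donor: str = BANTENG


def _lineage_pools(
    founders: HaplotypePanel,
    drifts: dict[str, float],
    private_rates: dict[str, float],
    seed: int,
) -> dict[str, HaplotypePanel]:
    """Drift the founders into lineage pools sharing one extended site map.

    Each lineage gets Poisson(rate * L) private sites, fixed derived in
    that lineage's pool and ancestral everywhere else.
    """
    rng = np.random.default_rng(seed)
    L = founders.contig_length
    used = set(int(p) for p in founders.positions)
    private_pos: dict[str, np.ndarray] = {}
    for lin in drifts:
        n_priv = int(rng.poisson(private_rates[lin] * L))
        chosen: list[int] = []
        while len(chosen) < n_priv:
            cand = int(rng.integers(L))
            if cand not in used:
                used.add(cand)
                chosen.append(cand)
        private_pos[lin] = np.sort(np.array(chosen, dtype=np.int64))

    all_pos = np.sort(
        np.concatenate([founders.positions] + [private_pos[l] for l in drifts])
    )
    shared_idx = np.searchsorted(all_pos, founders.positions)
    priv_idx = {lin: np.searchsorted(all_pos, private_pos[lin]) for lin in drifts}

    p = founders.alleles.mean(axis=0).clip(1e-6, 1 - 1e-6)
    pools: dict[str, HaplotypePanel] = {}
    for lin, F in drifts.items():
        alleles = np.zeros((founders.n_haplotypes, len(all_pos)), dtype=np.int8)
        p_drift = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        alleles[:, shared_idx] = (
            rng.random((founders.n_haplotypes, founders.n_sites)) < p_drift
        ).astype(np.int8)
        alleles[:, priv_idx[lin]] = 1  # lineage-private fixed substitutions
        pools[lin] = HaplotypePanel(alleles, all_pos, founders.chrom, None, L)
    return pools


def simulate_cohort(
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
) -> tuple[dict[str, HaplotypePanel], PopulationMap, TruthSet]:
    """Simulate the full study cohort with truth-tracked introgression.

    Banteng then gaur neutral tracts are implanted into the recipient at
    the configured genome fractions; an optional adaptive-introgression
    haplotype and an optional hard sweep are implanted afterwards.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(16) >> 1]  # keep < 2**31
    founders = make_founders(
        FounderPool(config.n_founders, config.seq_length, config.mut_rate_per_bp, seeds[0])
    )
    drifts = {
        "indicine_lineage": config.drift_indicine,
        "taurine_lineage": config.drift_taurine,
        "banteng_lineage": config.drift_wild,
        "gaur_lineage": config.drift_wild,
        "outgroup_lineage": config.drift_outgroup,
    }
    private_rates = {
        "indicine_lineage": config.private_rate_indicine,
        "taurine_lineage": config.private_rate_taurine,
        "banteng_lineage": config.private_rate_wild,
        "gaur_lineage": config.private_rate_wild,
        "outgroup_lineage": config.private_rate_outgroup,
    }
    pools = _lineage_pools(founders, drifts, private_rates, seeds[1])

    plan = [
        (RECIPIENT, "indicine_lineage", config.n_recipient, config.generations_domestic, seeds[2]),
        (CONTROL, "indicine_lineage", config.n_control, config.generations_domestic, seeds[3]),
        (TAURINE, "taurine_lineage", config.n_taurine, config.generations_domestic, seeds[4]),
        (BANTENG, "banteng_lineage", config.n_banteng, config.generations_wild, seeds[5]),
        (GAUR, "gaur_lineage", config.n_gaur, config.generations_wild, seeds[6]),
        (OUTGROUP, "outgroup_lineage", config.n_outgroup, config.generations_wild, seeds[7]),
    ]
    panels = {
        name: descend_population(
            pools[lin], PopulationSpec(name, n), config.recomb_rate, gens, s
        )
        for name, lin, n, gens, s in plan
    }

    truth = TruthSet()
    if config.adaptive_region is not None:
        panels[RECIPIENT], truth = implant_adaptive_introgression(
            panels[RECIPIENT], panels[config.adaptive_donor], config.adaptive_region,
            config.adaptive_carrier_fraction, seeds[8],
            donor_label=config.adaptive_donor, truth=truth,
        )
    if config.banteng_fraction > 0:
        panels[RECIPIENT], truth = implant_introgression(
            panels[RECIPIENT], panels[BANTENG], config.banteng_fraction,
            config.tract_len_mean, seeds[9], donor_label=BANTENG, truth=truth,
        )
    if config.gaur_fraction > 0:
        panels[RECIPIENT], truth = implant_introgression(
            panels[RECIPIENT], panels[GAUR], config.gaur_fraction,
            config.tract_len_mean, seeds[10], donor_label=GAUR, truth=truth,
        )
    if config.sweep_region is not None:
        panels[RECIPIENT], truth = implant_sweep(
            panels[RECIPIENT], config.sweep_region, config.sweep_carrier_fraction,
            seeds[11], truth=truth,
        )

    mapping = {s: name for name, p in panels.items() for s in p.sample_ids}
    return panels, PopulationMap(mapping), truth


def merge_panels(panels: Mapping[str, HaplotypePanel]) -> HaplotypePanel:
    """Stack cohort panels (sharing a site map) into one multi-population panel."""
    items = list(panels.values())
    ref = items[0]
    for p in items[1:]:
        if not np.array_equal(p.positions, ref.positions):
            raise ValueError("panels do not share the site map")
    alleles = np.vstack([p.alleles for p in items])
    sample_ids = [s for p in items for s in p.sample_ids]
    return HaplotypePanel(alleles, ref.positions.copy(), ref.chrom, sample_ids, ref.contig_length)


def export_cohort(
    panels: Mapping[str, HaplotypePanel],
    truth: TruthSet,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write VCF + popmap TSV + truth BED for a simulated cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "popmap": out / "popmap.tsv",
        "truth": out / "truth.bed",
    }
    _io.write_vcf(paths["vcf"], dict(panels), popmap_path=paths["popmap"])
    truth.write_bed(paths["truth"])
    return paths
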