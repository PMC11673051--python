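"""Core data carriers: haplotype panels, population maps, windows, frequencies.

Coordinates are 0-based half-open everywhere inside the package; the VCF
boundary (io module) converts to/from 1-based positions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: sentinel for a missing allele in the haplotype matrix
MISSING = -1


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in bp (default 50 kb windows, 20 kb step)."""

    size: int = 50_000
    step: int = 20_000

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"window size must be > 0, got {self.size}")
        if not (0 < self.step <= self.size):
            raise ValueError(
                f"step must satisfy 0 < step <= size, got step={self.step} size={self.size}"
            )


def make_windows(contig_length: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """All windows [k*step, k*step+size) whose start lies inside the contig.

    The last window may overhang the contig end.
    """
    if contig_length <= 0:
        raise ValueError(f"contig_length must be > 0, got {contig_length}")
    starts = range(0, contig_length, spec.step)
    return [(s, s + spec.size) for s in starts]


class HaplotypePanel:
    """Phased 0/1 haplotype matrix with positions and sample pairing.

    ``alleles`` is (n_haplotypes, n_sites) int8 over {0, 1, MISSING}.
    When ``sample_ids`` is given, haplotypes 2i and 2i+1 form diploid
    sample i; a panel without sample_ids is an unpaired pool (founders).
    """

    def __init__(
        self,
        alleles: np.ndarray,
        positions: np.ndarray,
        chrom: str = "1",
        sample_ids: Sequence[str] | None = None,
        contig_length: int | None = None,
    ):
        alleles = np.asarray(alleles, dtype=np.int8)
        positions = np.asarray(positions, dtype=np.int64)
        if alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if alleles.shape[1] != positions.shape[0]:
            raise ValueError(
                f"{alleles.shape[1]} allele columns but {positions.shape[0]} positions"
            )
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if sample_ids is not None:
            sample_ids = list(sample_ids)
            if 2 * len(sample_ids) != alleles.shape[0]:
                raise ValueError(
                    f"{len(sample_ids)} samples need {2 * len(sample_ids)} haplotypes, "
                    f"panel has {alleles.shape[0]}"
                )
        self.alleles = alleles
        self.positions = positions
        self.chrom = str(chrom)
        self.sample_ids = sample_ids
        if contig_length is None:
            contig_length = int(positions[-1]) + 1 if positions.size else 1
        self.contig_length = int(contig_length)

    # -- basic geometry -------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_samples(self) -> int:
        if self.sample_ids is None:
            raise ValueError("panel has no sample pairing")
        return len(self.sample_ids)

    def haplotype_indices(self, sample: str) -> tuple[int, int]:
        i = self.sample_ids.index(sample)
        return 2 * i, 2 * i + 1

    # -- derived matrices ----------------------------------------------
    def dosage(self) -> np.ndarray:
        """(n_samples, n_sites) float alt-allele dosage; NaN where any allele missing."""
        if self.sample_ids is None:
            raise ValueError("dosage requires diploid sample pairing")
        a = self.alleles.astype(float)
        a[self.alleles == MISSING] = np.nan
        return a[0::2] + a[1::2]

    # -- subsetting ------------------------------------------------------
    def take_sites(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypePanel(
            self.alleles[:, idx],
            self.positions[idx],
            self.chrom,
            self.sample_ids,
            self.contig_length,
        )

    def take_region(self, start: int, end: int) -> "HaplotypePanel":
        """Sites with start <= pos < end (half-open bp interval)."""
        lo = np.searchsorted(self.positions, start, side="left")
        hi = np.searchsorted(self.positions, end, side="left")
        return self.take_sites(np.arange(lo, hi))

    def take_samples(self, samples: Sequence[str]) -> "HaplotypePanel":
        if self.sample_ids is None:
            raise ValueError("panel has no sample pairing")
        rows = []
        for s in samples:
            h0, h1 = self.haplotype_indices(s)
            rows += [h0, h1]
        return HaplotypePanel(
            self.alleles[rows],
            self.positions,
            self.chrom,
            list(samples),
            self.contig_length,
        )

    def take_haplotypes(self, rows: Sequence[int]) -> "HaplotypePanel":
        """Unpaired sub-panel of the given haplotype rows."""
        return HaplotypePanel(
            self.alleles[np.asarray(rows, dtype=int)],
            self.positions,
            self.chrom,
            None,
            self.contig_length,
        )

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            self.alleles.copy(),
            self.positions.copy(),
            self.chrom,
            None if self.sample_ids is None else list(self.sample_ids),
            self.contig_length,
        )

    def __repr__(self) -> str:  # pragma: no cover
        pairing = f"{len(self.sample_ids)} samples" if self.sample_ids else "unpaired"
        return (
            f"<HaplotypePanel {self.n_haplotypes} haplotypes x {self.n_sites} sites "
            f"({pairing}, chrom={self.chrom})>"
        )


@dataclass
class PopulationMap:
    """Sample -> population label mapping."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for s, p in self.mapping.items():
            if not p:
                raise ValueError(f"empty population label for sample {s!r}")

    def __getitem__(self, sample: str) -> str:
        return self.mapping[sample]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.mapping.values():
            seen.setdefault(p)
        return list(seen)

    def samples(self, population: str) -> list[str]:
        out = [s for s, p in self.mapping.items() if p == population]
        if not out:
            raise KeyError(f"population {population!r} has no samples")
        return out

    def haplotype_rows(self, panel: HaplotypePanel, population: str) -> list[int]:
        rows: list[int] = []
        for s in self.samples(population):
            h0, h1 = panel.haplotype_indices(s)
            rows += [h0, h1]
        return rows

    def check_panel(self, panel: HaplotypePanel) -> None:
        unmapped = [s for s in (panel.sample_ids or []) if s not in self.mapping]
        if unmapped:
            raise ValueError(f"samples missing from population map: {unmapped}")


@dataclass
class WindowStat:
    """One genomic window of a scan statistic.

    ``value`` is NaN when the statistic is undefined in the window (never
    silently zero); ``rank`` is the empirical quantile in [0, 1] once
    assigned by the candidate machinery.
    """

    chrom: str
    start: int
    end: int
    name: str
    value: float
    n_sites: int = 0
    rank: float | None = None

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class SiteFrequencies:
    """Per-population alternate/derived allele frequency and called-allele count.

    ``p[pop]`` is NaN where no alleles were called.  When built with an
    outgroup (see core.allele_freqs) frequencies are polarized so the
    outgroup major allele is ancestral; ``polarize_tie`` flags sites where
    the outgroup was tied or uncallable and the alt allele was kept as
    derived.
    """

    chrom: str
    positions: np.ndarray
    p: dict[str, np.ndarray]
    n: dict[str, np.ndarray]
    polarized: bool = False
    polarize_flip: np.ndarray | None = None
    polarize_tie: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    def populations(self) -> list[str]:
        return list(self.p)
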