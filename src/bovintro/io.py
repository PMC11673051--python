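"""VCF, population-map and BED input/output.

Reading goes through cyvcf2; writing emits the small phased biallelic
subset of VCF v4.2 this package produces.  Internal coordinates are
0-based half-open and become 1-based POS only here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from cyvcf2 import VCF

from .panel import MISSING, HaplotypePanel, PopulationMap

logger = logging.getLogger(__name__)


@dataclass
class ReadReport:
    """Counts of records dropped while reading a VCF."""

    n_kept: int = 0
    n_non_biallelic_snp: int = 0


def read_vcf(
    path: str | Path,
    popmap_path: str | Path | None = None,
    require_phased: bool = False,
) -> tuple[HaplotypePanel, PopulationMap | None, ReadReport]:
    """Load biallelic SNPs into a HaplotypePanel.

    Non-biallelic or non-SNP records are dropped and counted in the report.
    With ``require_phased``, any called unphased genotype raises.  All
    records must share one chromosome (single-contig panels).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    positions: list[int] = []
    chrom = None
    report = ReadReport()
    contig_length = None
    try:
        seqlens = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:  # header without contig lengths
        seqlens = {}

    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            report.n_non_biallelic_snp += 1
            continue
        if chrom is None:
            chrom = var.CHROM
            contig_length = seqlens.get(chrom)
        elif var.CHROM != chrom:
            raise ValueError(
                f"multiple chromosomes in VCF ({chrom!r}, {var.CHROM!r}); "
                "read one contig at a time"
            )
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, (a0, a1, phased) in enumerate(var.genotypes):
            if require_phased and not phased and a0 >= 0 and a1 >= 0:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]!r} at "
                    f"{var.CHROM}:{var.POS} but phased input required"
                )
            col[2 * i] = a0 if a0 >= 0 else MISSING
            col[2 * i + 1] = a1 if a1 >= 0 else MISSING
        rows.append(col)
        positions.append(var.POS - 1)  # 1-based VCF -> 0-based internal
        report.n_kept += 1

    if report.n_non_biallelic_snp:
        logger.info("dropped %d non-biallelic/non-SNP records", report.n_non_biallelic_snp)

    alleles = (
        np.stack(rows, axis=1) if rows else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    panel = HaplotypePanel(
        alleles,
        np.asarray(positions, dtype=np.int64),
        chrom or "1",
        samples,
        contig_length,
    )
    popmap = None
    if popmap_path is not None:
        popmap = read_popmap(popmap_path)
        popmap.check_panel(panel)
    return panel, popmap, report


def write_vcf(
    path: str | Path,
    panels: Mapping[str, HaplotypePanel] | HaplotypePanel,
    popmap_path: str | Path | None = None,
) -> None:
    """Write one or more panels (sharing a site map) as a phased VCF v4.2.

    ``panels`` maps population label -> panel; sample columns are
    concatenated in mapping order.  Optionally writes the matching
    ``sample<TAB>population`` map.
    """
    if isinstance(panels, HaplotypePanel):
        panels = {"pop": panels}
    items = list(panels.items())
    ref_panel = items[0][1]
    for name, p in items[1:]:
        if not np.array_equal(p.positions, ref_panel.positions) or p.chrom != ref_panel.chrom:
            raise ValueError(f"panel {name!r} does not share the site map")
        if p.sample_ids is None:
            raise ValueError(f"panel {name!r} has no diploid sample pairing")
    if ref_panel.sample_ids is None:
        raise ValueError("panels must carry diploid sample pairing for VCF export")

    sample_line: list[str] = []
    for _, p in items:
        sample_line += list(p.sample_ids)
    if len(set(sample_line)) != len(sample_line):
        raise ValueError("duplicate sample ids across panels")

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref_panel.chrom},length={ref_panel.contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_line) + "\n")
        for j in range(ref_panel.n_sites):
            pos = int(ref_panel.positions[j]) + 1  # 0-based internal -> 1-based VCF
            gts: list[str] = []
            for _, p in items:
                col = p.alleles[:, j]
                for i in range(p.n_samples):
                    a0, a1 = col[2 * i], col[2 * i + 1]
                    s0 = "." if a0 == MISSING else str(int(a0))
                    s1 = "." if a1 == MISSING else str(int(a1))
                    gts.append(f"{s0}|{s1}")
            fh.write(
                f"{ref_panel.chrom}\t{pos}\t.\tA\tC\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )

    if popmap_path is not None:
        with open(popmap_path, "w") as fh:
            for name, p in items:
                for s in p.sample_ids:
                    fh.write(f"{s}\t{name}\n")


def read_popmap(path: str | Path) -> PopulationMap:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"popmap line {lineno}: expected sample<TAB>population")
            mapping[parts[0]] = parts[1]
    return PopulationMap(mapping)


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int  # 0-based half-open, as in BED
    end: int
    name: str


def read_gene_bed(path: str | Path) -> list[GeneRecord]:
    """BED4+ gene annotation (chrom, start, end, name); half-open coordinates."""
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line {lineno}: need at least 4 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"BED line {lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"BED line {lineno}: end <= start")
            genes.append(GeneRecord(parts[0], start, end, parts[3]))
    return genes
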