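"""File formats: minimal VCF, site tables, BED/BED-graph, PHYLIP, Newick.

Coordinate conventions: VCF positions are 1-based, BED intervals 0-based
half-open, all in-memory coordinates 0-based; conversion happens only at
these boundaries.  Each locus of a :class:`~canid_popgen.loci.LocusSet`
becomes one pseudo-contig in VCF output, with REF = ancestral allele and
ALT = derived allele by convention.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import ParseError
from .loci import Locus, LocusSet

logger = logging.getLogger("canid_popgen")

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_site_table",
    "read_site_table",
    "write_bed",
    "read_bed",
    "write_phylip",
    "read_phylip",
]

_REF, _ALT = "A", "T"  # arbitrary ancestral/derived alleles for simulated data


def write_vcf(data: LocusSet, path: str | Path) -> None:
    """Write a LocusSet as an uncompressed minimal VCF (GT only).

    One pseudo-contig per locus; internal 0-based positions become
     1-based VCF POS.  Missing genotypes become './.'.
    """
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=canid_popgen\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for loc in data.loci:
            fh.write(f"##contig=<ID={loc.id},length={loc.length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(data.samples)
            + "\n"
        )
        for loc in data.loci:
            for k in range(loc.n_sites):
                gts = "\t".join(
                    gt_strings[int(g)] for g in loc.genotypes[k]
                )
                fh.write(
                    f"{loc.id}\t{loc.positions[k] + 1}\t.\t{_REF}\t{_ALT}\t.\t"
                    f"PASS\tAA={_REF}\tGT\t{gts}\n"
                )


def read_vcf(path: str | Path, default_locus_length: int = 1000) -> LocusSet:
    """Read a VCF of biallelic SNVs into a LocusSet.

    Multi-allelic and indel records are skipped (counts logged).  Contig
    lengths come from the header when present, else
    ``default_locus_length``.  REF is taken as the ancestral allele.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        logger.warning("empty VCF file %s", path)
        return LocusSet([], [])
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    lengths = dict(zip(vcf.seqnames, vcf.seqlens or []))
    per_contig: dict[str, list[tuple[int, np.ndarray]]] = {}
    contig_order: list[str] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        gts = np.array(
            [
                -1 if a is None or b is None or a < 0 or b < 0 else int(a > 0) + int(b > 0)
                for a, b, *_ in variant.genotypes
            ],
            dtype=np.int8,
        )
        if variant.CHROM not in per_contig:
            per_contig[variant.CHROM] = []
            contig_order.append(variant.CHROM)
        per_contig[variant.CHROM].append((variant.POS - 1, gts))
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNV records", n_skipped)

    # preserve header contig order for contigs with data; headerless contigs
    # appear in record order
    ordered = [c for c in vcf.seqnames if c in per_contig]
    ordered += [c for c in contig_order if c not in ordered]
    loci = []
    for contig in ordered:
        recs = per_contig[contig]
        positions = np.array([p for p, _ in recs], dtype=np.int64)
        genotypes = np.array([g for _, g in recs], dtype=np.int8)
        order = np.argsort(positions, kind="stable")
        length = int(lengths.get(contig, default_locus_length))
        loci.append(Locus(contig, length, positions[order], genotypes[order]))
    return LocusSet(samples, loci)


def write_site_table(data: LocusSet, path: str | Path) -> None:
    """Plain-text site table: locus, position and one genotype column per sample."""
    locus_idx, g = data.stacked()
    rows = {
        "locus": [data.loci[i].id for i in locus_idx],
        "pos": np.concatenate([loc.positions for loc in data.loci])
        if data.loci
        else [],
    }
    df = pd.DataFrame(rows)
    for j, s in enumerate(data.samples):
        df[s] = g[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_site_table(
    path: str | Path, locus_length: int = 1000
) -> LocusSet:
    """Inverse of :func:`write_site_table` (loci in order of appearance)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return LocusSet(list(df.columns[2:]), [])
    samples = list(df.columns[2:])
    loci = []
    for locus_id, group in df.groupby("locus", sort=False):
        loci.append(
            Locus(
                str(locus_id),
                locus_length,
                group["pos"].to_numpy(dtype=np.int64),
                group[samples].to_numpy(dtype=np.int8),
            )
        )
    return LocusSet(samples, loci)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write a BED-style table (chrom, start, end, extra columns), no header."""
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path, columns: list[str] | None = None) -> pd.DataFrame:
    """Read a BED-style table; first three columns are chrom, start, end."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns or ["chrom", "start", "end"])
    names = ["chrom", "start", "end"]
    if columns:
        names = columns
    elif df.shape[1] > 3:
        names += [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = names[: df.shape[1]]
    return df


def write_phylip(values: np.ndarray, samples: list[str], path: str | Path) -> None:
    """Write a square distance matrix in PHYLIP format."""
    with open(path, "w") as fh:
        fh.write(f"{len(samples)}\n")
        for name, row in zip(samples, values):
            cells = " ".join(f"{v:.10g}" for v in row)
            fh.write(f"{name:<10s} {cells}\n")


def read_phylip(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square PHYLIP distance matrix -> (values, sample names)."""
    lines = Path(path).read_text().strip().splitlines()
    if not lines:
        raise ParseError("empty PHYLIP file", line=1)
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("first line must give the taxon count", line=1) from None
    if len(lines) - 1 < n:
        raise ParseError(f"expected {n} rows, found {len(lines) - 1}")
    names, rows = [], []
    for i, line in enumerate(lines[1 : n + 1], start=2):
        parts = line.split()
        if len(parts) != n + 1:
            raise ParseError(f"expected name + {n} values", line=i)
        names.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError:
            raise ParseError("non-numeric distance value", line=i) from None
    return np.array(rows), names
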