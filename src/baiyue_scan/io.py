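"""Readers and writers for every external format the pipeline touches.

Formats
-------
* VCF v4.2 (bi-allelic SNVs; FORMAT ``GT`` and ``DP``; INFO ``AA`` for the
  ancestral allele), read through cyvcf2/htslib, written as plain text.
* Two-column tab-delimited population map with a header line.
* BED3+name gene intervals, 0-based half-open.
* GMT gene sets (set id, description, gene names; tab-delimited).
* Tab-delimited ROH segment tables and population x haplogroup count tables.

All text readers accept gzip-compressed input (``.gz`` suffix).

Coordinate conventions are closed under round-trip: BED is 0-based
half-open, VCF positions are 1-based, and a gene whose BED interval ends
at ``e`` contains VCF position ``e`` (not ``e + 1``).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SiteCounts",
    "GeneInterval",
    "GeneSet",
    "RohSegment",
    "HaplogroupTable",
    "read_popmap",
    "write_popmap",
    "read_vcf_counts",
    "read_vcf_genotypes",
    "write_vcf",
    "read_bed_genes",
    "write_bed_genes",
    "read_gmt",
    "write_gmt",
    "read_roh",
    "write_roh",
    "read_haplogroup_table",
    "write_haplogroup_table",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SiteCounts:
    """Per-site, per-population allele counts with depth/missingness metadata.

    ``counts`` maps population label -> (derived_count, called_chromosomes).
    For unpolarizable sites (AA missing or matching neither allele) the
    "derived" orientation falls back to the ALT allele and ``polarizable``
    is False; such sites remain usable for F_ST/PBS (which are
    polarity-invariant) but are excluded from DAF outputs.
    """

    chrom: str
    pos: int  # 1-based
    site_id: str
    ref: str
    alt: str
    ancestral: Optional[str]
    counts: Dict[str, Tuple[int, int]]
    site_mean_depth: float  # NaN when no DP available
    missing_fraction: float
    polarizable: bool = True


@dataclass(frozen=True)
class GeneInterval:
    """A gene body as a BED-style 0-based half-open interval."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class GeneSet:
    set_id: str
    description: str
    genes: List[str]


@dataclass(frozen=True)
class RohSegment:
    """A run of homozygosity; start/end are 1-based inclusive."""

    sample: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class HaplogroupTable:
    """Population x haplogroup count matrix.

    ``n`` is the per-population sample size, i.e. the row sum of counts.
    """

    populations: List[str]
    haplogroups: List[str]
    counts: np.ndarray  # shape (n_pops, n_haplogroups), non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.populations), len(self.haplogroups)):
            raise FormatError("haplogroup count matrix shape mismatch")
        if np.any(self.counts < 0):
            raise FormatError("negative haplogroup count")

    @property
    def n(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------


def read_popmap(path) -> Tuple[Dict[str, str], List[str]]:
    """Read a two-column (sample, population) table with a header line.

    Returns the sample -> population mapping and the ordered list of
    distinct population labels (order of first appearance).
    """
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty population map")
        mapping: Dict[str, str] = {}
        labels: List[str] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-delimited columns")
            sample, pop = fields[0], fields[1]
            if sample in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            mapping[sample] = pop
            if pop not in labels:
                labels.append(pop)
    if not mapping:
        raise FormatError(f"{path}: population map has no samples")
    return mapping, labels


def write_popmap(mapping: Mapping[str, str], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("sample\tpopulation\n")
        for sample, pop in mapping.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def read_vcf_counts(
    vcf_path,
    popmap: Mapping[str, str],
    populations: Sequence[str],
) -> Iterator[SiteCounts]:
    """Stream per-site, per-population derived-allele counts from a VCF.

    Polarization uses the INFO ``AA`` tag (uppercased): AA == REF means
    the derived allele is ALT; AA == ALT means it is REF.  Sites with a
    missing or mismatching AA are yielded with ``polarizable=False`` and
    ALT-oriented counts.  Multi-allelic and non-SNV records are skipped
    (counts logged).  ``missing_fraction`` is the fraction of selected
    samples with a missing genotype; ``site_mean_depth`` is the mean of
    available per-sample DP (NaN when DP is absent).
    """
    vcf = VCF(str(vcf_path))
    header_samples = list(vcf.samples)
    sample_index = {s: i for i, s in enumerate(header_samples)}
    pop_indices: Dict[str, np.ndarray] = {}
    for pop in populations:
        members = [s for s, p in popmap.items() if p == pop]
        missing = [s for s in members if s not in sample_index]
        if missing:
            raise FormatError(
                f"samples of population {pop!r} absent from VCF header: {missing[:5]}"
            )
        if not members:
            raise FormatError(f"population {pop!r} has no samples in the popmap")
        pop_indices[pop] = np.array([sample_index[s] for s in members], dtype=int)
    selected = np.concatenate([pop_indices[p] for p in populations])

    n_skipped = 0
    n_unpolarizable = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        aa_raw = v.INFO.get("AA")
        aa = aa_raw.upper() if isinstance(aa_raw, str) else None
        polarizable = aa in (ref, alt)
        if not polarizable:
            n_unpolarizable += 1

        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None

        counts: Dict[str, Tuple[int, int]] = {}
        for pop in populations:
            idx = pop_indices[pop]
            g = gt[idx]
            called = int(2 * np.count_nonzero(g != 2))
            alt_count = int(np.count_nonzero(g == 1) + 2 * np.count_nonzero(g == 3))
            if polarizable and aa == alt:
                derived = called - alt_count
            else:
                derived = alt_count
            counts[pop] = (derived, called)

        g_sel = gt[selected]
        missing_fraction = float(np.count_nonzero(g_sel == 2) / g_sel.size)
        if dp is not None:
            d = np.asarray(dp).reshape(-1)[selected].astype(float)
            d = d[d >= 0]
            site_mean_depth = float(d.mean()) if d.size else float("nan")
        else:
            site_mean_depth = float("nan")

        site_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        yield SiteCounts(
            chrom=v.CHROM,
            pos=v.POS,
            site_id=site_id,
            ref=ref,
            alt=alt,
            ancestral=aa,
            counts=counts,
            site_mean_depth=site_mean_depth,
            missing_fraction=missing_fraction,
            polarizable=polarizable,
        )
    if n_skipped:
        logger.info("read_vcf_counts: skipped %d multi-allelic/non-SNV records", n_skipped)
    if n_unpolarizable:
        logger.info(
            "read_vcf_counts: %d sites unpolarizable (AA missing or mismatched)",
            n_unpolarizable,
        )


def read_vcf_genotypes(
    vcf_path, samples: Optional[Sequence[str]] = None
) -> Tuple[pd.DataFrame, np.ndarray, List[str]]:
    """Load ALT-dosage genotypes (-1 missing, 0/1/2) for LD computation.

    Returns a site table (chrom, pos, site_id), the dosage matrix with
    one row per site, and the sample list in matrix column order.
    """
    vcf = VCF(str(vcf_path))
    header_samples = list(vcf.samples)
    if samples is None:
        samples = header_samples
        idx = np.arange(len(header_samples))
    else:
        index = {s: i for i, s in enumerate(header_samples)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise FormatError(f"samples absent from VCF header: {missing[:5]}")
        idx = np.array([index[s] for s in samples], dtype=int)
    rows = []
    dosages = []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        gt = np.asarray(v.gt_types)[idx]
        dose = np.where(gt == 2, -1, np.where(gt == 3, 2, gt)).astype(np.int8)
        site_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        rows.append((v.CHROM, v.POS, site_id))
        dosages.append(dose)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "site_id"])
    matrix = np.array(dosages, dtype=np.int8) if dosages else np.empty((0, len(idx)), np.int8)
    return sites, matrix, list(samples)


def write_vcf(
    sites: pd.DataFrame,
    alt_dosage: np.ndarray,
    depth: Optional[np.ndarray],
    samples: Sequence[str],
    path,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write a bi-allelic SNV VCF v4.2 with GT/DP and an AA INFO tag.

    ``sites`` needs columns chrom, pos, site_id, ref, alt, aa;
    ``alt_dosage`` holds per-sample ALT-allele dosages (-1 = missing).
    Records are sorted by (chrom, pos) on write (logged if input order
    changed).  ``read_vcf_counts`` on the output reproduces the input
    counts exactly.
    """
    if len(sites) != len(alt_dosage):
        raise ValueError("site table and genotype matrix differ in length")
    if alt_dosage.shape[1] != len(samples):
        raise ValueError("genotype matrix width differs from sample list")

    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(sites))):
        logger.info("write_vcf: input records were unsorted; sorting by (chrom, pos)")
    path = Path(path)
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        chroms = list(dict.fromkeys(sites["chrom"].iloc[order]))
        for c in chroms:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        chrom_arr = sites["chrom"].to_numpy()
        pos_arr = sites["pos"].to_numpy()
        id_arr = sites["site_id"].to_numpy()
        ref_arr = sites["ref"].to_numpy()
        alt_arr = sites["alt"].to_numpy()
        aa_arr = sites["aa"].to_numpy()
        for i in order:
            dose = alt_dosage[i]
            if depth is not None:
                dp_row = depth[i]
                calls = "\t".join(
                    f"{_GT_STRINGS[int(d)]}:{int(dp)}" for d, dp in zip(dose, dp_row)
                )
            else:
                calls = "\t".join(_GT_STRINGS[int(d)] for d in dose)
            fmt = "GT:DP" if depth is not None else "GT"
            fh.write(
                f"{chrom_arr[i]}\t{pos_arr[i]}\t{id_arr[i]}\t{ref_arr[i]}\t"
                f"{alt_arr[i]}\t.\t.\tAA={aa_arr[i]}\t{fmt}\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# BED / GMT
# ---------------------------------------------------------------------------


def read_bed_genes(path) -> List[GeneInterval]:
    """Read BED3+name gene intervals; returns them sorted by (chrom, start)."""
    genes: List[GeneInterval] = []
    seen = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED3+name needs 4 columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end} for {name}"
                )
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            genes.append(GeneInterval(gene_id=name, chrom=chrom, start=start, end=end))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_bed_genes(genes: Sequence[GeneInterval], path) -> None:
    with _open_text(path, "wt") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def read_gmt(path) -> List[GeneSet]:
    """Read GMT gene sets; duplicate genes within a set are dropped (logged)."""
    sets: List[GeneSet] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-delimited fields"
                )
            set_id, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.info(
                    "read_gmt: set %s: removed %d duplicate genes",
                    set_id,
                    len(genes) - len(unique),
                )
            if not unique:
                raise FormatError(f"{path}:{lineno}: gene set {set_id!r} is empty")
            sets.append(GeneSet(set_id=set_id, description=description, genes=unique))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with _open_text(path, "wt") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description] + list(s.genes)) + "\n")


# ---------------------------------------------------------------------------
# ROH / haplogroup tables
# ---------------------------------------------------------------------------


def read_roh(path) -> List[RohSegment]:
    """Read a tab-delimited ROH table (sample, chrom, start, end, length)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: ROH table needs columns {sorted(required)}")
    segments = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end - start + 1 <= 0:
            raise FormatError(
                f"{path}: non-positive ROH length for {row.sample} {row.chrom}:{start}-{end}"
            )
        if hasattr(row, "length") and int(row.length) != end - start + 1:
            raise FormatError(
                f"{path}: stated length {row.length} != end - start + 1 "
                f"for {row.sample} {row.chrom}:{start}-{end}"
            )
        segments.append(
            RohSegment(sample=str(row.sample), chrom=str(row.chrom), start=start, end=end)
        )
    return segments


def write_roh(segments: Sequence[RohSegment], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("sample\tchrom\tstart\tend\tlength\n")
        for s in segments:
            fh.write(f"{s.sample}\t{s.chrom}\t{s.start}\t{s.end}\t{s.length}\n")


def read_haplogroup_table(path) -> HaplogroupTable:
    """Read a population x haplogroup count table (first column = population)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        frac, _ = np.modf(counts.astype(float))
        if np.any(frac != 0) or np.any(~np.isfinite(counts.astype(float))):
            bad = np.argwhere(frac != 0)
            r, c = (bad[0] if len(bad) else (0, 0))
            raise FormatError(
                f"{path}: non-integer count at population {df.index[r]!r}, "
                f"haplogroup {df.columns[c]!r}"
            )
        counts = counts.astype(int)
    if np.any(counts < 0):
        raise FormatError(f"{path}: negative haplogroup count")
    return HaplogroupTable(
        populations=list(df.index.astype(str)),
        haplogroups=list(df.columns.astype(str)),
        counts=counts,
    )


def write_haplogroup_table(table: HaplogroupTable, path) -> None:
    df = pd.DataFrame(table.counts, index=table.populations, columns=table.haplogroups)
    df.index.name = "population"
    df.to_csv(path, sep="\t")
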