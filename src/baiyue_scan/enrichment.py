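"""Polygenic-selection gene-set machinery.

A pathway under polygenic selection should show a PBS distribution
shifted toward larger values than the genomic background.  The pipeline
mirrors the standard recipe: curate pathway collections (drop genes off
the autosomes or absent from the interval list, then sets with fewer
than ten surviving genes), pool per-set PBS values over gene bodies
extended by a 20-kb flank (variants shared by two genes of a set count
once), test each set against the complement of scanned variants with a
one-sided Mann-Whitney U, and Bonferroni-adjust over the number of
curated sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .io import GeneInterval, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetTestResult",
    "prepare_gene_sets",
    "variants_to_genes",
    "mwu_shift_test",
    "run_polygenic_scan",
]

#: combined-sample-size cutoff below which the exact Mann-Whitney null
#: distribution is enumerated instead of the tie/continuity-corrected
#: normal approximation.
EXACT_CUTOFF = 20


@dataclass
class GeneSetTestResult:
    set_id: str
    n_genes_used: int
    n_variants_in_set: int
    n_variants_background: int
    u_statistic: float
    p_one_sided: float
    p_bonferroni: float
    significant: bool


def prepare_gene_sets(
    sets: Sequence[GeneSet],
    genes: Sequence[GeneInterval],
    autosomes: Sequence[str],
    min_size: int = 10,
) -> Tuple[List[GeneSet], pd.DataFrame]:
    """Curate a gene-set collection for the polygenic test.

    Per set: drop genes absent from the interval list ("unmapped") or on
    non-autosomes, then drop the set itself if fewer than ``min_size``
    genes remain.  Returns the curated sets and a per-set report
    (n_input, n_unmapped, n_nonautosomal, n_kept, kept).
    """
    autosome_set = set(autosomes)
    gene_chrom = {g.gene_id: g.chrom for g in genes}
    curated: List[GeneSet] = []
    rows = []
    for s in sets:
        unmapped = [g for g in s.genes if g not in gene_chrom]
        nonauto = [g for g in s.genes if g in gene_chrom and gene_chrom[g] not in autosome_set]
        kept_genes = [g for g in s.genes if g in gene_chrom and gene_chrom[g] in autosome_set]
        kept = len(kept_genes) >= min_size
        rows.append(
            {
                "set_id": s.set_id,
                "n_input": len(s.genes),
                "n_unmapped": len(unmapped),
                "n_nonautosomal": len(nonauto),
                "n_kept": len(kept_genes),
                "kept": kept,
            }
        )
        if kept:
            curated.append(GeneSet(set_id=s.set_id, description=s.description, genes=kept_genes))
    report = pd.DataFrame(rows)
    if not curated:
        raise ValueError("no gene sets survive curation")
    logger.info("prepare_gene_sets: %d of %d sets survive curation", len(curated), len(sets))
    return curated, report


def variants_to_genes(
    pbs_table: pd.DataFrame,
    genes: Sequence[GeneInterval],
    flank_bp: int = 20000,
) -> Dict[str, np.ndarray]:
    """Map each gene to the indices (rows of ``pbs_table``) of variants
    inside its body +/- ``flank_bp``.

    A variant inside several flanked genes contributes to each; set-level
    pooling later deduplicates variants shared by genes of one set.
    """
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        lo = max(1, g.start + 1 - flank_bp)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, g.end + flank_bp + 1, g.gene_id)
    assignment: Dict[str, List[int]] = {g.gene_id: [] for g in genes}
    for i, (chrom, pos) in enumerate(zip(pbs_table["chrom"], pbs_table["pos"])):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree[pos]:
            assignment[iv.data].append(i)
    return {gid: np.array(idx, dtype=int) for gid, idx in assignment.items()}


def mwu_shift_test(
    set_values: np.ndarray, background_values: np.ndarray
) -> Tuple[float, float]:
    """One-sided ("greater") Mann-Whitney U of set vs background.

    Exact enumeration of the null distribution when the combined sample
    is smaller than ``EXACT_CUTOFF`` and tie-free; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(set_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mwu_shift_test needs non-empty samples on both sides")
    combined = x.size + y.size
    has_ties = np.unique(np.concatenate([x, y])).size < combined
    method = "exact" if (combined < EXACT_CUTOFF and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="greater", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def run_polygenic_scan(
    pbs_table: pd.DataFrame,
    curated_sets: Sequence[GeneSet],
    genes: Sequence[GeneInterval],
    flank_bp: int = 20000,
    genic_background_only: bool = False,
    alpha: float = 0.05,
) -> List[GeneSetTestResult]:
    """Test every curated set for a PBS shift above the background.

    The background of each test is the complement: every scanned variant
    not assigned to a gene of the set under test ("the rest of the
    genome").  With ``genic_background_only`` the complement is further
    restricted to variants assigned to at least one curated-set gene.
    Bonferroni uses m = number of curated sets; results are sorted by
    raw p.
    """
    if not curated_sets:
        raise ValueError("run_polygenic_scan needs at least one curated set")
    pbs_values = pbs_table["pbs"].to_numpy()
    gene_idx = variants_to_genes(pbs_table, genes, flank_bp=flank_bp)
    genic_mask = np.zeros(len(pbs_values), dtype=bool)
    curated_gene_ids = {g for s in curated_sets for g in s.genes}
    for gid in curated_gene_ids:
        if gid in gene_idx:
            genic_mask[gene_idx[gid]] = True

    m = len(curated_sets)
    results: List[GeneSetTestResult] = []
    for s in curated_sets:
        in_set = np.zeros(len(pbs_values), dtype=bool)
        used = 0
        for gid in s.genes:
            idx = gene_idx.get(gid)
            if idx is not None and idx.size:
                in_set[idx] = True
                used += 1
        set_vals = pbs_values[in_set]
        bg_mask = ~in_set if not genic_background_only else (genic_mask & ~in_set)
        bg_vals = pbs_values[bg_mask]
        if set_vals.size == 0 or bg_vals.size == 0:
            logger.warning("set %s: empty side (set=%d, bg=%d); skipped", s.set_id, set_vals.size, bg_vals.size)
            continue
        u, p = mwu_shift_test(set_vals, bg_vals)
        p_bonf = min(1.0, m * p)
        results.append(
            GeneSetTestResult(
                set_id=s.set_id,
                n_genes_used=used,
                n_variants_in_set=int(set_vals.size),
                n_variants_background=int(bg_vals.size),
                u_statistic=u,
                p_one_sided=p,
                p_bonferroni=p_bonf,
                significant=p_bonf < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_one_sided, r.set_id))
    return results


def results_table(results: Sequence[GeneSetTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "n_genes_used": [r.n_genes_used for r in results],
            "n_variants_in_set": [r.n_variants_in_set for r in results],
            "n_variants_background": [r.n_variants_background for r in results],
            "U": [r.u_statistic for r in results],
            "p_one_sided": [r.p_one_sided for r in results],
            "p_bonferroni": [r.p_bonferroni for r in results],
            "significant": [r.significant for r in results],
        }
    )
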