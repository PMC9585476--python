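"""Genome-wide PBS scan for a three-population design.

A trio names a target population A, an ingroup B and an outgroup C.
After site filtering (site-mean depth, missingness, polymorphism in at
least one trio population) each surviving site gets per-site
Weir-Cockerham F_ST for the three pairs, branch lengths
T = -log(1 - F_ST), and PBS_A = (T_AB + T_AC - T_BC)/2.  Thresholds are
percentiles of the post-filter PBS distribution of the analysed trio:
the 99.995th and 99.999th define hit tiers, the 90th bounds the window
used by the trio-swap contrast.

Hits are annotated to every gene whose body extended by a 20-kb flank
contains them; the local-zoom helper reports squared dosage-correlation
(r^2) of every windowed site with the top-PBS variant of a gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from . import stats
from .io import GeneInterval, SiteCounts, read_popmap, read_vcf_counts

logger = logging.getLogger(__name__)

__all__ = [
    "TrioSpec",
    "SiteFilterConfig",
    "ScanThresholds",
    "FilterReport",
    "TrioContrastResult",
    "filter_sites",
    "pbs_table_from_counts",
    "run_pbs_scan",
    "extract_and_annotate_hits",
    "local_zoom",
    "trio_contrast",
]


@dataclass(frozen=True)
class TrioSpec:
    """Target population A scored against ingroup B and outgroup C."""

    target: str
    ingroup: str
    outgroup: str

    def __post_init__(self):
        labels = (self.target, self.ingroup, self.outgroup)
        if len(set(labels)) != 3:
            raise ValueError(f"trio labels must be distinct, got {labels}")

    @property
    def populations(self) -> Tuple[str, str, str]:
        return (self.target, self.ingroup, self.outgroup)

    def swapped(self) -> "TrioSpec":
        """The contrast design: ingroup becomes the target."""
        return TrioSpec(target=self.ingroup, ingroup=self.target, outgroup=self.outgroup)


@dataclass
class SiteFilterConfig:
    """Site filters applied before PBS.

    ``min_site_mean_depth`` of None disables the depth rule (only then
    do sites lacking DP pass it); missingness is strict (< max);
    polymorphism requires 0 < derived < called in at least one trio
    population.
    """

    min_site_mean_depth: Optional[float] = 10.0
    max_missing_fraction: float = 0.05
    require_polymorphic_in_any: bool = True

    def __post_init__(self):
        if self.min_site_mean_depth is not None and self.min_site_mean_depth < 0:
            raise ValueError("min_site_mean_depth must be non-negative")
        if self.max_missing_fraction < 0:
            raise ValueError("max_missing_fraction must be non-negative")


@dataclass(frozen=True)
class ScanThresholds:
    """PBS thresholds: the 90th, 99.995th and 99.999th percentiles."""

    p90: float
    p99995: float
    p99999: float

    def __post_init__(self):
        if not (self.p90 <= self.p99995 <= self.p99999):
            raise ValueError("thresholds must be ordered p90 <= p99995 <= p99999")


@dataclass
class FilterReport:
    """Per-rule removal counts; removed + kept = input (conservation)."""

    n_input: int = 0
    n_kept: int = 0
    removed: Dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> Dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept, "removed": dict(self.removed)}


def filter_sites(
    sites: Iterable[SiteCounts],
    cfg: SiteFilterConfig,
    trio: TrioSpec,
) -> Tuple[List[SiteCounts], FilterReport]:
    """Apply the scan's site filters; each removal is attributed to the
    first failing rule (depth, then missingness, then insufficient
    calls, then monomorphism)."""
    report = FilterReport(removed={"depth": 0, "missingness": 0, "insufficient_calls": 0, "monomorphic": 0})
    kept: List[SiteCounts] = []
    for site in sites:
        report.n_input += 1
        if cfg.min_site_mean_depth is not None and not (
            site.site_mean_depth >= cfg.min_site_mean_depth
        ):
            report.removed["depth"] += 1  # NaN depth fails unless rule disabled
            continue
        if not (site.missing_fraction < cfg.max_missing_fraction):
            report.removed["missingness"] += 1
            continue
        trio_counts = [site.counts[p] for p in trio.populations]
        if any(called < 2 for _, called in trio_counts):
            report.removed["insufficient_calls"] += 1
            continue
        if cfg.require_polymorphic_in_any and not any(
            0 < derived < called for derived, called in trio_counts
        ):
            report.removed["monomorphic"] += 1
            continue
        kept.append(site)
    report.n_kept = len(kept)
    for pop in trio.populations:
        # run_pbs_scan's precondition: every trio population usable somewhere
        if kept and all(s.counts[pop][1] < 2 for s in kept):
            logger.warning("population %s has <2 called chromosomes at every kept site", pop)
    logger.info(
        "filter_sites: kept %d of %d sites (removed %s)",
        report.n_kept,
        report.n_input,
        report.removed,
    )
    return kept, report


def pbs_table_from_counts(
    sites: Sequence[SiteCounts], trio: TrioSpec
) -> pd.DataFrame:
    """Per-site F_ST / branch-length / PBS table for already-filtered sites.

    Columns: chrom, pos, site_id, daf_a/daf_b/daf_c (NaN when the site
    is unpolarizable), raw fst_ab/fst_ac/fst_bc, t_ab/t_ac/t_bc, pbs.
    Rows are sorted by (chrom, pos) so output is invariant to input
    record order.
    """
    if not sites:
        raise ValueError("no sites survive filtering; nothing to scan")
    a_lab, b_lab, c_lab = trio.populations

    def counts_of(pop):
        d = np.array([s.counts[pop][0] for s in sites], dtype=float)
        n = np.array([s.counts[pop][1] for s in sites], dtype=float)
        return d, n

    da, na = counts_of(a_lab)
    db, nb = counts_of(b_lab)
    dc, nc = counts_of(c_lab)
    polar = np.array([s.polarizable for s in sites])

    def pair_fst(d1, n1, d2, n2):
        a, b = stats.fst_site_arrays(d1, n1, d2, n2)
        denom = a + b
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(denom != 0, a / denom, np.nan)
        return f

    fst_ab = pair_fst(da, na, db, nb)
    fst_ac = pair_fst(da, na, dc, nc)
    fst_bc = pair_fst(db, nb, dc, nc)
    # a pair monomorphic for the same allele carries zero branch length
    t_ab = stats.branch_length(np.nan_to_num(fst_ab, nan=0.0))
    t_ac = stats.branch_length(np.nan_to_num(fst_ac, nan=0.0))
    t_bc = stats.branch_length(np.nan_to_num(fst_bc, nan=0.0))
    pbs_vals = stats.pbs(t_ab, t_ac, t_bc)

    with np.errstate(invalid="ignore", divide="ignore"):
        daf = lambda d, n: np.where(polar & (n > 0), d / np.maximum(n, 1), np.nan)
    table = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "site_id": [s.site_id for s in sites],
            "daf_a": daf(da, na),
            "daf_b": daf(db, nb),
            "daf_c": daf(dc, nc),
            "fst_ab": fst_ab,
            "fst_ac": fst_ac,
            "fst_bc": fst_bc,
            "t_ab": t_ab,
            "t_ac": t_ac,
            "t_bc": t_bc,
            "pbs": pbs_vals,
        }
    )
    return table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def compute_thresholds(pbs_values: Sequence[float]) -> ScanThresholds:
    return ScanThresholds(
        p90=stats.percentile(pbs_values, 90.0),
        p99995=stats.percentile(pbs_values, 99.995),
        p99999=stats.percentile(pbs_values, 99.999),
    )


def run_pbs_scan(
    vcf_path,
    popmap_path,
    trio: TrioSpec,
    cfg: Optional[SiteFilterConfig] = None,
) -> Tuple[pd.DataFrame, ScanThresholds, FilterReport]:
    """Full scan: read the VCF, filter sites, compute per-site PBS and
    the percentile thresholds of the surviving-site distribution."""
    cfg = cfg or SiteFilterConfig()
    popmap, labels = read_popmap(popmap_path)
    for pop in trio.populations:
        if pop not in labels:
            raise ValueError(f"trio population {pop!r} absent from the population map")
    counts = read_vcf_counts(vcf_path, popmap, list(trio.populations))
    kept, report = filter_sites(counts, cfg, trio)
    table = pbs_table_from_counts(kept, trio)
    thresholds = compute_thresholds(table["pbs"].to_numpy())
    return table, thresholds, report


# ---------------------------------------------------------------------------
# hits and annotation
# ---------------------------------------------------------------------------


def _gene_trees(
    genes: Sequence[GeneInterval], flank_bp: int
) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        # 1-based inclusive window [start+1-flank, end+flank]; as a
        # half-open interval over positions: [start+1-flank, end+flank+1)
        lo = max(1, g.start + 1 - flank_bp)
        hi = g.end + flank_bp + 1
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)
    return trees


def extract_and_annotate_hits(
    pbs_table: pd.DataFrame,
    thresholds: ScanThresholds,
    genes: Sequence[GeneInterval],
    flank_bp: int = 20000,
) -> pd.DataFrame:
    """Sites above the 99.995th percentile, annotated with flanked genes.

    Tier 1 = above the 99.999th percentile, tier 2 = above the 99.995th
    only.  ``genes`` holds a comma-joined list of every gene whose body
    +/- ``flank_bp`` contains the hit, or "intergenic".
    """
    hits = pbs_table[pbs_table["pbs"] > thresholds.p99995].copy()
    trees = _gene_trees(genes, flank_bp)
    labels = []
    for chrom, pos in zip(hits["chrom"], hits["pos"]):
        tree = trees.get(chrom)
        found = sorted(iv.data for iv in tree[pos]) if tree is not None else []
        labels.append(",".join(found) if found else "intergenic")
    hits["genes"] = labels
    hits["tier"] = np.where(hits["pbs"] > thresholds.p99999, 1, 2)
    return hits.reset_index(drop=True)


# ---------------------------------------------------------------------------
# local zoom / LD
# ---------------------------------------------------------------------------


def _pairwise_r2(dosage: np.ndarray, index_row: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each dosage row with ``index_row``,
    with missing calls (-1) excluded pairwise."""
    out = np.full(dosage.shape[0], np.nan)
    for i, row in enumerate(dosage):
        ok = (row >= 0) & (index_row >= 0)
        if ok.sum() < 2:
            continue
        x = row[ok].astype(float)
        y = index_row[ok].astype(float)
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            out[i] = np.nan if not np.array_equal(x, y) else 1.0
            continue
        r = np.corrcoef(x, y)[0, 1]
        out[i] = r * r
    return out


def local_zoom(
    pbs_table: pd.DataFrame,
    geno_sites: pd.DataFrame,
    dosage: np.ndarray,
    gene: GeneInterval,
    flank_bp: int = 20000,
) -> pd.DataFrame:
    """Per-site PBS plus r^2 with the top-PBS variant around one gene.

    The window is the gene body +/- ``flank_bp``; the index variant is
    the window's maximum PBS (ties broken toward the smallest position).
    ``geno_sites``/``dosage`` come from :func:`io.read_vcf_genotypes`
    restricted to the trio samples; r^2 is the squared genotype-dosage
    correlation with missing calls pairwise-excluded.
    """
    lo = gene.start + 1 - flank_bp
    hi = gene.end + flank_bp
    window = pbs_table[
        (pbs_table["chrom"] == gene.chrom)
        & (pbs_table["pos"] >= lo)
        & (pbs_table["pos"] <= hi)
    ].copy()
    if window.empty:
        raise ValueError(f"no scanned sites within {flank_bp} bp of gene {gene.gene_id}")
    window = window.sort_values("pos", kind="mergesort").reset_index(drop=True)
    best = window.loc[window["pbs"].idxmax()]  # idxmax -> first (smallest pos) on ties

    key = geno_sites.assign(_row=np.arange(len(geno_sites))).set_index(["chrom", "pos"])
    rows = []
    for chrom, pos in zip(window["chrom"], window["pos"]):
        try:
            rows.append(int(key.loc[(chrom, pos), "_row"]))
        except KeyError:
            raise ValueError(f"genotypes missing for scanned site {chrom}:{pos}")
    sub = dosage[rows]
    index_pos = int(best["pos"])
    index_row = sub[list(window["pos"]).index(index_pos)]
    window["r2"] = _pairwise_r2(sub, index_row)
    window["is_index"] = window["pos"] == index_pos
    return window


# ---------------------------------------------------------------------------
# trio-swap contrast
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrioContrastResult:
    """One-sided Mann-Whitney test that the first windowed PBS
    distribution is stochastically lower than the second."""

    u_statistic: float
    p_value: float
    median1: float
    median2: float
    n1: int
    n2: int
    window: Tuple[float, float]


def _window_values(
    values: np.ndarray, window: Tuple[float, float], thresholds: Optional[ScanThresholds]
) -> np.ndarray:
    lo_q, hi_q = window
    if thresholds is not None and (lo_q, hi_q) == (90.0, 99.995):
        lo, hi = thresholds.p90, thresholds.p99995
    else:
        lo = stats.percentile(values, lo_q)
        hi = stats.percentile(values, hi_q)
    return values[(values > lo) & (values < hi)]


def trio_contrast(
    pbs_table_target: pd.DataFrame,
    pbs_table_swapped: pd.DataFrame,
    window: Tuple[float, float] = (90.0, 99.995),
    pooled_percentiles: bool = False,
) -> TrioContrastResult:
    """Compare two trio designs over the (90th, 99.995th) PBS window.

    Each table is restricted to the open interval between its own
    ``window`` percentiles (or percentiles of the pooled values when
    ``pooled_percentiles``), then a one-sided Mann-Whitney U tests
    whether the first distribution is lower than the second.
    """
    x = pbs_table_target["pbs"].to_numpy()
    y = pbs_table_swapped["pbs"].to_numpy()
    if pooled_percentiles:
        pooled = np.concatenate([x, y])
        lo = stats.percentile(pooled, window[0])
        hi = stats.percentile(pooled, window[1])
        xw = x[(x > lo) & (x < hi)]
        yw = y[(y > lo) & (y < hi)]
    else:
        xw = _window_values(x, window, None)
        yw = _window_values(y, window, None)
    if len(xw) < 10 or len(yw) < 10:
        raise ValueError(
            f"too few PBS values after windowing ({len(xw)} and {len(yw)}; need >=10 each)"
        )
    res = sps.mannwhitneyu(xw, yw, alternative="less")
    return TrioContrastResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median1=float(np.median(xw)),
        median2=float(np.median(yw)),
        n1=len(xw),
        n2=len(yw),
        window=window,
    )
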