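"""Synthetic trio + outgroup data with the structure the scan assumes.

The generator emulates a three-population selection-scan design (target,
ingroup, outgroup) descended from a common ancestral pool:

* Per-site ancestral derived-allele frequencies ``p`` are uniform within
  configurable bounds; each population's frequency is a Balding-Nichols
  draw, Beta-distributed with mean ``p`` and variance ``p(1-p)c`` where
  the drift parameter ``c`` is that population's expected F_ST against
  the ancestral pool.  Sites are independent (no linkage).
* Sweep loci override the drift draw: the target population's frequency
  is set exactly to ``target_derived_freq`` at the named site, leaving
  every other site untouched.
* Diploid genotypes are Hardy-Weinberg draws; calls are masked missing
  at a configurable rate; per-site mean read depth is Gamma-distributed
  (mean ``depth_mean``, variance ``depth_mean * depth_overdispersion``)
  with per-call depths Poisson around the site mean, i.e. a negative-
  binomial-like marginal.
* Each site's ancestral allele is emitted as REF or ALT on a fair coin,
  so polarization code downstream is exercised in both orientations.

Gene models, gene-set collections with one designated sweep-enriched
set, haplogroup count tables (Dirichlet-multinomial) and per-individual
ROH segment tables (exponential length mixture, non-overlapping) are
generated alongside.

Every component draws from its own sub-stream of a single seeded
generator, so e.g. adding sites does not perturb the haplogroup draws.
Identical configs (including seed) give byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import GeneInterval, GeneSet, HaplogroupTable, RohSegment

__all__ = [
    "ConfigError",
    "GenerationError",
    "SweepLocus",
    "SimConfig",
    "SimulatedPanel",
    "simulate_trio_frequencies",
    "sample_genotypes",
    "site_counts",
    "simulate_gene_model",
    "simulate_haplogroup_counts",
    "simulate_roh_segments",
]

_BASES = np.array(list("ACGT"))

# fixed sub-stream ids so components are insensitive to each other
_STREAMS = {
    "positions": 0,
    "frequencies": 1,
    "genotypes": 2,
    "depth": 3,
    "polarity": 4,
    "genes": 5,
    "haplogroups": 6,
    "roh": 7,
}


class ConfigError(ValueError):
    """A simulation recipe violates its own invariants."""


class GenerationError(RuntimeError):
    """Generation failed (e.g. segment placement exhausted its retries)."""


def _rng(seed: int, component: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[component],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SweepLocus:
    """One selected site: the target population's derived frequency is
    forced to ``target_derived_freq`` exactly, overriding the drift draw."""

    site_index: int
    target_population: str
    target_derived_freq: float


@dataclass
class SimConfig:
    """Full recipe for a reproducible synthetic trio panel."""

    n_sites: int
    chrom_plan: List[Tuple[str, int]]
    drift: Dict[str, float]  # population -> c in (0, 1), expected F_ST scale
    sample_sizes: Dict[str, int]  # population -> diploid count
    sweep_spec: List[SweepLocus] = field(default_factory=list)
    missing_rate: float = 0.0
    depth_mean: float = 30.0
    depth_overdispersion: float = 3.0
    ancestral_freq_bounds: Tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ConfigError("n_sites must be positive")
        if not self.chrom_plan:
            raise ConfigError("chrom_plan must name at least one chromosome")
        if set(self.drift) != set(self.sample_sizes):
            raise ConfigError("drift and sample_sizes must name the same populations")
        for pop, c in self.drift.items():
            if not 0.0 < c < 1.0:
                raise ConfigError(f"drift parameter for {pop!r} must be in (0,1), got {c}")
        for pop, n in self.sample_sizes.items():
            if n < 2:
                raise ConfigError(f"sample size for {pop!r} must be >= 2, got {n}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.depth_mean <= 0 or self.depth_overdispersion <= 0:
            raise ConfigError("depth parameters must be positive")
        lo, hi = self.ancestral_freq_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ConfigError("ancestral_freq_bounds must satisfy 0 < low < high < 1")
        for s in self.sweep_spec:
            if not 0 <= s.site_index < self.n_sites:
                raise ConfigError(f"sweep site_index {s.site_index} out of range")
            if s.target_population not in self.drift:
                raise ConfigError(f"sweep population {s.target_population!r} unknown")
            if not 0.0 <= s.target_derived_freq <= 1.0:
                raise ConfigError("target_derived_freq must be in [0, 1]")

    @property
    def populations(self) -> List[str]:
        return list(self.drift)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["chrom_plan"] = [tuple(x) for x in raw["chrom_plan"]]
        raw["sweep_spec"] = [SweepLocus(**s) for s in raw.get("sweep_spec", [])]
        if "ancestral_freq_bounds" in raw:
            raw["ancestral_freq_bounds"] = tuple(raw["ancestral_freq_bounds"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------


def _site_positions(config: SimConfig) -> pd.DataFrame:
    """Distinct, sorted site positions allotted across the chromosome plan."""
    rng = _rng(config.seed, "positions")
    lengths = np.array([l for _, l in config.chrom_plan], dtype=float)
    weights = lengths / lengths.sum()
    # multinomial allotment, then sorted draws without replacement per chrom
    per_chrom = rng.multinomial(config.n_sites, weights)
    rows = []
    for (chrom, length), k in zip(config.chrom_plan, per_chrom):
        if k > length:
            raise ConfigError(f"chromosome {chrom} too short for {k} sites")
        pos = np.sort(rng.choice(length, size=k, replace=False)) + 1  # 1-based
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    return pd.concat(rows, ignore_index=True)


def simulate_trio_frequencies(config: SimConfig) -> pd.DataFrame:
    """Per-site derived-allele frequencies for every population.

    Returns a DataFrame with columns chrom, pos, ancestral_freq, and one
    frequency column per population.  The ancestral pooled frequency is
    uniform within ``ancestral_freq_bounds``; population frequencies are
    Balding-Nichols Beta draws with mean p and variance p(1-p)c; sweep
    loci are then overwritten exactly per the sweep spec.
    """
    sites = _site_positions(config)
    rng = _rng(config.seed, "frequencies")
    p = rng.uniform(*config.ancestral_freq_bounds, size=config.n_sites)
    table = sites.copy()
    table["ancestral_freq"] = p
    for pop in config.populations:
        c = config.drift[pop]
        # Beta with mean p, variance p(1-p)c  =>  concentration (1-c)/c
        kappa = (1.0 - c) / c
        freqs = rng.beta(p * kappa, (1.0 - p) * kappa)
        table[pop] = freqs
    for sweep in config.sweep_spec:
        table.loc[sweep.site_index, sweep.target_population] = sweep.target_derived_freq
    return table


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class SimulatedPanel:
    """Genotype matrix plus the site/sample metadata needed to emit a VCF.

    ``derived_dosage`` counts derived alleles per call (-1 = missing);
    ``alt_dosage`` (property) is the same matrix re-oriented to the
    emitted REF/ALT alleles according to each site's ancestral polarity.
    """

    sites: pd.DataFrame  # chrom,pos,site_id,ref,alt,aa,anc_is_ref,site_mean_depth
    derived_dosage: np.ndarray  # (n_sites, n_samples), int8
    depth: np.ndarray  # (n_sites, n_samples), int32
    samples: List[str]
    sample_populations: List[str]
    config: SimConfig

    @property
    def alt_dosage(self) -> np.ndarray:
        anc_is_ref = self.sites["anc_is_ref"].to_numpy()[:, None]
        flipped = np.where(self.derived_dosage < 0, -1, 2 - self.derived_dosage)
        return np.where(anc_is_ref, self.derived_dosage, flipped).astype(np.int8)

    @property
    def popmap(self) -> Dict[str, str]:
        return dict(zip(self.samples, self.sample_populations))


def sample_genotypes(freq_table: pd.DataFrame, config: SimConfig) -> SimulatedPanel:
    """Draw diploid HWE genotypes, missingness, depth and polarity.

    Genotype dosages are binomial(2, q) per population; missing calls
    are masked at ``missing_rate``; per-site mean depth follows the
    Gamma-Poisson model; each site's ancestral allele is emitted as REF
    or ALT on a fair coin and recorded in the site metadata (INFO AA).
    """
    pops = config.populations
    for pop in pops:
        if pop not in freq_table.columns:
            raise ConfigError(f"frequency table lacks population {pop!r}")
    freqs = freq_table[pops].to_numpy()
    if np.any(freqs < 0) or np.any(freqs > 1):
        raise ConfigError("frequencies must lie in [0, 1]")
    n_sites = len(freq_table)

    rng = _rng(config.seed, "genotypes")
    blocks = []
    samples: List[str] = []
    sample_pops: List[str] = []
    for j, pop in enumerate(pops):
        n = config.sample_sizes[pop]
        q = freqs[:, j][:, None]
        blocks.append(rng.binomial(2, q, size=(n_sites, n)).astype(np.int8))
        samples.extend(f"{pop}_{i:03d}" for i in range(n))
        sample_pops.extend([pop] * n)
    dosage = np.concatenate(blocks, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = -1

    rng_d = _rng(config.seed, "depth")
    shape = config.depth_mean / config.depth_overdispersion
    site_mean = rng_d.gamma(shape, scale=config.depth_overdispersion, size=n_sites)
    depth = rng_d.poisson(site_mean[:, None], size=dosage.shape).astype(np.int32)

    rng_p = _rng(config.seed, "polarity")
    anc_is_ref = rng_p.random(n_sites) < 0.5
    ref_idx = rng_p.integers(0, 4, size=n_sites)
    alt_shift = rng_p.integers(1, 4, size=n_sites)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]
    aa = np.where(anc_is_ref, ref, alt)

    sites = freq_table[["chrom", "pos"]].copy()
    sites["site_id"] = [f"{c}:{p}" for c, p in zip(sites["chrom"], sites["pos"])]
    sites["ref"] = ref
    sites["alt"] = alt
    sites["aa"] = aa
    sites["anc_is_ref"] = anc_is_ref
    sites["site_mean_depth"] = site_mean
    return SimulatedPanel(
        sites=sites,
        derived_dosage=dosage,
        depth=depth,
        samples=samples,
        sample_populations=sample_pops,
        config=config,
    )


def site_counts(panel: SimulatedPanel) -> List["SiteCounts"]:
    """Per-site, per-population counts straight from a simulated panel.

    Equivalent to writing the panel as VCF and re-reading it with
    :func:`baiyue_scan.io.read_vcf_counts` (an equality the test suite
    asserts); useful when the VCF layer itself is not under study.
    """
    from .io import SiteCounts

    pops = panel.config.populations
    idx = {
        p: np.flatnonzero(np.array(panel.sample_populations) == p) for p in pops
    }
    dosage = panel.derived_dosage
    called_mask = dosage >= 0
    sites = panel.sites
    out: List[SiteCounts] = []
    per_pop = {
        p: (
            2 * called_mask[:, idx[p]].sum(axis=1),
            np.where(called_mask[:, idx[p]], dosage[:, idx[p]], 0).sum(axis=1),
        )
        for p in pops
    }
    missing_fraction = 1.0 - called_mask.mean(axis=1)
    for i in range(len(sites)):
        row = sites.iloc[i]
        counts = {p: (int(per_pop[p][1][i]), int(per_pop[p][0][i])) for p in pops}
        out.append(
            SiteCounts(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                site_id=row["site_id"],
                ref=row["ref"],
                alt=row["alt"],
                ancestral=row["aa"],
                counts=counts,
                site_mean_depth=float(panel.depth[i].mean()),
                missing_fraction=float(missing_fraction[i]),
                polarizable=True,
            )
        )
    return out


# ---------------------------------------------------------------------------
# gene model / gene sets
# ---------------------------------------------------------------------------


def simulate_gene_model(
    n_genes: int,
    chrom_plan: Sequence[Tuple[str, int]],
    n_sets: int,
    genes_per_set: int,
    enriched_set_fraction: float,
    seed: int,
    sweep_sites: Optional[Sequence[Tuple[str, int]]] = None,
) -> Tuple[List[GeneInterval], List[GeneSet], str]:
    """Non-overlapping gene intervals plus a gene-set collection.

    The first returned set (id ``SET_SELECTED``) is the designated
    "selected" set: its genes are placed so that at least
    ``enriched_set_fraction`` of the supplied sweep sites fall inside a
    gene body belonging to it.  Remaining sets sample genes uniformly
    without replacement (sets may share genes, as pathway collections
    do).  Returns (genes, sets, designated_set_id).
    """
    if genes_per_set > n_genes:
        raise ConfigError("genes_per_set exceeds n_genes")
    if not 0.0 <= enriched_set_fraction <= 1.0:
        raise ConfigError("enriched_set_fraction must be in [0, 1]")
    rng = _rng(seed, "genes")
    lengths = np.array([l for _, l in chrom_plan], dtype=float)
    per_chrom = np.floor(n_genes * lengths / lengths.sum()).astype(int)
    # distribute the remainder to the longest chromosomes
    for i in np.argsort(-lengths)[: n_genes - per_chrom.sum()]:
        per_chrom[i] += 1

    sweep_sites = list(sweep_sites or [])
    genes: List[GeneInterval] = []
    gid = 0
    slot_of_sweep: Dict[int, int] = {}  # index into `genes` covering sweep k
    for (chrom, length), k in zip(chrom_plan, per_chrom):
        if k == 0:
            continue
        slot = length // k
        if slot < 2:
            raise ConfigError(f"chromosome {chrom} too short for {k} genes")
        for s in range(k):
            # last slot absorbs the division remainder so no position is orphaned
            lo, hi = s * slot, (length if s == k - 1 else (s + 1) * slot)
            covered = [
                (j, pos)
                for j, (sc, pos) in enumerate(sweep_sites)
                if sc == chrom and lo < pos <= hi
            ]
            if covered:
                # force the slot's gene body over every sweep site in the slot
                ps = [pos for _, pos in covered]
                start = max(lo, min(ps) - 1 - int(rng.integers(0, max(1, slot // 10))))
                end = min(hi, max(ps) + int(rng.integers(0, max(1, slot // 10))))
                end = max(end, start + 1)
            else:
                glen = int(rng.integers(max(1, slot // 10), max(2, slot // 2)))
                start = lo + int(rng.integers(0, max(1, slot - glen)))
                end = min(start + glen, hi)
            g = GeneInterval(gene_id=f"G{gid:05d}", chrom=chrom, start=start, end=end)
            genes.append(g)
            gid += 1
            for j, _ in covered:
                slot_of_sweep[j] = len(genes) - 1

    n_cover = int(np.ceil(enriched_set_fraction * len(sweep_sites)))
    if len(slot_of_sweep) < n_cover:
        raise GenerationError("could not cover the requested fraction of sweep sites")
    covered_first = sorted(slot_of_sweep)[:n_cover]
    cover_gene_idx = sorted({slot_of_sweep[j] for j in covered_first})

    all_ids = [g.gene_id for g in genes]
    selected_genes = [genes[i].gene_id for i in cover_gene_idx]
    fill = [g for g in all_ids if g not in selected_genes]
    rng.shuffle(fill)
    selected_genes = selected_genes + fill[: max(0, genes_per_set - len(selected_genes))]
    sets = [GeneSet(set_id="SET_SELECTED", description="sweep-enriched", genes=selected_genes)]
    # null sets draw from the non-designated genes so the engineered
    # signal stays confined to the designated set
    null_pool = [g for g in all_ids if g not in set(selected_genes)]
    pool = null_pool if len(null_pool) >= genes_per_set else all_ids
    for s in range(1, n_sets):
        members = list(rng.choice(pool, size=genes_per_set, replace=False))
        sets.append(GeneSet(set_id=f"SET{s:04d}", description="null", genes=members))
    sets = sets[:n_sets]
    return genes, sets, "SET_SELECTED"


# ---------------------------------------------------------------------------
# haplogroups
# ---------------------------------------------------------------------------


def simulate_haplogroup_counts(
    pop_profiles: Mapping[str, Sequence[float]],
    n_per_pop: int,
    seed: int,
    haplogroup_labels: Optional[Sequence[str]] = None,
) -> HaplogroupTable:
    """Dirichlet-multinomial haplogroup counts, one row per population.

    ``pop_profiles`` maps population label -> Dirichlet concentration
    vector; counts per population are multinomial draws of ``n_per_pop``
    chromosomes from a Dirichlet-drawn frequency vector, so each row
    sums to ``n_per_pop`` exactly.
    """
    rng = _rng(seed, "haplogroups")
    pops = list(pop_profiles)
    k = len(next(iter(pop_profiles.values())))
    rows = []
    for pop in pops:
        conc = np.asarray(pop_profiles[pop], dtype=float)
        if conc.shape != (k,):
            raise ConfigError("all concentration vectors must share one length")
        if np.any(conc <= 0):
            raise ConfigError(f"concentrations for {pop!r} must be positive")
        freqs = rng.dirichlet(conc)
        rows.append(rng.multinomial(n_per_pop, freqs))
    labels = list(haplogroup_labels) if haplogroup_labels else [f"H{i}" for i in range(k)]
    return HaplogroupTable(populations=pops, haplogroups=labels, counts=np.array(rows))


# ---------------------------------------------------------------------------
# ROH
# ---------------------------------------------------------------------------


def simulate_roh_segments(
    n_individuals: int,
    length_mixture: Sequence[Tuple[float, float]],
    segs_per_individual: int,
    chrom_plan: Sequence[Tuple[str, int]],
    seed: int,
    max_retries: int = 100,
) -> List[RohSegment]:
    """Per-individual ROH segments with exponential-mixture lengths.

    ``length_mixture`` is a list of (weight, mean_length_bp) components;
    weights must sum to 1.  Segments are placed uniformly on the
    chromosome plan and re-drawn (up to ``max_retries``) until they do
    not overlap a previous segment of the same individual.
    """
    weights = np.array([w for w, _ in length_mixture], dtype=float)
    means = np.array([m for _, m in length_mixture], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ConfigError(f"mixture weights must sum to 1, got {weights.sum()}")
    if np.any(means <= 0):
        raise ConfigError("mixture mean lengths must be positive")
    rng = _rng(seed, "roh")
    chroms = [c for c, _ in chrom_plan]
    lens = np.array([l for _, l in chrom_plan], dtype=float)
    probs = lens / lens.sum()
    segments: List[RohSegment] = []
    for i in range(n_individuals):
        sample = f"IND_{i:03d}"
        placed: Dict[str, List[Tuple[int, int]]] = {}
        for _ in range(segs_per_individual):
            for attempt in range(max_retries):
                comp = rng.choice(len(weights), p=weights)
                length = max(1, int(rng.exponential(means[comp])))
                ci = rng.choice(len(chroms), p=probs)
                chrom, clen = chroms[ci], int(lens[ci])
                if length >= clen:
                    continue
                start = int(rng.integers(1, clen - length + 1))
                end = start + length - 1
                if all(e < start or s > end for s, e in placed.get(chrom, [])):
                    placed.setdefault(chrom, []).append((start, end))
                    segments.append(
                        RohSegment(sample=sample, chrom=chrom, start=start, end=end)
                    )
                    break
            else:
                raise GenerationError(
                    f"could not place ROH segment for {sample} after {max_retries} tries"
                )
    return segments
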