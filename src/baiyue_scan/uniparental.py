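"""Uniparental-marker summaries and ROH classification.

Haplogroup diversity for a population of sample size n with haplogroup
frequencies x_i is the unbiased heterozygosity analogue

    HD = n (1 - sum x_i^2) / (n - 1),

zero exactly when a single haplogroup is present.  Population structure
in haplogroup-frequency space is summarised by PCA (column-mean-centred
frequencies, SVD, no variance scaling; per-axis sign fixed by making
the largest-magnitude loading positive).

Runs of homozygosity are classified short (<= 0.5 Mb), medium
((0.5, 1] Mb) or long (> 1 Mb), and summarised per population and per
individual as count, total length and average length (= total / count).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import HaplogroupTable, RohSegment

logger = logging.getLogger(__name__)

__all__ = [
    "DiversityResult",
    "RohSummary",
    "haplogroup_diversity",
    "haplogroup_frequency_pca",
    "roh_classify_summarize",
    "ROH_CLASSES",
]

ROH_CLASSES = ("short", "medium", "long")


@dataclass(frozen=True)
class DiversityResult:
    population: str
    n: int
    hd: float


def haplogroup_diversity(table: HaplogroupTable) -> List[DiversityResult]:
    """HD = n(1 - sum x^2)/(n - 1) per population; x from counts / n.

    Populations with n < 2 are skipped with a warning (the unbiased
    correction is undefined for them).
    """
    results = []
    for i, pop in enumerate(table.populations):
        counts = table.counts[i].astype(float)
        n = int(counts.sum())
        if n < 2:
            warnings.warn(f"population {pop!r}: n={n} < 2, haplogroup diversity skipped")
            continue
        x = counts / n
        hd = n * (1.0 - float(np.sum(x * x))) / (n - 1)
        results.append(DiversityResult(population=pop, n=n, hd=hd))
    return results


def haplogroup_frequency_pca(
    table: HaplogroupTable, n_components: int = 2
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of populations in haplogroup-frequency space.

    Rows are converted to frequency vectors and column-mean-centred (no
    unit-variance scaling: frequencies already share a scale), then
    decomposed by SVD.  Returns per-population coordinates (PC1..PCk)
    and the explained-variance fractions.  Coordinates are deterministic
    up to sign; the sign is fixed so each component's largest-magnitude
    haplogroup loading is positive.  If the centred matrix has rank
    below ``n_components``, fewer components are returned with a
    warning.
    """
    if len(table.populations) < 3:
        raise ValueError("haplogroup PCA needs at least 3 populations")
    if len(table.haplogroups) < 2:
        raise ValueError("haplogroup PCA needs at least 2 haplogroups")
    freqs = table.frequencies
    centred = freqs - freqs.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    tol = max(centred.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"centred frequency matrix has rank {rank}; returning {k} components"
        )
    total_var = float(np.sum(s**2))
    explained = (s[:k] ** 2 / total_var) if total_var > 0 else np.zeros(k)
    coords = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            coords[:, j] = -coords[:, j]
    df = pd.DataFrame(
        coords,
        index=table.populations,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    df.index.name = "population"
    return df, explained


@dataclass
class RohSummary:
    """Per-population and per-individual ROH class summaries.

    Both tables carry one row per (group, class) with columns
    n_segments, total_bp, mean_bp; class totals are exact sums of the
    member segment lengths.
    """

    by_population: pd.DataFrame
    by_individual: pd.DataFrame
    bounds: Tuple[float, float]


def _classify(length: int, bounds: Tuple[float, float]) -> str:
    short_max, medium_max = bounds
    if length <= short_max:
        return "short"
    if length <= medium_max:
        return "medium"
    return "long"


def roh_classify_summarize(
    segments: Sequence[RohSegment],
    popmap: Mapping[str, str],
    bounds: Tuple[float, float] = (500_000, 1_000_000),
) -> RohSummary:
    """Classify segments into short/medium/long and summarise.

    The class boundaries partition the line: short <= bounds[0] <
    medium <= bounds[1] < long (a segment of exactly 0.5 Mb is short,
    exactly 1 Mb is medium).  Segments whose sample is absent from the
    population map are dropped with a warning.
    """
    rows = []
    n_dropped = 0
    for seg in segments:
        pop = popmap.get(seg.sample)
        if pop is None:
            n_dropped += 1
            continue
        rows.append(
            {
                "sample": seg.sample,
                "population": pop,
                "roh_class": _classify(seg.length, bounds),
                "length": seg.length,
            }
        )
    if n_dropped:
        warnings.warn(f"{n_dropped} ROH segments dropped: sample absent from popmap")
    df = pd.DataFrame(rows, columns=["sample", "population", "roh_class", "length"])

    def summarise(group_col: str) -> pd.DataFrame:
        if df.empty:
            return pd.DataFrame(
                columns=[group_col, "roh_class", "n_segments", "total_bp", "mean_bp"]
            )
        tmp = df.copy()
        tmp["roh_class"] = pd.Categorical(tmp["roh_class"], categories=ROH_CLASSES)
        g = (
            tmp.groupby([group_col, "roh_class"], observed=True)["length"]
            .agg(n_segments="count", total_bp="sum")
            .reset_index()
        )
        g["mean_bp"] = g["total_bp"] / g["n_segments"]
        g = g.sort_values([group_col, "roh_class"], kind="mergesort").reset_index(drop=True)
        g["roh_class"] = g["roh_class"].astype(str)
        return g

    return RohSummary(
        by_population=summarise("population"),
        by_individual=summarise("sample"),
        bounds=bounds,
    )
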