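"""Per-site population-genetic statistics.

This module is the numerical core of the pipeline: the two-population
Weir-Cockerham F_ST estimator on allele counts, the branch-length
transform T = -log(1 - F_ST), the population branch statistic

    PBS_A = (T_AB + T_AC - T_BC) / 2

for a target population A scored against an ingroup B and outgroup C,
derived-allele frequencies, and the percentile rule shared by every
threshold in the scan.

Conventions fixed here (and relied on by :mod:`baiyue_scan.scan`):

* F_ST is the Weir & Cockerham (1984) moment estimator for samples of
  allele copies (haploid samples of size ``called_chromosomes``), which
  corrects for unequal sample sizes.  Per-site values may be negative.
* Before the log transform, F_ST is clamped to ``[0, 1 - 1e-8]`` so
  branch lengths are non-negative and finite; the raw estimate is kept
  alongside for audit.
* ``log`` is the natural logarithm.
* Percentiles use linear interpolation (numpy's default, Hyndman-Fan
  type 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "FstComponents",
    "fst_site",
    "fst_site_arrays",
    "fst_region",
    "branch_length",
    "pbs",
    "derived_allele_frequency",
    "percentile",
]

#: upper clamp applied before the branch-length transform so that
#: T = -log(1 - F_ST) stays finite at fixed differences.
FST_CLAMP_HIGH = 1.0 - 1e-8


@dataclass(frozen=True)
class FstComponents:
    """Variance components of the two-population Weir-Cockerham estimator.

    ``fst = a / (a + b_plus_c)``; the ratio is undefined when both
    populations are monomorphic for the same allele (zero denominator),
    signalled by ``undefined`` rather than NaN propagation.
    """

    a: float
    b_plus_c: float
    fst: float
    undefined: bool


def fst_site_arrays(
    derived1: np.ndarray,
    called1: np.ndarray,
    derived2: np.ndarray,
    called2: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised Weir-Cockerham components for many sites at once.

    Parameters are allele counts: number of derived (or alt) copies and
    number of called chromosomes per population.  Returns ``(a, b)``
    arrays; ``fst = a / (a + b)`` wherever the denominator is non-zero.
    Sites with fewer than 2 called chromosomes in either population give
    NaN components.

    The two-population, two-allele form for samples of allele copies:
    with sample sizes n1, n2 (chromosomes), frequencies p1, p2,

        nbar = (n1 + n2) / 2
        nc   = n1 + n2 - (n1^2 + n2^2) / (n1 + n2)
        pbar = (n1 p1 + n2 p2) / (n1 + n2)
        s2   = [n1 (p1 - pbar)^2 + n2 (p2 - pbar)^2] / nbar
        a    = (nbar / nc) * [s2 - (pbar(1-pbar) - s2/2) / (nbar - 1)]
        b    = (nbar / (nbar - 1)) * [pbar(1-pbar) - s2/2]
    """
    d1 = np.asarray(derived1, dtype=float)
    n1 = np.asarray(called1, dtype=float)
    d2 = np.asarray(derived2, dtype=float)
    n2 = np.asarray(called2, dtype=float)

    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = d1 / n1
        p2 = d2 / n2
        ntot = n1 + n2
        nbar = ntot / 2.0
        nc = ntot - (n1 * n1 + n2 * n2) / ntot
        pbar = (d1 + d2) / ntot
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        inner = pbar * (1.0 - pbar) - s2 / 2.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * inner
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    return a, b


def fst_site(
    counts_pop1: Tuple[int, int], counts_pop2: Tuple[int, int]
) -> FstComponents:
    """Per-site Weir-Cockerham F_ST from two ``(derived, called)`` pairs.

    Raises :class:`ValueError` when either population has fewer than two
    called chromosomes (no within-population variance estimate exists).
    """
    d1, n1 = counts_pop1
    d2, n2 = counts_pop2
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"fst_site needs >=2 called chromosomes per population, got {n1} and {n2}"
        )
    if not (0 <= d1 <= n1) or not (0 <= d2 <= n2):
        raise ValueError("derived count outside [0, called_chromosomes]")
    a, b = fst_site_arrays(
        np.array([d1]), np.array([n1]), np.array([d2]), np.array([n2])
    )
    a_f, b_f = float(a[0]), float(b[0])
    denom = a_f + b_f
    if denom == 0.0:
        return FstComponents(a=a_f, b_plus_c=b_f, fst=np.nan, undefined=True)
    return FstComponents(a=a_f, b_plus_c=b_f, fst=a_f / denom, undefined=False)


def fst_region(components: Iterable[FstComponents]) -> float:
    """Multi-site ratio-of-sums F_ST: sum(a) / sum(a + b) over defined sites.

    The "ratio of averages" aggregate is the standard way to combine
    Weir-Cockerham components over a region; it is not the mean of the
    per-site ratios.  Returns NaN (flagged undefined) when no site
    contributes a non-zero denominator.
    """
    num = 0.0
    den = 0.0
    n_used = 0
    for comp in components:
        if comp.undefined:
            continue
        num += comp.a
        den += comp.a + comp.b_plus_c
        n_used += 1
    if n_used == 0:
        raise ValueError("fst_region needs at least one defined site")
    if den == 0.0:
        return float("nan")
    return num / den


def branch_length(fst):
    """Branch length T = -log(1 - F_ST), natural log.

    F_ST is clamped to ``[0, 1 - 1e-8]`` first: negative per-site
    estimates contribute zero branch length, and fixed differences map
    to a large but finite T.  Accepts scalars or arrays; NaN propagates
    (an undefined F_ST yields an undefined T).
    """
    f = np.clip(np.asarray(fst, dtype=float), 0.0, FST_CLAMP_HIGH)
    t = -np.log1p(-f)
    t = np.where(np.isnan(np.asarray(fst, dtype=float)), np.nan, t)
    if np.ndim(fst) == 0:
        return float(t)
    return t


def pbs(t_ab, t_ac, t_bc):
    """Population branch statistic PBS_A = (T_AB + T_AC - T_BC) / 2.

    A is the target population; B and C the ingroup and outgroup
    references.  The value may be negative and is not truncated; any
    NaN input propagates.
    """
    t_ab = np.asarray(t_ab, dtype=float)
    t_ac = np.asarray(t_ac, dtype=float)
    t_bc = np.asarray(t_bc, dtype=float)
    out = (t_ab + t_ac - t_bc) / 2.0
    if out.ndim == 0:
        return float(out)
    return out


def derived_allele_frequency(counts: Tuple[int, int]) -> float:
    """DAF = derived_count / called_chromosomes for a polarizable site."""
    derived, called = counts
    if called < 1:
        raise ValueError("derived_allele_frequency needs >=1 called chromosome")
    if not 0 <= derived <= called:
        raise ValueError("derived count outside [0, called_chromosomes]")
    return derived / called


def percentile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation (type 7) percentile of ``values`` at ``q`` percent.

    This single definition backs every threshold in the pipeline (90th,
    99.9th, 99.995th, 99.999th); q=0 gives the minimum, q=100 the
    maximum.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of empty sequence")
    if not 0.0 <= q <= 100.0:
        raise ValueError(f"percentile q must be in [0, 100], got {q}")
    return float(np.percentile(arr, q))
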