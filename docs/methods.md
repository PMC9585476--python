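# Methods

## Scan design and model

The scan targets a trio of populations: a target A, an ingroup
reference B, and an outgroup reference C (the design used for scans
such as Hainan-Li vs Han vs CEU). For every bi-allelic SNV the three
pairwise F<sub>ST</sub> values are turned into additive branch lengths
T = −log(1 − F<sub>ST</sub>) (natural log), and the statistic

PBS_A = (T_AB + T_AC − T_BC) / 2

measures allele-frequency change private to the A branch. The identity
PBS_A + PBS_B = T_AB (where PBS_B comes from the swapped trio) holds
sitewise and is enforced by the test suite to 1e−12.

### F_ST estimator

Per-site F<sub>ST</sub> is the Weir–Cockerham (1984) moment estimator
applied to samples of allele copies: with n₁, n₂ called chromosomes
and sample frequencies p₁, p₂,

- n̄ = (n₁+n₂)/2, n_c = n₁+n₂ − (n₁²+n₂²)/(n₁+n₂),
- p̄ the count-weighted mean frequency, s² the weighted variance,
- a = (n̄/n_c)·[s² − (p̄(1−p̄) − s²/2)/(n̄−1)],
- b = (n̄/(n̄−1))·(p̄(1−p̄) − s²/2), F<sub>ST</sub> = a/(a+b).

The estimator corrects for unequal sample sizes and can be negative;
multi-site (regional) F<sub>ST</sub> is the ratio of summed components
Σa / Σ(a+b), not the mean of per-site ratios. Sites where both
populations are monomorphic for the same allele have a zero denominator
and are flagged undefined rather than propagated as NaN.

### Numerical conventions

- Per-site F<sub>ST</sub> is clamped to [0, 1 − 1e−8] before the log
  transform: negative estimates contribute zero branch length, and
  fixed differences give a large but finite T. The raw estimate is
  kept in the per-site table for audit. PBS itself is never truncated;
  ranking and thresholding act on signed values.
- A pair flagged undefined (jointly monomorphic) carries zero branch
  length in the PBS sum; the site can still be scored when another pair
  is informative, and the polymorphism filter removes the fully
  monomorphic case up front.
- All percentiles (90th, 99.9th, 99.995th, 99.999th) use linear
  interpolation (the Hyndman–Fan type-7 definition, numpy's default),
  applied to the post-filter PBS distribution of the analysed trio.
- Mann–Whitney tests enumerate the exact null distribution when the
  combined sample is below 20 and tie-free; otherwise the normal
  approximation with tie and continuity corrections is used, so the
  small worked examples are reproducible bit-for-bit.

## Site filters

Sites enter the scan when (1) site-mean read depth across the selected
samples is ≥ 10× (non-strict; the filter can be disabled, and only then
do sites lacking DP pass), (2) the missing-genotype fraction is
strictly below 5%, and (3) the site is polymorphic (0 < derived count
< called chromosomes) in at least one of the three populations. Depth
is interpreted at the site level — a mean over per-sample DP — rather
than per sample, since a per-sample rule would interact with the
separate missingness filter; the choice is configurable. Each removal
is attributed to the first failing rule and reported, and removed +
kept = input is an enforced invariant.

## Polarization and DAF

The ancestral allele comes from the INFO AA tag (uppercased). AA equal
to REF means the derived allele is ALT; AA equal to ALT means it is
REF. Sites whose AA is missing or matches neither allele are retained
for F<sub>ST</sub>/PBS (which are polarity-invariant) but flagged
unpolarizable and excluded from derived-allele-frequency outputs; both
behaviours are logged with counts.

## Hits, annotation, local zoom, trio contrast

Hits are sites with PBS strictly above the 99.995th percentile; tier 1
additionally exceeds the 99.999th. Each hit is labelled with every gene
whose body extended by a 20-kb flank contains it (BED intervals are
0-based half-open; a gene ending at BED coordinate e contains VCF
position e, and the flank boundary is inclusive), or "intergenic". The
local zoom restricts the per-site table to one gene ± 20 kb, takes the
maximum-PBS variant as the index (ties broken toward the smaller
position), and reports each site's squared genotype-dosage Pearson
correlation with the index, with missing calls excluded pairwise —
an unphased-data substitute for haplotype r².

The trio-swap contrast compares two designs that share an outgroup
(e.g. A-B-C vs B-A-C). Each table is restricted to the open interval
between its own 90th and 99.995th PBS percentiles — the band where
branch-specific signal concentrates without being dominated by the few
extreme hits — and a one-sided Mann–Whitney U tests whether the first
windowed distribution is stochastically lower. Per-distribution
windowing is the default; a pooled-percentile mode is available because
the windowing convention is genuinely ambiguous in this design.

## Polygenic gene-set test

Gene sets are curated by dropping genes that are unmapped (absent from
the interval list) or non-autosomal, then dropping sets with fewer than
10 surviving genes. Variants are pooled per set over gene bodies
± 20 kb (the same flank as hit annotation; configurable down to body
only); a variant inside two genes of one set counts once. The
background for each test is the complement — every scanned variant not
assigned to the set under test — with a genic-only alternative behind a
flag. Each set is tested with a one-sided (greater) Mann–Whitney U and
Bonferroni-corrected with m = number of curated sets; significance is
adjusted p < 0.05. The assignment window and background definition are
surfaced as configuration because neither is fixed by the scan design
itself.

## Uniparental and ROH summaries

Haplogroup diversity per population is HD = n(1 − Σx²)/(n − 1), with n
the row sum of the haplogroup count table and x the count frequencies;
HD = 0 iff a single haplogroup is present, and populations with n < 2
are skipped. The haplogroup PCA converts rows to frequency vectors,
centres columns (no unit-variance scaling — frequencies already share a
scale), and decomposes by SVD; each axis's sign is fixed by making its
largest-magnitude loading positive, so coordinates are deterministic.

ROH segments (1-based inclusive, length = end − start + 1) are
classified short (≤ 0.5 Mb), medium ((0.5, 1] Mb) and long (> 1 Mb) —
the left-open/right-closed convention makes the three printed classes
partition the line at the ambiguous 0.5 and 1.0 Mb boundaries — and
summarised per population and per individual as count, total length
and average length (= total/count, exact by construction).

## Synthetic data generator

The generator emulates the study conditions the scan assumes:

- **Drift.** Per-site ancestral derived-allele frequencies p are
  uniform on (0.05, 0.95); each population's frequency is a
  Balding–Nichols draw, Beta with mean p and variance p(1−p)c. The
  drift parameter c is the population's expected F<sub>ST</sub> against
  the ancestral pool and is the generator's only divergence knob; the
  realized ratio-of-averages F<sub>ST</sub> between two populations
  with c = 0.05 lands within ±0.01 of 0.05 (verified over seeds), and
  is monotone in c.
- **Sweeps.** A sweep locus forces the target population's frequency to
  an exact value at one site, leaving all other sites byte-identical to
  a sweep-free run with the same seed. The calibrated sweep-recovery
  experiment uses 200,000 neutral sites at c = 0.02 (50 diploids per
  population, 1% missingness) plus 50 sweep sites with ancestral
  frequency ≤ 0.2 forced to 0.8–0.95; at least 80% of sweep sites clear
  the scan's 99.9th percentile (observed: ~100%), and a matched
  sweep-free run shows no excess at the same positions.
- **Genotypes.** Diploid Hardy–Weinberg draws per population; calls
  masked missing at a configurable rate; per-site mean depth is
  Gamma(mean 30×, overdispersion 3) with per-call depths Poisson around
  the site mean — a negative-binomial-like marginal emulating a
  30–50× sequencing panel and feeding the site-mean depth filter.
- **Polarity.** Each site's ancestral allele is emitted as REF or ALT
  on a fair coin, so both polarization paths are always exercised.
- **Gene model.** Non-overlapping gene intervals are placed in
  per-chromosome slots; a designated "selected" set's genes are forced
  over the supplied sweep positions so a chosen fraction of sweeps
  falls inside its gene bodies. Null sets sample from the remaining
  genes, keeping the engineered signal confined to the designated set.
  The polygenic-selection experiment boosts every variant inside the
  designated set's gene bodies by +0.3–0.5 in derived frequency — a
  many-variants, moderate-shift signal, which is what the gene-set test
  is designed to detect — while the null-calibration experiment uses
  1,000 genes and 500 random sets so between-set overlap is small
  enough for the rejection fraction to sit in its binomial band.
- **Haplogroups and ROH.** Haplogroup counts are Dirichlet-multinomial
  per population; ROH lengths follow an exponential mixture and are
  placed without within-individual overlap.
- **Determinism.** One seeded generator per run, with fixed sub-streams
  per component (positions, frequencies, genotypes, depth, polarity,
  genes, haplogroups, ROH), so enlarging one component does not perturb
  another; identical configs give byte-identical artifacts.

What the generator does **not** emulate: linkage (sites are
independent, so local-zoom r² on simulated data is only structural),
recombination and haplotype structure, realistic site-frequency
spectra, sequencing error in genotypes, or relatedness. Passing tests
therefore demonstrate the correctness and calibration of the
statistics under the stated drift model, not power on real genomes.

## Problem sizes

The test suite and the acceptance script run the sweep-recovery
experiment at 200,000 sites × 150 samples (through a full VCF
write/read cycle), the calibration experiments at 50,000 sites, and the
remaining checks at hundreds to thousands of sites — sizes chosen so
the whole suite completes in a few minutes on one CPU while keeping
every Monte-Carlo band meaningful.

## Known limitations

- The Weir–Cockerham implementation is the two-population, two-allele
  haploid-sample form; multi-allelic sites are skipped on read rather
  than decomposed.
- LD is genotype-dosage r² on unphased data; phased haplotype r² is out
  of scope.
- The trio-contrast windowing convention (per-distribution vs pooled
  percentiles) changes the compared samples; both are provided, and
  runs log which was used.
- ROH are consumed, not called; haplogroups are consumed, not assigned
  from sequence.
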