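# Methods

This note documents the models and procedures implemented in `mitofilter`,
the defaults they use, the design choices made where the procedure was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Data model and coordinates

Positions are 1-based rCRS coordinates ("np"). Deletion spans are half-open
`(start, end]` — `start` is the last retained position, `end` the last
deleted one — so `length == end - start` and the canonical 5,791 bp fixture
span is `(10154, 15945]`. The genome is treated as circular only in the
definition of the control region (two linear spans, np 16024–16569 and
1–576); moving windows never wrap the origin.

The default array layout interrogates 16,544 of 16,569 positions. Which 25
positions a real array misses is not public; the default mask excludes
positions 1–12 and 16557–16569 as a documented, configurable convention —
only the count carries meaning, and none of the pipeline statistics depend
on which positions are masked.

All probe intensities are clamped to a floor of ε = 1.0 fluorescence units
on read, so every ratio in the pipeline is defined.

## Quality-control gate

Three per-sample statistics are computed over the primary quality track:
the initial call rate (fraction of positions with quality ≥ 3), the mean
pairwise Pearson correlation with the other samples' quality vectors, and
the residual sum of squares against the per-position mean-quality baseline,
RSS_s = Σ_p (q_{s,p} − q̄_p)². A sample with zero quality variance has
undefined correlations; these are reported as 0 with a warning rather than
NaN so the gate stays total.

Rosner's generalized ESD many-outlier procedure is applied twice — to the
RSS vector and to the mean-correlation vector — with α = 0.05 and
k = ⌈0.2·n⌉ (capped at n − 2 so the t-quantile is defined). The ESD test is
two-sided internally; acceptance is directional: only removals with RSS
above the batch mean, or correlation below the batch mean, can flag a
sample. A sample fails if flagged by either view. Which statistics the
outlier test should scan is an open design point; RSS and mean pairwise
correlation were chosen because they are exactly the two summary views the
QC stage is built on (histograms are kept for inspection but not gated on,
and no separate test on low-quality histogram peaks is performed).

## Deletion detection

The per-position primary quality is smoothed with a centred 25 bp moving
average; edge windows are truncated to the available positions (no padding,
no wrap-around), and runs are broken at gaps in the interrogable positions.
The cutoff is pooled mean − 3 SD over deletion-free samples. Inside
`run_pipeline`, where true deletion status is unknown, the pool is the
QC-passing samples. Window means strictly below the cutoff are "low"; ties
are not deleted. A maximal run of low positions becomes a call with
`start = first low position − 1`, `end = last low position`. Boundary error
of at most half a window (±13 positions at the default window) is inherent
to window-mean crossing and is the tolerance used throughout the tests.
A parallel scan of the highest probe intensity (50 bp window, same
mean − 3 SD construction on the pooled intensity) is available as
corroborating evidence; the quality channel is authoritative, and no fusion
rule is applied.

Sensitivity versus deletion size is estimated by simulation: the cutoff is
computed once from 8 clean synthetic samples, then for each size and
replicate a fresh clean sample receives an injected deletion at a uniformly
random interrogable location and is scanned; a replicate counts as detected
iff some call overlaps the injected span. 200 replicates per size are used
by default. Under the default generator the best window over an 18 bp
deletion has expected mean (18·1.5 + 7·30)/25 ≈ 9.5, about ten window-SDs
below the ≈15.0 cutoff, so 18 bp deletions are detected essentially always,
while a 10 bp deletion's best window mean (≈18.6) sits well above the
cutoff and is essentially never called — the detector transitions sharply
near window/2.

## Base-call refinement

The combined signal-to-noise ratio of a position is, per strand, the
highest/second-highest probe-intensity ratio; the two strands are combined
by the minimum, and a top base is defined only when both strands agree on
the argmax. This conservative combination (rather than summing strands
first) prevents strand-discordant rescues.

Refinement applies, in order: (1) initial call = haploid call where
quality ≥ 3, else N; (2) rescue of N calls with SNR > threshold and a
defined top base; (3) demotion to N of non-rescued reference-mismatching
calls with quality < 12; (4) demotion to N of remaining non-rescued
reference-mismatching calls with SNR < threshold. Rescue precedes demotion,
and demotions never apply to rescued calls: a rescued call has already
passed the stricter SNR criterion, and re-applying the quality rule to it
would undo every rescue. Re-running refinement on its own output with the
`prior` track supplied (provenance-aware passthrough) is a no-op, which the
tests assert. "Variant" in the demotion rules means a call differing from
the reference sequence.

The default SNR threshold 1.26 can be re-derived from any set of pure-noise
ratios (e.g. a known-deleted region) as median + 4 × SD of the values lying
within [Q1, Q3]. "SD of the inter-quartile values" is read as the SD of the
within-IQR subsample (sample SD, ddof = 1); the multiplier and the reading
are both exposed.

## Redundant-probe consolidation

At positions tiled by ≥ 2 probe sets, all calls with quality strictly
above 3 vote (N never votes). A unique plurality wins. A two-way tie is
broken by a two-sided Wilcoxon rank-sum test on the two groups' quality
scores: exact by enumeration of all group assignments (midranks for ties)
when the pooled size is ≤ 10, tie-corrected normal approximation otherwise.
If p < 0.05 the group with the higher mean quality wins; otherwise the
position is called N and flagged as potential heteroplasmy (note that with
2-vs-2 votes the exact test cannot reach p < 0.05, so such ties always
flag). Ties among ≥ 3 bases flag directly. Flagged positions are merged
into the heteroplasmy candidate list before filtering.

## Heteroplasmy detection and quantitation

The per-position statistic is
`ln[(I_highest/I_second) / (I_second/I_lowest)]` over strand-summed
intensities. The log base is immaterial (only the shape of the left tail is
used); natural log is used. Candidates must satisfy, with k = 3:
`stat ≤ μ_sample − k·σ_sample` (within the sample, across positions) and
`stat ≤ μ_position − k·σ_position` (across samples at that position, both
conjunctively). Two numerical choices matter:

- The cross-sample moments are computed leave-one-out — the tested sample
  is excluded from the positional mean and SD. With all-sample moments a
  single strong heteroplasmy in a small batch inflates the positional SD
  enough to mask itself; leave-one-out removes that self-masking and needs
  n ≥ 3 samples (with fewer, an explicit `within_sample_only` flag screens
  on the within-sample tail alone).
- Candidacy additionally requires the statistic to lie strictly below the
  mean, so zero-variance (noise-free homoplasmic) batches yield no
  candidates instead of flagging every position in the degenerate
  `σ = 0` case.

The four-step filter then removes candidates whose strands disagree on the
highest-intensity base, whose haploid- and diploid-model calls agree (the
step is skipped with a warning flag when the diploid call is missing), or
which sit immediately adjacent (distance 1) to a variant call in the
sample's refined track. Note the strand-agreement step is intrinsically
lossy near a 50/50 allele mix: at f = 0.5 each strand's top allele is close
to a coin flip, so roughly half of exactly balanced sites are discarded.

The load of a surviving site uses the major/minor alleles ranked by
strand-summed intensity: r̄ = √[(I_maj/I_min)_sense · (I_maj/I_min)_anti]
(the "product average" is read as the geometric mean; a raw-product mode is
exposed as an option), reported as 100·r̄/(1 + r̄) percent for the major
allele, so the two alleles' percentages sum to exactly 100. On noise-free
synthetic data this recovers 100·(S·f + B)/(S + 2B) exactly for major
fraction f — the shared background B compresses estimates toward 50%, which
is the dominant bias of the method; with B → 0 the estimate equals 100·f.

## Synthetic-data generator

Intensities follow I = (S·f_b + B)·exp(σ_I·Z) per probe, with S = 1000,
B = 50, σ_I = 0.2 and f_b the allele fraction of base b in the sample's
true genotype (0 for every base across deleted spans). Quality is generated
directly rather than derived from intensities so that the QC and deletion
stages are controlled by explicit parameters: clean positions
Normal(30, 5) clipped to [0, 45], deleted positions Normal(1.5, 1) clipped
at 0, degraded samples Normal(18, 8) genome-wide plus a 10% low-quality
peak drawn from the deleted model. An optional mode derives
q = clip(round(10·ln(I₁/I₂)), 0, 45) for realism.

The clean and degraded SDs are split into a per-position probe effect
shared by all samples (SD 3) plus an independent component (SD √(5²−3²) = 4
for clean samples), so the marginal stays exactly Normal(30, 5) while
sample-sample quality correlations are informative (clean pairs ≈ 0.35,
degraded ≈ 0.17, deleted ≈ 0.07 under defaults). Without a shared
component, all correlations would be ≈ 0 and the correlation view of the
QC gate would carry no signal; with it, the generator reproduces the
qualitative QC geometry: degraded/deleted samples separate on both RSS and
mean correlation, and their initial call rates fall below every clean
sample's.

Haploid calls are the true major base where quality ≥ 3 (at deleted
positions, the brightest probe), else N; diploid calls are the two-allele
IUPAC code at heteroplasmic positions with minor fraction in [0.2, 0.8],
else equal to the haploid call.

What the generator does **not** emulate: probe thermodynamics and
sequence-dependent cross-hybridisation, batch effects beyond the
degraded-sample mode, quality/intensity coupling (in the default mode), and
small indels. Passing tests therefore demonstrate the correctness and
calibration of the filtering logic under the stated stochastic model, not
performance on real arrays — in real data the SNR threshold and deletion
cutoff should be re-derived from the data (the constructors for both are
provided), and heteroplasmy sensitivity will depend on probe-specific
behaviour the model ignores.

## Problem sizes and determinism

All randomness flows through one `numpy` generator seeded from
`GeneratorConfig.seed`; batches, the sensitivity simulation and pipeline
reports are bit-reproducible for a fixed seed. The test suite runs on a
670 k-draw scale or smaller per test (full-genome batches of up to 24
samples; 200-replicate sensitivity curves), chosen so the whole suite
completes in well under a minute while keeping every Monte-Carlo assertion
at least ~10 SDs away from its threshold.

## Known limitations

- Deletions shorter than about half the window are invisible by
  construction; small indels are out of scope.
- The heteroplasmy screen requires ≥ 3 QC-passing samples for cross-sample
  moments; the strand-agreement filter discards ~half of exactly balanced
  (f ≈ 0.5) sites; load estimates are background-biased toward 50%.
- Haplogroup assignment is best-match counting over a user-supplied SNP
  panel, with ties and zero-match tracks left "unassigned"; it is not
  phylogenetic placement and should be treated as a coarse label.
- The QC gate assumes approximate normality of the RSS and correlation
  summaries across samples (an ESD assumption); with very few samples the
  gate is conservative.
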