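# Methods

## Screen preprocessing

Raw guide counts (guides × samples, one baseline pool column) are quantile
normalized across all samples: every column is mapped, rank for rank, onto
the row-wise mean of the column-sorted matrix. Ties receive the mean of the
reference values their ranks span (`tie_rule="average"`), which is
deterministic and order-independent; with ties the "identical sorted columns"
property and exact idempotence hold only approximately, since different
columns can average different reference runs — for count data at realistic
depth ties are rare and the deviation is negligible. Depletion is the per-
guide log2 fold change of each tumor against the baseline pool on a counts-
per-million scale with pseudocount 0.5; cpm removes depth differences between
pool and tumors, log2 makes depletion and enrichment symmetric, and the
pseudocount keeps fully depleted guides finite.

**Per-gene quantile normalization and what it is for.** Forcing each gene's
guide × tumor fold-change submatrix onto a common distribution across tumor
columns absorbs per-tumor engraftment-bottleneck variance while preserving
the gene's overall depletion (the reference is the mean across tumors). It is
applied before the per-tumor gene-vs-NTC queries. It is deliberately **not**
applied before gene–gene correlations: equalizing a gene's distribution in
every tumor removes exactly the shared between-tumor variation that
co-essentiality measures — on simulated screens a planted pair's mean guide-
pair correlation drops from ~0.6 to ~0.001 when the across-tumor per-gene
step precedes correlation. Correlations therefore run on the globally
quantile-normalized fold changes. An `axis="guides"` variant (equalize the
gene's guides instead of its tumors, which preserves between-tumor structure)
is available and gives near-identical correlations.

Read counting is exact: a read increments a guide only when one 20-mer of the
read (at a fixed offset, or anywhere under the `scan` strategy) is an exact
match to exactly one library protospacer; imperfect matches and reads
matching two or more guides are discarded, and matched + discarded = total
always. Discarding multi-matches is the conservative extension of discarding
imperfect matches; fuzzy matching and UMIs are out of scope.

## Co-essentiality and the empirical FDR

A gene–gene score is the arithmetic mean of the Pearson correlations (across
tumors) of all (guide-of-A, guide-of-B) pairs; self-pairs are excluded when
A = B, and guides with zero variance across tumors are dropped with a warning
rather than assigned r = 0 (an undefined correlation should not dilute the
mean). At least 3 tumors are required so each pair correlation has ≥ 1
degree of freedom.

The null is built from the data: the pool of all C(n_NTC, 2) non-targeting
pair correlations, computed once per matrix. Each iteration draws n_pairs
correlations from the pool without replacement and averages them; the
empirical FDR is the fraction of 10,000 iteration means that meet or exceed
the observed mean (ties count as exceedances, which can only inflate the
FDR). Options: with-replacement sampling (needed when n_pairs exceeds the
pool), a two-sided |mean| comparison for negative-correlation queries, the
(x+1)/(N+1) correction (off by default, matching a raw-percentage report),
and exact exhaustive enumeration of all C(pool, n_pairs) subsets for small
pools.

*Sampler implementation.* Without-replacement iterations are generated by
permuting the pool and slicing consecutive disjoint blocks of n_pairs, giving
⌊pool/n_pairs⌋ valid uniform samples per permutation. Blocks within one
permutation are negatively dependent; the FDR estimator remains unbiased and
its Monte-Carlo variance can only shrink, so standard-error bounds computed
as √(f(1−f)/N) remain conservative. This makes 10,000 iterations over a
124,750-pair pool take about a second instead of minutes.

*Calibration.* On all-null screens the observed gene-pair mean is, by
exchangeability of targeting and NTC guides, one draw from the same null as
the resampled means (pair correlations sharing a guide are uncorrelated under
the null), so the FDR is approximately uniform on [0,1]. The acceptance suite
verifies KS < 0.1 over 75 gene-pair FDRs pooled across five all-null screens
at the full study geometry (6 × 83 + 500 guides, 14 tumors); 2,000
resampling iterations per pair give 5·10⁻⁴ FDR resolution, ample for that
check at modest cost. Compositional effects are real: when a planted pair
expands or contracts in a tumor, every other guide's relative share moves,
which shifts the NTC pool with it — using NTC pairs as the null absorbs this
common mode.

*Power regime.* The planted-pair reference condition uses a shared per-tumor
latent effect with sd 0.9; against the per-guide profile noise of the default
screen (≈ 0.56 sd, dominated by the 10,000-cell engraftment bottleneck, i.e.
~10 cells per guide) this yields guide-level profile correlations near
0.81/(0.81+0.31) ≈ 0.7.

## Binding model

`fraction_bound` evaluates the 1:1 mass-action quadratic in the numerically
stable form 2·A0·T0/(s + √(s²−4·A0·T0)), s = A0+T0+Kd, avoiding catastrophic
cancellation at large Kd; Kd = ∞ encodes a non-binder (returns 0), Kd = 0
the stoichiometric limit min(A0, T0). Titrations are geometric series: a
top stock serially diluted 2-fold for 16 points and mixed 1:1 with labeled
target (A0 = 20 nM final).

Fitting: response = baseline + amplitude·[AT]/A0, least squares
(Levenberg–Marquardt) over (log10 Kd, amplitude, baseline) with five
log-spaced Kd starts spanning [min(T0)/10, 100·max(T0)]; log10 Kd is clamped
to [−6, 12] (beyond which the curve is flat at machine precision) and fits
pinned at the upper clamp report Kd = ∞. Residual sd uses n−3 degrees of
freedom. The amplitude sign is free — the thermophoretic response direction
is not assumed.

"No binding" designation: a fit is a binder only if it converged, the fitted
|amplitude| is at least 5× the residual sd, and the fitted fraction-bound
span between the lowest and highest titrant concentration is at least 0.1.
These two thresholds are this package's declared operationalization of an
instrument-side screening step whose exact values are proprietary; both are
parameters. A binder whose Kd sits ~100× above the top concentration fails
the span criterion (< 1% of the target can be driven into complex in-window),
which is the intended behaviour: nothing can be said about affinity outside
the assayed range. Competition experiments are handled by fitting each
condition independently and comparing Kd/designations; no ternary model.

Recovery (measured by `scripts/acceptance.py` and the test suite): noiseless
curves return Kd to < 0.1% for Kd from 1 nM to 10 µM; at 1% amplitude noise
the median relative error is ~3% for Kd ∈ {10, 100, 1000} nM with a 5,000 nM
top concentration. The top concentration is a design choice: the 16-point
2-fold series then spans 0.15–5,000 nM and brackets all simulated Kd values.

## Interactome filter

Spectral counts are collapsed to gene level (sum per bait/gene/line/
condition/replicate, symbols upper-cased, rows without a gene dropped with a
tally); probability scores are external inputs in [0, 1] produced by an
upstream interaction-scoring model and are never recomputed here. KO
subclone replicates are averaged within a cell line before comparison.
Per line a prey supports "gained" when ΔP = P(KO) − P(WT) > 0.25 and
(KO+0.5)/(WT+0.5) > 1.5, "lost" under the mirrored conditions; a candidate
needs ≥ 2 supporting lines and no line supporting the opposite direction.
The 0.5 pseudocount defines the ratio when a prey is absent in one condition
(zeros are common in spectral counts). The filter is monotone in all three
thresholds.

## Synthetic generators

`simulate_screen` emulates a focused in-vivo tumorigenesis screen. Defaults:
6 genes × 83 guides + 500 non-targeting controls (≈ the emulated 500+500
library), 14 tumors plus one baseline pool, 10⁶ reads per sample, 10,000
engrafting cells per tumor (no per-tumor engraftment size is published; this
is an exposed guess), log-normal baseline abundances (σ = 0.5) mimicking
uneven library representation, per-guide growth 2^(gene effect + shared
latent effect + N(0, 0.1) guide noise), multinomial sampling at both the
bottleneck and sequencing stages (column sums equal the requested depth
exactly), optional Gamma–Poisson overdispersion. Co-essentiality is planted
as a shared per-tumor Gaussian effect added to both genes — the simplest
mechanism producing correlated depletion. Infection dynamics are absorbed
into the baseline abundances; read-level errors are not simulated. What
passing tests show is that the statistics behave correctly under this
mechanism; real screens add guide-efficacy heterogeneity, clonal dynamics and
PCR artifacts that this generator does not model.

`simulate_isotherm` returns exact mass-action curves plus additive Gaussian
noise; Kd = ∞ gives baseline + noise. `simulate_interactome` plants modulated
preys with a fixed probability delta and count fold change across all lines
(WT probability U(0.2, 0.6), Poisson counts around 30 — a realistic spectral-
count scale for a genuine proximity interactor — duplicate KO subclones per
line, score jitter sd 0.02, small relative to the 0.05 margin between the
planted delta 0.3 and the 0.25 threshold, as the generator contract requires
planted preys to clear the filter in every line).

All three generators are deterministic given their seed (bit-identical
reruns), and all stochastic stages in the package take explicit seeds.

## Problem sizes used in the shipped analyses

The analysis drivers and acceptance script run the full default screen
geometry (998 guides × 15 samples, 124,750-pair NTC pool, 10,000 FDR
iterations for single-pair queries, 2,000 for the 75-pair calibration sweep),
100 replicates per condition for Kd recovery, and 50-prey interactome tables
— sizes chosen so the complete pipeline reruns in about a minute while
keeping every Monte-Carlo error well below the margins being tested.

## Known limitations

- The empirical FDR is a per-pair exceedance probability against an NTC null,
  not a multiple-testing-adjusted q-value across pairs.
- Guide efficacy is homogeneous within a gene up to Gaussian noise; real
  libraries have bimodal efficacy, which widens guide-pair correlation
  spread.
- The binding module fits a single-site model only; cooperative or ternary
  competition mechanisms are out of scope.
- The interactome filter treats probability scores as given; garbage scores
  in, garbage candidates out.
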