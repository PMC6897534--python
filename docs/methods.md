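# Methods

This note records the models, estimators and numerical choices behind
`combokill`, and what the synthetic-data generators do and do not emulate.

## Interaction scoring on dose-response surfaces

**Input.** A checkerboard is a drugs × concentrations grid of viability
relative to untreated controls ("relative cell number"), with a zero-dose
row and column carrying the single-drug margins. Simulated grids use 11
log-spaced doses per axis spanning a 100-fold range centered on each drug's
IC50 (5 points per decade), matching common practice for two-drug
interaction assays.

**GR values.** `GR = log2(rv · 2^d) / d`, where `rv` is relative viability
and `d` the untreated control's population doublings over the assay window.
GR = 1 is unimpeded growth, GR = 0 means the final cell count equals the
initial one, GR < 0 net killing. No lower asymptote of −1 is imposed, so
strongly cytotoxic wells keep their full dynamic range.

**Bliss / excess over Bliss.** Kill fractions are `p = 1 − rv` clipped to
[0, 1): viability above 1 counts as zero kill. The expected combined kill is
`p_exp = p_a + (1 − p_a)·p_b` from the margins, and
`EOB = log10(1 − p_exp) − log10(1 − p_obs)`, so EOB counts extra log-kills:
+1 means ten-fold lower survival than independence predicts; negative values
mean antagonism. The log scale matters because 99% vs 99.9% kill differ by
under 1% linearly but by a full log of survival.

**Median smoothing.** Before isobole extraction, grids may be smoothed by a
nearest-neighbor median filter: each cell is replaced by the median of its
four axis neighbors with the center value counted three times. The center
weighting makes every surface monotone along both dose axes an exact fixed
point — the filter only edits locally non-monotone (jagged) responses and
removes isolated spikes. An unweighted 3×3 median does not have this
property (an axis-monotone surface with strong curvature is altered even in
the interior), which is why the weighted form is used.

**Isoboles.** Equal-effect contours are traced by marching squares
(`skimage.measure.find_contours`) with linear interpolation in log-dose
index space and mapped back to concentrations. Under Loewe additivity,
contour points satisfy `c_a/D_a + c_b/D_b = 1` and are straight in linear
dose; convexity indicates synergy, concavity antagonism. Levels outside the
surface's range return an empty contour with a warning.

**Effect-level crossings.** Single-agent and mixture crossings of an effect
level (default 50% kill on relative cell number) are located by piecewise-
linear interpolation in log10 dose, taking the first crossing. For noisy
replicate curves the response is first projected onto the nearest
non-increasing curve (isotonic regression); this leaves true dose responses
unchanged and removes the low bias that a first-crossing rule has on noisy
data (without it, 95% CIs on additive mixtures cover FIC = 1 in ~85% rather
than ≥ 95% of runs).

**FIC.** Mixtures are designed equipotent: weights proportional to each
drug's equi-effective concentration, so constituents contribute equally to
killing along the ray. `FIC = Σ_i w_i·T*/D_i`, with `T*` the mixture's
crossing and `D_i` the single-agent dose. Replicate plates each yield one
FIC; the 95% CI is a t-interval across replicates. A drug that never
reaches the effect level (as prednisolone-like agents that only slow
growth) raises an error naming it.

**Emergent FIC.** The order-N prediction is composed from measured
(N−1)-order FICs by treating each (N−1)-sub-mixture as a pseudo-drug: the
equipotent N-ray decomposes into the N sub-rays at total/N each, and
dose-additive composition makes the predicted FIC the harmonic mean of the
(N−1)-order FICs. Emergent FIC = observed / predicted; 1 means lower-order
interactions fully explain the N-drug response. This composition is exact
when the data are themselves Loewe-composed from the sub-mixtures, reduces
to 1 under full additivity, and isolates deviations that first appear at
order N. It is one of several defensible composition rules; the choice is
documented here because the literature does not fix one.

## Clone-tracing enrichment

**Pipeline.** Pretreatment counts are floored at the column's 5% quantile
(preventing barcodes with a handful of pretreatment reads from scoring as
enormously enriched), counts become within-sample frequencies, and
enrichment is post/pre frequency. Replicates are merged by the geometric
mean with each replicate floored at 1 — a barcode absent from one flask's
inoculum is not annihilated, while one-off stochastic enrichment is strongly
penalized (the score never exceeds the best replicate and reproducible
enrichment in 2 of 3 replicates still scores positive). Drug scores are
divided by the barcode's vehicle (DMSO) geometric-mean enrichment only when
that exceeds 1, discounting drug-independent fitness without rewarding
vehicle depletion. Whether vehicle normalization should apply per replicate
or to the aggregate is ambiguous in practice; the aggregate is the default
and a per-replicate mode is provided.

**FDR.** The null scrambles barcode identities independently within every
replicate column and re-applies the aggregation, preserving each column's
marginal distribution exactly while destroying cross-replicate consistency.
`FDR(t, m) = E[null barcodes with score ≥ t in ≥ m drugs] / max(observed, 1)`,
clipped to 1. Raw curves can be non-monotone at sparse thresholds, so a
right-to-left cumulative maximum regularizes them (both are reported).
Beyond explicit permutations, an `independent` mode estimates each drug's
null exceedance from the scrambles and combines drugs analytically
(Poisson-binomial), emulating an effectively unbounded number of scrambled
replicate triples. Thresholds are evaluated on the log-ish grid
{2, 5, 10, 20, 50, 100}; 10 is the operating point for resistance calls.

**Calls and overlap.** Resistant sets per drug at the threshold feed exact
Venn-region counts and single/double/triple/quadruple tallies.

## CRISPR screen scoring

**Phenotypes.** With a pseudocount of 10 added to all counts (half-library
preset: 1 added to zero counts only), frequencies are formed per sample and
`rho = (log2(f_treated/f_vehicle) − median_NT) / Δdoublings`. Centering on
the non-targeting median makes the control median exactly 0 and cancels
sequencing-depth factors, so rho is invariant to rescaling any sample's
counts. Guides need ≥ 25 raw counts in at least one condition; gamma
(vehicle vs T0) and tau (treated vs T0) use the same computation with other
column pairs. Doubling differences are inputs; the defaults (O 7.60,
C 9.34, H 7.41, R 7.53) are the measured knockdown-screen values.

**Gene scores.** Per gene/TSS: the signed mean of the five strongest rho
values by absolute value (averaging signed values of the largest-|rho|
guides), and a two-sided Mann-Whitney test of all the gene's rho values
against the non-targeting controls using the normal approximation with
tie/continuity correction — exact enumeration is infeasible at 10-vs-4000,
and tests verify the approximation against an exact rank-sum enumeration on
10-vs-50 downsamples. Genes with fewer than eight observed phenotypes are
dropped; multi-TSS genes are represented by the TSS with the lowest p (ties:
larger |mean-top rho|, then lexicographic). `resistance score =
mean_top_rho × (−log10 p)`; the hypersensitivity score is its negation, so
each direction is called at a positive cutoff.

**Control genes and cutoff.** Pseudo-genes are random groups of 10
non-targeting guides (drawn without replacement within a group; guides may
recur across groups), one set per real gene count, 10 sets by default,
scored identically to real genes. The multi-drug cutoff is the smallest
value on a 0.01 grid at which the mean count (over control sets) of
pseudo-genes scoring above the cutoff in ≥ 2 drugs is ≤ 1. This is lenient
for single-drug calls by design — it biases the analysis *against* the
low-cross-resistance hypothesis being tested. Raising the cutoff never
increases the control count, so the smallest qualifying cutoff is well
defined (implemented via the pooled second-best-score order statistic,
equivalent to the grid scan).

## Cross-resistance parameter ξ

For single-drug resistance frequencies `10^-A` and `10^-B`, the chance
floor for double resistance is `10^-(A+B)` (ξ = 0) and the ceiling is the
smaller single frequency (ξ = 1); an observed MDR frequency defines
`ξ = (min − obs) / (min − max)`. The formula applies equally to counts on a
shared denominator (screen gene counts). For more than two drugs the
minimum is the product over all drugs and the maximum the overall smallest
frequency — the natural extension of the two-drug weighted sum. Observed
values outside the bounds (possible with sampling noise) yield a clamped ξ
plus a flag rather than an error, so batch analyses do not abort; both
arithmetic and geometric summaries over drug sets are reported because
per-set ξ spans orders of magnitude.

Design arithmetic: flask coverage `1 − (1 − 1/n)^m`; growth-selection
enrichment `(1/(1−inhibition))^divisions`; barcode uniqueness
`(1 − 1/library)^(clones−1)` per clone. The last gives 98.6% for 1e6 clones
on a 7×10^7-barcode library — commonly quoted as ">99%" under approximations
that count expected collisions rather than per-clone uniqueness; the
per-clone form is reported as the more conservative bound.

## Synthetic-data generators

**Checkerboards.** Hill kill curves `kill(c) = max_kill·c^h/(c^h+IC50^h)`
combined as: Bliss — product of survivals; Loewe — the dose pair acts as the
potency-normalized summed dose on the first curve (exact dose equivalence
for parallel curves; sham self-combinations are exact); antagonism —
survival = `min(1, bliss·(1 + α·Π kill_i))`, which preserves the margins
exactly and is strictly super-Bliss off-margin, giving the EOB sign property
a sharp test. Noise is multiplicative log-normal with unit mean and
configurable CV (default scenarios use 5–10%); plate spatial effects are not
modeled, since randomized layouts convert them to exactly this kind of
random error in the real assay.

**Clone tracing.** A universe of n clones (default 1e5) carries per-drug
resistance at configurable frequencies (defaults 2e-3 to 1e-2, the range
observed in drug-selection studies at this scale). Cross-resistance is
generated by chaining drugs in descending frequency with
`P(small | large) = ξ·f_s/f_l + (1−ξ)·f_s` and
`P(small | ¬large) = (1−ξ)·f_s`, so the expected pair overlap is exactly
`ξ·min + (1−ξ)·product` — the same mixture the estimator inverts, making
parameter recovery a sharp test. Adjacent pairs in the frequency ordering
are coupled exactly; in universes with more than two drugs, non-adjacent
pairs couple more weakly than ξ. Selection is two pulses of per-cell
binomial survival (resistant 0.5, sensitive 0.005 per pulse by default,
chosen so resistant clones enrich ≥ 10-fold as in strong 72-hour
selections), separated by deterministic exponential regrowth to twice the
inoculum (real regrowth has birth-death noise; drift is therefore
understated between pulses, while the dominant bottleneck noise is
retained). Inocula are multinomial draws at 12-fold clone coverage;
sequencing is multinomial at fixed depth (default 1e6 reads per sample for
tests, configurable; real experiments use ~10× more).

**Screens.** 10 sgRNAs per gene plus ~4000 non-targeting controls (scaled
down in tests); a gene's true rho, attenuated by per-guide efficacy in
[0.6, 1], acts as a selection coefficient per population doubling:
treated-arm abundance is multiplied by `2^(efficacy·rho·Δdoublings)` before
multinomial sequencing, so the recomputed rho estimates efficacy-weighted
truth. T0, vehicle and treated arms are emitted; gamma effects default to
zero.

What the generators do **not** emulate: mechanistic pharmacology of the
cell-cycle antagonisms, immune-mediated killing, PCR amplification bias,
guide-level off-target effects, and stochastic regrowth drift. Passing
tests therefore demonstrate that the estimators recover their own generative
quantities under realistic sampling noise — not that any particular real
dataset satisfies the generative assumptions.

## Problem sizes and numerics

Test and acceptance runs use 1e5 clones, depth 1e6, triplicates (clone
tracing); 400–600 genes, 1000 non-targeting guides, depth 2e6 (screens);
and 101-point dose gradients — sizes chosen so each downstream statistic is
comfortably past its noise floor while the full suite runs in minutes.
Kill fractions are clipped below 1 by machine epsilon so log-survival stays
finite; geometric means are computed in log space; p-values are floored at
the smallest positive float before taking −log10; the ξ estimator flags
rather than errors on out-of-range inputs; and all generators are
reproducible from a single integer seed.

## Known limitations

- The emergent-FIC composition rule and the ξ chain-coupling for > 2 drugs
  are documented package choices among several defensible ones.
- FDR estimates from scrambled nulls can be strongly conservative or
  anti-conservative when replicate marginals are heavy-tailed and the
  observed count at a threshold is near zero; the regularized curve should
  be read alongside the raw one.
- On cleanly separated synthetic data the realized FDR at the calling
  threshold is near zero, well below values seen in real selections, whose
  noise floor reflects biology the generator does not model.
- Mann-Whitney p-values for very strong hits saturate at the normal
  approximation's resolution; scores of top hits are then driven mostly by
  the mean-top-rho factor.
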