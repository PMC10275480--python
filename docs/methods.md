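# Methods

`paralogdiv` models how two copies of a duplicated gene diverge in
transcription and translation after a whole-genome or small-scale
duplication, and provides the statistics used to compare simulated and
observed divergence patterns. This note records the model, its
assumptions, the numerical conventions, and the design choices made where
the problem was genuinely open.

## Expression phenotypes and rate calculus

A gene's expression phenotype is a transcription rate β_m (mRNA/h) and a
translation rate β_p (proteins per mRNA per h). With mRNA and protein
decay rates α_m, α_p (1/h; genome-wide medians 5.10 and 1.34 for budding
yeast, both including dilution by growth at a 99-minute division time),
steady state gives mRNA abundance m = β_m/α_m and protein abundance

    p = β_m β_p / (α_m α_p).

Measurements enter through RPKM shares: mRNA copies are the cellular pool
N_m = 60 000 split by mRNA-seq share, and translation rates split the
total synthesis flux N_p·α_p (N_p = 1.1e8 proteins/cell) by
ribosome-footprint share divided by mRNA abundance. Both conversions are
exactly conservative (Σm = N_m; Σβ_p·m = N_p·α_p), and both normalize over
exactly the genes present in the table — subsetting changes absolute
rates.

## Divergence statistics

Within a pair, divergence of a trait θ is the log2-fold change
log2(max(θ1,θ2)/min(θ1,θ2)); the signed variant is computed in both
orientations and duplicated to 2n rows, making the signed Spearman
correlation invariant to which copy is labeled first. The divergence
ratio D = fc(β_m) − fc(β_p) is positive for transcription-biased pairs.
Bootstrap CIs (percentile, 10 000 resamples by default) resample *pairs*,
then re-duplicate orientations, so the two orientations of one pair are
never treated as independent; the signed correlation's p-value is
computed on 2n rows and is reported together with that n as a caveat.
Mood's median test uses the grand-median 2×2 chi-square without
continuity correction, with ties counted below the median; a closed-form
fast path (validated against scipy) serves the simulation stop check.

## Fitness model

Each gene carries a parabolic fitness function of protein abundance with
vertex (p_opt, μ), μ = 0.42/h the maximal growth rate, and curvature set
by a noise sensitivity Q (per squared protein deviation):

    W(p) = μ + a (p − p_opt)²,   a = −μQ/2.

After duplication the pair is selected on cumulative abundance with the
optimum moved to Δ_opt·p_opt (Q, μ unchanged). The minimal model
evaluates W at the mean cumulative abundance; the precision-economy model
takes the populational mean of W over the noisy abundance distribution
and subtracts a linear transcription cost l_m·c_m·(β_m1+β_m2) (l_m =
1350 nt median pre-mRNA length, c_m = 1.2e-9 per nt). Because W is
quadratic, E[W] = a(σ_tot² + P_tot²) + b·P_tot + c exactly.

### Pair noise variance

Protein-abundance noise of a singleton is σ² = p²(1/p + α_p/β_m + cv0²):
protein-number (Poisson) noise, mRNA-fluctuation noise — smaller for
transcription-heavy expression — and a noise floor cv0 = 0.1. For a pair,
the intrinsic terms of the two copies fluctuate independently and sum,
while the floor is extrinsic cell-state noise, coherent across two
co-expressed copies of the same gene:

    σ_tot² = P_tot + α_p (p1²/β_m1 + p2²/β_m2) + cv0² P_tot².

For identical copies this collapses to the singleton formula at the
summed transcription rate. For diverged copies the mRNA term depends on
how transcription is *allocated*: at fixed totals it is minimized when
each copy's transcription tracks its expression share. This allocation
dependence is deliberate — it is the lever by which the precision-economy
trade-off biases divergence toward transcription (see below) — and it is
the one place where pair fitness is not a function of totals alone.

### Two conventions linking Q to the rates

The noise sensitivity of a gene can be read off its rates in two
arrangements, both exposed behind `infer_q(convention=...)` and both
invertible to a rate construction at a given abundance optimum:

- **balance** (default): Q = c_m·α_m·l_m·(β_m/β_p). At fixed Q the
  implied transcription rate scales as √p — the square-root rate law of
  the precision-economy literature. This convention defines the
  admissibility envelope and the post-duplication optimum derivation.
- **optimality**: Q = 2·l_m·c_m·β_m²/(μ·α_p·p²), the curvature for which
  the observed rate balance exactly maximizes this package's singleton
  precision-economy fitness (marginal noise gain of transcription equals
  its marginal cost). This convention builds the Q distribution that
  drives the evolutionary simulations: it keeps the typical simulated
  fitness function soft enough (scaled stiffness Q·p_opt² ~ 1e-4–1e-2)
  for sequential fixation to explore the landscape on realistic
  timescales, while leaving a stiff tail. Under it, the closed-form rate
  construction and the global differential-evolution optimum nearly
  coincide, the optimizer pulling abundance slightly below p_opt because
  noise grows with expression.

Values of Q above the theoretical maximum Q_max = 6.8588e-6 are excluded
wherever Q is sampled.

### Admissibility and the post-duplication optimum (Δ_opt = 1.87)

A fitness function is admissible when it tolerates its own expression
noise: the noise load (Q/2)σ² at the optimum, with β_m at its Q-optimal
(balance) value, may not exceed 1 — equivalently, the parabola stays
non-negative within one SD of abundance noise. This caps the abundance
optimum at p_max(Q); at Q_max, p_max ≈ 3889 proteins/cell, where the
mRNA-fluctuation term is comparable to the noise floor.

A duplication doubles abundance to 2p_opt. The post-duplication optimum
multiple Δ_opt is the smallest multiple (0.01 granularity) for which
W(2p_opt) > 0 under the shifted parabola for *every* admissible (p_opt,
Q) — the binding case being the narrowest admissible function, Q = Q_max
at p_max(Q_max). Positivity requires 2 − Δ < 1/(p√(Q/2)) = 0.1388, giving
Δ_opt = 1.87. At half the maximal sensitivity the same scan returns 1.86
(wider parabolas tolerate more overshoot); scripts/acceptance.py
recomputes this derivation from scratch.

### Curvature filter

Immediately after duplication, losing one copy must be deleterious or the
new pair would not survive the constant rain of loss-of-function
mutations. Sampled (p_opt, Q) combinations are kept only when halving
cumulative abundance from 2p_opt to p_opt drops scaled fitness by more
than 1/N (N the selection-efficacy parameter): about 10% of combinations
fail at N = 1e6 and 25% at N = 1e5 under the default synthetic pool. The
same 1/N rule, applied to zeroing one copy's expression at the end of a
run, is the post-hoc loss filter.

## Sequential-fixation engine

Each pair starts as two identical copies of a generated ancestral
singleton: (p_opt, Q) are sampled independently with replacement from the
rate pool's abundance and (optimality-convention) Q distributions,
re-drawn until the curvature filter and noise-load bound pass. Minimal-
model ancestors get the closed-form rates and then a fresh Q resampled
from the pool (decoupling the landscape from precision-economy
constraints); precision-economy ancestors get differential-evolution
optimal rates (log-rate space, polished, seeded also from the closed
form so the optimizer can never fall below it).

Per round, one mutation per pair: a relative effect from the chosen
family (normal; skew-normal re-parameterized so the distribution itself
has mean 0 and SD σ_mut; or bivariate normal acting on both rates with
correlation r_mut), assigned to transcription or translation with
probabilities proportional to the target sizes P_βm : P_βp, to one copy
with probability 1/2, and applied multiplicatively. Candidates taking any
rate to zero/negative or above the rate caps (pool maxima by default) are
rejected outright and consume the round. Fitness is scaled by μ;
candidates with non-positive fitness are rejected; otherwise the
modified Metropolis rule fixes the mutation with probability 1 if it is
non-deleterious and exp(−2N·ΔlogF) if deleterious.

Randomness is organized round-major: streams keyed by (seed, purpose)
emit per-round arrays consumed identically whichever models run, so the
nth pair of the minimal and precision-economy simulations receives the
exact same mutation series and acceptance uniforms, a single-model run is
bit-identical to its half of a joint run, and rounds vectorize across
pairs. Runs stop as soon as Mood's median test cannot distinguish
(p > 0.1) the simulated protein-abundance |log2 fc| distribution from the
reference, checked every round; a 200 000-round cap is a safety valve
only, and capped runs are flagged rather than silently kept.

For the bivariate family, per-level effect SDs are calibrated so the mean
|relative protein-abundance change| per mutation matches a univariate
reference σ_mut (analytically σ_mut·√(2/π)); because effects are
multiplicative the ancestral rates cancel from this matching. A brute
grid plus root solve on common random numbers does the calibration to 1%.

### Why the trade-off biases divergence toward transcription

With the allocation-dependent mRNA-noise term, a pair whose protein
abundances have drifted apart is noisier when the more-expressed copy is
not also the more-transcribed one. Selection therefore drags β_m
allocation along with expression divergence — transcription fold changes
track protein fold changes while translation changes are suppressed. In
the mock run (50 pairs, σ_mut = 0.025, N = 1e6, equal target sizes) this
produces a strongly transcription-biased final state, with ~90% of pairs
having their most-transcribed copy also most abundant, and a fitness
trajectory that gains almost everything in the first fifth of the run
while β_m keeps diverging afterwards. The late "plateau" is not exactly
flat: fitness keeps creeping upward slowly as realignment reduces noise,
at roughly 2e-4 of the per-pair fitness range per 100 rounds.

## Synthetic data

The generator stands in for the genome-scale yeast rate table and its
paralog annotations. Defaults, chosen once: 4440 genes; log-normal β_m
with natural-log scale 2.0 (mRNA marginals spanning ~3 decades; with the
60 000-transcript pool over 4440 genes this puts the median at ~1.8
mRNA/cell, matching single-molecule counts in yeast) and β_p with scale
0.45 (the residual spread of footprints against mRNA when their log
correlation is 0.981); locations follow from the transcript-pool and
flux-conservation constraints, putting the median protein at ~2250
copies/cell. The β_m–β_p correlation is solved numerically so that
corr(log m, log s) hits 0.981. Gene-specific decay rates are log-normal
with medians at the genome constants.

Paralog pairs (245 WGD + 164 SSD by default) are imprinted by rewriting
the second member's rates as paralog-1 rates times 2^δ, with (δ_bm, δ_bp)
mean-zero bivariate normal, SDs 2.29 and 1.11 log2 units (transcription-
dominant truth) and Pearson correlation 2·sin(π·ρ_s/6) so the *rank*
correlation of signed fold changes targets ρ_s (default 0.45, a realistic
mid-range for the signed-divergence association). Global rescalings then
restore Σm = N_m and Σβ_p·m = N_p·α_p — they preserve all within-pair
fold changes, and make β_p exactly recoverable from the stored (s, m) via
the footprint-share identity. Ground truth (the drawn δ's and the
generating parameters) is emitted alongside every table.

What the generator does *not* emulate: real gene identities, chromosomal
or regulatory structure, the empirical shape of the abundance
distribution beyond log-normality, correlated measurement error between
platforms, or evolutionary signal beyond the imprinted pair structure.
Passing tests therefore demonstrate that the pipeline's statistics and
simulations behave correctly under a controlled data-generating process
with the stated moments — not that any biological conclusion about real
paralogs is reproduced from real measurements.

## Robustness studies

Measurement noise: paralog-1 rates are drawn from a pool, true log2 fold
changes from normals with SDs (σ_Δβm, σ_Δβp), exact measurements formed
as m ∝ β_m and s = β_p·m, Gaussian *relative* errors added (negative
draws re-drawn, not clipped, to keep measurements positive), and apparent
rates recomputed assuming constant decay. The summary is the median
fc(β_m) / median fc(β_p) ratio, apparent vs true. The decay variant draws
gene-specific decay rates and decay fold changes so true abundances use
them while apparent rates assume the median — isolating the bias from
unmodeled decay variation. Because β_p = s/m compounds the error of both
measurements, noise inflates apparent translational divergence and the
apparent ratio falls below truth.

Spurious correlations: pseudo-rates β_m = m and β_p = s/m are computed
from random abundances with no evolutionary structure. On the default log
scale, s is modeled as m times an independent log-normal efficiency whose
spread is solved from the requested corr(log m, log s); for independent
m, s the shared-m construction alone produces a strongly negative signed
divergence correlation (≈ −0.7), while at the dataset-like r = 0.98 the
artifact vanishes; at r = 1 the pseudo-translation fold changes collapse
and the correlations are returned as NaN. A linear-scale variant is
provided.

Protein-abundance validation correlates rate-implied protein fold changes
(p = m·β_p/α_p, optionally with a gene-specific protein-decay table)
against measured ones, with a null built from 10 000 shuffles of β_p
across genes.

## Assessment

A run is summarized against a reference by the three two-sample KS
statistics (|log2 fc| of β_m, β_p, protein) and their mean, matching
Mood p-values, and the two divergence correlations; replicates combine
into grand means. The grid search evaluates (model, σ_mut, target-size
ratio) cells with a fixed replicate seed set — per-cell seeding makes the
table independent of evaluation order — and reports the cell minimizing
the grand mean KS. Correlation replication follows an at-least-one-of-
three-replicates-inside-the-CI rule, with the empirical CI always
supplied as data, never hard-coded. Under the default synthetic
reference, the KS landscape improves monotonically down to σ_mut ≈ 0.01
(smaller effects leave fewer near-frozen pairs), so grids that do not
extend below 0.025 find their best σ at the low edge; the target-size
ratio axis has an interior optimum at 3.

## Numerical choices and problem sizes

Defaults scale the study to a desk: mock runs use 50 pairs, grid-search
replicates 250 pairs × 3 seeds, Monte-Carlo robustness studies 10 000
pairs, and bootstrap CIs 10 000 resamples (configurable down for
exploration). The differential-evolution optimizer runs vectorized with
up to 150 generations, tolerance 1e-12, and L-BFGS-B polish from both the
DE solution and the closed-form seed; restarts agree to ~1e-8 relative in
fitness. Exact-zero mutation effects are accepted as neutral; fitness
ties fix with probability 1 (exp(0)). All tables are plain TSV with '.'
for missing values; every random draw descends from explicit seeds and
double-runs reproduce byte-identical outputs.

## Known limitations

Sequential fixation ignores segregating variation and compensatory double
mutants; trans-acting mutations (which cannot diverge identical copies)
are excluded by design; gene loss is handled only as a post-hoc filter
because in-run loss makes the stop condition a moving target. The
Metropolis rule values all beneficial changes equally, overstating
selection on infinitesimal gains. The noise-floor term treats extrinsic
noise as perfectly coherent between copies; partial coherence would
interpolate between the collapsed and summed forms. The admissibility
envelope and Δ_opt derivation use the balance convention's rate law,
while simulations sample Q from the optimality convention — the two
coincide only at the precision-economy optimum, and this split of roles
is a deliberate design choice documented above.
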