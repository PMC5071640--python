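# Methods

`icekit` quantifies a retrotransposon-based in vivo mutagenesis platform in
yeast: a galactose-inducible Ty1 element replicates through an error-prone
transcription / reverse-transcription cycle and re-integrates, mutagenizing a
synthetic cargo each cycle. The package implements the quantitative layer of
such a study — rate estimation from platings, mutation-spectrum calling from
amplicon sequencing, library-diversity arithmetic, and growth statistics —
together with a forward simulator of the whole process, so every estimator
can be exercised against known ground truth without wet-lab data.

## Transposition-rate estimation

**Model.** In a low-density induction, cells divide as the element is
active, so a transposition early in outgrowth founds a clonal lineage of
prototrophs: selective colony counts across parallel cultures follow the
Luria–Delbrück distribution. We model growth as synchronous doublings; at
each division every newborn cell independently completes a transposition
with probability τ, and transposant lineages double thereafter. The expected
number of transposition events per culture is then m = τ·(N_final −
N_initial).

**MSS maximum likelihood.** `ld_pmf` evaluates the Luria–Delbrück
probability mass by the Ma–Sandri–Sarkar recursion
(p₀ = e^(−m), p_k = (m/k)·Σ_{i<k} p_i/(k−i+1)); `mss_mle` maximises the
joint log-likelihood of the replicate counts over m. Numerical choices:

- The recursion is O(k²); replicates with more than `k_cap` (default 512)
  colonies — jackpot cultures — are *censored at the cap* and contribute
  through the right-tail probability. The smallest count is always kept
  exact so the likelihood retains a finite maximum even when every culture
  is a jackpot.
- A coarse logarithmic grid brackets the optimum before the bounded scalar
  search (tolerance 1e-6 on m); for large m the log-likelihood bottoms out
  at the floating-point floor, a plateau that can trap a plain
  golden-section search. Exact plateau ties resolve toward smaller m.
- 95% intervals are profile likelihood at a log-likelihood drop of 1.92
  (χ²₁). With all counts zero, m̂ = 0 and only the upper bound
  1.92/replicates is reported. In round-trip simulations at m ≈ 6 with 3
  replicates the intervals cover the true m in ≈ 96–97% of experiments.

**Per-cell rates.** `rate_from_m` divides m̂ by the final cell count and,
optionally, by elapsed days or generations. Dividing a per-culture estimate
by *time* versus by *generations* are materially different conventions and
neither is canonical for an induction that spans both growth and stationary
phase, so the divisor mode is always recorded in the result; the benchmark
recoveries use the undivided per-cell frequency.

**Partial plating.** The default correction divides m̂ by the plated
fraction. This is near-unbiased above ~70% plating but anticonservative
below it (≈ +18% at 50%, ≈ +60% at 20% plating in our simulations), because
a binomially thinned Luria–Delbrück distribution is not the distribution of
a smaller m. Stewart's correction m̂·(f−1)/(f·ln f) is available via
`plating_correction(..., method="stewart")` for strong thinning; the method
used should always be reported with the estimate.

**High-density inductions.** At saturating density over a multi-day
exposure, additional growth is negligible, so events accumulate as
Poisson(cells × rate × days) and `direct_frequency` reports the plain
per-cell frequency mean(count/plating_fraction)/cells with a t-interval
over replicates (exact binomial optional).

## Amplicon mutation-spectrum pipeline

The pipeline mirrors a MiSeq amplicon experiment: barcoded primer pairs
amplify the mutagenized cargo from ~20 independent cultures plus an
un-mutagenized control amplicon; overlapping 2×250 bp mates are merged,
demultiplexed, aligned to the unmutated reference, and mutations are called
and background-corrected.

- **Merging** picks the ungapped overlap maximising the quality-weighted
  agreement Σw·[bases agree]/Σw with w = min(q₁, q₂); pairs scoring below
  0.95 are rejected. The statistic echoes a stringent read-merger threshold
  of 0.95 but is not a reimplementation of any particular tool's posterior.
  Disagreements resolve to the higher-quality base (ties to the forward
  mate); merged qualities take the max.
- **Demultiplexing** assigns a read to the unique barcode within Hamming
  distance 1; the table invariant (pairwise distance ≥ 2) guarantees
  uniqueness, and ambiguous or 2+-error reads go to an unassigned bin
  (≈ 2% at a 1% per-base error rate on 22 bp barcodes — these are dropped,
  not guessed).
- **Alignment** is global three-state Needleman–Wunsch with affine gaps
  (match +1, mismatch −1, gap open −3, extend −1) inside a diagonal band
  (default 15, widened automatically when the length difference demands);
  tie-breaking places gaps at their leftmost equivalent position, and
  ground-truth indels are left-normalised the same way before comparisons.
  Scores are verified against an unbanded full-DP oracle.
- **Calling** treats a contiguous gap run as one indel event, classifies
  substitutions as transitions/transversions, and ignores N positions and
  terminal gap runs.
- **Summaries** express class rates as events per sequenced reference base.
  Reported metrics: mutations/kb, Ts/Tv, the transition-rate ratio
  (A→G + T→C)/(G→A + C→T) — defined on transitions only; whether
  transversions at A:T pairs should count is a convention, so the class
  sets are explicit in the code — class percentages of all events (they sum
  to 100 by construction), a per-position rate profile, and a per-read
  mutation-count histogram (with/without indels).
- **Background subtraction** averages the per-sample class rates of the
  cargo cultures (unweighted — each culture is one biological observation),
  averages the control samples likewise, and subtracts control from cargo
  class-wise, flooring at zero (floored classes are flagged). Derived
  ratios recompute from corrected rates. Intervals: raw tallies carry exact
  (Clopper–Pearson) binomial intervals; corrected quantities carry
  propagated variances (both channels' counting noise) with normal or
  delta-method intervals, since subtraction happens before interval
  construction.

## Synthetic data

The simulator generates every input with per-event ground truth:

- **Spectrum.** `SpectrumProfile` carries the per-base substitution rate, a
  row-stochastic P(alt|ref) matrix, insertion/deletion event fractions, and
  per-reference-base substitution propensities. The conditional matrix
  alone cannot produce a marginal base-usage bias on a balanced reference,
  which is why the propensity vector is a model parameter. The built-in
  Ty1 reverse-transcription profile encodes 0.15 events/kb, Ts/Tv 1.06,
  AT→GC/GC→AT 0.28, 69.4% of events at G:C pairs, 0.08% insertions and
  1.6% deletions, with strand symmetry and transversions split evenly.
- **Reads.** Templates are barcode + (optionally mutagenized) insert;
  defaults use a 430 bp insert with 22 bp barcodes so that 250 bp mates
  overlap by ~48 bp (overlapping mates are a precondition of merging; a
  multi-kb amplicon cannot be merged from 2×250 reads). References are
  generated with exactly balanced base composition so that per-class
  sequencing-error rates match between cargo and control amplicons — with
  skewed compositions the background subtraction would inherit a
  composition-mismatch bias. Qualities are constant Phred 33 with optional
  linear decay; real instrument quality structure is not modelled.
  Sequencing errors: i.i.d. substitutions at 5e-4/base (a realistic
  post-filter short-read figure) and rare frame slips at 1e-6/base
  (read length is kept fixed, so a slip truncates or pulls in one trailing
  base). Because the error channel is identical for both amplicons, it
  cancels in subtraction; its value matters for variance, not bias.
- **Colony counts.** Low-density cultures simulate the synchronous-doubling
  model exactly (binomial births, clonal doubling; Poisson limit above a
  10⁷-cell cap). High-density cultures draw Poisson event counts. Note the
  synchronous-doubling clone sizes are dyadic, a slightly coarser clone-size
  law than the continuous Luria–Delbrück model the estimator assumes; the
  profile-interval coverage quoted above is measured under this mismatch.
- **Reversion assays.** A cargo with an engineered premature stop codon
  reverts when a replication pass substitutes the stop into any sense codon
  (a whitelist of codons can restrict this; the default is deliberately
  permissive since the engineered stop's identity is a free design choice).
  The per-event reversion probability is computed exactly from the spectrum
  and codon table; above 10⁵ events per culture the event-level loop is
  replaced by a binomial draw with that probability (distributionally
  identical, validated against the event-level path). The no-element arm
  draws Poisson background reversions at a user-set genomic rate.
- **Growth and selection.** OD curves are logistic with a lag and
  multiplicative log-normal noise, sampled every 15 min. Serial selection
  grows a genotype mixture deterministically and exponentially with
  condition-dependent rate multipliers, transfers at an OD threshold into
  the next level of a non-decreasing escalation schedule, and samples five
  clones per transfer multinomially. No death, mutation during selection,
  or density dependence is modelled.

All simulators take a single seed; per-sample streams derive from it by
stable hashing, so results are bit-reproducible and insensitive to sample
ordering.

**What passing round-trips do and do not show.** Recovery of generating
values demonstrates that the estimators are correct under the stated
models — not that real libraries satisfy those models. Real data adds PCR
chimeras and jackpots, quality-dependent and context-dependent error
spectra, unequal amplification across barcodes, and integration-site
effects, none of which the generator emulates.

## Library diversity

`distinct_transposants` is rate × cells (clonal daughters excluded by the
definition of a unique transposant). `expected_distinct_mutants` treats each
transposition as an independent replication pass: K ~ Poisson(μL) mutations;
K = 0 returns wild type; the single-substitution class (3L genotypes) is
counted by the exact occupancy expectation Σ_g (1 − (1 − p_g)^N), either
equiprobable or spectrum-weighted; all other classes (multi-mutation
genotypes, indels) occupy a vastly larger genotype space and are counted as
all-distinct — an overcount only when single-indel events are a substantial
share of a short cargo's events. The closed form agrees with event-level
Monte Carlo within 2% at the default operating point (L = 100, 0.15/kb,
10⁴ events). `length_tradeoff` combines a user-supplied cargo-length →
transposition-rate table with this expectation; no specific published
length-rate curve is hard-coded, and no single "distinct mutants per litre"
headline is reproduced here because its derivation (density, duration,
distinctness convention) is not fixed by the main text of the study.

## Growth statistics

`fit_growth_curve` takes the maximum slope of sliding 9-point least-squares
fits to ln OD (≈ 2 h of 15-min samples — wide enough to average noise,
narrow enough to sit inside the exponential phase; configurable), defines
the lag by the classical tangent construction (the max-slope tangent's
intersection with the initial OD level, the initial level being the median
of the first window), and reports the maximum of the median-smoothed curve
as OD_max. Flat curves (best slope < 1e-3 h⁻¹) report μ_max = 0 with lag
NaN. ODs are floored at 1e-4 before the log transform.

`mann_whitney_u` enumerates the exact mid-rank U distribution when
n_x + n_y ≤ 12 and otherwise uses the tie-corrected normal approximation
with continuity correction; the exact branch matches independent exact
enumeration, and exact vs approximate p agree within 0.02 at n = 10 + 10.
`fishers_method` refers −2Σln p to χ²(2k); zero p-values are rejected
rather than silently floored. `compare_libraries` runs one-tailed tests per
(metric, condition, ordered group pair) — lag time reversed so "better"
means shorter — and reports significant counts and an "on par or better"
count operationalised as *not significantly worse* at the chosen α, which
is one reasonable reading of such tallies, stated here explicitly because
no operational definition is canonical.

## Benchmarks and problem sizes

`icekit.benchmarks` pins the desk-scale study conditions: the initial
plasmid system at a per-cell frequency of 6.1e-4 (3-replicate fluctuation
assays on 10 → 10,240-cell cultures, m ≈ 6 — the classic operating regime
of a fluctuation assay), the optimized system at 3.7e-2 per cell (10⁵-cell
high-density inductions, 2% platings), and the sequencing benchmark at 20
cargo samples × 30,000 templates plus a 5:2 molar control channel
(~2.1 × 10⁶ read pairs, a desk-scale stand-in for a MiSeq run; ~4 minutes
on one CPU with the banded aligner). `scripts/acceptance.py` re-runs the
sequencing benchmark end to end and reports the corrected bias metrics.

## Known limitations

- The synchronous-doubling growth model and the MSS likelihood differ in
  clone-size fine structure; at very large m (hundreds of colonies per
  plate) the profile intervals under-cover modestly (≈ 90% observed).
- The simple plating correction biases upward at small plated fractions
  (see above); heavy thinning needs the Stewart option or a full thinned
  likelihood, which is not implemented.
- The aligner assumes merged reads span the full amplicon (global
  alignment); partial fragments would need local alignment.
- Sequencing errors are i.i.d. and quality-blind; no chimera detection or
  quality recalibration is performed.
- Multi-mutation genotypes are assumed distinct in the diversity closed
  form; indel sequence identity is ignored there.
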