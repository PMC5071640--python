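# icekit

Analytics for retrotransposon-driven *in vivo* mutagenesis and continuous
evolution in yeast.

A galactose-inducible Ty1 retroelement replicates through an error-prone
RNA → cDNA cycle and re-integrates into the genome, mutagenizing a synthetic
cargo gene on every cycle. Coupled to growth selection, this turns a yeast
culture into a self-contained directed-evolution machine. Quantifying such a
platform requires four kinds of analysis, and `icekit` implements all of
them for experimentalists and modellers working with these systems:

1. **Transposition/mutation rates from platings** (`icekit.fluctuation`).
   Low-density inductions are fluctuation assays: selective colony counts
   k_r across replicate cultures follow the Luria–Delbrück distribution,
   whose mass function comes from the Ma–Sandri–Sarkar recursion

       p_0 = e^(−m),   p_k = (m/k) · Σ_{i=0}^{k−1} p_i / (k − i + 1),

   and `mss_mle` finds the expected events per culture m̂ = argmax
   Σ_r log p_{k_r}(m) with a profile-likelihood 95% CI, converting to a
   per-cell rate τ = m̂/N. High-density inductions (negligible growth) use
   the direct frequency mean(count/plating fraction)/cells.
2. **Mutation spectra from amplicon sequencing** (`icekit.spectrum`).
   Overlapping read pairs are merged by quality-weighted overlap agreement,
   demultiplexed by error-tolerant barcodes, globally aligned to the
   unmutated amplicon (banded affine-gap Needleman–Wunsch), and called;
   per-class rates from ~20 mutagenized cultures are averaged and the
   un-mutagenized control amplicon's rates are subtracted to remove the
   sequencing-error background. Outputs are the standard bias metrics —
   mutations/kb, Ts/Tv, (A→G+T→C)/(G→A+C→T), class percentages — with
   exact binomial (Clopper–Pearson) or propagated intervals.
3. **Library diversity** (`icekit.diversity`). Expected distinct
   transposants (τ × cells) and distinct mutant genotypes: per event
   K ~ Poisson(μL) mutations, with the 3L single-substitution genotypes
   counted by the occupancy expectation Σ_g (1 − (1 − p_g)^N) and larger
   genotype classes as all-distinct; plus the cargo-length trade-off
   between transposition rate and mutable positions.
4. **Growth statistics** (`icekit.growth`). μ_max by sliding-window fits to
   ln OD, lag by the tangent construction, exact/asymptotic Mann–Whitney U
   tests, Fisher's method, and library-vs-library comparison matrices.

Everything is exercised against a forward simulator (`icekit.simulate`)
that generates colony counts, paired-end FASTQ runs with sidecar ground
truth, stop-codon reversion counts, OD curves, and serial-selection logs —
so the whole analysis stack is testable end to end with no external data.

## Worked example

```python
import tempfile
from icekit import benchmarks

est = benchmarks.fluctuation_recovery(seed=1)
print(f"fluctuation assay: m = {est.m:.2f}, "
      f"rate = {est.rate:.2e} per cell "
      f"(95% CI {est.ci_low:.2e} - {est.ci_high:.2e})")

est = benchmarks.induction_recovery(seed=1)
print(f"high-density induction: rate = {est.rate:.3e} per cell "
      f"(95% CI {est.ci_low:.3e} - {est.ci_high:.3e})")

with tempfile.TemporaryDirectory() as tmp:
    _, result, truth = benchmarks.spectrum_benchmark(
        seed=1, out_dir=tmp, n_cargo_samples=2, templates_per_cargo=30_000)
c = result.corrected
print(f"spectrum (corrected): {c.mut_per_kb:.3f} mut/kb, "
      f"Ts/Tv {c.ts_tv:.2f}, AT>GC/GC>AT {c.at_gc_over_gc_at:.2f}, "
      f"G,C->N {c.gc_to_n_pct:.1f}%, deletions {c.del_pct:.2f}%")
```

prints

```
fluctuation assay: m = 4.61, rate = 4.50e-04 per cell (95% CI 1.71e-04 - 8.38e-04)
high-density induction: rate = 3.517e-02 per cell (95% CI 2.644e-02 - 4.389e-02)
spectrum (corrected): 0.156 mut/kb, Ts/Tv 1.12, AT>GC/GC>AT 0.31, G,C->N 68.7%, deletions 1.52%
```

Reading it: three simulated low-density cultures generated at a per-cell
transposition frequency of 6.1 × 10⁻⁴ yield m̂ = 4.61 expected events per
~10⁴-cell culture, i.e. 4.5 × 10⁻⁴ per cell with a 95% interval covering
the generating value. The optimized high-density system (generated at
3.7 × 10⁻²) is recovered directly from triplicate platings. The sequencing
round trip — two cargo samples of 30,000 templates plus a 5:2 molar control
channel, mutagenized at 0.15 kb⁻¹ with the Ty1 substitution bias — returns
the corrected rate and bias metrics within their counting noise of the
generating spectrum (0.15 kb⁻¹, Ts/Tv 1.06, ratio 0.28, 69.4% at G:C,
1.6% deletions).

A thin CLI wraps the same functions: `icekit simulate
{fluctuation,induction,amplicon,growth}`, `icekit fluctuation --table
counts.tsv`, `icekit spectrum --r1 ... --r2 ... --ref ... --barcodes ...`,
`icekit diversity`, `icekit growth fit`. See `docs/methods.md` for models,
parameter defaults and their rationale, and limitations.

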