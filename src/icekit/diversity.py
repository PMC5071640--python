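"""Library-size and distinct-mutant expectations.

Translates a per-cell transposition rate and a mutational spectrum into the
expected number of distinct library members: how many unique cells completed
a retrotransposition cycle, and how many distinct mutant genotypes those
events sample given the per-base mutation rate and cargo length. The
single-substitution genotype class (3L genotypes) saturates first and is
evaluated by exact occupancy expectation; rarer classes (multi-mutation
genotypes, indels) occupy a vastly larger genotype space and are counted as
all-distinct.
"""

from __future__ import annotations

import numpy as np

from .simulate import _sample_calls, seq_to_codes, random_reference
from .types import SpectrumProfile


def distinct_transposants(rate: float, cells: float) -> float:
    """Expected number of unique cells with at least one completed
    retrotransposition cycle (clonal daughters excluded by definition)."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0,1]")
    if cells < 0:
        raise ValueError("cells must be non-negative")
    return rate * cells


def expected_distinct_mutants(
    n_events: float,
    length_bp: int,
    spectrum: SpectrumProfile,
    *,
    weighted: bool = False,
    components: bool = False,
):
    """Closed-form expected number of distinct non-wild-type genotypes among
    ``n_events`` independent replication passes over an ``length_bp`` cargo.

    Per event the number of mutations K is Poisson(mu*L); K=0 events return
    wild type. Single-substitution genotypes (3L of them) are counted by the
    exact occupancy expectation sum_g (1 - (1 - p_g)^N) — equiprobable by
    default, spectrum-weighted (balanced base composition assumed) with
    ``weighted=True``. All other non-wild-type classes are approximated as
    all-distinct.
    """
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    if length_bp < 1:
        raise ValueError("length_bp must be positive")
    N = float(n_events)
    L = length_bp
    mu = spectrum.total_rate_per_base
    lam = mu * L
    p0 = np.exp(-lam)
    p_k1 = lam * np.exp(-lam)
    p_single_sub = p_k1 * spectrum.sub_frac

    if N == 0:
        singles = 0.0
    elif not weighted:
        q = p_single_sub / (3.0 * L)
        singles = 3.0 * L * (1.0 - np.power(1.0 - q, N))
    else:
        # balanced composition: L/4 positions per reference base; position
        # weight w_b / (L * mean(w)); alt by the conditional matrix row
        w = spectrum.ref_weights
        wbar = w.mean()
        singles = 0.0
        for b in range(4):
            for a in range(4):
                if a == b:
                    continue
                q = (
                    p_single_sub
                    * (w[b] / (L * wbar))
                    * spectrum.sub_matrix[b, a]
                )
                singles += (L / 4.0) * (1.0 - np.power(1.0 - q, N))
    higher = N * max(0.0, 1.0 - p0 - p_single_sub)
    total = float(singles + higher)
    if components:
        return {
            "total": total,
            "single_substitution": float(singles),
            "other_classes": float(higher),
        }
    return total


def mc_distinct_mutants(
    n_events: int,
    length_bp: int,
    spectrum: SpectrumProfile,
    seed: int = 0,
    n_reps: int = 20,
) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of the number of distinct
    mutant genotypes, by direct event-level simulation on a balanced random
    reference. Guarded at 1e7 events per replicate."""
    if n_events > 1e7:
        raise ValueError(
            "n_events > 1e7: use expected_distinct_mutants instead"
        )
    if n_reps < 2:
        raise ValueError("need >= 2 Monte-Carlo replicates")
    ref = random_reference(length_bp, seed=seed, balanced=True)
    codes = seq_to_codes(ref)
    lam = spectrum.total_rate_per_base * length_bp
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_reps)
    for rep in range(n_reps):
        genotypes = set()
        ks = rng.poisson(lam, int(n_events))
        for k in ks[ks > 0]:
            calls = _sample_calls(codes, spectrum, rng, int(k))
            genotypes.add(frozenset(c.key() for c in calls))
        counts[rep] = len(genotypes)
    return float(counts.mean()), float(counts.std(ddof=1) / np.sqrt(n_reps))


def length_tradeoff(
    length_to_rate: dict[int, float],
    mut_per_kb: float,
    cell_density: float,
    *,
    spectrum: SpectrumProfile | None = None,
    weighted: bool = False,
) -> list[dict]:
    """Cargo-length trade-off: longer cargo transposes less often but offers
    more mutable positions. Returns one row per length with the expected
    distinct transposants and the maximum attainable distinct mutants."""
    if not length_to_rate:
        raise ValueError("empty length->rate table")
    if len(set(length_to_rate)) != len(length_to_rate):
        raise ValueError("duplicate cargo lengths")
    rows = []
    for length, rate in sorted(length_to_rate.items()):
        spec = spectrum
        if spec is None:
            spec = SpectrumProfile.uniform(mut_per_kb=mut_per_kb)
        else:
            scale = (mut_per_kb * 1e-3) / spec.total_rate_per_base
            spec = SpectrumProfile(
                sub_rate_per_base=spec.sub_rate_per_base * scale,
                sub_matrix=spec.sub_matrix,
                ins_frac=spec.ins_frac,
                del_frac=spec.del_frac,
                ref_weights=spec.ref_weights,
            )
        transposants = distinct_transposants(rate, cell_density)
        mutants = expected_distinct_mutants(
            transposants, length, spec, weighted=weighted
        )
        rows.append(
            {
                "length_bp": length,
                "transposition_rate": rate,
                "distinct_transposants": transposants,
                "max_distinct_mutants": mutants,
            }
        )
    return rows
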