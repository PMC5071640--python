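"""Canonical desk-scale benchmark configurations.

These bundle the study conditions under which the package's estimators are
expected to recover their generating parameters: the initial plasmid-based
low-density induction (per-cell frequency 6.1e-4), the fully optimized
high-density induction (3.7e-2 per cell over a 3-day exposure), and the
Ty1RT-RNAPII amplicon-sequencing run (0.15 mutations/kb with the measured
substitution bias, sequenced as barcoded overlapping read pairs with a 5:2
molar excess of control amplicon).

Culture sizes are desk scale: the low-density assay uses ~10^4-cell
cultures, the operating regime of a classic fluctuation assay (expected
events per culture m ~ 6, selective counts mostly 0-30), where the
profile-likelihood intervals are well calibrated.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .fluctuation import direct_frequency, mss_mle, rate_from_m
from .seqio import derive_seed
from .simulate import make_barcode_table, random_reference, \
    simulate_amplicon_run, simulate_high_density_induction, \
    simulate_luria_delbruck_culture
from .spectrum import run_pipeline
from .types import CultureParams, RateEstimate, SpectrumProfile

#: per-cell transposition frequency of the initial plasmid-based system
INITIAL_PLASMID_FREQUENCY = 6.1e-4
#: per-cell transposition frequency of the fully optimized system (3-day
#: high-density induction)
OPTIMIZED_FREQUENCY = 3.7e-2
INDUCTION_DAYS = 3.0


def initial_plasmid_culture() -> CultureParams:
    """Low-density induction at the initial plasmid configuration."""
    return CultureParams(
        n_initial=10,
        n_final=10 * 2**10,
        transposition_rate=INITIAL_PLASMID_FREQUENCY,
        induction_days=INDUCTION_DAYS,
        plating_fraction=1.0,
        mode="low_density",
    )


def optimized_induction_culture() -> CultureParams:
    """High-density induction at the fully optimized configuration."""
    return CultureParams(
        n_initial=100_000,
        n_final=100_000,
        transposition_rate=OPTIMIZED_FREQUENCY / INDUCTION_DAYS,
        induction_days=INDUCTION_DAYS,
        plating_fraction=0.02,
        mode="high_density",
    )


def fluctuation_recovery(seed: int, replicates: int = 3) -> RateEstimate:
    """Simulate one low-density fluctuation assay and estimate the per-cell
    frequency (MSS MLE, no time divisor)."""
    params = initial_plasmid_culture()
    table = simulate_luria_delbruck_culture(params, replicates, seed)
    est = mss_mle(table)
    return rate_from_m(
        est, n_final=float(table.total_cells.mean()), divisor_mode="none"
    )


def induction_recovery(seed: int, replicates: int = 3) -> RateEstimate:
    """Simulate one optimized high-density induction and estimate the
    per-cell frequency directly."""
    params = optimized_induction_culture()
    table = simulate_high_density_induction(params, replicates, seed)
    return direct_frequency(table)


def spectrum_generating_values(
    profile: SpectrumProfile | None = None,
) -> dict:
    """Expected spectrum metrics implied by the generating profile on a
    base-balanced reference."""
    profile = profile or SpectrumProfile.ty1_rnapii()
    p = profile.class_probabilities(gc_fraction=0.5)
    ts = p["A>G"] + p["T>C"] + p["G>A"] + p["C>T"]
    tv = sum(v for k, v in p.items() if ">" in k) - ts
    gc = sum(v for k, v in p.items() if ">" in k and k[0] in "GC")
    at = sum(v for k, v in p.items() if ">" in k and k[0] in "AT")
    return {
        "mut_per_kb": profile.mut_per_kb,
        "ts_tv": ts / tv,
        "at_gc_over_gc_at": (p["A>G"] + p["T>C"]) / (p["G>A"] + p["C>T"]),
        "at_to_n_pct": 100 * at,
        "gc_to_n_pct": 100 * gc,
        "ins_pct": 100 * p["ins"],
        "del_pct": 100 * p["del"],
    }


def spectrum_benchmark(
    seed: int,
    out_dir,
    *,
    n_cargo_samples: int = 20,
    templates_per_cargo: int = 30_000,
    n_control_samples: int = 2,
    control_molar_factor: float = 2.5,
    insert_length: int = 430,
    read_len: int = 250,
    seq_error_rate: float = 5e-4,
    indel_error_rate: float = 1e-6,
):
    """Simulate a Ty1RT-RNAPII amplicon run and push it through the full
    pipeline.

    Amplicons are ``insert_length`` bp inserts behind 22 bp barcodes, so the
    2 x ``read_len`` mates overlap; control depth is ``control_molar_factor``
    times the summed cargo depth (the run's control:cargo molar ratio),
    split over the control barcodes. Returns (run, pipeline result,
    generating metric values).
    """
    profile = SpectrumProfile.ty1_rnapii()
    refs = {
        "cargo": random_reference(
            insert_length, derive_seed(seed, "bench:cargo-ref")
        ),
        "control": random_reference(
            insert_length, derive_seed(seed, "bench:control-ref")
        ),
    }
    barcodes = make_barcode_table(
        n_cargo_samples, n_control_samples, length=22,
        seed=derive_seed(seed, "bench:barcodes"),
    )
    per_control = int(
        round(control_molar_factor * n_cargo_samples * templates_per_cargo
              / n_control_samples)
    )
    templates: Mapping[str, int] = {
        e.sample_id: (templates_per_cargo if e.role == "cargo"
                      else per_control)
        for e in barcodes
    }
    run = simulate_amplicon_run(
        refs,
        barcodes,
        templates,
        profile,
        seq_error_rate=seq_error_rate,
        indel_error_rate=indel_error_rate,
        read_len=read_len,
        seed=derive_seed(seed, "bench:run"),
        out_dir=out_dir,
    )
    result = run_pipeline(run.r1_path, run.r2_path, refs, barcodes)
    return run, result, spectrum_generating_values(profile)
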