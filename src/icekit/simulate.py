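"""Forward simulator of retrotransposon-driven in vivo mutagenesis.

Generates every input the analysis stages consume, with known ground truth:

* Luria–Delbrück colony-count replicates from low-density inductions
  (synchronous doublings; transposition at birth; clonal propagation).
* High-density induction platings (non-growing population, Poisson events
  over the galactose exposure).
* Mutagenized cargo sequences drawn from a :class:`SpectrumProfile`.
* Paired-end amplicon sequencing runs (barcoded templates, per-base
  sequencing errors, 2 x ``read_len`` reads) with a sidecar truth table.
* Stop-codon reversion assays (mutagenesis arm vs background-drift arm).
* Logistic-with-lag OD curves and serial transfer/escalation selections.

All simulators are bit-reproducible given (seed, parameters); per-sample
streams are derived from the master seed by stable hashing so that adding a
sample never perturbs the others.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .seqio import derive_seed, write_fastq
from .types import (
    BASES,
    BarcodeEntry,
    BarcodeTable,
    CargoSpec,
    ColonyCountTable,
    CultureParams,
    GenotypeRecord,
    MutationCall,
    ODSeries,
    SpectrumProfile,
    is_transition,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}

# byte <-> 2-bit code tables (A,C,G,T = 0..3; complement is 3 - code)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def seq_to_codes(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if np.any(arr == 255):
        pos = int(np.argmax(arr == 255))
        raise ValueError(f"unknown base {seq[pos]!r} at position {pos}")
    return arr


def codes_to_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def random_reference(length: int, seed: int, balanced: bool = True) -> str:
    """A random ACGT sequence; ``balanced`` forces an exact 25% composition
    (up to remainder), which keeps per-class sequencing-error rates matched
    between cargo and control amplicons."""
    rng = np.random.default_rng(seed)
    if balanced:
        reps = length // 4 + 1
        codes = np.tile(np.arange(4, dtype=np.uint8), reps)[:length]
        rng.shuffle(codes)
    else:
        codes = rng.integers(0, 4, length, dtype=np.uint8)
    return codes_to_seq(codes)


def make_barcode_table(
    n_cargo: int,
    n_control: int,
    *,
    length: int = 22,
    seed: int = 0,
    cargo_reference: str = "cargo",
    control_reference: str = "control",
) -> BarcodeTable:
    """Random barcodes of the given length, pairwise Hamming distance >= 3
    (comfortably satisfying the >= 2 guarantee the demultiplexer needs)."""
    rng = np.random.default_rng(seed)
    codes: list[np.ndarray] = []
    while len(codes) < n_cargo + n_control:
        cand = rng.integers(0, 4, length, dtype=np.uint8)
        if all(int(np.sum(cand != c)) >= 3 for c in codes):
            codes.append(cand)
    entries = []
    for i in range(n_cargo):
        entries.append(
            BarcodeEntry(f"cargo{i + 1:02d}", codes_to_seq(codes[i]),
                         "cargo", cargo_reference)
        )
    for j in range(n_control):
        entries.append(
            BarcodeEntry(f"control{j + 1:02d}",
                         codes_to_seq(codes[n_cargo + j]),
                         "control", control_reference)
        )
    return BarcodeTable(entries)


# ---------------------------------------------------------------------------
# Colony-count simulators
# ---------------------------------------------------------------------------

def simulate_luria_delbruck_culture(
    params: CultureParams,
    replicates: int,
    seed: int,
    population_cap: float = 1e7,
) -> ColonyCountTable:
    """Low-density induction: synchronous doublings from ``n_initial``.

    At every division each newborn cell independently completes a
    transposition with probability ``transposition_rate``; transposant
    lineages then propagate clonally. The population undergoes
    ``round(log2(n_final/n_initial))`` doublings, so the realised final count
    is ``n_initial * 2**g`` (recorded in the returned table). Above
    ``population_cap`` non-transposant cells, the binomial birth draw is
    replaced by its Poisson limit.
    """
    if params.mode != "low_density":
        raise ValueError("low-density simulator needs mode='low_density'")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    generations = int(round(np.log2(params.n_final / params.n_initial)))
    if generations < 1:
        raise ValueError("n_final must allow at least one doubling")
    tau = params.transposition_rate
    selective = np.zeros(replicates, dtype=np.int64)
    totals = np.zeros(replicates, dtype=float)
    for r in range(replicates):
        w, t = float(params.n_initial), 0.0
        for _ in range(generations):
            if w <= population_cap:
                new = rng.binomial(int(w), tau)
            else:
                new = rng.poisson(w * tau)
            t = 2.0 * t + new
            w = 2.0 * w - new
        mutants = int(t)
        selective[r] = rng.binomial(mutants, params.plating_fraction)
        totals[r] = w + t
    return ColonyCountTable(
        replicate_id=[f"rep{r + 1}" for r in range(replicates)],
        selective_count=selective,
        total_cells=totals,
        plating_fraction=np.full(replicates, params.plating_fraction),
        mode="low_density",
    )


def simulate_high_density_induction(
    params: CultureParams,
    replicates: int,
    seed: int,
    exposure_days: Optional[float] = None,
) -> ColonyCountTable:
    """High-density induction: the population is treated as non-growing, and
    transposition events accumulate as Poisson(n_final * rate * days)."""
    if params.mode != "high_density":
        raise ValueError("high-density simulator needs mode='high_density'")
    if params.n_final <= 0:
        raise ValueError("zero cells exposed")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    days = params.induction_days if exposure_days is None else exposure_days
    rng = np.random.default_rng(seed)
    lam = params.n_final * params.transposition_rate * days
    events = rng.poisson(lam, replicates)
    selective = rng.binomial(events, params.plating_fraction)
    return ColonyCountTable(
        replicate_id=[f"rep{r + 1}" for r in range(replicates)],
        selective_count=selective,
        total_cells=np.full(replicates, float(params.n_final)),
        plating_fraction=np.full(replicates, params.plating_fraction),
        mode="high_density",
    )


# ---------------------------------------------------------------------------
# Cargo mutagenesis
# ---------------------------------------------------------------------------

def _sample_calls(
    codes: np.ndarray,
    spectrum: SpectrumProfile,
    rng: np.random.Generator,
    n_events: int,
) -> list[MutationCall]:
    """Draw ``n_events`` mutation events on a coded sequence.

    Event class by the spectrum's (sub, ins, del) fractions; substitution
    positions weighted by the per-base propensities, indel positions uniform;
    substitution identity from the conditional matrix row. Positions are kept
    distinct so the call list maps one-to-one onto the mutated sequence.
    """
    L = len(codes)
    pos_weights = spectrum.ref_weights[codes]
    pos_weights = pos_weights / pos_weights.sum()
    class_p = np.array(
        [spectrum.sub_frac, spectrum.ins_frac, spectrum.del_frac]
    )
    calls: list[MutationCall] = []
    used: set[int] = set()
    for _ in range(n_events):
        cls = rng.choice(3, p=class_p)
        for _attempt in range(1000):
            if cls == 0:
                pos = int(rng.choice(L, p=pos_weights))
            else:
                pos = int(rng.integers(0, L))
            if pos not in used:
                break
        else:  # pragma: no cover - pathological saturation
            raise RuntimeError("could not place mutation event")
        used.add(pos)
        ref = BASES[codes[pos]]
        if cls == 0:
            alt = BASES[rng.choice(4, p=spectrum.sub_matrix[codes[pos]])]
            kind = "transition" if is_transition(ref, alt) else "transversion"
            calls.append(MutationCall(pos, ref, alt, kind))
        elif cls == 1:
            ins = BASES[rng.integers(0, 4)]
            calls.append(MutationCall(pos, "", ins, "insertion"))
        else:
            calls.append(MutationCall(pos, ref, "", "deletion"))
    return calls


def _apply_calls(seq: str, calls: Sequence[MutationCall]) -> str:
    out = seq
    for c in sorted(calls, key=lambda c: c.position, reverse=True):
        p = c.position
        if c.kind in ("transition", "transversion"):
            out = out[:p] + c.alt_allele + out[p + 1:]
        elif c.kind == "deletion":
            out = out[:p] + out[p + len(c.ref_allele):]
        else:  # insertion before position p
            out = out[:p] + c.alt_allele + out[p:]
    return out


def mutate_cargo(
    seq: str,
    spectrum: SpectrumProfile,
    rng: np.random.Generator,
    n_events: Optional[int] = None,
) -> tuple[str, list[MutationCall]]:
    """One pass of retroelement replication over a cargo sequence.

    The number of mutation events is Poisson with mean
    ``total_rate_per_base * len(seq)`` unless ``n_events`` pins it. Returns
    the mutated sequence and the calls in reference coordinates.
    """
    if not seq:
        raise ValueError("empty cargo sequence")
    codes = seq_to_codes(seq.upper())
    if n_events is None:
        n_events = int(rng.poisson(spectrum.total_rate_per_base * len(codes)))
    if n_events == 0:
        return seq.upper(), []
    calls = _sample_calls(codes, spectrum, rng, n_events)
    return _apply_calls(seq.upper(), calls), calls


def normalize_call(call: MutationCall, reference: str) -> MutationCall:
    """Left-shift an indel to its leftmost equivalent placement.

    A 1-bp indel inside a repeat has several equivalent reference positions;
    the aligner's tie-break reports the leftmost one, so ground-truth calls
    are normalised the same way before comparison.
    """
    if call.kind == "deletion":
        p, allele = call.position, call.ref_allele
        while p > 0 and reference[p - 1] == allele[-1]:
            p -= 1
            allele = reference[p:p + len(allele)]
        return MutationCall(p, allele, "", "deletion", call.read_id)
    if call.kind == "insertion":
        p, allele = call.position, call.alt_allele
        while p > 0 and reference[p - 1] == allele[-1]:
            p -= 1
            allele = reference[p] + allele[:-1]
        return MutationCall(p, "", allele, "insertion", call.read_id)
    return call


# ---------------------------------------------------------------------------
# Amplicon sequencing run
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AmpliconRun:
    """Paths and ground truth of one simulated paired-end run."""

    r1_path: Path
    r2_path: Path
    truth: pd.DataFrame  # read_id, sample_id, n_events, calls
    truth_class_counts: dict  # sample_id -> Counter over event classes
    templates_per_sample: dict
    refs: Mapping[str, str]
    barcodes: BarcodeTable
    read_len: int

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _calls_to_str(calls: Sequence[MutationCall]) -> str:
    parts = []
    for c in calls:
        if c.kind in ("transition", "transversion"):
            parts.append(f"{c.position}:{c.ref_allele}>{c.alt_allele}")
        elif c.kind == "insertion":
            parts.append(f"{c.position}:ins:{c.alt_allele}")
        else:
            parts.append(f"{c.position}:del:{c.ref_allele}")
    return ";".join(parts)


def parse_truth_calls(text: str) -> list[MutationCall]:
    calls = []
    if not isinstance(text, str) or not text:
        return calls
    for part in text.split(";"):
        fields = part.split(":")
        pos = int(fields[0])
        if fields[1].startswith("ins"):
            calls.append(MutationCall(pos, "", fields[2], "insertion"))
        elif fields[1].startswith("del"):
            calls.append(MutationCall(pos, fields[2], "", "deletion"))
        else:
            ref, alt = fields[1].split(">")
            kind = "transition" if is_transition(ref, alt) else "transversion"
            calls.append(MutationCall(pos, ref, alt, kind))
    return calls


def _quality_string(read_len: int, base_quality: int, decay: float) -> str:
    q = np.maximum(base_quality - decay * np.arange(read_len), 2.0)
    return (q.astype(np.int64) + 33).astype(np.uint8).tobytes().decode()


def _apply_sub_errors(mat: np.ndarray, rate: float,
                      rng: np.random.Generator) -> None:
    if rate <= 0 or mat.size == 0:
        return
    n_err = rng.binomial(mat.size, rate)
    if n_err == 0:
        return
    flat = rng.integers(0, mat.size, n_err)
    shift = rng.integers(1, 4, n_err).astype(np.uint8)
    mat.flat[flat] = (mat.flat[flat] + shift) % 4


def _apply_indel_errors(mat: np.ndarray, rate: float,
                        rng: np.random.Generator) -> None:
    """Rare read-frame slips: shift the read tail, keeping length fixed
    (an inserted base truncates the end; a dropped base pulls in one random
    trailing base, as the sequencer keeps reading)."""
    if rate <= 0 or mat.size == 0:
        return
    n_err = rng.binomial(mat.size, rate)
    for _ in range(n_err):
        row = rng.integers(0, mat.shape[0])
        pos = rng.integers(0, mat.shape[1] - 1)
        if rng.random() < 0.5:  # insertion
            mat[row, pos + 1:] = mat[row, pos:-1]
            mat[row, pos] = rng.integers(0, 4)
        else:  # deletion
            mat[row, pos:-1] = mat[row, pos + 1:]
            mat[row, -1] = rng.integers(0, 4)


def simulate_amplicon_run(
    refs: Mapping[str, str],
    barcodes: BarcodeTable,
    templates_per_sample: Mapping[str, int] | int,
    spectrum: SpectrumProfile,
    *,
    seq_error_rate: float = 5e-4,
    indel_error_rate: float = 1e-6,
    read_len: int = 250,
    seed: int = 0,
    out_dir,
    base_quality: int = 33,
    quality_decay: float = 0.0,
    gzip_output: bool = False,
    chunk_size: int = 100_000,
) -> AmpliconRun:
    """Simulate a barcoded paired-end amplicon run.

    Each sample's templates are ``barcode + amplicon``; cargo samples pass
    through :func:`mutate_cargo`, control samples do not. R1 reads the
    template start, R2 the reverse complement of its end; independent
    per-base substitution errors (plus rare frame slips) are layered on both
    mates. Ground truth is returned as a sidecar table.
    """
    by_sample = barcodes.by_sample()
    if isinstance(templates_per_sample, int):
        templates_per_sample = {
            s: templates_per_sample for s in by_sample
        }
    for entry in barcodes:
        template_len = len(entry.barcode) + len(refs[entry.reference])
        if 2 * read_len <= template_len:
            raise ValueError(
                f"sample {entry.sample_id}: read pairs cannot overlap "
                f"(2*{read_len} <= template {template_len})"
            )
        if template_len < read_len + 2:
            raise ValueError(
                f"sample {entry.sample_id}: template shorter than a read"
            )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    r1_path = out_dir / f"r1{suffix}"
    r2_path = out_dir / f"r2{suffix}"

    qual_cache: dict[int, str] = {}

    def qual_for(n: int) -> str:
        if n not in qual_cache:
            qual_cache[n] = _quality_string(n, base_quality, quality_decay)
        return qual_cache[n]

    truth_rows: list[tuple] = []
    class_counts: dict[str, Counter] = {}

    from .seqio import _open_text  # shares the gzip-aware opener

    with _open_text(r1_path, "wt") as f1, _open_text(r2_path, "wt") as f2:
        for entry in barcodes:
            sample = entry.sample_id
            rng = np.random.default_rng(derive_seed(seed, f"amplicon:{sample}"))
            ref = refs[entry.reference].upper()
            bc = entry.barcode
            n_templates = int(templates_per_sample[sample])
            counts = class_counts.setdefault(sample, Counter())
            base_template = bc + ref
            lam = spectrum.total_rate_per_base * len(ref)

            if entry.role == "cargo":
                n_events = rng.poisson(lam, n_templates)
            else:
                n_events = np.zeros(n_templates, dtype=np.int64)

            ref_codes = seq_to_codes(ref)
            done = 0
            tpl_index = 0
            while done < n_templates:
                n_chunk = min(chunk_size, n_templates - done)
                ev = n_events[done:done + n_chunk]
                templates: list[str] = []
                ids: list[str] = []
                for k in ev:
                    rid = f"{sample}.{tpl_index}"
                    tpl_index += 1
                    if k == 0:
                        templates.append(base_template)
                        truth_rows.append((rid, sample, 0, ""))
                    else:
                        calls = _sample_calls(ref_codes, spectrum, rng, int(k))
                        templates.append(bc + _apply_calls(ref, calls))
                        truth_rows.append(
                            (rid, sample, int(k), _calls_to_str(calls))
                        )
                        for c in calls:
                            counts[c.event_class] += 1
                    ids.append(rid)
                done += n_chunk

                # group by template length so each group is a rectangular
                # code matrix; R1/R2 slices and error layers are vectorised
                by_len: dict[int, list[int]] = {}
                for i, t in enumerate(templates):
                    by_len.setdefault(len(t), []).append(i)
                for tl, idx in sorted(by_len.items()):
                    block = "".join(templates[i] for i in idx)
                    mat = _CODE[
                        np.frombuffer(block.encode(), dtype=np.uint8)
                    ].reshape(len(idx), tl)
                    r1 = mat[:, :read_len].copy()
                    r2 = (3 - mat[:, ::-1])[:, :read_len].copy()
                    _apply_sub_errors(r1, seq_error_rate, rng)
                    _apply_sub_errors(r2, seq_error_rate, rng)
                    _apply_indel_errors(r1, indel_error_rate, rng)
                    _apply_indel_errors(r2, indel_error_rate, rng)
                    q = qual_for(read_len)
                    buf1, buf2 = [], []
                    for row, i in enumerate(idx):
                        rid = ids[i]
                        buf1.append(
                            f"@{rid}\n{codes_to_seq(r1[row])}\n+\n{q}\n"
                        )
                        buf2.append(
                            f"@{rid}\n{codes_to_seq(r2[row])}\n+\n{q}\n"
                        )
                    f1.write("".join(buf1))
                    f2.write("".join(buf2))

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample_id", "n_events", "calls"]
    )
    return AmpliconRun(
        r1_path=r1_path,
        r2_path=r2_path,
        truth=truth,
        truth_class_counts=class_counts,
        templates_per_sample=dict(templates_per_sample),
        refs=dict(refs),
        barcodes=barcodes,
        read_len=read_len,
    )


# ---------------------------------------------------------------------------
# Stop-codon reversion assay
# ---------------------------------------------------------------------------

def reverting_fraction(codon: str,
                       whitelist: Optional[set] = None) -> float:
    """Fraction of the 9 single-base changes to a stop codon that restore a
    sense codon (or, with a whitelist, that produce a listed codon)."""
    codon = codon.upper()
    if codon not in STOP_CODONS:
        raise ValueError(f"{codon!r} is not a stop codon")
    n_ok = 0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if whitelist is not None:
                n_ok += alt in whitelist
            else:
                n_ok += alt not in STOP_CODONS
    return n_ok / 9.0


def reversion_probability(
    cargo: CargoSpec,
    spectrum: SpectrumProfile,
    whitelist: Optional[set] = None,
) -> float:
    """Probability that one replication pass over the cargo restores a sense
    codon at the engineered stop site (computed exactly from the spectrum)."""
    if cargo.stop_site is None:
        raise ValueError("cargo has no stop_site")
    codes = seq_to_codes(cargo.sequence)
    L = len(codes)
    w = spectrum.ref_weights[codes]
    w = w / w.sum()
    lam_total = spectrum.total_rate_per_base * L
    codon = cargo.sequence[cargo.stop_site:cargo.stop_site + 3]
    lam_revert = 0.0
    for i in range(3):
        pos = cargo.stop_site + i
        for ai, b in enumerate(BASES):
            if b == codon[i]:
                continue
            alt_codon = codon[:i] + b + codon[i + 1:]
            if whitelist is not None:
                ok = alt_codon in whitelist
            else:
                ok = alt_codon not in STOP_CODONS
            if ok:
                lam_revert += (
                    lam_total
                    * spectrum.sub_frac
                    * w[pos]
                    * spectrum.sub_matrix[codes[pos], ai]
                )
    return float(1.0 - np.exp(-lam_revert))


def simulate_reversion_assay(
    cargo: CargoSpec,
    params: CultureParams,
    spectrum: SpectrumProfile,
    background_rate_per_base: float,
    seed: int,
    replicates: int = 3,
    whitelist: Optional[set] = None,
    event_cap: int = 100_000,
) -> dict:
    """dKanMX-style reversion counts with and without the retroelement.

    Mutagenesis arm: transposition events ~ Poisson(cells * rate * days);
    each event re-replicates the cargo and reverts if a substitution restores
    a sense codon at the stop site. Below ``event_cap`` events this is
    simulated event by event through :func:`mutate_cargo`; above it, the
    exact per-event reversion probability stands in via a binomial draw.
    Drift arm: revertants ~ Poisson(cells * background_rate * 3 * reverting
    fraction of the stop codon).
    """
    if cargo.stop_site is None:
        raise ValueError("reversion assay requires cargo.stop_site")
    rng = np.random.default_rng(seed)
    days = params.induction_days
    cells = params.n_final
    lam_events = cells * params.transposition_rate * days
    p_rev = reversion_probability(cargo, spectrum, whitelist)
    codon = cargo.sequence[cargo.stop_site:cargo.stop_site + 3]
    stop_positions = {cargo.stop_site, cargo.stop_site + 1,
                      cargo.stop_site + 2}

    ice_counts = np.zeros(replicates, dtype=np.int64)
    for r in range(replicates):
        n_ev = int(rng.poisson(lam_events))
        if n_ev <= event_cap:
            rev = 0
            for _ in range(n_ev):
                _, calls = mutate_cargo(cargo.sequence, spectrum, rng)
                for c in calls:
                    if (
                        c.kind in ("transition", "transversion")
                        and c.position in stop_positions
                    ):
                        i = c.position - cargo.stop_site
                        alt_codon = codon[:i] + c.alt_allele + codon[i + 1:]
                        if whitelist is not None:
                            ok = alt_codon in whitelist
                        else:
                            ok = alt_codon not in STOP_CODONS
                        if ok:
                            rev += 1
                            break
        else:
            rev = int(rng.binomial(n_ev, p_rev))
        ice_counts[r] = rng.binomial(rev, params.plating_fraction)

    lam_drift = (
        cells * background_rate_per_base * 3.0 * reverting_fraction(
            codon, whitelist
        )
    )
    drift = rng.poisson(lam_drift, replicates)
    drift_counts = rng.binomial(drift, params.plating_fraction)

    return {
        "ice_counts": ice_counts,
        "drift_counts": drift_counts,
        "p_revert_per_event": p_rev,
        "reverting_fraction": reverting_fraction(codon, whitelist),
        "expected_events": lam_events,
    }


# ---------------------------------------------------------------------------
# Growth curves and serial selection
# ---------------------------------------------------------------------------

def simulate_growth_curve(
    mu_max: float,
    lag_h: float,
    od0: float,
    od_max: float,
    sample_interval_h: float = 0.25,
    duration_h: float = 72.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ODSeries:
    """Logistic growth delayed by a lag, with multiplicative log-normal
    noise, sampled on a regular grid (15-minute default)."""
    if mu_max <= 0:
        raise ValueError("mu_max must be positive")
    if not 0 < od0 < od_max:
        raise ValueError("need 0 < od0 < od_max")
    if lag_h < 0 or noise_sd < 0 or sample_interval_h <= 0:
        raise ValueError("negative parameters rejected")
    t = np.arange(0.0, duration_h + 1e-9, sample_interval_h)
    shifted = np.maximum(t - lag_h, 0.0)
    od = od_max / (1.0 + (od_max / od0 - 1.0) * np.exp(-mu_max * shifted))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od * np.exp(rng.normal(0.0, noise_sd, od.shape))
    return ODSeries(time_h=t, od=od)


@dataclasses.dataclass
class TransferEvent:
    transfer_index: int
    time_h: float          # absolute time of the transfer
    condition: float       # 5-FOA level of the culture that just finished
    clone_sample: list     # genotype names sampled at transfer
    frequencies: dict      # genotype name -> frequency at transfer


def simulate_serial_selection(
    library: Sequence[GenotypeRecord],
    od_threshold: float = 3.0,
    escalation_schedule: Sequence[float] = (0.3, 0.5, 1.0, 1.5, 2.0),
    seed: int = 0,
    *,
    od0: float = 0.05,
    mu_base: float = 0.35,
    clones_per_transfer: int = 5,
    initial_frequencies: Optional[Sequence[float]] = None,
    max_phase_h: float = 2000.0,
) -> list[TransferEvent]:
    """Serial transfer under an escalating counter-selection schedule.

    The mixed population grows deterministically and exponentially, each
    genotype at ``mu_base * fitness_at(level)``; whenever total OD exceeds
    ``od_threshold`` the culture is diluted back to ``od0`` into the next
    level of the schedule and clones are sampled (multinomially) for
    characterisation. A culture that can no longer reach the threshold ends
    the run (no further transfers are logged).
    """
    if not library:
        raise ValueError("empty library")
    sched = list(escalation_schedule)
    if any(b < a for a, b in zip(sched, sched[1:])):
        raise ValueError("escalation schedule must be non-decreasing")
    rng = np.random.default_rng(seed)
    names = [
        g.name or f"g{i}" for i, g in enumerate(library)
    ]
    if initial_frequencies is None:
        freqs = np.full(len(library), 1.0 / len(library))
    else:
        freqs = np.asarray(initial_frequencies, dtype=float)
        freqs = freqs / freqs.sum()
    a = od0 * freqs  # per-genotype OD contribution
    t_abs = 0.0
    log: list[TransferEvent] = []
    for k, level in enumerate(sched):
        rates = mu_base * np.array(
            [g.fitness_at(level) for g in library]
        )

        def total_od(t):
            return float(np.sum(a * np.exp(np.minimum(rates * t, 700.0))))

        if total_od(max_phase_h) < od_threshold:
            break  # stalled: threshold unreachable at this level
        t_hit = optimize.brentq(
            lambda t: total_od(t) - od_threshold, 0.0, max_phase_h
        )
        a = a * np.exp(rates * t_hit)
        t_abs += t_hit
        p = a / a.sum()
        picks = rng.multinomial(clones_per_transfer, p)
        clones = [
            n for n, c in zip(names, picks) for _ in range(c)
        ]
        log.append(
            TransferEvent(
                transfer_index=k + 1,
                time_h=t_abs,
                condition=level,
                clone_sample=clones,
                frequencies={n: float(x) for n, x in zip(names, p)},
            )
        )
        a = od0 * p  # dilute into the next flask
    return log
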