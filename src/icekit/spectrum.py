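"""Amplicon-sequencing mutation pipeline.

merge pairs -> demultiplex by barcode -> align to the unmutated amplicon ->
call mutations -> per-sample spectrum summaries -> average cargo samples ->
subtract the control-amplicon background -> exact binomial intervals.

The pipeline is streaming (constant memory in the number of read pairs) and
order-invariant: only per-sample call tallies and read counts are kept.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from . import _align
from .seqio import FastqRead, read_fastq
from .simulate import codes_to_seq, seq_to_codes
from .types import (
    BASES,
    BarcodeTable,
    MutationCall,
    SUB_TYPES,
    is_transition,
)

log = logging.getLogger("icekit")

TRANSITION_CLASSES = ("A>G", "G>A", "C>T", "T>C")
AT_GC_CLASSES = ("A>G", "T>C")
GC_AT_CLASSES = ("G>A", "C>T")
AT_REF_CLASSES = tuple(c for c in SUB_TYPES if c[0] in "AT")
GC_REF_CLASSES = tuple(c for c in SUB_TYPES if c[0] in "GC")
ALL_CLASSES = SUB_TYPES + ("ins", "del")


# ---------------------------------------------------------------------------
# Exact binomial interval
# ---------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval via Beta
    quantiles; lower bound 0 at k=0, upper bound 1 at k=n."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid (k={k}, n={n})")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -3.0
    gap_extend: float = -1.0
    band: int = 15


@dataclasses.dataclass
class AlignmentResult:
    read: str
    reference: str
    score: float
    ops: np.ndarray  # OP_MATCH / OP_INS / OP_DEL codes, start to end


def _align_codes(read_codes: np.ndarray, ref_codes: np.ndarray,
                 scoring: AlignmentScoring):
    diff = abs(len(read_codes) - len(ref_codes))
    band = scoring.band if diff <= scoring.band - 2 else diff + scoring.band
    band = min(band, max(len(read_codes), len(ref_codes)))
    return _align.banded_affine_align(
        read_codes, ref_codes,
        scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend, band,
    )


def align_read(read: str, reference: str,
               scoring: Optional[AlignmentScoring] = None) -> AlignmentResult:
    """Global alignment of a merged read to its unmutated amplicon."""
    scoring = scoring or AlignmentScoring()
    if len(read) > 2 * len(reference):
        raise ValueError(
            f"read of length {len(read)} exceeds twice the reference "
            f"({len(reference)} bp); rejected as artefact"
        )
    rc = _codes_with_n(read)
    fc = _codes_with_n(reference)
    score, ops, n_ops = _align_codes(rc, fc, scoring)
    return AlignmentResult(read, reference, float(score),
                           ops[:n_ops].copy())


def _codes_with_n(seq: str) -> np.ndarray:
    tbl = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        tbl[b] = i
    tbl[ord("N")] = 4
    arr = tbl[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if np.any(arr == 255):
        pos = int(np.argmax(arr == 255))
        raise ValueError(f"unknown base {seq[pos]!r} at position {pos}")
    return arr


def _events_to_calls(kinds, ref_pos, read_pos, lengths, n_events,
                     read_codes, ref_codes, read_id=None) -> list[MutationCall]:
    calls = []
    for e in range(n_events):
        kind = kinds[e]
        j = int(ref_pos[e])
        i = int(read_pos[e])
        ln = int(lengths[e])
        if kind == 0:
            ref_b = BASES[ref_codes[j]]
            alt_b = BASES[read_codes[i]]
            k = "transition" if is_transition(ref_b, alt_b) else "transversion"
            calls.append(MutationCall(j, ref_b, alt_b, k, read_id))
        elif kind == 1:
            ins = codes_to_seq(read_codes[i:i + ln])
            calls.append(MutationCall(j, "", ins, "insertion", read_id))
        else:
            dele = codes_to_seq(ref_codes[j:j + ln])
            calls.append(MutationCall(j, dele, "", "deletion", read_id))
    return calls


def call_mutations(aln: AlignmentResult,
                   read_id: Optional[str] = None) -> list[MutationCall]:
    """Mutation events from an alignment.

    A contiguous gap run is one indel event; gap runs before the first or
    after the last aligned base (terminal overhangs) and substitutions
    involving N are ignored.
    """
    rc = _codes_with_n(aln.read)
    fc = _codes_with_n(aln.reference)
    kinds, jpos, ipos, lens, nev = _extract_events(aln.ops, rc, fc)
    return _events_to_calls(kinds, jpos, ipos, lens, nev, rc, fc, read_id)


def _extract_events(ops: np.ndarray, read_codes: np.ndarray,
                    ref_codes: np.ndarray):
    n_ops = len(ops)
    kinds = np.empty(n_ops, dtype=np.int64)
    jpos = np.empty(n_ops, dtype=np.int64)
    ipos = np.empty(n_ops, dtype=np.int64)
    lens = np.empty(n_ops, dtype=np.int64)
    nev = _align_extract(ops, n_ops, read_codes, ref_codes,
                         kinds, jpos, ipos, lens)
    return kinds, jpos, ipos, lens, nev


from numba import njit  # noqa: E402  (kernel colocated with its caller)


@njit(cache=True)
def _align_extract(ops, n_ops, read, ref, out_kind, out_j, out_i, out_len):
    first_match = -1
    last_match = -1
    for t in range(n_ops):
        if ops[t] == 0:
            if first_match < 0:
                first_match = t
            last_match = t
    nev = 0
    i = 0
    j = 0
    t = 0
    while t < n_ops:
        op = ops[t]
        if op == 0:
            if read[i] != ref[j] and read[i] < 4 and ref[j] < 4:
                out_kind[nev] = 0
                out_j[nev] = j
                out_i[nev] = i
                out_len[nev] = 1
                nev += 1
            i += 1
            j += 1
            t += 1
        elif op == 1:  # insertion run
            start = t
            i0 = i
            while t < n_ops and ops[t] == 1:
                i += 1
                t += 1
            if first_match >= 0 and start > first_match and start < last_match:
                out_kind[nev] = 1
                out_j[nev] = j
                out_i[nev] = i0
                out_len[nev] = i - i0
                nev += 1
        else:  # deletion run
            start = t
            j0 = j
            while t < n_ops and ops[t] == 2:
                j += 1
                t += 1
            if first_match >= 0 and start > first_match and start < last_match:
                out_kind[nev] = 2
                out_j[nev] = j0
                out_i[nev] = i
                out_len[nev] = j - j0
                nev += 1
    return nev


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------

_EARLY_ACCEPT = 1.0  # a perfect overlap scores exactly 1


def _read_matrices(reads: Sequence[FastqRead], revcomp: bool = False):
    n = len(reads)
    maxlen = max((len(r) for r in reads), default=0)
    codes = np.full((n, maxlen), 4, dtype=np.uint8)
    quals = np.zeros((n, maxlen), dtype=np.float64)
    lengths = np.empty(n, dtype=np.int64)
    for i, r in enumerate(reads):
        c = _codes_with_n(r.seq)
        q = r.quality_array().astype(np.float64)
        if revcomp:
            c = np.where(c < 4, 3 - c, 4)[::-1]
            q = q[::-1]
        codes[i, : len(c)] = c
        quals[i, : len(c)] = q
        lengths[i] = len(c)
    return codes, quals, lengths


def _merge_matrices(r1_reads, r2_reads, min_overlap, quality_threshold):
    if len(r1_reads) != len(r2_reads):
        raise ValueError("unpaired FASTQ input: read counts differ")
    c1, q1, l1 = _read_matrices(r1_reads)
    c2, q2, l2 = _read_matrices(r2_reads, revcomp=True)
    n = len(r1_reads)
    out_w = int(l1.max() + l2.max()) if n else 0
    out_seq = np.full((n, out_w), 4, dtype=np.uint8)
    out_q = np.zeros((n, out_w), dtype=np.float64)
    out_len = np.zeros(n, dtype=np.int64)
    out_score = np.zeros(n, dtype=np.float64)
    out_k = np.zeros(n, dtype=np.int64)
    if n:
        _align.merge_batch(
            c1, q1, c2, q2, l1, l2,
            min_overlap, quality_threshold, _EARLY_ACCEPT,
            out_seq, out_q, out_len, out_score, out_k,
        )
    return out_seq, out_q, out_len, out_score, out_k


def _q_to_qual(q: np.ndarray) -> str:
    q = np.clip(np.round(q), 2, 41)
    return (q.astype(np.int64) + 33).astype(np.uint8).tobytes().decode()


def merge_pairs(
    r1_reads: Sequence[FastqRead],
    r2_reads: Sequence[FastqRead],
    min_overlap: int = 20,
    quality_threshold: float = 0.95,
) -> tuple[list[FastqRead], list[tuple[str, str]]]:
    """Merge mate pairs by their best ungapped overlap.

    The overlap is chosen by a quality-weighted agreement score (mean
    per-base posterior agreement over the overlap); pairs whose best
    normalised score falls below ``quality_threshold`` are rejected and
    logged. Overlap disagreements resolve to the higher-quality base and the
    merged quality is the better (max) of the two.
    """
    out_seq, out_q, out_len, out_score, _ = _merge_matrices(
        r1_reads, r2_reads, min_overlap, quality_threshold
    )
    merged: list[FastqRead] = []
    rejects: list[tuple[str, str]] = []
    for i, r in enumerate(r1_reads):
        ln = int(out_len[i])
        if ln == 0:
            rejects.append(
                (r.id, f"best overlap score {out_score[i]:.4f} below "
                       f"threshold")
            )
            continue
        merged.append(
            FastqRead(
                r.id,
                codes_to_seq_n(out_seq[i, :ln]),
                _q_to_qual(out_q[i, :ln]),
            )
        )
    return merged, rejects


def codes_to_seq_n(codes: np.ndarray) -> str:
    dec = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return dec[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def _barcode_matrix(table: BarcodeTable) -> tuple[np.ndarray, list[str]]:
    ids = [e.sample_id for e in table]
    mat = np.stack([seq_to_codes(e.barcode) for e in table])
    return mat, ids


def _assign_barcodes(prefix_codes: np.ndarray, bc_mat: np.ndarray,
                     max_mismatch: int) -> np.ndarray:
    """Index of the unique barcode within ``max_mismatch`` per read, -1 for
    unassigned/ambiguous."""
    dist = (prefix_codes[:, None, :] != bc_mat[None, :, :]).sum(axis=2)
    within = dist <= max_mismatch
    n_hit = within.sum(axis=1)
    best = dist.argmin(axis=1)
    out = np.where(n_hit == 1, best, -1)
    return out.astype(np.int64)


def demultiplex(
    reads: Iterable[FastqRead],
    table: BarcodeTable,
    max_mismatch: int = 1,
) -> tuple[dict[str, list[FastqRead]], list[FastqRead]]:
    """Assign reads to the unique barcode within ``max_mismatch`` and trim
    it; ambiguous or unmatched reads land in the unassigned bin."""
    bc_mat, ids = _barcode_matrix(table)
    bl = table.barcode_length
    assigned: dict[str, list[FastqRead]] = {s: [] for s in ids}
    unassigned: list[FastqRead] = []
    reads = list(reads)
    if not reads:
        return assigned, unassigned
    ok = [r for r in reads if len(r) > bl]
    unassigned.extend(r for r in reads if len(r) <= bl)
    if not ok:
        return assigned, unassigned
    prefix = np.stack([_codes_with_n(r.seq[:bl]) for r in ok])
    hits = _assign_barcodes(prefix, bc_mat, max_mismatch)
    for r, h in zip(ok, hits):
        if h < 0:
            unassigned.append(r)
        else:
            assigned[ids[h]].append(
                FastqRead(r.id, r.seq[bl:], r.qual[bl:])
            )
    return assigned, unassigned


# ---------------------------------------------------------------------------
# Spectrum summaries
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SpectrumSummary:
    """Aggregated mutation-spectrum metrics for one sample (or an average of
    samples, or a background-corrected average).

    ``class_rates`` holds events per sequenced reference base for each of
    the 12 substitution types plus ``ins``/``del``; ``class_var`` the
    variance of each rate estimate (Poisson for raw tallies, propagated
    through averaging and subtraction otherwise).
    """

    n_reads: int
    n_ref_bases: float
    class_rates: dict
    class_var: dict
    corrected: bool = False
    floored: tuple = ()

    def rate(self, classes: Sequence[str]) -> float:
        return float(sum(self.class_rates[c] for c in classes))

    def var(self, classes: Sequence[str]) -> float:
        return float(sum(self.class_var[c] for c in classes))

    @property
    def total_rate(self) -> float:
        return self.rate(ALL_CLASSES)

    @property
    def mut_per_kb(self) -> float:
        return 1000.0 * self.total_rate

    @property
    def ts_tv(self) -> float:
        tv_classes = [c for c in SUB_TYPES if c not in TRANSITION_CLASSES]
        tv = self.rate(tv_classes)
        ts = self.rate(TRANSITION_CLASSES)
        return ts / tv if tv > 0 else math.inf

    @property
    def at_gc_over_gc_at(self) -> float:
        den = self.rate(GC_AT_CLASSES)
        num = self.rate(AT_GC_CLASSES)
        return num / den if den > 0 else math.inf

    def _pct(self, classes: Sequence[str]) -> float:
        t = self.total_rate
        return 100.0 * self.rate(classes) / t if t > 0 else 0.0

    @property
    def at_to_n_pct(self) -> float:
        return self._pct(AT_REF_CLASSES)

    @property
    def gc_to_n_pct(self) -> float:
        return self._pct(GC_REF_CLASSES)

    @property
    def ins_pct(self) -> float:
        return self._pct(["ins"])

    @property
    def del_pct(self) -> float:
        return self._pct(["del"])

    def class_ci(self, cls: str, alpha: float = 0.05) -> tuple[float, float]:
        """95% CI on the per-base rate of one event class: exact binomial
        for raw integer tallies, normal approximation for corrected rates."""
        r = self.class_rates[cls]
        if not self.corrected:
            k = int(round(r * self.n_ref_bases))
            lo, hi = clopper_pearson(k, int(self.n_ref_bases), alpha)
            return lo, hi
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * math.sqrt(self.class_var[cls])
        return max(0.0, r - half), r + half

    def metric_ci(self, metric: str, alpha: float = 0.05) -> tuple[float, float]:
        """Propagated 95% CI for a derived metric.

        Ratio metrics use the log-normal delta method on the two class-rate
        sums; percentage metrics the delta method on the share a/(a+b);
        mut_per_kb a plain normal interval on the total rate.
        """
        z = stats.norm.ppf(1 - alpha / 2)
        if metric == "mut_per_kb":
            t = self.total_rate
            half = z * math.sqrt(self.var(ALL_CLASSES))
            return max(0.0, (t - half)) * 1000.0, (t + half) * 1000.0
        ratio_sets = {
            "ts_tv": (
                TRANSITION_CLASSES,
                [c for c in SUB_TYPES if c not in TRANSITION_CLASSES],
            ),
            "at_gc_over_gc_at": (AT_GC_CLASSES, GC_AT_CLASSES),
        }
        if metric in ratio_sets:
            num_c, den_c = ratio_sets[metric]
            num, den = self.rate(num_c), self.rate(den_c)
            if num <= 0 or den <= 0:
                return 0.0, math.inf
            sd_log = math.sqrt(
                self.var(num_c) / num**2 + self.var(den_c) / den**2
            )
            r = num / den
            return r * math.exp(-z * sd_log), r * math.exp(z * sd_log)
        pct_sets = {
            "at_to_n_pct": AT_REF_CLASSES,
            "gc_to_n_pct": GC_REF_CLASSES,
            "ins_pct": ("ins",),
            "del_pct": ("del",),
        }
        if metric in pct_sets:
            classes = pct_sets[metric]
            a = self.rate(classes)
            rest = [c for c in ALL_CLASSES if c not in classes]
            b = self.rate(rest)
            t = a + b
            if t <= 0:
                return 0.0, 100.0
            var_f = (
                b**2 * self.var(classes) + a**2 * self.var(rest)
            ) / t**4
            f = a / t
            half = z * math.sqrt(var_f)
            return max(0.0, f - half) * 100.0, min(1.0, f + half) * 100.0
        raise ValueError(f"unknown metric {metric!r}")

    def as_dict(self) -> dict:
        return {
            "mut_per_kb": self.mut_per_kb,
            "ts_tv": self.ts_tv,
            "at_gc_over_gc_at": self.at_gc_over_gc_at,
            "at_to_n_pct": self.at_to_n_pct,
            "gc_to_n_pct": self.gc_to_n_pct,
            "ins_pct": self.ins_pct,
            "del_pct": self.del_pct,
            "n_reads": self.n_reads,
            "n_ref_bases": self.n_ref_bases,
        }


@dataclasses.dataclass
class PositionRateProfile:
    """Per-position mutation rate and coverage along the reference."""

    counts: np.ndarray
    coverage: np.ndarray

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.coverage > 0,
                            self.counts / self.coverage, 0.0)


def summarize_sample(
    calls: Sequence[MutationCall],
    n_reads: int,
    reference: str,
) -> tuple[SpectrumSummary, PositionRateProfile]:
    """Tally calls from one sample into spectrum metrics.

    Rates are events per sequenced reference base (``n_reads * len(ref)``
    bases); class percentages are shares of all mutation events and sum to
    100 by construction.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    L = len(reference)
    counts = {c: 0 for c in ALL_CLASSES}
    pos_counts = np.zeros(L, dtype=np.int64)
    for c in calls:
        counts[c.event_class] += 1
        if c.position < L:
            pos_counts[c.position] += 1
    n_bases = float(n_reads) * L
    rates = {k: v / n_bases for k, v in counts.items()}
    var = {k: v / n_bases**2 for k, v in counts.items()}
    summary = SpectrumSummary(
        n_reads=n_reads,
        n_ref_bases=n_bases,
        class_rates=rates,
        class_var=var,
    )
    profile = PositionRateProfile(
        counts=pos_counts,
        coverage=np.full(L, n_reads, dtype=np.int64),
    )
    return summary, profile


def per_read_histogram(
    calls: Sequence[MutationCall],
    n_reads: int,
    include_indels: bool = True,
) -> np.ndarray:
    """Frequency of observing k mutations per read, k = 0..max."""
    per_read: dict[str, int] = {}
    for c in calls:
        if not include_indels and c.kind in ("insertion", "deletion"):
            continue
        per_read[c.read_id] = per_read.get(c.read_id, 0) + 1
    kmax = max(per_read.values(), default=0)
    hist = np.zeros(kmax + 1, dtype=np.int64)
    for v in per_read.values():
        hist[v] += 1
    hist[0] = n_reads - len(per_read)
    return hist


def average_summaries(summaries: Sequence[SpectrumSummary]) -> SpectrumSummary:
    """Unweighted mean of per-sample class rates (each culture's library is
    one observation, regardless of its read depth)."""
    if not summaries:
        raise ValueError("no summaries to average")
    s = len(summaries)
    rates = {
        c: float(np.mean([x.class_rates[c] for x in summaries]))
        for c in ALL_CLASSES
    }
    var = {
        c: float(sum(x.class_var[c] for x in summaries)) / s**2
        for c in ALL_CLASSES
    }
    return SpectrumSummary(
        n_reads=int(sum(x.n_reads for x in summaries)),
        n_ref_bases=float(sum(x.n_ref_bases for x in summaries)),
        class_rates=rates,
        class_var=var,
    )


def background_subtract(sample: SpectrumSummary,
                        control: SpectrumSummary) -> SpectrumSummary:
    """Subtract the control amplicon's per-class rates from the sample's.

    Corrected rates are floored at 0 (flagged in ``floored``); every derived
    ratio and percentage recomputes from the corrected class rates. Variances
    add, so corrected intervals reflect both channels' counting noise.
    """
    rates = {}
    floored = []
    for c in ALL_CLASSES:
        d = sample.class_rates[c] - control.class_rates[c]
        if d < 0:
            floored.append(c)
            d = 0.0
        rates[c] = d
    var = {
        c: sample.class_var[c] + control.class_var[c] for c in ALL_CLASSES
    }
    if control.total_rate >= sample.total_rate:
        log.warning(
            "control mutation rate (%.3g/kb) >= sample rate (%.3g/kb); "
            "corrected rates floored at zero",
            1000 * control.total_rate, 1000 * sample.total_rate,
        )
    return SpectrumSummary(
        n_reads=sample.n_reads,
        n_ref_bases=sample.n_ref_bases,
        class_rates=rates,
        class_var=var,
        corrected=True,
        floored=tuple(floored),
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def write_calls_tsv(calls: Sequence[MutationCall], path) -> None:
    """Per-sample mutation calls, 1-based positions in the output."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "position_1based": c.position + 1,
                "ref": c.ref_allele,
                "alt": c.alt_allele,
                "kind": c.kind,
                "read_id": c.read_id or "",
            }
            for c in calls
        ],
        columns=["position_1based", "ref", "alt", "kind", "read_id"],
    ).to_csv(path, sep="\t", index=False)


def write_summary_tsv(summaries: dict, path) -> None:
    """One row per summary (sample, average or corrected), with the
    standard bias-metric columns."""
    import pandas as pd

    rows = []
    for name, s in summaries.items():
        row = {"sample": name}
        row.update(s.as_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_profile_tsv(profile: PositionRateProfile, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "position_1based": np.arange(1, len(profile.counts) + 1),
            "mutations": profile.counts,
            "coverage": profile.coverage,
            "rate": profile.rates,
        }
    ).to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class SampleResult:
    sample_id: str
    role: str
    n_reads: int
    calls: list
    summary: SpectrumSummary
    profile: PositionRateProfile


@dataclasses.dataclass
class PipelineResult:
    samples: dict
    cargo_summary: SpectrumSummary
    control_summary: SpectrumSummary
    corrected: SpectrumSummary
    n_pairs: int
    n_merge_rejected: int
    n_unassigned: int
    n_artefacts: int


def _chunked_pairs(r1_iter, r2_iter, n: int):
    while True:
        c1 = list(itertools.islice(r1_iter, n))
        c2 = list(itertools.islice(r2_iter, n))
        if not c1 and not c2:
            return
        if len(c1) != len(c2):
            raise ValueError("unpaired FASTQ input: files differ in length")
        yield c1, c2


def run_pipeline(
    r1_path,
    r2_path,
    refs,
    barcodes: BarcodeTable,
    *,
    min_overlap: int = 20,
    quality_threshold: float = 0.95,
    max_mismatch: int = 1,
    scoring: Optional[AlignmentScoring] = None,
    chunk_pairs: int = 50_000,
    keep_read_ids: bool = False,
) -> PipelineResult:
    """Full merge -> demux -> align -> call -> subtract pipeline.

    Cargo samples are summarised individually, averaged (unweighted), and
    background-corrected with the averaged control samples.
    """
    scoring = scoring or AlignmentScoring()
    bc_mat, ids = _barcode_matrix(barcodes)
    entry_by_idx = list(barcodes)
    bl = barcodes.barcode_length
    ref_codes = {
        name: seq_to_codes(seq.upper()) for name, seq in refs.items()
    }

    n_pairs = 0
    n_rejected = 0
    n_unassigned = 0
    n_artefacts = 0
    sample_calls: dict[str, list] = {e.sample_id: [] for e in barcodes}
    sample_reads: dict[str, int] = {e.sample_id: 0 for e in barcodes}

    r1_iter = read_fastq(r1_path)
    r2_iter = read_fastq(r2_path)
    for c1, c2 in _chunked_pairs(r1_iter, r2_iter, chunk_pairs):
        n_pairs += len(c1)
        out_seq, _out_p, out_len, _sc, _k = _merge_matrices(
            c1, c2, min_overlap, quality_threshold
        )
        valid = np.flatnonzero(out_len > bl)
        n_rejected += len(c1) - int((out_len > 0).sum())
        n_unassigned += int(((out_len > 0) & (out_len <= bl)).sum())
        if len(valid) == 0:
            continue
        hits = _assign_barcodes(
            out_seq[valid, :bl], bc_mat, max_mismatch
        )
        for row, h in zip(valid, hits):
            if h < 0:
                n_unassigned += 1
                continue
            entry = entry_by_idx[h]
            rc = out_seq[row, bl:out_len[row]]
            fc = ref_codes[entry.reference]
            sample_reads[entry.sample_id] += 1
            if rc.shape[0] == fc.shape[0] and np.array_equal(rc, fc):
                continue  # perfect read, no events
            if rc.shape[0] > 2 * fc.shape[0]:
                n_artefacts += 1
                sample_reads[entry.sample_id] -= 1
                continue
            _score, ops, n_ops = _align_codes(rc, fc, scoring)
            kinds, jpos, ipos, lens, nev = (
                np.empty(n_ops, dtype=np.int64),
                np.empty(n_ops, dtype=np.int64),
                np.empty(n_ops, dtype=np.int64),
                np.empty(n_ops, dtype=np.int64),
                0,
            )
            nev = _align_extract(ops, n_ops, rc, fc, kinds, jpos, ipos, lens)
            rid = c1[row].id if keep_read_ids else None
            sample_calls[entry.sample_id].extend(
                _events_to_calls(kinds, jpos, ipos, lens, nev, rc, fc, rid)
            )

    samples: dict[str, SampleResult] = {}
    for entry in barcodes:
        sid = entry.sample_id
        n_reads = sample_reads[sid]
        if n_reads == 0:
            continue
        summ, prof = summarize_sample(
            sample_calls[sid], n_reads, refs[entry.reference]
        )
        samples[sid] = SampleResult(
            sample_id=sid,
            role=entry.role,
            n_reads=n_reads,
            calls=sample_calls[sid],
            summary=summ,
            profile=prof,
        )

    cargo = [s.summary for s in samples.values() if s.role == "cargo"]
    control = [s.summary for s in samples.values() if s.role == "control"]
    if not cargo or not control:
        raise ValueError(
            "pipeline needs at least one cargo and one control sample "
            "with assigned reads"
        )
    cargo_avg = average_summaries(cargo)
    control_avg = average_summaries(control)
    corrected = background_subtract(cargo_avg, control_avg)
    return PipelineResult(
        samples=samples,
        cargo_summary=cargo_avg,
        control_summary=control_avg,
        corrected=corrected,
        n_pairs=n_pairs,
        n_merge_rejected=n_rejected,
        n_unassigned=n_unassigned,
        n_artefacts=n_artefacts,
    )
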