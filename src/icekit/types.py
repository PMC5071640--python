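"""Shared domain types for the ICE analysis toolkit.

The types here are deliberately thin: they carry validated data between the
simulator and the analysis stages and know how to check their own invariants,
but all computation lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: transition partner of each base (purine<->purine, pyrimidine<->pyrimidine)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: the 12 possible single-base substitutions, in a fixed canonical order
SUB_TYPES = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a
)
#: event-class labels used throughout the spectrum machinery
EVENT_CLASSES = SUB_TYPES + ("ins", "del")


def is_transition(ref: str, alt: str) -> bool:
    return TRANSITION.get(ref) == alt


@dataclass(frozen=True)
class SpectrumProfile:
    """Per-base mutation rate plus a normalized mutational spectrum.

    Parameters
    ----------
    sub_rate_per_base:
        Substitutions per base per replication (reverse-transcription) event.
    sub_matrix:
        4x4 conditional probabilities ``P(alt | ref)`` with rows/columns in
        A, C, G, T order; the diagonal is zero and each row sums to 1.
    ins_frac, del_frac:
        Fractions of *all* mutation events that are insertions / deletions.
    ref_weights:
        Relative substitution propensity of each reference base (A, C, G, T).
        This carries the marginal base-usage bias of the polymerase (e.g. a
        G:C-biased reverse transcriptase); uniform by default.
    """

    sub_rate_per_base: float
    sub_matrix: np.ndarray
    ins_frac: float = 0.0
    del_frac: float = 0.0
    ref_weights: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        m = np.asarray(self.sub_matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("sub_matrix must be 4x4 (A,C,G,T order)")
        if np.any(np.diag(m) != 0):
            raise ValueError("sub_matrix diagonal must be zero")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("sub_matrix entries must lie in [0,1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each sub_matrix row must sum to 1")
        if not (0 <= self.ins_frac <= 1 and 0 <= self.del_frac <= 1):
            raise ValueError("ins_frac/del_frac must lie in [0,1]")
        if self.ins_frac + self.del_frac > 1 + 1e-12:
            raise ValueError("ins_frac + del_frac must not exceed 1")
        if self.sub_rate_per_base < 0:
            raise ValueError("sub_rate_per_base must be non-negative")
        w = np.asarray(self.ref_weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("ref_weights must be 4 non-negative values")
        object.__setattr__(self, "sub_matrix", m)
        object.__setattr__(self, "ref_weights", w / w.sum())

    @property
    def sub_frac(self) -> float:
        """Fraction of all mutation events that are substitutions."""
        return 1.0 - self.ins_frac - self.del_frac

    @property
    def total_rate_per_base(self) -> float:
        """Mutation events (of any class) per base per replication."""
        if self.sub_frac == 0:
            raise ValueError("profile has no substitution channel")
        return self.sub_rate_per_base / self.sub_frac

    @property
    def mut_per_kb(self) -> float:
        return 1000.0 * self.total_rate_per_base

    @classmethod
    def ty1_rnapii(cls) -> "SpectrumProfile":
        """Spectrum of the Ty1 reverse-transcription / RNAPII cycle.

        Encodes the measured bias of the retroelement's replication channel:
        0.15 mutations per kb overall; transitions slightly favoured over
        transversions (Ts/Tv 1.06); a strong excess of events at G:C pairs
        (69.4% vs 28.8% at A:T) with AT->GC/GC->AT = 0.28; indels rare
        (0.08% insertions, 1.6% deletions). Transversions are split evenly
        between the two possible alternatives and the two strands are
        treated symmetrically.
        """
        total = 28.8 + 69.4 + 0.08 + 1.6  # = 99.88 (class table rounding)
        ins_frac = 0.08 / total
        del_frac = 1.6 / total
        sub_frac = (28.8 + 69.4) / total
        # Among substitutions: share at A:T vs G:C reference pairs.
        w_at = 28.8 / (28.8 + 69.4)
        w_gc = 69.4 / (28.8 + 69.4)
        ts_total = 1.06 / (1 + 1.06)          # transitions among subs
        at_gc = 0.28 / (1 + 0.28) * ts_total  # A->G + T->C share
        gc_at = ts_total - at_gc              # G->A + C->T share
        ts_at = at_gc / w_at   # P(transition | sub at A or T)
        ts_gc = gc_at / w_gc   # P(transition | sub at G or C)
        tv_at = (1 - ts_at) / 2
        tv_gc = (1 - ts_gc) / 2
        #        A      C      G      T
        m = np.array(
            [
                [0.0, tv_at, ts_at, tv_at],  # A
                [tv_gc, 0.0, tv_gc, ts_gc],  # C
                [ts_gc, tv_gc, 0.0, tv_gc],  # G
                [tv_at, ts_at, tv_at, 0.0],  # T
            ]
        )
        total_rate = 0.15e-3  # events per base (0.15 per kb)
        return cls(
            sub_rate_per_base=total_rate * sub_frac,
            sub_matrix=m,
            ins_frac=ins_frac,
            del_frac=del_frac,
            ref_weights=np.array([w_at / 2, w_gc / 2, w_gc / 2, w_at / 2]),
        )

    @classmethod
    def uniform(cls, mut_per_kb: float = 0.15,
                ins_frac: float = 0.0, del_frac: float = 0.0
                ) -> "SpectrumProfile":
        """Unbiased spectrum: all 12 substitutions equiprobable."""
        m = np.full((4, 4), 1 / 3.0)
        np.fill_diagonal(m, 0.0)
        sub_frac = 1.0 - ins_frac - del_frac
        return cls(
            sub_rate_per_base=mut_per_kb * 1e-3 * sub_frac,
            sub_matrix=m,
            ins_frac=ins_frac,
            del_frac=del_frac,
        )

    def class_probabilities(self, gc_fraction: float = 0.5) -> dict:
        """Expected share of each event class (12 subs + ins + del).

        ``gc_fraction`` is the G+C fraction of the mutagenized reference;
        substitutions are apportioned by ``ref_weights`` conditioned on the
        base composition.
        """
        comp = np.array(
            [(1 - gc_fraction) / 2, gc_fraction / 2,
             gc_fraction / 2, (1 - gc_fraction) / 2]
        )
        w = comp * self.ref_weights
        w = w / w.sum()
        probs = {}
        for ri, r in enumerate(BASES):
            for ai, a in enumerate(BASES):
                if r == a:
                    continue
                probs[f"{r}>{a}"] = (
                    self.sub_frac * w[ri] * self.sub_matrix[ri, ai]
                )
        probs["ins"] = self.ins_frac
        probs["del"] = self.del_frac
        return probs


@dataclass
class CultureParams:
    """Parameters of one induction culture.

    ``transposition_rate`` is the probability that a newborn cell completes a
    full retrotransposition cycle, per division (``low_density`` mode) or per
    cell per day of galactose exposure (``high_density`` mode).
    """

    n_initial: int
    n_final: int
    transposition_rate: float
    induction_days: float = 3.0
    plating_fraction: float = 1.0
    mode: str = "low_density"

    def __post_init__(self):
        if self.mode not in ("low_density", "high_density"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_initial < 1 or self.n_final < self.n_initial:
            raise ValueError("need 1 <= n_initial <= n_final")
        if not 0 <= self.transposition_rate <= 1:
            raise ValueError("transposition_rate must lie in [0,1]")
        if not 0 < self.plating_fraction <= 1:
            raise ValueError("plating_fraction must lie in (0,1]")
        if self.induction_days <= 0:
            raise ValueError("induction_days must be positive")


@dataclass
class CargoSpec:
    """A cargo sequence carried (and mutagenized) by the retroelement."""

    sequence: str
    stop_site: Optional[int] = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set(BASES):
            raise ValueError("cargo sequence must be over ACGT")
        if self.stop_site is not None:
            codon = self.sequence[self.stop_site:self.stop_site + 3]
            if codon not in ("TAA", "TAG", "TGA"):
                raise ValueError(
                    f"stop_site {self.stop_site} indexes {codon!r}, "
                    "not a stop codon"
                )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class MutationCall:
    """One called mutation event in reference coordinates (0-based)."""

    position: int
    ref_allele: str
    alt_allele: str
    kind: str  # transition | transversion | insertion | deletion
    read_id: Optional[str] = None

    def __post_init__(self):
        if self.kind in ("transition", "transversion"):
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution alleles must be single bases")
            ts = is_transition(self.ref_allele, self.alt_allele)
            if ts != (self.kind == "transition"):
                raise ValueError(
                    f"{self.ref_allele}>{self.alt_allele} is not a "
                    f"{self.kind}"
                )
        elif self.kind == "insertion":
            if self.alt_allele == "":
                raise ValueError("insertion needs inserted bases")
        elif self.kind == "deletion":
            if self.alt_allele != "" or self.ref_allele == "":
                raise ValueError("deletion must have empty alt allele")
        else:
            raise ValueError(f"unknown mutation kind {self.kind!r}")

    @property
    def event_class(self) -> str:
        if self.kind == "insertion":
            return "ins"
        if self.kind == "deletion":
            return "del"
        return f"{self.ref_allele}>{self.alt_allele}"

    def key(self) -> tuple:
        """Identity of the event irrespective of which read carried it."""
        return (self.position, self.ref_allele, self.alt_allele, self.kind)


@dataclass
class GenotypeRecord:
    """A library member: its mutations and condition-dependent fitness.

    ``fitness`` maps a named/numeric condition (e.g. a 5-FOA concentration in
    g/l) to a multiplicative growth-rate factor; conditions not listed default
    to ``base_fitness``.
    """

    mutations: Sequence[MutationCall] = ()
    fitness: Mapping[float, float] = field(default_factory=dict)
    base_fitness: float = 1.0
    name: str = ""

    def fitness_at(self, condition) -> float:
        f = self.fitness.get(condition, self.base_fitness)
        if f < 0:
            raise ValueError("fitness multiplier must be >= 0")
        return f


@dataclass
class ColonyCountTable:
    """Replicate plating counts from an induction experiment."""

    replicate_id: Sequence[str]
    selective_count: np.ndarray
    total_cells: np.ndarray
    plating_fraction: np.ndarray
    mode: str

    def __post_init__(self):
        self.selective_count = np.asarray(self.selective_count)
        self.total_cells = np.asarray(self.total_cells, dtype=float)
        pf = np.asarray(self.plating_fraction, dtype=float)
        if pf.ndim == 0:
            pf = np.full(len(self.selective_count), float(pf))
        self.plating_fraction = pf
        if self.mode not in ("low_density", "high_density"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if np.any(self.selective_count < 0):
            raise ValueError("selective counts must be non-negative")
        if not np.all(self.selective_count == np.floor(self.selective_count)):
            raise ValueError("selective counts must be integers")
        self.selective_count = self.selective_count.astype(np.int64)
        if np.any((pf <= 0) | (pf > 1)):
            raise ValueError("plating fractions must lie in (0,1]")
        n = len(self.selective_count)
        if not (len(self.replicate_id) == len(self.total_cells) == len(pf) == n):
            raise ValueError("column lengths differ")

    def __len__(self) -> int:
        return len(self.selective_count)


@dataclass
class RateEstimate:
    """A per-cell rate with its 95% confidence interval.

    ``m`` is the expected number of mutational events per culture (only for
    the fluctuation-assay route); ``rate`` is per cell, divided by the number
    of generations or days recorded in ``divisor_mode``/``divisor``.
    """

    rate: float
    ci_low: float
    ci_high: float
    method: str  # mss_mle | direct
    m: Optional[float] = None
    m_ci_low: Optional[float] = None
    m_ci_high: Optional[float] = None
    divisor_mode: str = "none"  # generations | days | none
    divisor: float = 1.0

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValueError("need ci_low <= rate <= ci_high")


@dataclass
class BarcodeEntry:
    sample_id: str
    barcode: str
    role: str  # cargo | control
    reference: str  # name of the amplicon reference this sample carries


class BarcodeTable:
    """Sample -> barcode map with the pairwise Hamming >= 2 guarantee."""

    def __init__(self, entries: Sequence[BarcodeEntry]):
        if not entries:
            raise ValueError("empty barcode table")
        lens = {len(e.barcode) for e in entries}
        if len(lens) != 1:
            raise ValueError("barcodes must all have equal length")
        ids = [e.sample_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        for e in entries:
            if e.role not in ("cargo", "control"):
                raise ValueError(f"unknown role {e.role!r}")
            if set(e.barcode) - set(BASES):
                raise ValueError("barcodes must be over ACGT")
        for i, a in enumerate(entries):
            for b in entries[i + 1:]:
                d = sum(x != y for x, y in zip(a.barcode, b.barcode))
                if d < 2:
                    raise ValueError(
                        f"barcodes {a.sample_id}/{b.sample_id} are at "
                        f"Hamming distance {d} < 2"
                    )
        self.entries = list(entries)

    @property
    def barcode_length(self) -> int:
        return len(self.entries[0].barcode)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def by_sample(self) -> Mapping[str, BarcodeEntry]:
        return {e.sample_id: e for e in self.entries}


@dataclass
class ODSeries:
    """An OD600 time series from a plate reader or flask sampling."""

    time_h: np.ndarray
    od: np.ndarray
    blank: float = 0.0

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_h.shape != self.od.shape or self.time_h.ndim != 1:
            raise ValueError("time_h and od must be matching 1-D arrays")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")

    def corrected_od(self, floor: float = 1e-4) -> np.ndarray:
        """Blank-subtracted OD floored at a small positive value."""
        return np.maximum(self.od - self.blank, floor)


@dataclass
class GrowthStats:
    """Summary statistics of one growth curve."""

    mu_max: float  # 1/h
    lag_h: float   # NaN when undefined (flat curve)
    od_max: float
    fit_window: tuple = (0, 0)

    def __post_init__(self):
        if self.mu_max < 0:
            raise ValueError("mu_max must be non-negative")


@dataclass
class DiversityParams:
    transposition_rate: float
    cell_density: float  # cells per litre
    cargo_length_bp: int
    spectrum: SpectrumProfile = field(
        default_factory=SpectrumProfile.ty1_rnapii
    )
    n_events: Optional[float] = None

    def __post_init__(self):
        if not 0 <= self.transposition_rate <= 1:
            raise ValueError("transposition_rate must lie in [0,1]")
        if self.n_events is None and self.cell_density <= 0:
            raise ValueError("cell_density must be positive")
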