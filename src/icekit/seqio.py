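"""Format readers/writers, configuration and seed plumbing.

FASTQ handling is a deliberately small 4-line-record parser: the pipelines
stream millions of synthetic reads and need the error contract (line numbers
on malformed records) that the analysis stages rely on. FASTA goes through
Biopython.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import io
import logging
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import BarcodeEntry, BarcodeTable, ColonyCountTable, ODSeries

log = logging.getLogger("icekit")

PHRED_OFFSET = 33  # Phred+33 is the only supported quality encoding


@dataclasses.dataclass
class FastqRead:
    id: str
    seq: str
    qual: str

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id}: sequence and quality lengths differ"
            )

    def __len__(self):
        return len(self.seq)

    def quality_array(self) -> np.ndarray:
        return np.frombuffer(
            self.qual.encode(), dtype=np.uint8
        ).astype(np.int32) - PHRED_OFFSET


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[FastqRead]:
    """Stream 4-line FASTQ records; malformed records name their line."""
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            lineno += 4
            if any(not l for l in lines):
                raise ValueError(
                    f"{path}: truncated FASTQ record starting at line "
                    f"{lineno - 3}"
                )
            header, seq, plus, qual = (l.rstrip("\n") for l in lines)
            if not header.startswith("@"):
                raise ValueError(
                    f"{path}: line {lineno - 3}: expected '@' header, "
                    f"got {header[:20]!r}"
                )
            if not plus.startswith("+"):
                raise ValueError(
                    f"{path}: line {lineno - 1}: expected '+' separator"
                )
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: line {lineno}: quality length != sequence "
                    "length"
                )
            yield FastqRead(header[1:].split()[0], seq, qual)


def write_fastq(reads: Iterable[FastqRead], path) -> int:
    """Write reads to (optionally gzipped) FASTQ; returns record count."""
    n = 0
    chunk: list[str] = []
    with _open_text(path, "wt") as fh:
        for r in reads:
            chunk.append(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
            if len(chunk) >= 20000:
                fh.write("".join(chunk))
                chunk.clear()
        fh.write("".join(chunk))
    return n


def read_fasta(path) -> dict[str, str]:
    """Named sequences, uppercased; duplicate names rejected."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"{path}: duplicate record name {rec.id!r}")
            out[rec.id] = str(rec.seq).upper().replace(" ", "")
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="")
        for name, s in seqs.items()
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Tabular IO. TSV is the canonical dialect; CSV accepted on input.
# ---------------------------------------------------------------------------

def _read_frame(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if ".csv" in path.suffixes or path.suffix == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_colony_table(path) -> ColonyCountTable:
    df = _read_frame(path)
    _require_columns(
        df,
        ["replicate_id", "selective_count", "total_cells",
         "plating_fraction", "mode"],
        path,
    )
    for i, row in df.iterrows():
        if row["selective_count"] < 0:
            raise ValueError(
                f"{path}: row {i + 1}: negative selective_count"
            )
    modes = set(df["mode"])
    if len(modes) != 1:
        raise ValueError(f"{path}: all replicates must share a mode")
    return ColonyCountTable(
        replicate_id=[str(x) for x in df["replicate_id"]],
        selective_count=df["selective_count"].to_numpy(),
        total_cells=df["total_cells"].to_numpy(),
        plating_fraction=df["plating_fraction"].to_numpy(),
        mode=modes.pop(),
    )


def write_colony_table(table: ColonyCountTable, path) -> None:
    pd.DataFrame(
        {
            "replicate_id": table.replicate_id,
            "selective_count": table.selective_count,
            "total_cells": table.total_cells,
            "plating_fraction": table.plating_fraction,
            "mode": table.mode,
        }
    ).to_csv(path, sep="\t", index=False)


def read_barcode_table(path) -> BarcodeTable:
    df = _read_frame(path)
    _require_columns(df, ["sample_id", "barcode", "role", "reference"], path)
    entries = [
        BarcodeEntry(
            sample_id=str(r["sample_id"]),
            barcode=str(r["barcode"]).upper(),
            role=str(r["role"]),
            reference=str(r["reference"]),
        )
        for _, r in df.iterrows()
    ]
    return BarcodeTable(entries)


def write_barcode_table(table: BarcodeTable, path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "barcode": e.barcode,
                "role": e.role,
                "reference": e.reference,
            }
            for e in table
        ]
    ).to_csv(path, sep="\t", index=False)


def read_od_series(path) -> dict[str, ODSeries]:
    """Plate-reader data in long format: well, time_h, od."""
    df = _read_frame(path)
    _require_columns(df, ["well", "time_h", "od"], path)
    out = {}
    for well, grp in df.groupby("well"):
        grp = grp.sort_values("time_h")
        out[str(well)] = ODSeries(
            time_h=grp["time_h"].to_numpy(), od=grp["od"].to_numpy()
        )
    return out


def write_od_series(series: Mapping[str, ODSeries], path) -> None:
    frames = [
        pd.DataFrame({"well": name, "time_h": s.time_h, "od": s.od})
        for name, s in series.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration and seeds
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """A run's master seed plus per-stage parameter blocks."""

    seed: int = 0
    stages: dict = dataclasses.field(default_factory=dict)
    version: str = "icekit-0.1.0"

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            stages=raw.get("stages", {}),
            version=raw.get("version", "icekit-0.1.0"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"seed": self.seed, "stages": self.stages,
                 "version": self.version},
                fh,
                sort_keys=True,
            )

    def config_hash(self) -> str:
        buf = io.StringIO()
        yaml.safe_dump(
            {"seed": self.seed, "stages": self.stages}, buf, sort_keys=True
        )
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return derive_seed(self.seed, stage)


def derive_seed(master: int, label: str) -> int:
    """A stable 31-bit child seed for a named stream."""
    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def rng_for(master: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, label))
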