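"""Mock-community read simulation with truth labels, and read trimming.

The error model is substitutions only (no indels): each base is
independently replaced by a uniformly chosen different base with
probability ``sub_rate``. Truth labels ride inside the read id
(``<record_id>|<start>|<strand>|<serial>``) and in a sidecar truth table so
any downstream SAM retains provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import ReferenceCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "SimulatedRead",
    "CommunityDesign",
    "simulate_reads",
    "trim_reads",
    "TrimSummary",
    "write_reads_fasta",
    "write_reads_fastq",
    "read_reads",
    "write_truth_table",
    "truth_table",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0 C=1 G=2 T=3 N=4)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = set(seq) - set("ACGTNacgtn")
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return arr


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class SimulatedRead:
    """A simulated read with embedded ground truth."""

    read_id: str
    sequence: str
    truth_species: str
    truth_record: str
    truth_start: int
    truth_strand: str  # "+" or "-"


@dataclass
class CommunityDesign:
    """Per-source read counts for a mock community.

    Rows are (record_id, read_count); the total is their sum.
    """

    rows: list[tuple[str, int]]

    def __post_init__(self) -> None:
        for rec_id, count in self.rows:
            if count < 0:
                raise ValueError(f"negative read count for {rec_id!r}")

    @property
    def total(self) -> int:
        return sum(count for _, count in self.rows)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CommunityDesign":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
        cols = list(df.columns)
        return cls([(str(r[cols[0]]), int(r[cols[1]])) for _, r in df.iterrows()])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.rows, columns=["record_id", "read_count"]).to_csv(
            path, sep="\t", index=False
        )


def simulate_reads(
    genomes: ReferenceCatalog,
    design: CommunityDesign,
    read_length: int,
    sub_rate: float = 0.01,
    seed: int | None = None,
) -> list[SimulatedRead]:
    """Draw reads uniformly from each design source with substitution errors.

    Start positions are uniform over the valid starts of the source record,
    strands uniform, and every base is independently substituted with
    probability ``sub_rate``. Reads never wrap around record ends. Output
    order follows the design; identical seed and inputs give identical
    output.
    """
    if seed is None:
        raise ValueError("seed is mandatory for simulation")
    if not 0 <= sub_rate < 1:
        raise ValueError("sub_rate must be in [0, 1)")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")

    by_id = {rec.record_id: rec for rec in genomes}
    missing = [rid for rid, c in design.rows if c > 0 and rid not in by_id]
    if missing:
        raise KeyError(f"design references records absent from the catalog: {missing}")
    for rid, count in design.rows:
        if count > 0 and by_id[rid].length < read_length:
            raise ValueError(
                f"record {rid!r} ({by_id[rid].length} bp) shorter than read length {read_length}"
            )

    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    serial = 0
    for rec_id, count in design.rows:
        if count == 0:
            continue
        rec = by_id[rec_id]
        genome = encode_sequence(rec.sequence)
        n_starts = rec.length - read_length + 1
        starts = rng.integers(0, n_starts, size=count)
        strands = rng.integers(0, 2, size=count)  # 0 = +, 1 = -

        windows = genome[starts[:, None] + np.arange(read_length)]
        rev = strands == 1
        if rev.any():
            windows[rev] = _COMPLEMENT[windows[rev, ::-1]]

        if sub_rate > 0:
            err = rng.random(windows.shape) < sub_rate
            err &= windows < 4  # never substitute N
            shifts = rng.integers(1, 4, size=windows.shape, dtype=np.uint8)
            windows[err] = (windows[err] + shifts[err]) % 4

        for i in range(count):
            strand = "-" if strands[i] else "+"
            start = int(starts[i])
            read_id = f"{rec_id}|{start}|{strand}|{serial}"
            reads.append(
                SimulatedRead(
                    read_id=read_id,
                    sequence=decode_sequence(windows[i]),
                    truth_species=rec.species_key,
                    truth_record=rec_id,
                    truth_start=start,
                    truth_strand=strand,
                )
            )
            serial += 1
    return reads


@dataclass
class TrimSummary:
    kept: int
    dropped: int


def trim_reads(
    reads: Iterable,
    target_length: int,
    offset: int = 0,
) -> tuple[list, TrimSummary]:
    """Cut each read to bases [offset, offset + target_length).

    Reads too short to yield a full window are dropped and counted in the
    returned summary. Input items may be :class:`SimulatedRead` or any
    object with ``read_id`` and ``sequence`` attributes; trimmed copies of
    the same shape are returned.
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    out = []
    dropped = 0
    for read in reads:
        seq = read.sequence
        if len(seq) < offset + target_length:
            dropped += 1
            continue
        trimmed_seq = seq[offset : offset + target_length]
        if isinstance(read, SimulatedRead):
            out.append(
                SimulatedRead(
                    read_id=read.read_id,
                    sequence=trimmed_seq,
                    truth_species=read.truth_species,
                    truth_record=read.truth_record,
                    truth_start=read.truth_start,
                    truth_strand=read.truth_strand,
                )
            )
        else:
            out.append(PlainRead(read.read_id, trimmed_seq))
    summary = TrimSummary(kept=len(out), dropped=dropped)
    if dropped:
        logger.info("trim_reads: dropped %d reads shorter than %d bp", dropped, offset + target_length)
    return out, summary


@dataclass(frozen=True)
class PlainRead:
    """A bare (read_id, sequence) record for reads without truth labels."""

    read_id: str
    sequence: str


def write_reads_fasta(reads: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id}\n{read.sequence}\n")


def write_reads_fastq(reads: Iterable, path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{quality_char * len(read.sequence)}\n")


def read_reads(path: str | Path) -> list[PlainRead]:
    """Load reads from FASTA or FASTQ (format sniffed from the first byte)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    from Bio import SeqIO

    return [PlainRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def truth_table(reads: Sequence[SimulatedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "species_key": [r.truth_species for r in reads],
            "record_id": [r.truth_record for r in reads],
            "start": [r.truth_start for r in reads],
            "strand": [r.truth_strand for r in reads],
        }
    )


def write_truth_table(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    truth_table(reads).to_csv(path, sep="\t", index=False)
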