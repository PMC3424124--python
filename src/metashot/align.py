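"""Read-to-reference alignment: built-in ungapped aligner and SAM plumbing.

The built-in aligner exists so the whole pipeline can run self-contained:
it reports, per read, the single best ungapped placement with at most k
mismatches over both strands, with deterministic tie-breaking (record
order, leftmost position, forward strand first). It is exact — any
placement with <= k mismatches is found — via a pigeonhole seed table:
a read with <= k mismatches must contain one clean seed among k+1
non-overlapping seeds.

Coordinates are 0-based half-open internally; conversion to/from SAM's
1-based POS happens only at the file boundary.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .reference import ReferenceCatalog
from .simulate import _COMPLEMENT, decode_sequence, encode_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "builtin_align",
    "read_alignments",
    "write_sam",
    "invoke_external_aligner",
    "ReferenceIndex",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """Normalized view of one read's primary alignment (or lack thereof)."""

    read_id: str
    mapped: bool
    record_id: str | None = None
    start: int | None = None  # 0-based leftmost
    strand: str | None = None
    mismatches: int | None = None
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not self.mapped and (self.record_id is not None or self.start is not None):
            raise ValueError("unmapped alignment must not carry a position")


class ReferenceIndex:
    """Exact-seed index over a concatenated view of the catalog's records."""

    def __init__(self, catalog: ReferenceCatalog, seed_length: int = 12):
        self.catalog = catalog
        self.record_ids = [rec.record_id for rec in catalog]
        self.lengths = np.array([rec.length for rec in catalog], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.genome = np.concatenate(
            [encode_sequence(rec.sequence) for rec in catalog]
        ) if len(catalog) else np.zeros(0, dtype=np.uint8)
        self.seed_length = int(seed_length)
        self._build(self.seed_length)

    def _build(self, s: int) -> None:
        g = self.genome
        n_pos = len(g) - s + 1
        if n_pos <= 0:
            self.sorted_hashes = np.zeros(0, dtype=np.int64)
            self.sorted_positions = np.zeros(0, dtype=np.int64)
            return
        # base-4 hash over codes & 3 (N hashes like A; verification is exact)
        h = np.zeros(n_pos, dtype=np.int64)
        for j in range(s):
            h += (g[j : j + n_pos].astype(np.int64) & 3) << (2 * (s - 1 - j))
        order = np.argsort(h, kind="stable")
        self.sorted_hashes = h[order]
        self.sorted_positions = order.astype(np.int64)

    def seed_hashes(self, mat: np.ndarray, offsets: Sequence[int]) -> np.ndarray:
        """(R, n_seeds) hashes of read seeds at the given column offsets."""
        s = self.seed_length
        out = np.zeros((mat.shape[0], len(offsets)), dtype=np.int64)
        for j_idx, off in enumerate(offsets):
            block = mat[:, off : off + s].astype(np.int64) & 3
            h = np.zeros(mat.shape[0], dtype=np.int64)
            for j in range(s):
                h += block[:, j] << (2 * (s - 1 - j))
            out[:, j_idx] = h
        return out


def _best_per_read(
    read_idx: np.ndarray,
    mm: np.ndarray,
    strand_flag: np.ndarray,
    rec_idx: np.ndarray,
    pos: np.ndarray,
    n_reads: int,
) -> dict[int, tuple[int, int, int, int]]:
    """Pick the winning candidate per read under the documented tie-break."""
    if len(read_idx) == 0:
        return {}
    order = np.lexsort((strand_flag, pos, rec_idx, mm, read_idx))
    read_sorted = read_idx[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = read_sorted[1:] != read_sorted[:-1]
    winners = order[first]
    return {
        int(read_idx[w]): (int(mm[w]), int(strand_flag[w]), int(rec_idx[w]), int(pos[w]))
        for w in winners
    }


def builtin_align(
    reads: Iterable,
    reference: ReferenceCatalog,
    max_mismatches: int = 2,
    index: ReferenceIndex | None = None,
    chunk_size: int = 20_000,
) -> list[AlignmentRecord]:
    """Ungapped <=k-mismatch alignment of reads against the catalog.

    For each read the single best placement (fewest mismatches over both
    strands) is reported; ties go to the earlier record, then the leftmost
    position, then the forward strand. Reads with no placement at <= k
    mismatches come back unmapped. Exact with respect to an exhaustive scan.
    """
    k = int(max_mismatches)
    if k < 0:
        raise ValueError("max_mismatches must be >= 0")
    read_list = list(reads)
    results: dict[str, AlignmentRecord] = {}

    # group by read length: seed geometry depends on it
    by_length: dict[int, list[int]] = {}
    for i, r in enumerate(read_list):
        by_length.setdefault(len(r.sequence), []).append(i)

    for length, indices in sorted(by_length.items()):
        if length == 0:
            for i in indices:
                results[read_list[i].read_id] = AlignmentRecord(read_list[i].read_id, mapped=False)
            continue
        seed_len = max(1, min(12, length // (k + 1)))
        idx = index
        if idx is None or idx.seed_length != seed_len:
            idx = ReferenceIndex(reference, seed_length=seed_len)
        n_seeds = k + 1
        seed_offsets = [j * seed_len for j in range(n_seeds)]
        if seed_offsets[-1] + seed_len > length:  # reads shorter than (k+1)*seed_len
            seed_offsets = list(range(0, length - seed_len + 1, seed_len)) or [0]

        for c0 in range(0, len(indices), chunk_size):
            chunk = indices[c0 : c0 + chunk_size]
            mat_fwd = np.vstack(
                [encode_sequence(read_list[i].sequence) for i in chunk]
            )
            mat_rev = _COMPLEMENT[mat_fwd[:, ::-1]]
            found = _align_chunk(mat_fwd, mat_rev, idx, seed_offsets, k, length)
            for local_i, global_i in enumerate(chunk):
                read = read_list[global_i]
                if local_i in found:
                    mm, strand_flag, rec_i, pos = found[local_i]
                    results[read.read_id] = AlignmentRecord(
                        read_id=read.read_id,
                        mapped=True,
                        record_id=idx.record_ids[rec_i],
                        start=pos,
                        strand="-" if strand_flag else "+",
                        mismatches=mm,
                    )
                else:
                    results[read.read_id] = AlignmentRecord(read.read_id, mapped=False)

    return [results[r.read_id] for r in read_list]


def _align_chunk(
    mat_fwd: np.ndarray,
    mat_rev: np.ndarray,
    idx: ReferenceIndex,
    seed_offsets: Sequence[int],
    k: int,
    length: int,
) -> dict[int, tuple[int, int, int, int]]:
    n_reads = mat_fwd.shape[0]
    genome = idx.genome
    g_len = len(genome)
    cand_read: list[np.ndarray] = []
    cand_start: list[np.ndarray] = []
    cand_strand: list[np.ndarray] = []

    for strand_flag, mat in ((0, mat_fwd), (1, mat_rev)):
        hashes = idx.seed_hashes(mat, seed_offsets)
        for j_idx, off in enumerate(seed_offsets):
            h = hashes[:, j_idx]
            lo = np.searchsorted(idx.sorted_hashes, h, side="left")
            hi = np.searchsorted(idx.sorted_hashes, h, side="right")
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            read_of = np.repeat(np.arange(n_reads), counts)
            # flatten [lo_i, hi_i) ranges into one index vector
            flat = np.concatenate([np.arange(l, hh) for l, hh in zip(lo, hi) if hh > l])
            gpos = idx.sorted_positions[flat]
            starts = gpos - off
            ok = (starts >= 0) & (starts + length <= g_len)
            cand_read.append(read_of[ok])
            cand_start.append(starts[ok])
            cand_strand.append(np.full(int(ok.sum()), strand_flag, dtype=np.int64))

    if not cand_read:
        return {}
    read_idx = np.concatenate(cand_read)
    starts = np.concatenate(cand_start)
    strand = np.concatenate(cand_strand)

    # dedupe (read, strand, start) triples
    key = (read_idx * 2 + strand) * np.int64(g_len + 1) + starts
    _, uniq = np.unique(key, return_index=True)
    read_idx, starts, strand = read_idx[uniq], starts[uniq], strand[uniq]

    # candidates must lie inside a single record
    rec_idx = np.searchsorted(idx.offsets, starts, side="right") - 1
    inside = starts + length <= idx.offsets[rec_idx + 1]
    read_idx, starts, strand, rec_idx = (
        read_idx[inside], starts[inside], strand[inside], rec_idx[inside]
    )
    if len(read_idx) == 0:
        return {}

    # verify mismatch counts in vectorized slabs
    mm = np.empty(len(read_idx), dtype=np.int64)
    slab = 200_000
    cols = np.arange(length)
    for s0 in range(0, len(read_idx), slab):
        sl = slice(s0, min(s0 + slab, len(read_idx)))
        window = genome[starts[sl, None] + cols]
        rows_f = strand[sl] == 0
        reads_mat = np.where(rows_f[:, None], mat_fwd[read_idx[sl]], mat_rev[read_idx[sl]])
        mm[sl] = (window != reads_mat).sum(axis=1)

    keep = mm <= k
    read_idx, starts, strand, rec_idx, mm = (
        read_idx[keep], starts[keep], strand[keep], rec_idx[keep], mm[keep]
    )
    pos_in_rec = starts - idx.offsets[rec_idx]
    return _best_per_read(read_idx, mm, strand, rec_idx, pos_in_rec, n_reads)


def write_sam(
    alignments: Iterable[AlignmentRecord],
    reads: Iterable,
    reference: ReferenceCatalog,
    path: str | Path,
) -> None:
    """Emit minimal valid SAM (mandatory fields + NM tag) for the alignments.

    Reverse-strand records carry the reverse-complemented read sequence, per
    the SAM convention.
    """
    seq_by_id = {r.read_id: r.sequence for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rec in reference:
            fh.write(f"@SQ\tSN:{rec.record_id}\tLN:{rec.length}\n")
        fh.write("@PG\tID:metashot\tPN:metashot\n")
        for aln in alignments:
            seq = seq_by_id.get(aln.read_id, "*")
            if aln.mapped:
                flag = 16 if aln.strand == "-" else 0
                if aln.strand == "-" and seq != "*":
                    seq = _revcomp(seq)
                cigar = f"{len(seq)}M" if seq != "*" else "*"
                nm = f"\tNM:i:{aln.mismatches}" if aln.mismatches is not None else ""
                fh.write(
                    f"{aln.read_id}\t{flag}\t{aln.record_id}\t{aln.start + 1}\t255\t"
                    f"{cigar}\t*\t0\t0\t{seq}\t*{nm}\n"
                )
            else:
                fh.write(f"{aln.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")


def _revcomp(seq: str) -> str:
    return decode_sequence(_COMPLEMENT[encode_sequence(seq)][::-1])


def read_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream primary alignments from a SAM/BAM file.

    SAM's 1-based POS becomes a 0-based start; secondary and supplementary
    records are dropped; the mismatch count comes from the NM tag when
    present. Malformed input raises ``ValueError`` naming the file.
    """
    path = str(path)
    try:
        with pysam.AlignmentFile(path, check_sq=False) as sam:
            for rec in sam:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.is_unmapped:
                    yield AlignmentRecord(read_id=rec.query_name, mapped=False)
                    continue
                nm = rec.get_tag("NM") if rec.has_tag("NM") else None
                yield AlignmentRecord(
                    read_id=rec.query_name,
                    mapped=True,
                    record_id=sam.get_reference_name(rec.reference_id),
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(nm) if nm is not None else None,
                )
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed or unreadable SAM/BAM file {path}: {exc}") from exc


def invoke_external_aligner(
    reads_path: str | Path,
    index_prefix: str | Path,
    out_sam: str | Path,
    command_template: str = "bowtie -t {index} --sam -f {reads} {out}",
    extra_params: str = "",
) -> Path:
    """Run an external SAM-emitting aligner via a command template.

    The template is formatted with ``{index}``, ``{reads}``, ``{out}`` and
    ``{extra}``; any extra parameter string is passed through verbatim. The
    exact command line is logged. A missing executable or non-zero exit
    raises with the captured stderr — there is no silent fallback to the
    built-in aligner.
    """
    if "{extra}" not in command_template:
        command_template = command_template.replace("{reads}", "{extra} {reads}", 1)
    cmd = command_template.format(
        index=str(index_prefix), reads=str(reads_path), out=str(out_sam), extra=extra_params
    )
    argv = shlex.split(cmd)
    logger.info("external aligner command: %s", cmd)
    try:
        proc = subprocess.run(argv, capture_output=True, text=True)
    except FileNotFoundError as exc:
        raise RuntimeError(
            f"external aligner executable {argv[0]!r} not found on PATH; "
            "install it or use the built-in aligner explicitly"
        ) from exc
    if proc.returncode != 0:
        raise RuntimeError(
            f"external aligner exited with {proc.returncode}: {proc.stderr.strip()}"
        )
    out = Path(out_sam)
    if not out.exists():
        raise RuntimeError(f"external aligner reported success but {out} was not created")
    return out
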