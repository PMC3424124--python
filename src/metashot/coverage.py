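"""Read-placement statistics: coverage profiles, the no-overlap probability,
feature length/abundance estimation, and the localized-hits flag.

The no-overlap probability is defined generatively: n reads of length l
drop independently and uniformly onto the L - l + 1 valid start positions
of a sequence of length L; it is the probability that no two of their
[start, start + l) intervals intersect. With m = L - l + 1 valid starts
the count of non-overlapping ordered placements is a falling factorial of
M = m - (n - 1)(l - 1), giving

    p = M! / (M - n)! / m**n        (0 when M < n, i.e. when n*l > L)

evaluated in log space. A species whose mapped reads show a gross overlap
excess relative to this null, or occupy far fewer genome bins than uniform
placement predicts, is flagged as a likely false positive (homologous
islands, low-complexity pile-ups).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CoverageProfile",
    "OverlapStat",
    "FeatureEstimate",
    "coverage_profile",
    "coverage_profile_from_starts",
    "no_overlap_pvalue",
    "overlap_stat",
    "estimate_feature_metrics",
    "flag_localized",
    "expected_occupied_bins",
]

DEFAULT_BIN_SIZE = 10_000


@dataclass
class CoverageProfile:
    """Binned placement summary of one reference record's mapped reads."""

    record_id: str
    record_length: int
    read_length: int
    starts: np.ndarray  # sorted, 0-based
    bin_size: int = DEFAULT_BIN_SIZE
    bin_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.starts = np.sort(np.asarray(self.starts, dtype=np.int64))
        n_bins = max(1, math.ceil(self.record_length / self.bin_size))
        self.bin_counts = np.bincount(self.starts // self.bin_size, minlength=n_bins)

    @property
    def n_reads(self) -> int:
        return len(self.starts)

    @property
    def n_bins(self) -> int:
        return len(self.bin_counts)

    @property
    def occupied_bins(self) -> int:
        return int((self.bin_counts > 0).sum())

    def has_overlap(self) -> bool:
        """True when any two read intervals intersect on the reference."""
        if self.n_reads < 2:
            return False
        return bool((np.diff(self.starts) < self.read_length).any())


def coverage_profile(
    alignments: Iterable,
    record_length: int,
    read_length: int,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> CoverageProfile:
    """Profile from mapped :class:`AlignmentRecord` items of one record."""
    starts = []
    record_id = ""
    for aln in alignments:
        if not aln.mapped:
            continue
        if record_id and aln.record_id != record_id:
            raise ValueError(
                f"alignments span multiple records: {record_id!r} vs {aln.record_id!r}"
            )
        record_id = aln.record_id
        starts.append(aln.start)
    return CoverageProfile(
        record_id=record_id,
        record_length=record_length,
        read_length=read_length,
        starts=np.array(starts, dtype=np.int64),
        bin_size=bin_size,
    )


def coverage_profile_from_starts(
    starts: Sequence[int] | np.ndarray,
    record_length: int,
    read_length: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    record_id: str = "",
) -> CoverageProfile:
    return CoverageProfile(
        record_id=record_id,
        record_length=record_length,
        read_length=read_length,
        starts=np.asarray(starts, dtype=np.int64),
        bin_size=bin_size,
    )


def no_overlap_pvalue(n: int, l: int, L: int) -> float:
    """Probability that n uniform reads of length l on L bp never overlap.

    Exact combinatorial evaluation (log space); monotone non-increasing in
    n and l, non-decreasing in L. Zero whenever n*l > L (pigeonhole).
    """
    if l < 1 or L < 1:
        raise ValueError("l and L must be >= 1")
    if l > L:
        raise ValueError(f"read length l={l} exceeds sequence length L={L}")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n <= 1:
        return 1.0
    m = L - l + 1
    M = m - (n - 1) * (l - 1)
    if M < n:
        return 0.0
    log_p = math.lgamma(M + 1) - math.lgamma(M - n + 1) - n * math.log(m)
    return math.exp(log_p)


@dataclass
class OverlapStat:
    n: int
    l: int
    L: int
    p_no_overlap: float


def overlap_stat(n: int, l: int, L: int) -> OverlapStat:
    return OverlapStat(n=n, l=l, L=L, p_no_overlap=no_overlap_pvalue(n, l, L))


@dataclass
class FeatureEstimate:
    n_feature: int
    length_hat: float | None  # None when no reads hit the feature
    abundance_hat: float


def estimate_feature_metrics(
    n_feature: int,
    read_length: int,
    density_hat: float,
) -> FeatureEstimate:
    """Infer feature length and abundance from its mapped-read count.

    Under uniform placement at genome-wide density ``density_hat`` (mapped
    reads per valid start), a feature of length Lf is expected to collect
    density_hat * (Lf + l - 1) reads — any read starting within l - 1 bp
    upstream overlaps it. Inverting gives

        length_hat = n_feature / density_hat - l + 1   (floored at 0)

    The abundance estimate normalizes the read count by density and the
    read footprint, yielding read-length-equivalent units of sequence:
    abundance_hat = n_feature / (density_hat * l). It is linear in
    n_feature at fixed density.
    """
    if density_hat <= 0:
        raise ValueError("density_hat must be > 0")
    if n_feature < 0:
        raise ValueError("n_feature must be >= 0")
    if n_feature == 0:
        return FeatureEstimate(n_feature=0, length_hat=None, abundance_hat=0.0)
    length_hat = max(0.0, n_feature / density_hat - read_length + 1)
    abundance_hat = n_feature / (density_hat * read_length)
    return FeatureEstimate(n_feature=n_feature, length_hat=length_hat, abundance_hat=abundance_hat)


def expected_occupied_bins(n_reads: int, record_length: int, bin_size: int) -> float:
    """Poisson-occupancy expectation of non-empty bins under uniform starts."""
    if record_length < 1:
        return 0.0
    n_full, rem = divmod(record_length, bin_size)
    exp_occ = n_full * (1.0 - math.exp(-n_reads * bin_size / record_length))
    if rem:
        exp_occ += 1.0 - math.exp(-n_reads * rem / record_length)
    return exp_occ


def flag_localized(
    profile: CoverageProfile,
    min_occupied_fraction: float = 0.2,
    overlap_alpha: float = 0.01,
) -> tuple[bool, list[str]]:
    """Flag a record whose reads concentrate in restricted loci.

    Fires when the occupied-bin count falls below ``min_occupied_fraction``
    of the Poisson-model expectation, or when overlapping reads are observed
    although the no-overlap null makes any overlap rarer than
    ``overlap_alpha``. Returns (flag, reasons).
    """
    if profile.n_reads < 1:
        raise ValueError("profile must contain at least one read")
    reasons: list[str] = []

    exp_occ = expected_occupied_bins(profile.n_reads, profile.record_length, profile.bin_size)
    if exp_occ > 0 and profile.occupied_bins / exp_occ < min_occupied_fraction:
        reasons.append(
            f"occupied_bins {profile.occupied_bins} < {min_occupied_fraction:.2f} "
            f"of expected {exp_occ:.1f}"
        )

    p_null = no_overlap_pvalue(profile.n_reads, profile.read_length, profile.record_length)
    if 1.0 - p_null < overlap_alpha and profile.has_overlap():
        reasons.append(
            f"overlap observed although P(any overlap)={1.0 - p_null:.2e} "
            f"< alpha={overlap_alpha}"
        )

    return bool(reasons), reasons
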