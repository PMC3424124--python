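"""Roll primary alignments up to species counts; threshold; decontaminate.

Each primary mapped alignment contributes one count to the species of its
reference record; multiple records of one species (chromosomes, or strains
sharing a species key) are summed into a single row. Multi-mapping reads
are counted once, via the aligner's primary alignment — that is this
artifact's attribution semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .align import AlignmentRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesCountTable",
    "DetectionConfig",
    "count_by_species",
    "detect_species",
    "filter_reads_by_reference",
    "attribute_reads",
]


@dataclass
class SpeciesCountTable:
    """Per-species mapped-read counts plus run totals."""

    counts: dict[str, int] = field(default_factory=dict)
    record_counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    mapped_reads: int = 0
    unmapped_reads: int = 0

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.mapped_reads:
            raise ValueError("species counts do not sum to mapped_reads")
        if self.mapped_reads + self.unmapped_reads != self.total_reads:
            raise ValueError("mapped + unmapped must equal total_reads")

    def sorted_rows(self) -> list[tuple[str, int]]:
        """(species_key, count) rows, count descending, ties by key."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_dataframe(self) -> pd.DataFrame:
        rows = self.sorted_rows()
        total = self.total_reads
        return pd.DataFrame(
            {
                "species_key": [k for k, _ in rows],
                "read_count": [c for _, c in rows],
                "fraction_of_total": [c / total if total else 0.0 for _, c in rows],
            }
        )

    def record_dataframe(self) -> pd.DataFrame:
        rows = sorted(self.record_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {"record_id": [k for k, _ in rows], "read_count": [c for _, c in rows]}
        )

    def write_tsv(self, species_path: str | Path, record_path: str | Path | None = None,
                  comment: str | None = None) -> None:
        _write_table(self.to_dataframe(), species_path, comment)
        if record_path is not None:
            _write_table(self.record_dataframe(), record_path, comment)


def _write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class DetectionConfig:
    """Detection threshold: minimum mapped reads for a species to be called."""

    min_reads: int = 100

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")


def count_by_species(
    alignments: Iterable[AlignmentRecord],
    metadata: Mapping[str, str],
) -> SpeciesCountTable:
    """Count primary mapped alignments per species via the record->species map.

    Unmapped reads enter the totals only. A mapped record_id missing from
    the metadata is an error listing every offending id.
    """
    counts: dict[str, int] = {}
    record_counts: dict[str, int] = {}
    total = mapped = unmapped = 0
    missing: set[str] = set()
    for aln in alignments:
        if not aln.is_primary:
            continue
        total += 1
        if not aln.mapped:
            unmapped += 1
            continue
        species = metadata.get(aln.record_id)
        if species is None:
            missing.add(aln.record_id)
            continue
        mapped += 1
        counts[species] = counts.get(species, 0) + 1
        record_counts[aln.record_id] = record_counts.get(aln.record_id, 0) + 1
    if missing:
        raise KeyError(
            f"alignment record ids absent from reference metadata: {sorted(missing)}"
        )
    return SpeciesCountTable(
        counts=counts,
        record_counts=record_counts,
        total_reads=total,
        mapped_reads=mapped,
        unmapped_reads=unmapped,
    )


def detect_species(table: SpeciesCountTable, config: DetectionConfig) -> list[str]:
    """Species whose count meets the (inclusive) threshold, best first."""
    return [k for k, c in table.sorted_rows() if c >= config.min_reads]


def attribute_reads(
    alignments: Iterable[AlignmentRecord],
    metadata: Mapping[str, str],
) -> dict[str, str | None]:
    """Per-read species attribution (None for unmapped reads)."""
    out: dict[str, str | None] = {}
    missing: set[str] = set()
    for aln in alignments:
        if not aln.is_primary:
            continue
        if aln.mapped:
            species = metadata.get(aln.record_id)
            if species is None:
                missing.add(aln.record_id)
                continue
            out[aln.read_id] = species
        else:
            out[aln.read_id] = None
    if missing:
        raise KeyError(
            f"alignment record ids absent from reference metadata: {sorted(missing)}"
        )
    return out


def filter_reads_by_reference(
    reads: Iterable,
    decoy_alignments: Iterable[AlignmentRecord],
) -> tuple[list, list]:
    """Partition reads into (retained, removed) by decoy-mapping status.

    A read whose primary alignment against the decoy reference is mapped is
    removed (contaminant screening); everything else is retained. Decoy
    alignments for unknown read ids are ignored with a warning.
    """
    read_list = list(reads)
    known = {r.read_id for r in read_list}
    hit: set[str] = set()
    unknown: set[str] = set()
    for aln in decoy_alignments:
        if not aln.is_primary:
            continue
        if aln.read_id not in known:
            unknown.add(aln.read_id)
            continue
        if aln.mapped:
            hit.add(aln.read_id)
    if unknown:
        logger.warning(
            "decoy alignment stream names %d read ids absent from the read set", len(unknown)
        )
    retained = [r for r in read_list if r.read_id not in hit]
    removed = [r for r in read_list if r.read_id in hit]
    return retained, removed
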