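"""Build a one-representative-strain-per-species metagenomic reference.

A reference is a multi-record FASTA (one record per chromosome) plus a
metadata table mapping every sequence record to a normalized species key.
The species rollup in downstream counting happens through that table, so
no physical concatenation of sequences is ever performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeRecord",
    "ReferenceCatalog",
    "parse_organism_name",
    "select_representatives",
    "build_reference",
    "load_catalog",
    "read_metadata_table",
    "write_metadata_table",
]


@dataclass
class GenomeRecord:
    """One reference sequence record (a chromosome or contig).

    ``species_key`` is the normalized "Genus species" identifier that the
    classification rolls up to; ``strain_label`` keeps the remaining tokens
    of the organism description.
    """

    record_id: str
    organism_name: str
    species_key: str
    strain_label: str = ""
    release_date: date | None = None
    sequence: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.species_key:
            raise ValueError(f"record {self.record_id!r}: species_key must be non-empty")


@dataclass
class ReferenceCatalog:
    """An ordered collection of :class:`GenomeRecord` with a species index."""

    records: list[GenomeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id {rec.record_id!r} in catalog")
            seen.add(rec.record_id)

    @property
    def species_index(self) -> dict[str, set[str]]:
        """Mapping species_key -> set of record_ids."""
        index: dict[str, set[str]] = {}
        for rec in self.records:
            index.setdefault(rec.species_key, set()).add(rec.record_id)
        return index

    @property
    def species_keys(self) -> set[str]:
        return {rec.species_key for rec in self.records}

    def record_to_species(self) -> dict[str, str]:
        return {rec.record_id: rec.species_key for rec in self.records}

    def get(self, record_id: str) -> GenomeRecord:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def parse_organism_name(description: str) -> tuple[str, str]:
    """Split a free-text organism description into (species_key, strain_label).

    The species key is the first two name tokens ("Genus species"), with two
    refinements: a second token of ``sp.`` keeps the following token in the
    key (placeholder species are only identifiable at that granularity), and
    a leading ``Candidatus`` is retained as part of the key. Everything after
    the key becomes the strain label.

    Total over printable input: a single-token description yields that token
    as the key (with a warning) rather than raising.
    """
    tokens = description.split()
    if not tokens:
        raise ValueError("organism description must be non-empty")
    n_key = 2
    if tokens[0].lower() == "candidatus" and len(tokens) > 1:
        n_key = 3
    if len(tokens) > n_key - 1 and tokens[n_key - 1].rstrip(".").lower() == "sp" and tokens[n_key - 1].endswith("."):
        # "Genus sp. TOKEN": the token after "sp." is part of the species key
        n_key += 1
    if len(tokens) < min(n_key, 2):
        logger.warning("single-token organism description %r; using it as species_key", description)
        return tokens[0], ""
    species_key = " ".join(tokens[:n_key])
    strain_label = " ".join(tokens[n_key:])
    return species_key, strain_label


def _strain_sort_key(strain_label: str, earliest: date | None) -> tuple:
    # missing dates sort last; ties broken by lexicographic strain label
    if earliest is None:
        return (1, date.min, strain_label)
    return (0, earliest, strain_label)


def select_representatives(catalog: ReferenceCatalog) -> ReferenceCatalog:
    """Keep, per species, all records of the earliest-released strain.

    Strains are grouped by (species_key, strain_label); a strain's date is
    the earliest release date among its records. Strains with no date sort
    last; when no strain of a species carries a date the lexicographically
    smallest strain label wins (logged). Deterministic and idempotent.
    """
    by_species: dict[str, dict[str, list[GenomeRecord]]] = {}
    for rec in catalog.records:
        by_species.setdefault(rec.species_key, {}).setdefault(rec.strain_label, []).append(rec)

    keep: set[str] = set()
    for species_key, strains in by_species.items():
        ranked = []
        for strain_label, recs in strains.items():
            dates = [r.release_date for r in recs if r.release_date is not None]
            earliest = min(dates) if dates else None
            ranked.append((_strain_sort_key(strain_label, earliest), strain_label))
        ranked.sort()
        if all(key[0] == 1 for key, _ in ranked) and len(ranked) > 1:
            logger.warning(
                "species %r: no release dates; falling back to lexicographic strain order",
                species_key,
            )
        chosen = ranked[0][1]
        keep.update(r.record_id for r in strains[chosen])

    return ReferenceCatalog([rec for rec in catalog.records if rec.record_id in keep])


def build_reference(
    catalog: ReferenceCatalog,
    fasta_path: str | Path,
    meta_path: str | Path,
    include: Iterable[str] | None = None,
    exclude: Iterable[str] | None = None,
) -> ReferenceCatalog:
    """Write the selected records as a reference FASTA plus a metadata TSV.

    ``include``/``exclude`` are species-key filters; unknown keys only
    trigger a warning. The FASTA carries sequences verbatim; the metadata
    table has one row per record (record_id, species_key, strain_label,
    length). Returns the catalog that was written.
    """
    known = catalog.species_keys
    include_set = set(include) if include is not None else None
    exclude_set = set(exclude) if exclude is not None else set()
    for unknown in ((include_set or set()) | exclude_set) - known:
        logger.warning("species key %r not present in catalog", unknown)

    selected = [
        rec
        for rec in catalog.records
        if (include_set is None or rec.species_key in include_set)
        and rec.species_key not in exclude_set
    ]
    if not selected:
        raise ValueError("reference selection is empty: no records survive include/exclude")

    out = ReferenceCatalog(selected)
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.record_id, description=rec.organism_name)
        for rec in out
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    write_metadata_table(out, meta_path)
    return out


def write_metadata_table(catalog: ReferenceCatalog, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "record_id": rec.record_id,
                "species_key": rec.species_key,
                "strain_label": rec.strain_label,
                "length": rec.length,
            }
            for rec in catalog
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    """Read a reference metadata TSV (record_id, species_key, strain_label, length)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "record_id" not in df.columns:
        raise ValueError(f"{path}: metadata table must carry a record_id column")
    if "species_key" not in df.columns:
        if "organism_name" not in df.columns:
            raise ValueError(
                f"{path}: metadata table needs a species_key or organism_name column"
            )
        df["species_key"] = [parse_organism_name(n)[0] for n in df["organism_name"]]
    df["strain_label"] = df.get("strain_label", pd.Series([""] * len(df))).fillna("")
    return df


def _parse_date(value) -> date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None
    return date.fromisoformat(s)


def load_catalog(
    fasta_path: str | Path,
    meta_path: str | Path | None = None,
    metadata: Mapping[str, Mapping] | None = None,
) -> ReferenceCatalog:
    """Load genomes from a multi-FASTA, with organism metadata.

    Metadata comes either from a side TSV (columns: record_id,
    organism_name, strain, date) or, failing that, is parsed from the FASTA
    header description via :func:`parse_organism_name`.
    """
    side: dict[str, dict] = {}
    if meta_path is not None:
        df = pd.read_csv(meta_path, sep="\t", dtype=str, comment="#")
        for _, row in df.iterrows():
            side[str(row["record_id"])] = dict(row)
    elif metadata is not None:
        side = {k: dict(v) for k, v in metadata.items()}

    records: list[GenomeRecord] = []
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        header_desc = seq_rec.description
        if header_desc.startswith(seq_rec.id):
            header_desc = header_desc[len(seq_rec.id):].strip()
        info = side.get(seq_rec.id, {})
        organism = info.get("organism_name") or header_desc or seq_rec.id
        species_key, strain_from_name = parse_organism_name(organism)
        strain = info.get("strain") or strain_from_name
        records.append(
            GenomeRecord(
                record_id=seq_rec.id,
                organism_name=organism,
                species_key=species_key,
                strain_label=strain or "",
                release_date=_parse_date(info.get("date")),
                sequence=str(seq_rec.seq).upper(),
            )
        )
    return ReferenceCatalog(records)
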