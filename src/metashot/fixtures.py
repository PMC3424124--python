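"""Synthetic genomes and mock-community designs for tests and benchmarks."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .reference import GenomeRecord, ReferenceCatalog, parse_organism_name
from .simulate import CommunityDesign, decode_sequence

__all__ = [
    "random_sequence",
    "random_catalog",
    "marine_mock_design",
    "marine_mock_catalog",
    "write_fixture_set",
    "MARINE_MOCK_COMMUNITY",
]

# The ten-strain marine mock community used by the benchmark harness:
# (organism name, read count). Totals 100,000 reads.
MARINE_MOCK_COMMUNITY: list[tuple[str, int]] = [
    ("Marinomonas sp. MWYL1", 17391),
    ("Shewanella loihica PV-4", 15665),
    ("Oceanobacillus iheyensis HTE831", 12473),
    ("Nitrosococcus oceani ATCC19707", 11890),
    ("Alcanivorax borkumensis SK2", 10509),
    ("Synechococcus elongatus PCC6301", 9252),
    ("Halobacterium salinarum R1", 6911),
    ("Prochlorococcus marinus CCMP1375", 5946),
    ("Nitrosopumilus maritimus SCM1", 5619),
    ("Candidatus Pelagibacter ubique HTCC1062", 4344),
]


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """A random nucleotide string with the given GC content."""
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)
    return decode_sequence(codes)


def random_catalog(
    n_genomes: int,
    genome_length: int,
    seed: int,
    name_prefix: str = "Synthetica",
) -> ReferenceCatalog:
    """Independent random genomes, one species each, for self-contained tests."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_genomes):
        organism = f"{name_prefix} species{i} ST{i}"
        species_key, strain = parse_organism_name(organism)
        records.append(
            GenomeRecord(
                record_id=f"SYN{i:03d}",
                organism_name=organism,
                species_key=species_key,
                strain_label=strain,
                sequence=random_sequence(genome_length, rng),
            )
        )
    return ReferenceCatalog(records)


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name)


def marine_mock_catalog(seed: int, genome_length: int = 1_000_000) -> ReferenceCatalog:
    """Random surrogate genomes named after the ten marine mock-community strains.

    Sequences are independent random DNA (a desk-scale stand-in for the real
    genomes), but organism names — and hence species keys — match the
    benchmark community so detection results are reported per real taxon.
    """
    rng = np.random.default_rng(seed)
    records = []
    for organism, _count in MARINE_MOCK_COMMUNITY:
        species_key, strain = parse_organism_name(organism)
        records.append(
            GenomeRecord(
                record_id=_slug(organism),
                organism_name=organism,
                species_key=species_key,
                strain_label=strain,
                sequence=random_sequence(genome_length, rng),
            )
        )
    return ReferenceCatalog(records)


def marine_mock_design() -> CommunityDesign:
    """The ten-strain benchmark design keyed by surrogate record ids."""
    return CommunityDesign([(_slug(name), count) for name, count in MARINE_MOCK_COMMUNITY])


def write_fixture_set(out_dir: str | Path, seed: int, n_genomes: int = 3,
                      genome_length: int = 50_000) -> dict[str, Path]:
    """Write a small synthetic genome set + design for pipeline tests.

    Emits genomes.fasta, genomes.meta.tsv (record_id, organism_name, strain,
    date) and design.tsv under ``out_dir``; returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = random_catalog(n_genomes, genome_length, seed)
    fasta = out_dir / "genomes.fasta"
    with open(fasta, "w") as fh:
        for rec in catalog:
            fh.write(f">{rec.record_id} {rec.organism_name}\n{rec.sequence}\n")
    meta = out_dir / "genomes.meta.tsv"
    with open(meta, "w") as fh:
        fh.write("record_id\torganism_name\tstrain\tdate\n")
        for i, rec in enumerate(catalog):
            fh.write(f"{rec.record_id}\t{rec.organism_name}\t{rec.strain_label}\t2008-01-{i + 1:02d}\n")
    design_path = out_dir / "design.tsv"
    rng = np.random.default_rng(seed + 1)
    counts = rng.integers(500, 1500, size=len(catalog))
    CommunityDesign(
        [(rec.record_id, int(c)) for rec, c in zip(catalog, counts)]
    ).to_tsv(design_path)
    return {"fasta": fasta, "meta": meta, "design": design_path}
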