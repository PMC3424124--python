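# metashot

Species-level taxonomic attribution of short metagenomic shotgun reads.

Reads are aligned against a reference containing **one representative strain
per species**; each read's primary alignment is rolled up to its species via
a metadata table, species are called at a mapped-read detection threshold
(default 100), and read-placement statistics (coverage uniformity, the
no-overlap probability) screen calls whose reads pile up on restricted loci
such as shared genomic islands. The package ships its own mock-community
simulator with truth labels, a built-in exact ≤k-mismatch aligner so the
whole pipeline runs self-contained, and an evaluation harness for detection
recall/precision and per-species assignment accuracy.

## Modules

| module | purpose |
| --- | --- |
| `metashot.reference` | organism-name parsing, earliest-strain representative selection, reference FASTA + metadata construction |
| `metashot.simulate` | mock-community read simulation (uniform starts/strands, substitution errors, truth sidecar), read trimming |
| `metashot.align` | built-in seed-and-verify ≤k-mismatch aligner (exact vs. exhaustive scan), SAM/BAM reading via pysam, minimal SAM writing, external-aligner adapter |
| `metashot.attribute` | species rollup of primary alignments, detection thresholding, decoy-based contaminant read removal |
| `metashot.coverage` | coverage profiles, the exact no-overlap probability, feature length/abundance estimation, localized-hits flag |
| `metashot.evaluate` | detection reports (reference-aware FN accounting) and per-species assignment accuracy |
| `metashot.pipeline` / `metashot.cli` | one-command reproducible runs with a JSON manifest |
| `metashot.fixtures` | synthetic genomes and the ten-strain marine benchmark design |

## CLI

Every stage is a `metashot` subcommand:

```sh
metashot make-fixtures --seed 1 --out fx/                 # synthetic genomes + design
metashot build-ref --genomes fx/genomes.fasta --meta fx/genomes.meta.tsv --out-prefix ref
metashot simulate --ref ref.fasta --meta ref.meta.tsv --design fx/design.tsv \
    --length 50 --error 0.01 --seed 1 --out reads
metashot align --reads reads.fasta --ref ref.fasta --max-mismatches 2 --out out.sam
metashot attribute --sam out.sam --meta ref.meta.tsv --min-reads 100 --out attr
metashot coverage --sam out.sam --meta ref.meta.tsv --read-length 50 --out coverage.tsv
metashot overlap-p --n 5 --l 50 -L 1000
metashot run --config run.yaml          # full pipeline, manifest-logged
```

An external SAM-emitting aligner can replace the built-in one via a command
template, with extra parameters passed through verbatim:

```sh
metashot align --reads reads.fasta --ref ref.fasta --out out.sam \
    --external "bowtie -t {index} --sam -f {extra} {reads} {out}" \
    --extra-params "-p 4"
```

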