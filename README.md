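# epipair

Reference-free reconstruction of pre-bisulfite GBS fragments.

In a single-enzyme bisulfite GBS library (e.g. PstI) each genomic fragment
is inserted in **two orientations** between a barcoded adapter and a
hemimethylated common adapter, so the sequenced catalog contains one
bisulfite image of each strand of every fragment.  Bisulfite conversion
maps C to T — a pyrimidine to a pyrimidine — so the purine/pyrimidine (RY)
image of every locus is conversion-invariant.  `epipair` pairs catalog
entries whose RY images are exact reverse complements of each other,
decodes each pair back into the original fragment sequence with a
per-position methylation call, and stitches the fragments into a single
**mock genome** (with a boundary table) usable as a mapping reference for
standard bisulfite aligners and methylation callers.

The package contains five modules:

| module              | contents |
|---------------------|----------|
| `epipair.simulate`  | forward model of the library (random genomes, in-silico restriction digestion, context-dependent CpG/CHG/CHH methylation, strand-wise bisulfite conversion, paired-read generation with ground truth) |
| `epipair.preprocess`| demultiplexing by inline barcodes, fixed-position trimming, pad-gap joining, expected-error-rate filtering, wobble-based PCR-clone removal, conversion-rate estimation from the adapter check cytosine |
| `epipair.catalog`   | exact-match stacking, per-sample locus building and cross-sample catalog construction (simplified ustacks/cstacks equivalent); reads Stacks v2 `catalog.fa(.gz)` |
| `epipair.reconstruct` | RY encoding, Watson/Crick pair discovery, position-wise decoding, pad removal and overlap merging, mock-genome assembly |
| `epipair.annotate`  | mapping mock-genome positions (e.g. differentially methylated cytosines) back to fragments and offsets |

## Command-line usage

Everything is reachable through the `epipair` entry point:

```sh
# simulate a library with ground truth
epipair simulate --outdir sim --genome-length 100000 --depth 5 --seed 1

# expected fragment counts per size range for a real genome
epipair digest-stats genome.fasta --ranges 150-250,100-300,100-400

# demultiplex / trim / join / quality-filter raw paired FASTQ
epipair preprocess sim/R1.fastq.gz sim/R2.fastq.gz --outdir pre

# bisulfite conversion rate from the adapter check position of raw read 2
epipair convrate sim/R2.fastq.gz

# per-sample loci and cross-sample catalog
epipair catalog pre/*.joined.fastq --out catalog.fa --table catalog.tsv

# pair strand images, reconstruct fragments, build the mock genome
epipair reconstruct catalog.fa --outdir rec

# map caller positions back to fragments
epipair seek --positions dmc.tsv --boundaries rec/boundaries.tsv --out hits.tsv
```

`epipair reconstruct` also accepts a Stacks v2 catalog
(`catalog.fa`/`catalog.fa.gz`) as its input, so the stacking stage can be
replaced by the original tools if preferred.

Defaults follow a 2×100 bp PstI library: strip 4 bases from the forward
read and 14 from the reverse read (barcode is removed separately at
demultiplexing), truncate both to 86 bases, join with an `ATATATAT` pad
at quality 40, filter at an expected-error rate of 0.01, and allow 4
mismatches between sample loci when building the catalog.

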