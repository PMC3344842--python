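# ghostseek

Translated (BLASTX-style) homology search of short DNA reads against a
protein database, built around three stages:

1. **Index** — database sequences are concatenated with delimiters, greedily
   packed into chunks under a residue limit, and indexed by every K-mer
   offset (`ghostseek.db_index`).
2. **Candidate search** — reads are translated in all six frames (codons
   containing N become X), query K-mers are sampled every `s` residues, and
   predicted alignment starts are counted in regions of size `r`: a region
   pair holding at least `t` seed matches yields a candidate
   (`ghostseek.translate`, `ghostseek.seed_search`).
3. **Restricted alignment** — each candidate is scored with affine-gap
   Smith-Waterman confined to a window of size `m + 2r + 2e` around the
   candidate position, converted to bit scores, merged across chunks,
   sorted, and written as 12-column BLAST tabular output
   (`ghostseek.local_align`, `ghostseek.pipeline`, `ghostseek.seq_io`).

`ghostseek.oracle_fixtures` provides the evaluation harness: synthetic
protein databases (BLOSUM62 background composition), reads reverse-translated
from database fragments at controlled amino-acid divergence, an exhaustive
(unrestricted) Smith-Waterman oracle, and recall-vs-bit-score curves.

## CLI

```sh
# build an index: seed length K=4, chunk limit 128e6 residues
ghostseek db -k 4 -l 128 -i proteins.fasta -o proteins.idx

# search reads (defaults: -s 2 -r 4 -e 2 -t 2)
ghostseek aln -l 128 -s 2 -r 4 -e 2 -t 2 \
    -i proteins.idx -q reads.fastq -o hits.tsv

# one-parameter sensitivity sweep
ghostseek sweep -d proteins.fasta -q reads.fastq -o sweep.tsv \
    --param t --values 1,2,3
```

`aln` accepts FASTQ or FASTA queries; `--qc` applies the quality trim
(longest run of Q>=15, kept if >=60 bp). `--top N` keeps the N best hits per
read plus ties within one bit. Output is 12-column BLAST tabular
(`-outfmt 6` style); the e-value column holds `NA` unless `--evalue` is
given. Exit codes distinguish usage errors (2), missing inputs (3), index
seed-length mismatches (4), unwritable output (5), and format errors (6).

Output is deterministic: byte-identical across database chunkings, query
batch sizes, and `--threads` settings.

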