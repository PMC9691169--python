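# tickmito

Comparative mitogenomics toolkit for hard-tick (Ixodidae) mitochondrial
genomes. It implements the record-level and alignment-level analyses used
in tick comparative mitogenomics as a tested, scriptable pipeline:

- **I/O & annotation** (`tickmito.io`, `tickmito.genes`): GenBank / FASTA /
  feature-TSV readers and writers with 0-based half-open internal
  coordinates, origin-wrapping feature support, canonical 37-gene +
  control-region naming (synonym normalization: `nad4l` → `ND4L`,
  `tRNA-Leu(CUN)` → `trnL1`, `A+T rich region` → `CR`, ...), and PCG
  start/stop-codon QC (ATA/ATT/ATC/ATG starts; TAA/TAG or truncated-T
  stops).
- **Composition** (`tickmito.composition`): base counts, A+T%,
  AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C) at whole-genome,
  per-gene (coding or heavy-strand orientation) and control-region level,
  plus per-genus aggregates.
- **Microsatellites** (`tickmito.ssr`): perfect SSR mining with
  per-motif-length minimum repeats (10/5/4/3/3/3 for mono- through
  hexa-nucleotides), primitive-motif maximal-tract semantics, motif-class
  standardization by cyclic rotation + reverse complement (switchable),
  relative abundance (loci/kb), and per-type/per-motif summaries. A naive
  brute-force oracle ships alongside the scanner for validation.
- **Degenerate motifs** (`tickmito.motif`): IUPAC consensus scanning on
  both strands (default: the 17 bp tick control motif
  `TTGYRTCHWWWTWWGDA`), mismatch tolerance, circular-origin windows, and
  genomic-context labels (within / downstream of a gene / intergenic).
- **Distances & delimitation** (`tickmito.distance`): Kimura 2-parameter
  distances with pairwise deletion, square matrix TSV/PHYLIP output, and
  threshold-based species-complex delimitation (single linkage; default
  thresholds rrnL 0.0525, COX1 0.0613; all-markers-below rule).
- **Diversity** (`tickmito.diversity`): variable-site counts, nucleotide
  diversity π, sliding-window π (default 200/20), and partitioned
  supermatrix concatenation (RAxML + NEXUS partition files).
- **Gene order** (`tickmito.gene_order`): signed circular gene orders,
  arrangement typing against a catalog (built-in T1 = ancestral arthropod
  order), per-gene rearrangement status/score vs a benchmark, total
  rearrangement score (RS), per-gene rearrangement frequency (RF), and
  conserved-segment detection.
- **Synthetic data** (`tickmito.simulate`): fully seeded generator of
  annotated ~14.5 kb circular mitogenomes with target A+T/skews, planted
  SSRs and motif instances (with truth logs), K2P sequence evolution with
  exact event probabilities, programmed rearrangement events, and grouped
  marker alignments.

Packaged reference tables (`tickmito.data`) include the published pairwise
K2P matrices for the *I. ovatus* / *I. acutitarsus* species complexes and
the published Ixodidae/Ixodes SSR per-type count tables.

## CLI

```sh
tickmito compose records.gb -o composition.tsv          # composition/skew table
tickmito ssr records.gb -o ssr_loci.tsv                 # microsatellites
tickmito motif records.gb --max-mismatch 1              # degenerate motif scan
tickmito dist aligned_cox1.fasta -o cox1_k2p.tsv        # K2P matrix
tickmito group --matrix rrnL=m1.tsv --matrix COX1=m2.tsv
tickmito diversity whole_genomes.fasta --track pi.tsv   # π + sliding window
tickmito order records.gb                               # arrangement typing, RF/RS
tickmito simulate --seed 1 --out-prefix sim             # synthetic genome + truth
tickmito run-all records.gb --out-dir runs              # all record-level stages
```

FASTA inputs need a companion `--features` TSV
(`record_id  name  start  end  strand`); GenBank records are self-contained.

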