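# duplexrepair

Strand-resolved, single-molecule analysis of double-strand-break (DSB)
repair products from designed extrachromosomal substrates.

A DSB comprises two strand breaks. This package reconstructs, for each
repaired substrate molecule, which of its two strands were joined and by
which path:

* **model 1** (parallel, symmetric): both strand breaks ligated
  independently, each strand carrying its own product;
* **model 2** (ordered, semi-conservative): one strand repaired first, the
  second synthesised using the first as template, so the second strand's
  junction is the templated copy of the first strand's product.

Molecules are resolved by a double-stranded sequencing adapter carrying a
10-nt random UMI shared by both strands of one duplex, and strands are
identified by a designed 5-nt fully mismatched "strand-ID" region. A
synthetic-data module simulates two-strand repair kinetics (exponential
hazards, parallel or ordered), ribonucleotide marking with RER decay, and
UMI-tagged, barcoded, error-bearing amplicon libraries, so the entire
pipeline is exercised without external data.

## Modules

| module                     | contents |
|----------------------------|----------|
| `duplexrepair.substrate`   | substrate specs (strands, end structures, strand-ID), validation, enumeration of expected junction references per repair path, degenerate-pair detection |
| `duplexrepair.simulate`    | kinetics simulation (`simulate_repair`), strand rendering, read synthesis (`synthesize_reads`), UMI drawing, alkali-qPCR emulation |
| `duplexrepair.readproc`    | demultiplexing, pair merging, UMI extraction, strand assignment, junction classification by bounded edit distance |
| `duplexrepair.duplex`      | UMI grouping, the 2% family filter and 20% strand filter, per-strand consensus, molecule/path classification, summaries and preference ratios |
| `duplexrepair.quant`       | spike-in-normalised qPCR fold changes, alkali fraction-RNA, ddPCR Poisson concentrations and bottom:top ratios, time-course assembly |
| `duplexrepair.pipeline` / `cli` / `io` / `config` | end-to-end orchestration, file round-tripping, JSON-lines run log |

## CLI

```bash
# simulate + analyse a parallel-kinetics library on the bundled
# 5'-overhang demo substrate
duplexrepair all --substrate gt5 --n-molecules 2000 --harvest-time 10 \
    --oversampling-mean 50 --error-rate 0.002 --seed 1 --outdir out_gt5

# ordered kinetics on the 3'-GAG/GAG demo substrate (+C insertions)
duplexrepair all --substrate gag3 --kinetics-mode ordered --first-strand top \
    --k-top 0.2 --k-second 0.1 --insertion-labels C --harvest-time 30 \
    --n-molecules 2000 --oversampling-mean 50 --seed 2 --outdir out_gag3

# analyse an existing FASTQ
duplexrepair analyze --substrate gt5 --fastq out_gt5/reads.fastq \
    --n-input-templates 2000 --outdir reanalysis

# bulk quantification from Ct / droplet tables
duplexrepair quantify --qpcr-csv ct.csv --dpcr-csv droplets.csv --outdir quant
```

Substrates may also be given as YAML/JSON files with keys `name`,
`top_seq`, `bottom_seq`, `head`, `tail`, `strand_id`; see
`duplexrepair.substrate.substrate_to_mapping` for the exact schema. Three
demo substrates are bundled: `gt5` (symmetric 5' overhangs whose ligation
leaves terminal G:T mispairs), `gag3` (symmetric non-complementary 3'-GAG
overhangs, repaired via +C/+TC/+CTC insertions) and `blunt` (fully
complementary; the two paths are indistinguishable and reported as such).

Outputs per run: `reads.fastq`, ground-truth tables (simulation),
`annotated_reads.tsv`, `duplex_calls.tsv`, `summary.json`/`summary.tsv`,
and `run_log.jsonl` recording every threshold, drop count and the computed
mean oversampling ratio. Identical config + seed reproduces byte-identical
outputs.

## Filtering rules

For each library the mean oversampling ratio is total reads divided by the
number of input template molecules (an explicit input, measured by digital
PCR for real libraries, taken from ground truth in simulations). UMI
families with fewer reads than 2% of that ratio are excluded, then a
strand within a family is excluded if it holds <20% of the family's reads.
Both comparisons are strict. Each surviving UMI is called as one molecule.

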