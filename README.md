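# mirtail

Toolkit for quantifying miRNA 3' mono-adenylation from small RNA-seq, running
qPCR relative-quantification screens, and evaluating simple plate-assay
formulas — together with a ground-truth simulator so every stage is testable
without external data.

## What it does

- **simulate** (`mirtail.simulate`) — generates a synthetic mature-miRNA
  reference, per-sample FASTQ libraries in which each read is a mature
  sequence or that sequence plus one non-templated 3' A (condition-dependent
  probability, abundance heterogeneity, optional adapter read-through and
  substitution errors), a qPCR Ct panel with a stable internal control and a
  designed "down-and-restored" subset, and LDH / dual-luciferase plate
  readings. Fully deterministic under a single seed.
- **count** (`mirtail.counting`) — builds paired canonical and "+A"
  references (one extra A per mature sequence, collisions reported), trims 3'
  adapters, and classifies each read by full-length exact-length Hamming
  comparison (default 0 mismatches) as canonical / adenylated / ambiguous /
  unassigned, producing per-sample count tables with a conservation
  guarantee.
- **adenylation** (`mirtail.adenylation`) — applies the strict `>100`
  adenylated-count filter (sum-over-samples or every-sample mode), computes
  the adenylation level `adenylated / (adenylated + canonical) * 100` per
  miRNA per sample, and compares groups with one-way ANOVA plus Fisher's LSD
  post hoc tests.
- **screen** (`mirtail.screen`) — 2^-ddCt quantification against an internal
  control gene and averaged control-sample dCt, the internal-control-free
  2^-dCt variant, the "downregulated in disease AND restored on knockdown"
  selection (thresholds configurable and written into output headers), and a
  log2-fold heat-map matrix export.
- **assays** (`mirtail.assays`) — LDH relative cell death
  `sup / (sup + attached)`, firefly/Renilla luciferase ratio, and
  normalization of densitometry values to the control-sample mean.

## CLI

All stages are subcommands of `mirtail`:

```bash
# 1. synthesize a dataset with known truth
mirtail simulate --config cfg.yaml --outdir sim/ --seed 7

# 2. count canonical vs +A reads (manifest: TSV with sample, fastq[, group])
mirtail count --reference sim/reference.fasta --samples sim/manifest.tsv \
    --max-mismatch 0 --out counts.tsv

# 3. adenylation levels + ANOVA / Fisher's LSD
mirtail adenylation --counts counts.tsv --design sim/design.csv \
    --threshold 100 --mode sum --alpha 0.05 --out aden.tsv

# 4. ddCt quantification and the down-and-restored screen
mirtail screen --ct sim/qpcr_ct.csv --design sim/qpcr_design.csv \
    --control-gene U6 --down 0.8 --restore-low 0.8 --restore-high 1.25 \
    --out screen.tsv

# 5. plate-assay formulas
mirtail assays --mode ldh --in sim/ldh_plate.csv --out ldh_results.csv
```

A minimal simulate config:

```yaml
seed: 7
n_mirnas: 20
length_range: [20, 24]
samples:
  - {id: ctrl_1, condition: control, reads: 10000}
  - {id: dis_1, condition: disease, reads: 10000}
adenylation_prob:
  "*": {control: 0.05, disease: 0.3}   # "*" = default for all miRNAs
adapter: ""          # optional 3' adapter appended to every read
error_rate: 0.0      # per-base substitution probability
qpcr: {n_targets: 200, n_down_restored: 20, replicates: 3, noise_sd: 0.0}
assay:
  ldh: {true_death: [0.1, 0.25, 0.5]}
  luciferase: {true_ratio: [1.0, 2.0]}
```

## Notes on defaults

- Read assignment is length-exact; reads matching both references or several
  miRNAs are discarded as ambiguous by default (`--priority canonical`
  reproduces a canonical-wins policy).
- The `>100` adenylated-count filter is strict (`101` kept, `100` dropped)
  and defaults to the sum over all samples.
- Screen thresholds default to disease fold <= 0.8 and rescue fold within
  [0.8, 1.25] of control; both are reported in the output header and should
  be widened under Ct noise.
- Missing Ct values propagate as missing folds; zero-total count cells yield
  missing adenylation levels (never a silent 0).
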