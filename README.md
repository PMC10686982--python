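# regspot

Recurrent non-coding variant ("hotspot") discovery and scoring for cancer
whole-genome variant sets.

Somatic variant calls from many donors are merged by single-linkage chaining
(default: 3+ records within 25 bp), scored by donor recurrence
(donor score = D²/G, where D is the number of variant records and G the
number of distinct mutated positions) and weighted by a pre-computed
per-variant functional-impact track (hotspot score = donor score × mean
weight). Hotspots inside a regulatory-region set (union of peak BEDs minus
exons and an exclusion list) are tested against the empirical score
distribution of hotspots outside it, with Benjamini–Hochberg FDR control.
The package also provides strand-normalized offsets of variants to the
nearest ETS core (GGAA/TTCC), consensus-derived PWM construction and
log-odds scanning, simple feature annotation (promoter / exon / intron /
downstream / distal intergenic + nearest gene), and a fully deterministic
synthetic-data generator with a planted-hotspot truth manifest.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
reproduction, cohort arithmetic, oracle-equivalence properties, the
20-seed planted-recovery benchmark, and the motif suite).

## CLI

Subcommands compose into the full pipeline (`regspot --help` for flags):

```sh
# generate a synthetic benchmark dataset
regspot simulate --seed 1 --outdir sim/

# regulatory region set = union(peaks) - exons - blacklist
regspot build-pmrr --peaks peaks1.bed --peaks peaks2.bed \
    --exons exons.bed --blacklist bl.bed --out pmrr.bed

# merge + score hotspots
regspot call-hotspots --variants variants.tsv --window 25 --min-count 3 \
    --funseq funseq.bed --out hotspots.tsv

# compartments, empirical p-values, BH q-values
regspot test-hotspots --hotspots hotspots.tsv --pmrr pmrr.bed \
    --exons exons.bed --blacklist bl.bed --alpha 0.05 --out tested.tsv

# feature labels + nearest genes
regspot annotate --hotspots tested.tsv --genes genes.tsv --out annotated.tsv

# ETS-core offset histogram for variants in significant hotspots
regspot motif-offsets --hotspots tested.tsv --variants variants.tsv \
    --genome genome.fa --out offsets.tsv

# consensus-derived PWMs and scanning
regspot pwm-build --consensus CCGGAAGGCC --out pwm.tsv
regspot pwm-scan --consensus CCGGAAGGCC --regions pmrr.bed \
    --genome genome.fa --max-instances 50000 --seed 1 --out hits.bed

# or everything at once from a YAML config
regspot run --config pipeline.yaml --outdir out/
```

`pipeline.yaml` names the inputs:

```yaml
variants: sim/variants.tsv
peaks: [sim/pmrr.bed]
exons: sim/exons.bed
blacklist: sim/blacklist.bed
funseq: sim/funseq.bed
genome: sim/genome.fa   # optional; enables motif offsets
alpha: 0.05
```

Every output is accompanied by a `.manifest.json` recording version,
parameters, input digests and seed.

## Formats

- variants: VCF 4.x or a tab-separated table with header columns
  `donor_id chrom pos1 ref alt` (optional `funseq`, `gerp`); `pos1` is
  1-based, chromosome names are never normalized
- regions: BED3+ (0-based half-open); score track: 4-column BED-graph-like
  TSV with non-overlapping entries
- gene models: BED12 or a 6-column TSV
  (`gene_id chrom strand tx_start tx_end exons`)
- hotspot tables: TSV with `chrom start end n_variants n_positions
  donor_score mean_funseq hotspot_score compartment p_value q_value`
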