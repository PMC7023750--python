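# wpal

Toolkit for analyzing the female-specific (W) half of a plant ZW
sex-determination region: sexed-coverage identification of W-linked
sequence, detection of large DNA palindromes, gene-conversion signatures
between palindrome arms, Z–W gene homology and synonymous divergence, and
molecular-clock dating of LTR retrotransposon insertions. A fully
ledgered synthetic-data generator ties everything together, so every
detector can be validated end-to-end against planted ground truth.

## Background

In a ZW system females are the heterogametic sex (Z + W). The
sex-determination region (SDR) of the W stops recombining with the Z, and
from that moment on it accumulates a characteristic set of features:

* **Hemizygous sequence** present only on the W. Reads from males (ZZ)
  leave these regions empty, so the female/male depth-of-coverage contrast
  identifies them: pooled-by-sex genotyping depths plus deep resequencing
  of one individual per sex yield "female-specific" markers, and
  contiguous low-male-depth windows delimit W-specific regions.
* **Palindromes** — large inverted repeats with arms tens of kilobases
  long, often nested (multi-shell) and flanked by partial "pre-arm"
  copies. Arms of one palindrome stay nearly identical because gene
  conversion keeps homogenizing them.
* **Gene conversion between arms.** When reads from all arms of both of
  two sister species are collapsed onto a single arm reference,
  arm-private variants appear as paralogous sequence variants (PSVs,
  allele fractions near m/4 for four collapsed arms) while
  species-diagnostic sites appear as near-fixed differences. A converted
  tract is a PSV-free interval that still carries fixed interspecific
  differences at the elevated (~4N) depth of four collapsed copies.
* **Degenerating gene content.** W genes fall into recognizable classes:
  Z–W homologs (mutual best hits across haplotypes), tandem duplicates,
  genes transposed from autosomes, ancestral genes lost on the Z, and
  orphans. Synonymous divergence (dS) of Z–W pairs along the Z coordinate
  records when recombination stopped; a step in dS indicates evolutionary
  strata.
* **Transposable-element accumulation.** An LTR retrotransposon inserts
  with two identical long terminal repeats and a 5–20 bp target-site
  duplication; the divergence of the two repeats divided by twice the
  mutation rate (2.5e-9 substitutions/site/year) dates the insertion.

## Worked example

Simulate a ZW pair with a planted two-palindrome block, then detect the
palindromes from sequence alone:

```python
from wpal import synthetic_data as sd, palindrome_detect as pdx

config = sd.SimulationConfig(seed=1)
truth = sd.simulate_zw_pair(config)
print(f"W length: {len(truth.w_sequence):,} bp; "
      f"{len(truth.hemizygous_intervals)} hemizygous intervals; "
      f"{len(truth.ltr_elements)} LTR elements")

palindromes, secondary = pdx.detect_palindromes(truth.w_sequence)
for p in palindromes:
    print(p.report().to_string(index=False))
```

Output:

```
W length: 611,377 bp; 12 hemizygous intervals; 3 LTR elements
name component  start    end  size orientation
W.P1   pre-arm 154044 166043 12000           +
W.P1      arm1 166044 186043 20000           +
W.P1      arm2 189644 209643 20000           -
W.P1   Spacer1 186044 189643  3600           .
name component  start    end  size orientation
W.P2     arm3a 212344 232343 20000           +
W.P2     arm3b 235344 243343  8000           +
W.P2     arm4b 243344 251343  8000           -
W.P2     arm4a 254344 274343 20000           -
W.P2   Spacer2   <NA>   <NA>  <NA>           .
```

The detector recovers the planted structure exactly: palindrome 1 with a
located spacer and a partial pre-arm copy, and palindrome 2 as a nested
(multi-shell) palindrome whose inner arms abut — its spacer is reported
as unidentified. Coordinates are 1-based inclusive, so every component
satisfies `size = end − start + 1`.

## Command line

The `wpal` entry point wraps the main stages:

```
wpal simulate  --seed 1 --out truth/          # write a ledgered synthetic genome
wpal sexlink   --gbs gbs.tsv --out markers.tsv
wpal palindrome --fasta genome.fasta --chrom Chr15W --out palindromes.tsv
wpal geneconv  --sites sites.tsv --reference-length 20000 --out tracts.tsv
wpal ltrdate   --fasta genome.fasta --out ages.tsv
wpal run       --config pipeline.yaml         # full pipeline with run report
```

`wpal run` executes simulate → sexlink → palindrome → geneconv → zwgenes
→ ltrclock, derives one deterministic sub-seed per stage, checksums every
output, and supports `--resume`.

## Modules

| module | contents |
| --- | --- |
| `synthetic_data` | ZW-pair simulator with full ground-truth ledger: hemizygous insertions, palindrome block, conversion tracts, LTR elements, gene sets, sexed read depths, pooled GBS intervals, collapsed-arm pileups |
| `coverage_sexlink` | windowed median depth, log2 depth ratios, the two-rule female-specific marker classifier, W-contig and W-specific-region calls, marker recoding |
| `palindrome_detect` | inverted k-mer seeding (k=100, step 20), anti-diagonal chaining, exact + block-tolerant extension, alignment verification, palindrome assembly with shells/spacers/pre-arms, arm divergence profiles |
| `gene_conversion` | variant filtering (Q20 / depth ≤ 300), PSV vs fixed-difference classification, 100-bp density tracks, relative depth in N units, converted-region detection |
| `zw_homology` | all-vs-all protein search, mutual best hits, tandem arrays, gene categorization, codon alignment, NG86 dS/dN with Jukes–Cantor correction, strata scan |
| `ltr_clock` | direct-repeat detection with TSD pinning, K2P and gamma-K2P distances, insertion ages with column bootstrap, autonomy classification |
| `pipeline_cli` | YAML-configured end-to-end pipeline with per-stage seeds, checksums and resume |

## Validation

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
runs the whole workflow at a given seed and writes the headline quantities
(marker sensitivity/FPR, tract recovery, gene-category accuracy, dS, LTR
age errors, strata detection) as JSON. The pytest suite (`pytest -q`)
covers every module, including property-based checks against independent
oracles (brute-force seed enumeration, pathway-enumeration NG86,
closed-form K2P) and parameter-recovery runs against the simulator's
truth ledger.
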