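# oncopanel

Design and evaluate cost-effective cancer gene sequencing panels from
somatic mutation cohorts.

Given a mutation cohort (MAF-like TSV), gene exon models (BED) and one
or more candidate gene lists, the tool:

1. **Detects mutational hotspots** per gene — iteratively extracting the
   ≤100 bp window with the most protein-affecting mutations (PAMs) until
   every remaining site has fewer than two, and keeping the hotspots only
   if they jointly capture ≥80% of the gene's PAMs (otherwise the whole
   exome is used). Both thresholds are configurable.
2. **Ranks candidates greedily** by marginal contribution to the
   cumulative mutational frequency (CMF) — the fraction of cohort
   samples with a PAM in at least one selected item.
3. **Classifies three tiers** by comparing each item's marginal gain to
   the slope of the CMF regression line (Tier 1 ≥ slope, doubled under
   the stringent option; Tier 3 contributes nothing).
4. **Evaluates cost-effectiveness** of any panel (designed or external
   BED) on any cohort: coverage at depth k = 1, 2, 3 distinct regions
   versus total DNA targeted (Kbps), with multi-panel comparison tables.
5. **Annotates** mutations and genes against user-supplied TSV catalogs
   (validated oncogenic mutations, drug response/resistance biomarkers,
   gene mode of action and clonality).

A fully deterministic **simulator** generates synthetic cohorts with
implanted hotspots and known ground truth, so the whole pipeline is
testable offline.

## CLI

```sh
# generate a synthetic cohort with ground truth
oncopanel simulate --seed 42 --n-samples 100 --n-genes 20 --out sim/

# design a panel (hotspots on by default)
oncopanel design --cohort sim/cohort.tsv --samples sim/samples.txt \
    --genes sim/drivers.txt:driver --models sim/exons.bed --out design/
# -> design/panel.tsv, design/panel.bed, design/summary.json, design/manifest.json

# evaluate any panel BED against a cohort
oncopanel evaluate --cohort sim/cohort.tsv --panel-bed design/panel.bed \
    --driver-catalog sim/drivers.txt --out eval/

# compare several panels (coverage vs Kbps, bubble-plot data)
oncopanel compare --cohort sim/cohort.tsv \
    --panel-bed mine=design/panel.bed --panel-bed other=other_panel.bed --out cmp/

# annotate mutations against catalogs
oncopanel annotate --cohort sim/cohort.tsv --oncogenic sim/oncogenic.tsv \
    --biomarkers sim/biomarkers.tsv --gene-catalog sim/gene_catalog.tsv --out ann/
```

Useful design flags: `--no-hotspots`, `--max-hotspot-bp` (default 100),
`--min-captured-fraction` (default 0.8), `--stringent`, `--flank-bp`.
Exit codes: 0 success, 1 usage error, 2 data/format error.

## Conventions

* Mutation tables are 1-based inclusive (`simple_tsv` columns:
  sample/gene/chrom/pos/ref/alt/consequence, or standard MAF headers via
  `--dialect maf`); all BED I/O is 0-based half-open.
* PAM classes: missense, nonsense/stop-gain, stop-loss, start-loss,
  splice-site, frameshift and in-frame indels. Unknown consequence
  strings are treated as non-protein-affecting with a warning.
* Hotspot windows are measured in genomic coordinates (they may span
  intron gaps); indels count at their start position.
* Duplicate mutation rows (same sample/gene/pos/alt) are deduplicated;
  samples listed in a `--samples` manifest stay in the coverage
  denominator even with zero mutations.

## Layout

```
src/oncopanel/
  cohort_io.py   mutation/gene-model/gene-list/BED I/O, PAM classification
  hotspots.py    iterative max-count window extraction, whole-exome fallback
  design.py      greedy CMF ranking, tier assignment, panel assembly
  evaluate.py    coverage-vs-Kbps scoring and panel comparison
  annotate.py    oncogenic / biomarker / gene-catalog joins
  simulate.py    synthetic cohorts with ground truth
  cli.py         command-line entry points
tests/           unit, property (hypothesis) and acceptance suites
scripts/         acceptance report generator
```
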