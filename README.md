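# hydroxyscape

Genome-wide analysis of 5-hydroxymethylcytosine (5-hmC) enrichment
sequencing — and, more generally, of any enriched-mark tag library paired
with an unenriched input control — aimed at epigenomics researchers who
want the full integration workflow (signal tracks, peak calls, feature
enrichment, sequence composition, positional profiles) as a tested,
scriptable Python library rather than a chain of one-off scripts.

5-hmC is the Tet-oxidation product of 5-methylcytosine. Affinity-enriched
sequencing of 5-hmC-containing fragments yields aligned single-end tags
whose genome-wide density, relative to an input library, localises the
mark; bisulfite sequencing cannot separate 5-hmC from 5-mC, which makes
this enrichment-based readout (and its integration with histone-mark ChIP,
MeDIP and methyl-seq data) the practical route to studying the mark.

## What it computes

Given tag libraries (BED-converted alignments), a chromosome-size table,
and annotations (genes with RPKM, CpG islands, chromatin-signature promoter
and enhancer classes, TF binding sites), the package computes:

* **Binned signal** — tags counted by 5′ coordinate into fixed-width bins
  (1/5/10 kb), normalised to reads per million (RPM = count / (N/10⁶)),
  with the identically processed input subtracted per bin.
* **Chromosome densities** — observed reads/million per chromosome against
  the chance expectation 10⁶·L_c/L_G, optionally halved for haploid sex
  chromosomes.
* **Cross-mark correlation** — squared Pearson r over genome-wide bins
  between two input-corrected tracks; coverage-weighted percent-methylation
  tracks (100·Σmeth/Σtotal per bin) from per-cytosine call tables.
* **Peaks** — a sliding-window local-lambda Poisson scan: each window's
  background rate is the most conservative of a genome-wide rate and local
  rates over 200-bp/1000-bp flanking ranges (estimated from input, scaled
  to IP depth); significance is the Poisson upper tail P(X ≥ k; λ_local)
  at p ≤ 10⁻⁸; nearby significant windows merge.
* **Feature enrichment** — the fraction of peaks overlapping an annotation
  by ≥ 1 bp versus the fraction expected from the annotation's base
  coverage, and their ratio (fold over expected); member-level Venn-style
  overlap counts between interval sets.
* **Sequence composition** — pooled dinucleotide observed/expected ratios
  (O/E = observed 2-mer frequency / product of mononucleotide frequencies),
  per-region GC content with cumulative distributions, and length-matched
  random-region nulls.
* **Positional profiles** — expression-stratified TSS/TES metagenes
  (100-bp bins, ±5 kb), three-segment profiles at chromatin-signature
  classes (4-kb core plus 4-kb flanks, 120 columns), and length-scaled
  TF-site profiles (40 portions per segment), all strand-aware, RPM
  normalised and input-subtracted.
* **Synthetic studies** — a generator that plants enhancer folds, bimodal
  (TSS-depleted) vs unimodal promoter intensity shapes, expression-stratum
  gene-body folds, CpG-island-like sequence and methylation structure, then
  draws IP/input libraries from the implied intensity, with a
  machine-readable truth record for recovery testing.

## Worked example

Run the whole pipeline on a simulated two-chromosome 4 Mb study:

```yaml
# cfg.yaml
out_dir: out
seed: 11
simulation:
  chrom_lengths: [2000000, 2000000]
  n_genes: 80
  n_enhancers: 40
  ip_tags: 300000
  input_tags: 300000
n_random_regions: 500
```

```bash
hydroxyscape run --config cfg.yaml
```

prints the per-stage manifest, ending with (abridged):

```
"deduplicate":       {"ip_tags": 290501, "input_tags": 294562},
"correlation":       {"n_bins_used": 400, "r_squared": 0.0386},
"call_peaks":        {"peaks": 192},
"set_overlap":       {"n_a": 192, "n_b": 40, "a_overlapping_b": 40, "b_overlapping_a": 40}
```

and `out/feature_association.tsv` contains

```
feature     n_peaks  n_overlapping  observed_fraction  expected_fraction  fold_change
enhancers   192      40             0.2083             0.0100             20.83
cgi_like    192      49             0.2552             0.0105             24.31
```

Read: 192 regions passed the p ≤ 10⁻⁸ cutoff; every planted enhancer was
recovered (40/40 both directions); 20.8% of peaks fall in enhancers that
cover 1% of the genome — a 20.8-fold enrichment over chance, reflecting
the planted fold-8 enhancer intensity concentrating peak calls there. The
low r² (0.039) between the 5-hmC-like signal and percent CG methylation is
expected at these library sizes: methylation is near-uniform outside
islands, so shared spatial structure is weak.

The same stages are available as library calls
(`hydroxyscape.run_pipeline`, or the individual functions in
`signal_binning`, `peak_enrichment`, `track_correlation`,
`sequence_composition`, `feature_profiles`) and as subcommands
(`simulate`, `bin-tags`, `call-peaks`, `associate-features`,
`overlap-sets`, `seq-comp`).

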