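# irkit

Intron retention (IR) analysis for bulk RNA-seq cohorts: quantify per-intron
retention from spliced alignments, count IR events per sample under strict
cohort filters, call differentially retained introns with beta regression,
screen expression for retention correlates and condition-exclusive genes,
and test RNA-binding-protein (RBP) motif enrichment around splice sites.

## Who it is for and what it does

Intron retention — an intron surviving splicing into the mature transcript —
is a widespread form of alternative splicing that is dysregulated in many
cancers. Comparing IR between tumours and matched normal tissue requires
careful read-level accounting: intronic depth must be weighed against
splice-junction evidence, and poorly supported introns filtered before any
per-sample burden statistic is meaningful. `irkit` implements that pipeline
for transcriptomics researchers, end to end, with a ground-truth simulator
so every stage can be validated without any controlled-access data.

For each intron and sample the package computes the intron depth `ID`
(median per-base depth), `coverage`, the flanking junction reads `SL`/`SR`,
the exact-junction reads `SE`, and the IR ratio

```
IR = ID / (ID + max(SL, SR))
```

the estimated fraction of the gene's transcripts retaining the intron.
Introns enter the per-sample IR event count only if, cohort-wide,
0.7 ≤ SL/SR ≤ 1.3, (SL+SR) > 10 and coverage > 0.5 each hold in ≥ 50% of
samples, and IR > 0.05 in ≥ 50% of at least one group; an **IR event** is a
filtered intron with IR > 0.1 in that sample. Differential retention is
tested per intron by beta regression, y ~ Beta(μφ, (1−μ)φ) with
logit(μ) = β₀ + β₁·group, a Wald test on β₁, Benjamini–Hochberg FDR, and
the call rule |ΔIR| > 0.1 with q < 0.05 (ΔIR = mean IR in cancer − normal).
The Audic–Claverie exact test covers low-replicate designs. Motif
enrichment scans 50-nt exonic/intronic flanks of every splice site (in
transcript orientation) with PWMs at an exactly calibrated log-odds
threshold and compares hit frequencies between retained and non-retained
introns with Student's t test. See `docs/methods.md` for the full model
description and assumptions.

## Worked example

Simulate a 20+20-sample tumour/normal cohort (40 introns, 20% with a
planted retention increase of 0.2) and run the pipeline:

```
$ irkit simulate cohort --out demo --seed 3
40 samples, 40 introns -> demo

$ irkit build-ref --gtf demo/annotation.gtf --out-bed demo/introns.bed
40 introns from 20 genes -> demo/introns.bed

$ for sam in demo/sams/*.sam; do s=$(basename $sam .sam); \
    irkit quantify --sam $sam --ref-bed demo/introns.bed \
      --gtf demo/annotation.gtf --sample-id $s --out demo/quants/$s.tsv; done

$ irkit filter --quant-dir demo/quants --meta demo/metadata.tsv \
    --out-mask demo/mask.tsv --out-events demo/events.tsv
40/40 introns pass all filters

$ irkit diff-ir --quant-dir demo/quants --meta demo/metadata.tsv \
    --mask demo/mask.tsv --out demo/dir.tsv
8 differentially retained introns -> demo/dir.tsv
```

All 40 simulated introns are deeply covered with balanced junctions, so all
pass the cohort filters; cancer samples average 21.15 IR events vs 19.40 in
normals. The 8 significant introns are exactly the 8 the simulator planted
(recall 1.0, no false calls). The first rows of `demo/dir.tsv`:

```
intron_id             mean_ir_normal  mean_ir_cancer  delta_ir  q         significant  direction
chr1:220-280:+:G0000  0.0865          0.2926          0.2061    3.3e-17   True         up
chr1:400-460:+:G0000  0.1039          0.0956          -0.0083   0.596     False        ns
```

The planted intron shows the injected ~0.2 retention increase; the null
intron sits at its baseline with q ≈ 0.6. The exact test for two-library
designs is also exposed directly:

```
$ irkit ac-test --x 5 --y 25 --n1 1e6 --n2 1e6
p = 0.000324914
```

Library calls mirror the CLI one-to-one (`irkit.quantify.collect_alignments`,
`irkit.filters.apply_cohort_filters`, `irkit.diffir.run_differential_ir`,
`irkit.motifs.motif_region_enrichment`, ...), returning pandas objects.

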