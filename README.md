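# tsrna-nrs

Transfer RNAs are processed into tRNA-derived small RNAs (tsRNAs). A
Dicer-dependent subset of these, loaded onto Ago2, silences genes by a
nuclear route distinct from classical post-transcriptional or
transcriptional silencing: the tsRNA guides Ago2 to *intronic* sequence of
the nascent transcript, which is cleaved before splicing completes —
nascent RNA silencing (NRS).

`tsrna-nrs` implements the complete computational route from raw
small-RNA reads to a catalogue of NRS target genes, and — because the
real inputs are deposited sequencing libraries — pairs it with a
synthetic-data generator that emulates every input with *planted, recorded
ground truth*, so each stage can be tested against what was actually put
in. It is aimed at people building or auditing small-RNA target-discovery
pipelines.

The stages, with their decision rules:

1. **Read preprocessing** — 3' adapter (full or partial) trimming,
   minimum insert 18 nt; collapse to unique sequences; a feature must be
   supported by more than one read.
2. **tRNA origin annotation** — ungapped best-stratum alignment (≤3
   mismatches, the behaviour of `bowtie -v3 --all --best --strata`)
   against mature, mature+CCA, pre-tRNA and ±7 nt flanked forms;
   hierarchical classes `tRNA_CCA_end > tRNA_3p_end > tRNA_5p_end >
   pre_tRNA > tRNA_other`.
3. **Differential abundance** — median-of-ratios normalisation and a
   negative-binomial Wald test (method-of-moments dispersion, t reference)
   per unique tsRNA feature and per gene; thresholds padj < 0.005 (Dicer,
   Ago2 knockdown chromatin RNA), < 0.05 (Drosha), < 0.001 (mRNA).
4. **PAR-CLIP selection** — reads equalized to their genomic sequence
   (reverting T→C crosslink conversions), length 18–22 nt, occurrence ≥25
   in every Ago set and ≥323/41/19 in a Dicer replicate; grouping of
   near-identical sequences (one terminal nucleotide per step); Dicer
   dependence = |log2FC| > 1 in small-RNA-seq.
5. **Target prediction** — miRanda-style scan of each tsRNA against full
   unspliced gene bodies: local alignment under complementarity scoring
   (+5 match, +1 G:U, −3 mismatch, −9/−4 affine gaps), tsRNA seed
   positions 2–8 scaled ×4, reported at score ≥ 150 with nearest-neighbor
   duplex energy ≤ −30 kcal/mol (relaxed cross-species mode: score ≥ 140,
   no energy filter).
6. **Integration** — Venn of knockdown-upregulated genes (universe =
   Dicer ∩ Ago2 − Drosha), intron/exon target partition, intronic
   metagene at x = (i + p)/N, rank-sum conservation comparison,
   cross-species conservation fraction (a homolog is conserved when ≥90%
   of the human gene's tsRNAs also hit it), one-sided Fisher
   gene–disease enrichment, and the tRNA-expression vs tsRNA-abundance
   Spearman correlation.

## Worked example

The numbered scripts under `analysis/` run one deterministic synthetic
study (seed 42: 20 tRNA genes, 40 genes, 10 with planted intronic target
sites) end to end:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_preprocess_and_annotate.py
python analysis/03_differential_abundance.py
python analysis/04_select_tsrnas.py
python analysis/05_predict_targets.py
python analysis/06_integrate.py
```

The final script prints (among other lines):

```
metagene: 32 intronic sites; 81% of density in the first quarter of intron space
conservation, dependent vs other sites: medians 0.83 vs 0.27, rank-sum p = 2.09e-04
mouse homologs conserved (fraction >= 0.9): 9 of 9
tRNA expression vs tsRNA abundance: Spearman rho = 0.52 (p = 0.0199)
truth check: planted recall 100%, false inclusion 0%
```

Reading: all ten genes that the generator seeded with intronic tsRNA
target sites are recovered in the final intronic target partition, no
unplanted gene is called (recall 100%, false inclusion 0%); predicted
sites concentrate in early introns (the metagene's first quarter), sites
of Dicer-dependent tsRNAs sit on markedly higher conservation scores than
other sites, and every evaluable mouse homolog retains the planted sites
it was given. The same run is available as one call:

```sh
tsrna-nrs run --seed 42 --outdir results/study
```

which writes per-stage TSVs, `report.json` and a provenance log
(parameters, seed, input hashes); identical configurations reproduce the
bundle byte for byte.

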