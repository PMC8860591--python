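# Methods

This note records the models, parameter choices and known limits of the
package; every number quoted here is computed by the test suite, the
analysis scripts or `scripts/acceptance.py`.

## The synthetic study

Real NRS discovery runs on deposited sequencing libraries. The generator
(`tsrna_nrs.simulate`) replaces them with inputs whose answers are known:

* **tRNA reference.** `n` genes with mature bodies of 60–90 nt, the
  anticodon near position 34, 5' leaders and 3' trailers of 5–20 nt, and a
  10–30 nt intron just 3' of the anticodon loop in ~25% of genes (the
  canonical intron position). Four sequence forms are emitted per gene —
  mature, mature+CCA, pre-tRNA (leader + unspliced body + trailer) and the
  pre-tRNA with ±7 nt genomic context — as FASTA plus a sidecar table.
  All sequence is DNA alphabet; U on input maps to T.
* **Fragment universe.** Each tRNA yields fragments from eight classes:
  CCA-terminal 18–22-mers, 3'-end 18–24-mers, 5'-end 26–32-mers, 5' and 3'
  halves (30–38 nt), internal 23–30-mers, trailer fragments (tRF-1-like)
  and leader-junction fragments. Fragment abundance couples to a lognormal
  tRNA expression level through a per-tRNA "processing efficiency" noise
  term (lognormal, σ=1.2), which leaves a moderate positive
  expression–abundance correlation rather than a deterministic one. The
  halves carry the largest abundance weights: they dominate real small-RNA
  libraries, are Dicer-independent, and it is exactly this unchanged bulk
  that anchors median-of-ratios normalisation when whole fragment classes
  are depleted by the knockdown.
* **Reads.** Counts per fragment and replicate are negative binomial with
  variance μ + αμ² (α = 0.1 throughout). Dicer knockdown multiplies the
  mean of affected fragments by 2^lfc, with true lfc ~ U(−3.5, −2) for the
  CCA-end, 3'-end and trailer classes and 0 elsewhere. Reads carry the 3'
  library adapter (80% full, 15% partial) and substitution errors at 0.5%
  per base, capped at three — matching the mapper's mismatch tolerance;
  indels are out of model, qualities are constant. Defaults: 3 replicates
  per condition, 20 000 reads per sample.
* **PAR-CLIP sets.** Candidate tsRNAs (18–22 nt fragments with measurable
  library coverage) receive occurrences above every threshold in the Ago1–4
  and Dicer rep1–3 sets; part of each candidate's mass is emitted as a
  one-base T→C conversion variant (the crosslink signature), and some
  candidates also appear as one-terminal-nt genomic extensions to exercise
  grouping. Decoys fall below the occurrence thresholds, exceed the length
  window, or are random non-tRNA sequence.
* **Gene space.** One gene per synthetic chromosome: 3–8 exons of 80–300
  nt; the first intron is drawn longer (800–2000 nt) than the rest
  (200–1200 nt), so "early intron" placement is meaningful. A planted gene
  receives 1–2 intronic sites — the reverse complement of an assigned
  Dicer-dependent tsRNA, with an early-intron bias — verified at planting
  time by rescoring with the scanner (score ≥ 150 and duplex energy ≤ −30;
  a tsRNA whose duplex cannot clear the energy bar is swapped out). Half
  of the planted genes also receive a site for a Dicer-*independent*
  candidate, which exercises the dependence restriction and provides the
  "other" group for the conservation comparison.
* **Knockdown expression.** Chromatin-RNA counts for control, shDicer,
  shAgo2 and shDrosha: planted genes are derepressed (lfc ~ U(3, 4)) under
  shDicer and shAgo2 but not shDrosha; two unplanted genes respond in all
  three knockdowns (miRNA-like, removed by the Venn exclusion) and two in
  shDrosha only. Five replicates per condition. These effect sizes and the
  replicate count are the study's own design point: the deliberately
  unshrunk NB test (below) at padj < 0.005 needs either of them; the
  printed significance thresholds are never touched.
* **Homologs, conservation, disease.** Mouse homologs are 5%-mutated
  copies of the human gene region; planted site regions are copied
  verbatim for exactly round(conservation_fraction × n_mapped) pairs
  (seeded shuffle) and replaced with random sequence otherwise — exact
  allocation, so the parameter is identifiable. One planted gene is left
  out of the homolog map to exercise the drop-and-log path. The
  conservation track holds 25-nt bins of U(0.05, 0.45) baseline scores
  with planted dependent sites elevated to U(0.75, 0.98). Disease labels
  are Bernoulli with the requested odds ratio for planted genes
  (background association probability 0.25, 12 diseases in 4 classes);
  synonym aliases and a deliberate NCBI/Ensembl symbol mismatch exercise
  universe construction.

Identical seeds give byte-identical files everywhere.

## The NB test

The differential stage is a transparent replacement for a shrinkage
estimator pipeline: median-of-ratios size factors (rescaled to geometric
mean 1), per-feature method-of-moments dispersion α̂ = mean over the two
conditions of (s² − m)/m², floored at 1e−8, log2 fold change on
pseudocounted (0.5) normalised means computed as a difference of logs (so
label swap negates it bitwise), a delta-method standard error from the NB
variance μ + α̂μ², and a Wald statistic referred to a **t distribution
with nA + nB − 2 degrees of freedom**. The t reference is the small-sample
correction for the estimated SE: with three-vs-three replicates it puts
the null type-I error at p < 0.05 near 0.05 (measured 0.046–0.050 on
2000-feature null simulations), where a normal reference is markedly
anti-conservative. There is no dispersion or fold-change shrinkage and no
independent filtering; the cost is power, which the synthetic study
compensates with replicates and effect size, not with looser thresholds.
Multiple testing is Benjamini–Hochberg.

## Scoring and energy model

The scanner aligns the reversed tsRNA to the gene sequence with
Smith–Waterman/Gotoh under complementarity scoring (A:T, G:C = +5;
G:U = +1; mismatch = −3; gap open −9, extend −4). Column scores at tsRNA
positions 2–8 (1-based from the 5' end) are multiplied by 4.0;
**gap penalties are not seed-scaled** (documented convention; the
independent test oracle shares it). A perfect 22-mer complement scores
15·5 + 7·5·4 = 215. The per-gene scan is column-vectorised; the vertical
affine-gap recurrence is resolved by a prefix scan, exact because
gap_open < gap_extend (a gap re-opened from a gap-derived cell can never
beat extending the existing gap). Non-overlapping local optima are taken
greedily by descending score per tsRNA/gene pair.

Duplex energy is a simplified nearest-neighbor sum: Watson–Crick stacks
from a Turner-style table keyed by the tsRNA dinucleotide, a flat
−1.0 kcal/mol for stacks involving a G:U pair, +4.09 initiation, +0.45
per weak (A:T or G:U) terminal pair; mismatches and gaps interrupt
stacking — no loop thermodynamics or accessibility. This reproduces the
qualitative behaviour of the −30 kcal/mol filter (GC-rich 20-mers pass,
AT-rich ones fail) and nothing more.

### Chance hits in relaxed mode

At the relaxed threshold (score ≥ 140, no energy filter) a perfect 7-nt
seed match alone reaches threshold, so random sequence yields on the
order of 0.2–0.6 sites per kb per tsRNA. Two consequences, both
deliberate: (i) the full-gene cross-species scan in the default scenario
reports an honestly *inflated* conserved-homolog count (chance hits make
unconserved full-length homologs look targeted); (ii) the
conservation-recovery fixture therefore uses orthologous site *loci*
(planted site ± 150 nt) as the homolog unit, and additionally verifies at
generation time that scrambled loci contain no chance hit — the mirror
image of the positive-site verification. On that fixture the recovered
fraction equals the generator parameter exactly (0.700 on 150 pairs).

## Statistics

* Venn/partition/metagene are exact set arithmetic; the metagene
  coordinate is x = (i + p)/N over the ordered intron space (the only
  reading under which "early introns" is expressible); a within-intron
  variant (x = p) is available.
* The conservation comparison is a two-sided Mann–Whitney rank-sum test
  (scipy, exact method for small groups).
* Fisher enrichment is the exact hypergeometric upper tail evaluated in
  integer arithmetic, which is what makes agreement with scipy's tail to
  1e−12 over all 2×2 tables with N ≤ 60 attainable.
* Spearman's ρ uses mid-rank ties; the p-value is an exact permutation
  enumeration for n ≤ 9 and the t approximation otherwise.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_length` | 18 nt | insert floor after adapter trimming |
| `max_mismatch` | 3 | aligner mismatch tolerance |
| `length_min/max` | 18/22 nt | PAR-CLIP working window |
| `ago_min_occurrence` | 25 | per-Ago-set occurrence floor (`each_set`; `combined` sums) |
| `dicer_rep_min` | 323/41/19 | per-replicate Dicer floors (library-size driven) |
| `dicer_dep_threshold` | 1.0 | sRNA-seq \|log2FC\| rule (`absolute`; `negative` exposed) |
| `chr_alpha_*` | 0.005/0.005/0.05 | chromatin-RNA padj thresholds (Dicer/Ago2/Drosha) |
| `score_threshold` | 150 | strict alignment score floor |
| `energy_threshold` | −30 kcal/mol | strict duplex energy ceiling |
| relaxed score | 140 | cross-species run, energy filter off |
| `conservation_threshold` | 0.9 | fraction at which a homolog counts as conserved |
| pseudocount | 0.5 | fold-change stabiliser for sparse counts |
| dispersion α | 0.1 | NB variance parameter of the counts model |

Open readings resolved as package choices: "25 times in all AGO sets" is
read per-set (`each_set`), with the summed reading one flag away; the
Dicer rule is an OR across replicates; end-boundary rules in annotation
tolerate zero slack (configurable); grouping allows one terminal
nucleotide per edge with transitive closure; cluster-level Dicer
dependence is assessed on summed member counts; 3'-end and CCA-end reads
are separate classes.

## What passing tests do and do not show

The generator plants clean, strong signals: perfect-complement sites,
well-separated effect sizes, substitution-only errors, one gene per
chromosome, plus strand only, no isoforms, no ligation or PCR bias, no
multi-locus tRNA families beyond shared 3' ends. Recovering 100% of
planted targets here demonstrates that the pipeline's logic and
thresholds compose correctly — not that the thresholds are optimal for
real libraries, where crosslink efficiency, repeat-derived multimapping
and dispersion heterogeneity all bite. The acceptance checks are
correspondingly property-based (oracle equivalence, calibration,
parameter recovery, determinism) rather than comparisons to any
published count.

Problem sizes in the default runs — 20 tRNA genes, 40 genes with 10
planted, 20 000 reads per sample, 150 conservation pairs, 2000-feature
calibration — are the package's chosen desk-scale study conditions.
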