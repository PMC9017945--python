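# poetools

Allele-resolved analysis of parent-of-origin effects in *Arabidopsis*-style
triploid endosperm: small-RNA quantification and cluster calling,
reference-normalized differential abundance, dosage-aware DMR calling,
imprinting classification, and inference of antagonistic maternal/paternal
regulatory effects — together with a ground-truth synthetic-data generator
that emulates the reciprocal-cross experimental design end to end.

## Who this is for

Endosperm is a triploid seed tissue carrying two maternal genomes for every
paternal one. Crossing wild-type plants reciprocally to mutants of RNA
polymerase IV (the polymerase that initiates 24-nt siRNA biogenesis in the
RdDM pathway) yields four genotypes — WT, mutant-mother heterozygote
(`mat_het`), mutant-father heterozygote (`pat_het`), and the homozygous
null — whose sRNA, mRNA and methylome differences separate the *maternal*
from the *paternal* contribution of the polymerase. `poetools` implements
the analysis layer of such experiments for users who start from aligned
reads and SNP tables between the two parental accessions.

The scientific core:

- **Allele assignment.** Reads are assigned maternal/paternal by voting
  over the accession SNPs they cover against the reference and the
  SNP-substituted pseudogenome (identical coordinate frames, so no
  liftover). In balanced endosperm the maternal fraction of DNA-derived
  reads recovers the genome dosage, E[%maternal] = 2/3.
- **Reference-feature library-size normalization.** Because most
  TE-derived siRNAs vanish in the Pol IV null, global median-of-ratios
  size factors mistake biology for sequencing depth. Size factors are
  computed over a caller-chosen reference set (genic + miRNA features)
  only:  `s_j = median_i (K_ij / (prod_j K_ij)^(1/m))` over reference
  features `i`.
- **NB Wald differential test.** Per feature, counts are modeled as
  NB(μ·s_j, α); the Wald statistic log2(μ̂_B/μ̂_A)/SE uses a delta-method
  SE with an empirical-Bayes-moderated method-of-moments dispersion and a
  t reference with n_A+n_B−2+d₀ degrees of freedom. Calls require
  |log2FC| ≥ 1, BH-adjusted p ≤ 0.05, and a reference-condition mean ≥ 5.
- **Windowed DMR calling with endosperm filters.** 300-bp/100-bp-step
  windows, ≥3 cytosines informative in both samples, mean depth ≥ 6,
  conversion QC on the chloroplast (≥98%), retention only of windows whose
  DNA reads are 67±15% maternal, replicate-variability masking, and
  context thresholds ΔCHH ≥ 10, ΔCHG ≥ 20, ΔCG ≥ 30 percentage points.
- **Antagonism.** For each gene the two heterozygote contrasts estimate a
  maternal effect β_mat and paternal effect β_pat; with no zygotic
  effect the null should show their *sum* (log2-additive prediction). The
  analysis partitions misregulated gene sets, tests enrichment of
  opposite-direction changes (hypergeometric), and fits the inverse
  mat/pat relationship by OLS.

## Worked example

```python
from poetools import simulate as sim, diffex, antagonism

cfg = sim.SimulationConfig(seed=7)
genome, snps, annotations, truth = sim.simulate_genome_and_snps(cfg)
total, mat, pat = sim.simulate_mrna_counts(truth)

groups = total.sample_meta["genotype"].to_dict()
res = {g: diffex.run_differential(total, groups, "WT", g)
       for g in ("mat_het", "pat_het", "null")}
summary = antagonism.antagonism_summary(res["mat_het"], res["pat_het"],
                                        res["null"])
print(f"genes misregulated in both heterozygotes: {summary['n_shared']}")
print(f"  of those, opposite direction:           {summary['n_opposite']}")
for label, fit in summary["slopes"].items():
    print(f"slope({label}): {fit['slope']:.2f}  (n={fit['n']})")
```

prints

```
genes misregulated in both heterozygotes: 48
  of those, opposite direction:           30
slope(mat_only): -0.73  (n=58)
slope(mat_and_null): 0.19  (n=76)
```

Reading: of the 48 genes significantly misregulated in *both* reciprocal
heterozygotes, 30 move in opposite directions — the planted antagonistic
panel. Genes misregulated maternally but silent in the null (`mat_only`)
show a clear inverse maternal/paternal relationship (negative slope):
their maternal effect is partially cancelled by an opposing paternal
effect, which is exactly why they disappear in the double mutant. Genes
whose maternal effect persists in the null show no such inverse relation.

A shell workflow over files uses the CLI:

```bash
poetools simulate --seed 7 --outdir ds/
poetools allelic  --reads ds/srna_WT_rep1.tsv --genome ds/genome.fa \
                  --snps ds/snps.vcf --features ds/annotations.bed \
                  --out allelic_WT.tsv
poetools srna     --reads ds/srna_WT_rep1.tsv --genome ds/genome.fa \
                  --outdir srna_WT/
poetools methylome --cx-a ds/methylome_WT_rep1.cx.tsv \
                   --cx-b ds/methylome_null_rep1.cx.tsv \
                   --genome ds/genome.fa --outdir dmrs/
```

## Layout

| module | contents |
| --- | --- |
| `poetools.io` | formats (FASTA, VCF subset, BED/GFF3, bedGraph, alignment TSV, CX methylation TSV) and the shared 0-based half-open coordinate model |
| `poetools.simulate` | synthetic endosperm datasets with ground truth |
| `poetools.allelic` | pseudogenome construction, allele assignment, per-feature allelic tallies |
| `poetools.srna` | deduplication, size binning, window/feature counting, cluster calling |
| `poetools.diffex` | reference-normalized NB differential abundance |
| `poetools.methylome` | context pileup, conversion QC, window methylation, dosage filter, DMR calling |
| `poetools.imprinting` | 20/80 allelic-bias classes, ISR summaries, hypergeometric enrichment |
| `poetools.antagonism` | set partitioning, opposite-direction test, additive prediction, inverse-slope fits |
| `poetools.integrate` | proximity and relative-distance statistics, 5′-end (NanoPARE-style) site classification |

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
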