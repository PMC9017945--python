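# Methods

This note records the models, defaults and numerical choices behind
`poetools`, in the spirit of a package methods appendix. It states no
empirical claims beyond what the test suite and `scripts/acceptance.py`
compute.

## Experimental design being modeled

Reciprocal crosses between wild-type plants and mutants of RNA Pol IV
produce four endosperm genotypes distinguished by which *parent* carried
the mutation: `WT`, `mat_het` (mutant mother), `pat_het` (mutant father),
`null` (both). Endosperm is triploid with two maternal genomes per
paternal genome, so DNA-derived reads are expected to be 2/3 maternal and
balanced transcripts 2/3 maternal as well. The two parental accessions
differ by single-nucleotide substitutions; a pseudogenome built by
substituting the alternate allele into the reference shares the reference
coordinate frame exactly, which is why allele assignment needs no
liftover.

## Allele assignment

A read votes with every SNP it covers: all informative positions agreeing
on one parent assigns the read; no covered SNP, a base matching neither
parent, or conflicting votes leave it `ambiguous`. Conflicted reads are
*kept as ambiguous* rather than discarded so that sequencing artifacts
cannot create allele-specific losses. Multimapped reads (n_hits > 1) are
excluded from allelic tallies — a read with several equally good
placements cannot anchor an allele call — but still count in non-allelic
totals. A read counts toward the single feature containing its
biological 5′ end (ties to the earlier-sorted feature), so totals are
conserved across overlapping annotations. Features need ≥ 10
allele-informative reads to be testable for bias; percent maternal in
[20, 80] (inclusive) is *biallelic*, above 80 maternally biased, below 20
paternally biased.

## Small-RNA processing

PCR duplicates are collapsed to one representative per distinct sequence
string (library protocols carry random terminal bases, so identical
strings are amplification copies; the simulator emits duplicate-free
libraries, and deduplication is exercised on constructed fixtures).
Size binning covers 21–24 nt. Window counting supports both dialects used
in this kind of analysis — 300-bp windows with 100-bp step for
region-level summaries, and an exact-partition "conserve" mode where each
read counts once. Cluster calling merges read-start islands closer than
`pad` = 75 bp, discards clusters below 0.5 reads-per-million, and labels a
cluster's predominant size as the modal length within the dicer range
[20, 25] provided the dicer-range fraction is ≥ 0.8 and the mode is a
strict plurality; ties and dicer-poor clusters are explicitly "no
predominant size class". Multimapped reads contribute fractional weight
proportional to the unique-read start coverage within ±pad of their
reported site (alternative unreported sites are assumed to carry the
genome-average unique coverage); a unique-only mode is available. The
0.8 threshold and pad follow common practice for this cluster-caller
family; both are config-exposed.

## Differential abundance

Counts are modeled NB(μ·s_j, α). Size factors are median-of-ratios over a
*reference feature set*: for Pol IV sRNA libraries the TE compartment
collapses in the null, so only genic + miRNA features (largely Pol IV
independent) give an honest library-size estimate; with the reference set
equal to all features the estimator reduces to the standard global one.
Factors are reported rescaled to geometric mean one.

The per-feature test is a Wald statistic log2(μ̂_B/μ̂_A)/SE with SE from
the delta method, Var(q̄_g) = (μ mean(1/s_j) + α μ²)/n. The dispersion is
a pooled within-group method-of-moments estimate *moderated* toward the
across-feature median with d₀ = 9 prior degrees of freedom, and the
statistic is referred to a t distribution with n_A + n_B − 2 + d₀ degrees
of freedom. Both choices are calibration-driven: raw per-feature moment
dispersions at 2–3 replicates are so noisy that power collapses, and a
normal reference is anti-conservative (measured type-I ≈ 0.12 at nominal
0.05 on the package's own null simulations); the moderated-t combination
measures ≈ 0.049 at nominal 0.05 on a 3-vs-3, mean-100, dispersion-0.05
null while detecting planted 4-fold effects with > 95% power. d₀ = 0
recovers the unmoderated estimator. When one group is observed entirely
at zero, the log ratio is guarded with the 0.5 pseudocount but the
variance scale for that group is taken from the pooled mean
(score-test style): the evidence in "no counts at all" is how many counts
were expected, and the guard value alone grossly understates it. The
displayed log2 fold change always uses the 0.5 pseudocount; features
all-zero in both groups are untested. Multiplicity is handled by
Benjamini–Hochberg; calls require |log2FC| ≥ log2(2), padj ≤ 0.05, and a
reference-condition normalized mean ≥ 5 (below the floor a feature is
"untested", not "not significant").

## Methylome

Cytosine contexts (CG/CHG/CHH, H ∈ {A,C,T}) are read from the
strand-appropriate trinucleotide; minus-strand contexts are read 5′→3′ on
the reverse complement, and cytosines whose context cannot be determined
at a contig end are dropped. Bisulfite conversion is estimated from
chloroplast cytosines (assumed unmethylated) with pooled depth ≥ 10; the
QC floor is 98%.

Window comparisons use 300-bp windows at 100-bp step and count only
cytosines covered in *both* samples: ≥ 3 common informative cytosines and
depth ≥ 6 reads per cytosine are required. "Depth 6" is interpreted as
*mean* depth over the window's common cytosines — a strict per-cytosine
rule discards most windows at ~30× genome coverage — with a
`depth_rule="strict"` switch for the literal reading. Windows whose DNA
reads fall outside 67 ± 15% maternal (inclusive bounds, applied per
window) are discarded: allele-biased coverage in a triploid tissue
distorts apparent methylation before any genotype difference can be
trusted. Windows methylation-variable between replicates of the same
genotype (by the same context thresholds) are masked from between-genotype
comparison. Differential windows (ΔCHH ≥ 10, ΔCHG ≥ 20, ΔCG ≥ 30
percentage points; replicates pooled per genotype) merge into DMRs when
they spatially overlap with the same context and direction; the merged
region's methylation is recomputed from the summed constituent-window
counts. Mixed-direction overlaps never merge. CHG DMRs are computed but
carry no downstream integration by default.

## Antagonism model

Per gene, log2 E[count] = β₀ + β_mat·I(mother mutant) +
β_pat·I(father mutant). A gene with β_mat·β_pat < 0 (both nonzero) is
antagonistic. Under this purely parental (no-zygotic-effect) model the
null genotype's fold change is *additive*: log2FC_null = log2FC_mat +
log2FC_pat; `additive_prediction` reports that sum and its fold-scale
value, and the per-gene discrepancy observed − predicted. The
opposite-direction test counts genes called in both heterozygote
contrasts whose estimated fold changes disagree in sign — direction uses
the sign of the estimate once a gene is called in its own contrast,
without re-imposing the 2-fold threshold on the partner contrast — and
evaluates enrichment with an exact hypergeometric tail: conditional on
the shared set and its two up/down margins, the same-direction overlap is
hypergeometric, so P(opposite ≥ observed) is a hypergeometric CDF. The
inverse mat/pat relationship is an OLS fit of log2FC_pat on log2FC_mat
reported for two gene classes defined by the maternal and null calls
only (misregulated maternally and in the null, vs maternally but *not*
in the null), since that is the contrast in which opposing paternal
effects reveal themselves; the paternal contrast's own call status is
deliberately not part of the class definition.

## Spatial statistics

`proximity_fraction` is the fraction of genes within an edge-to-edge
distance (default 1 kb) of any region, overlap counting as zero.
`relative_distance` places each query midpoint between its two flanking
reference midpoints, scaled to [0, 0.5]; midpoints use floor((start+end)/2)
and queries outside the reference span are skipped and counted. Under
spatial independence the statistic is uniform, so each 0.01 bin carries
≈ 0.02 of the mass; the package also draws matched random interval sets
(default 5 replicates) as a baseline. 5′-end (NanoPARE-style) analysis
tests every nucleotide position with the NB engine (no fold floor,
padj ≤ 0.05) and labels significant sites TSS-proximal when within ±50 nt
of the annotated, strand-aware gene 5′ end (config-exposed; the choice of
50 nt is a convention, not a measurement), otherwise internal — putative
cleavage.

## Synthetic data generator

The generator is first-class, tested code; every downstream recovery test
runs against its ground truth. What it emulates, and its defaults:

- **Genome**: 2 nuclear contigs × 200 kb plus a 150-kb chloroplast;
  uniform random sequence. SNPs at rate 1/200 bp (Col-0/Ler-like
  density), never adjacent, none on the chloroplast; the reference acts
  as the paternal genome (mother carries the alternate alleles, as in a
  Ler × Col reference frame).
- **Panel**: ~400 genes (500 bp), ~200 TEs (300 bp), 20 miRNA loci,
  30 maternal-memory and 30 paternal-memory imprinted sRNA regions
  (ISRs), placed without overlap.
- **sRNA libraries**: 100k reads nominal; per-locus NB counts
  (dispersion 0.2) around lognormal means; 24-nt-dominant size
  distribution at Pol IV loci, 21-nt at miRNA loci; biallelic loci draw
  per-read alleles from a Beta(8,4) per-locus bias (mean 2/3); memory
  ISRs are 95% single-parent. Genotype rules: biallelic Pol IV loci are
  silent only in the null; maternal-memory loci require a wild-type
  mother (silent in `mat_het` and `null`); paternal-memory loci are
  symmetric; miRNA loci are genotype-independent. A 2% uniform
  background with degradation-like sizes (18–30 nt) is added; 5% of TE
  reads are flagged multimapped.
- **mRNA counts**: NB dispersion 0.05 around log2 means β₀ ~ U(6, 9)
  obeying the additive parental-effect model exactly. Effect panels:
  40 maternal-only and 40 paternal-only (|β| ~ U(1, 3)), 30 strongly
  antagonistic (both |β| ~ U(1.5, 3), opposite signs — the magnitude a
  several-fold reciprocal misregulation implies), 60 weakly antagonistic
  with an exact planted ratio β_pat = −0.25·β_mat and |β_mat| ~
  U(1.1, 1.33) so the paternal pull stays below the 2-fold call
  threshold, and 20 same-sign controls. Allelic splits are
  beta-binomial (ν = 50) around 2/3, or 0.95/0.05 for the 20 maternally
  and 10 paternally expressed imprinted genes; 20% of reads are
  allele-informative.
- **Methylome**: Poisson depth 30× split 2:1 maternal:paternal per
  cytosine; baselines CG 25%, CHG 10%, CHH 3%; RdDM targets (TEs and
  ISRs) carry 30% CHH, dropping to 5% when the driving parent is mutant
  (TEs require both parents mutant); a truly unmethylated cytosine reads
  methylated with probability 1 − conversion, conversion success 0.99;
  the chloroplast is truly unmethylated.
- **5′-end tracks**: per-gene TSS spike proportional to the genotype's
  mRNA mean; 30 cleavage-target genes carry an internal mid-gene spike
  only while their sRNA locus is active; sparse uniform noise over gene
  bodies.

Randomness flows from one master seed through stable blake2s-derived
child streams per (dataset, genotype, replicate), so adding a replicate
never perturbs existing ones, and a fixed seed reproduces outputs
byte-identically.

What the generator does **not** model: sequencing/alignment errors,
mappability structure, adapter artifacts, PCR duplication, seed-coat
contamination, chromatin context, or any correlation between methylation
and expression beyond the planted RdDM regions. Passing recovery tests
therefore demonstrate that the *statistical logic* of the pipeline is
correct under the stated generative assumptions — not that real
endosperm libraries are this clean.

## Problem sizes and determinism

Default desk-scale sizes (550 kb genome, 100k-read sRNA libraries, 30×
methylomes, 400 genes × 12 mRNA samples) were chosen so that every
simulation-backed check runs in seconds while keeping per-locus counts in
the regime the statistics assume; all sizes are config fields and scale
up linearly. `scripts/acceptance.py --seed N` derives all stream seeds
from N (kept below 2³¹) and is fully deterministic.

## Known limitations

- The Wald test's zero-group handling is a pragmatic score-style guard,
  not an exact conditional test; extremely low-count features near the
  testability floor inherit its approximations.
- Dispersion moderation assumes a roughly common dispersion scale across
  features; strongly heterogeneous dispersions would favor a trended
  prior.
- The multimapper weighting scheme sees only the reported placement of a
  multimapped read and assumes average coverage elsewhere.
- Per-allele DMR calling is out of scope: the dosage filter guards
  against allele-biased coverage instead of splitting methylomes by
  allele.
- The hypergeometric opposite-direction test conditions on the observed
  shared set and margins; it does not model selection into the shared
  set.
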