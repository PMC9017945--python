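"""Synthetic allele-resolved endosperm datasets with known ground truth.

The generator emulates the statistical structure of reciprocal-cross
endosperm experiments: a Col-0-like reference with Ler-like SNPs, a
triploid 2 maternal : 1 paternal genome dosage, Pol IV-dependent sRNA
loci (biallelic, plus imprinted regions with parental "memory" -- loci
that only fire when the corresponding parent carried a functional
polymerase), NB-distributed mRNA counts whose log2 means are additive in
a maternal and a paternal effect, allele-resolved methylomes with
incomplete bisulfite conversion, and per-nucleotide 5'-end tracks with
TSS and cleavage spikes.

Genotypes name the *parental* origin of the mutation: ``WT`` (neither
parent mutant), ``mat_het`` (mutant mother), ``pat_het`` (mutant father),
``null`` (both). All randomness flows from one master seed through stable
per-(dataset, genotype, replicate) child streams, so adding a replicate
never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .allelic import build_pseudogenome
from .io import (AlignedRead, CountMatrix, GenomeSequence, GenomicInterval,
                 SnpRecord, SnpTable)

GENOTYPES = ("WT", "mat_het", "pat_het", "null")

LOCUS_POLIV = "polIV_biallelic"
LOCUS_MAT_MEMORY = "mat_memory"
LOCUS_PAT_MEMORY = "pat_memory"
LOCUS_MIRNA = "mirna"


def mother_mutant(genotype: str) -> bool:
    _check_genotype(genotype)
    return genotype in ("mat_het", "null")


def father_mutant(genotype: str) -> bool:
    _check_genotype(genotype)
    return genotype in ("pat_het", "null")


def _check_genotype(genotype: str) -> None:
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of "
                         f"{GENOTYPES}")


def locus_active(locus_class: str, genotype: str) -> bool:
    """Whether an sRNA locus emits above-background reads in a genotype.

    Biallelic Pol IV loci need at least one functional parental allele
    after fertilization; parental-memory loci need the *corresponding*
    parent to have carried functional Pol IV before fertilization; miRNA
    loci are Pol IV independent.
    """
    if locus_class == LOCUS_POLIV:
        return genotype != "null"
    if locus_class == LOCUS_MAT_MEMORY:
        return not mother_mutant(genotype)
    if locus_class == LOCUS_PAT_MEMORY:
        return not father_mutant(genotype)
    if locus_class == LOCUS_MIRNA:
        return True
    raise ValueError(f"unknown locus class {locus_class!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    n_contigs: int = 2
    contig_length: int = 200_000
    chloroplast_length: int = 150_000
    chloroplast_name: str = "chrC"
    snp_rate: float = 1.0 / 200.0  # Col/Ler-like SNP density


@dataclass
class PanelConfig:
    n_genes: int = 400
    n_tes: int = 200
    n_mirna: int = 20
    n_isr_mat: int = 30
    n_isr_pat: int = 30
    gene_length: int = 500
    te_length: int = 300
    mirna_length: int = 150
    isr_length: int = 300


@dataclass
class SrnaConfig:
    reads_per_library: int = 100_000
    #: size distribution at Pol IV loci (24-nt predominant)
    size_probs: dict = field(default_factory=lambda: {
        21: 0.06, 22: 0.04, 23: 0.10, 24: 0.80})
    #: miRNA loci emit 21-nt reads
    mirna_size_probs: dict = field(default_factory=lambda: {21: 0.9, 22: 0.1})
    background_fraction: float = 0.02
    background_sizes: tuple = (18, 30)  # degradation-like, no dicer signature
    frac_genes_with_srna: float = 0.3
    dispersion: float = 0.2  # NB dispersion of per-locus counts across reps
    locus_mean_sigma: float = 0.6  # lognormal spread of per-locus means
    memory_bias: float = 0.95  # maternal fraction at mat-memory ISRs
    biallelic_bias_beta: tuple = (8.0, 4.0)  # Beta(a, b), mean 2/3
    multimapper_fraction: float = 0.05  # TE reads flagged n_hits=2


@dataclass
class MrnaConfig:
    n_replicates: int = 3
    dispersion: float = 0.05
    informative_fraction: float = 0.2  # reads overlapping a SNP
    beta0_range: tuple = (6.0, 9.0)  # log2 baseline mean
    n_mat_only: int = 40
    n_pat_only: int = 40
    n_antagonistic: int = 30
    n_weak_antagonistic: int = 60
    n_same_sign: int = 20
    effect_range: tuple = (1.0, 3.0)  # |log2| single-parent effects
    antagonistic_range: tuple = (1.5, 3.0)  # |log2|, both parents, opposed
    #: weak antagonism: beta_pat = -ratio * beta_mat with the paternal pull
    #: below the 2-fold call threshold, so these genes surface as
    #: maternally misregulated but (mostly) silent in the null
    antagonism_ratio: float = 0.25
    weak_effect_range: tuple = (1.1, 1.33)
    n_meg: int = 20  # maternally expressed imprinted genes
    n_peg: int = 10  # paternally expressed imprinted genes
    imprint_bias: float = 0.95
    betabinom_nu: float = 50.0  # allelic overdispersion concentration


@dataclass
class MethylConfig:
    depth: float = 30.0
    conversion_rate: float = 0.99
    baseline: dict = field(default_factory=lambda: {
        "CG": 0.25, "CHG": 0.10, "CHH": 0.03})
    rddm_chh: float = 0.30  # CHH at active RdDM targets
    rddm_chh_lost: float = 0.05  # after loss of the driving sRNAs
    maternal_fraction: float = 2.0 / 3.0


@dataclass
class NanopareConfig:
    tss_scale: float = 0.2  # TSS spike = scale * mRNA mean
    cleavage_mean: float = 30.0
    noise_per_bp: float = 0.002
    n_cleavage_targets: int = 30


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    srna: SrnaConfig = field(default_factory=SrnaConfig)
    mrna: MrnaConfig = field(default_factory=MrnaConfig)
    methylome: MethylConfig = field(default_factory=MethylConfig)
    nanopare: NanopareConfig = field(default_factory=NanopareConfig)

    def validate(self) -> None:
        for rate in (self.genome.snp_rate, self.srna.background_fraction,
                     self.methylome.conversion_rate,
                     self.methylome.maternal_fraction,
                     self.mrna.informative_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.methylome.depth <= 0 or self.srna.reads_per_library <= 0:
            raise ValueError("depths and library sizes must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def child_seed(master_seed: int, *tags) -> int:
    """Stable child seed below 2**31 derived from the master seed and a tag
    tuple (dataset, genotype, replicate, ...)."""
    key = ":".join([str(master_seed), *map(str, tags)]).encode()
    digest = hashlib.blake2s(key, digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Latent simulator state: everything recovery tests compare against."""

    config: SimulationConfig
    genome: GenomeSequence
    pseudogenome: GenomeSequence  # maternal (alt-substituted) genome
    snps: SnpTable
    annotations: list[GenomicInterval]
    srna_loci: pd.DataFrame   # locus_id, contig, start, end, cls, mean_reads, maternal_bias
    genes: pd.DataFrame       # gene_id, coords, strand, beta0, beta_mat, beta_pat, imprint, antagonistic, cleavage_target
    meth_regions: pd.DataFrame  # region_id, coords, memory in {mat, pat, both}, wt_chh, lost_chh
    maternal_genome_dosage: float = 2.0 / 3.0

    def maternal_sequence(self, contig: str) -> str:
        return self.pseudogenome[contig]

    def paternal_sequence(self, contig: str) -> str:
        return self.genome[contig]

    def mrna_mean(self, gene_id: str, genotype: str) -> float:
        """Noise-free expected count: log2 mean = beta0 + beta_mat*I(mother
        mutant) + beta_pat*I(father mutant); exactly additive in the null."""
        row = self.genes.loc[gene_id]
        log2_mean = row["beta0"]
        if mother_mutant(genotype):
            log2_mean += row["beta_mat"]
        if father_mutant(genotype):
            log2_mean += row["beta_pat"]
        return float(2.0 ** log2_mean)


# ---------------------------------------------------------------------------
# genome, SNPs, annotations
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])

def _place_panel(rng: np.random.Generator, contig_names: list[str],
                 contig_length: int, features: list[tuple[str, str, int]]
                 ) -> list[GenomicInterval]:
    """Place (feature_id, feature_class, length) tuples without overlap.

    Features are shuffled, partitioned across contigs, and laid out left to
    right with random gaps drawn from the remaining free space, which makes
    placement deterministic-in-distribution and guarantees non-overlap (a
    hard error suggests a smaller panel when the panel cannot fit).
    """
    features = list(features)
    order = rng.permutation(len(features))
    features = [features[i] for i in order]
    per_contig: dict[str, list] = {c: [] for c in contig_names}
    used = {c: 0 for c in contig_names}
    budget = int(contig_length * 0.95)
    for feat in features:
        target = min(contig_names, key=lambda c: used[c])
        if used[target] + feat[2] > budget:
            raise ValueError(
                "locus panel cannot be placed without overlap at this "
                "density; reduce panel sizes or lengths"
            )
        per_contig[target].append(feat)
        used[target] += feat[2]
    out = []
    for contig in contig_names:
        feats = per_contig[contig]
        free = contig_length - used[contig]
        # n+1 gap slots summing to the free space
        gaps = rng.multinomial(free, np.ones(len(feats) + 1) /
                               (len(feats) + 1))
        cursor = 0
        for (fid, fclass, length), gap in zip(feats, gaps[:-1]):
            cursor += gap
            strand = "+" if rng.random() < 0.5 else "-"
            if fclass in ("ISR", "window"):
                strand = "."
            out.append(GenomicInterval(contig, cursor, cursor + length,
                                       strand, fid, fclass))
            cursor += length
    return sorted(out, key=lambda f: (f.contig, f.start))


def simulate_genome_and_snps(config: SimulationConfig
                             ) -> tuple[GenomeSequence, SnpTable,
                                        list[GenomicInterval], GroundTruth]:
    """Build the reference genome, SNP table, annotations and ground truth.

    The nuclear contigs carry Bernoulli(snp_rate) SNPs (never adjacent);
    the chloroplast contig carries none and is truly unmethylated. The
    reference plays the paternal (Col-0-like) genome; the alt-substituted
    pseudogenome is maternal (Ler-like).
    """
    config.validate()
    gcfg, pcfg = config.genome, config.panel
    rng = np.random.default_rng(child_seed(config.seed, "genome"))

    genome = GenomeSequence()
    nuclear = [f"chr{i + 1}" for i in range(gcfg.n_contigs)]
    for name in nuclear:
        genome.contigs[name] = _random_sequence(rng, gcfg.contig_length)
    genome.contigs[gcfg.chloroplast_name] = _random_sequence(
        rng, gcfg.chloroplast_length)

    # SNPs: iid Bernoulli per nuclear position, adjacent positions dropped
    records = []
    for name in nuclear:
        hits = np.nonzero(rng.random(gcfg.contig_length) <
                          gcfg.snp_rate)[0]
        if len(hits) > 1:
            keep = np.concatenate([[True], np.diff(hits) > 1])
            hits = hits[keep]
        seq = genome[name]
        for pos in hits:
            ref = seq[pos]
            alt = "ACGT"[("ACGT".index(ref) + rng.integers(1, 4)) % 4]
            records.append(SnpRecord(name, int(pos), ref, alt,
                                     parent_of_ref="paternal"))
    snps = SnpTable(records)
    pseudogenome = build_pseudogenome(genome, snps)

    feats: list[tuple[str, str, int]] = []
    feats += [(f"gene_{i:04d}", "gene", pcfg.gene_length)
              for i in range(pcfg.n_genes)]
    feats += [(f"te_{i:04d}", "TE", pcfg.te_length)
              for i in range(pcfg.n_tes)]
    feats += [(f"mirna_{i:03d}", "miRNA", pcfg.mirna_length)
              for i in range(pcfg.n_mirna)]
    feats += [(f"isr_mat_{i:03d}", "ISR", pcfg.isr_length)
              for i in range(pcfg.n_isr_mat)]
    feats += [(f"isr_pat_{i:03d}", "ISR", pcfg.isr_length)
              for i in range(pcfg.n_isr_pat)]
    annotations = _place_panel(rng, nuclear, gcfg.contig_length, feats)
    by_id = {f.feature_id: f for f in annotations}

    srna_loci = _build_srna_loci(rng, config, by_id)
    genes = _build_gene_effects(rng, config, by_id, srna_loci)
    meth_regions = _build_meth_regions(config, by_id)

    truth = GroundTruth(config, genome, pseudogenome, snps, annotations,
                        srna_loci, genes, meth_regions,
                        config.methylome.maternal_fraction)
    return genome, snps, annotations, truth


def _build_srna_loci(rng, config, by_id) -> pd.DataFrame:
    scfg = config.srna
    rows = []
    gene_ids = sorted(i for i in by_id if i.startswith("gene_"))
    n_srna_genes = int(round(len(gene_ids) * scfg.frac_genes_with_srna))
    srna_genes = sorted(rng.choice(gene_ids, n_srna_genes, replace=False))
    for fid, f in by_id.items():
        if f.feature_class == "TE" or fid in srna_genes:
            cls = LOCUS_POLIV
            bias = rng.beta(*scfg.biallelic_bias_beta)
        elif fid.startswith("isr_mat_"):
            cls = LOCUS_MAT_MEMORY
            bias = scfg.memory_bias
        elif fid.startswith("isr_pat_"):
            cls = LOCUS_PAT_MEMORY
            bias = 1.0 - scfg.memory_bias
        elif f.feature_class == "miRNA":
            cls = LOCUS_MIRNA
            bias = 2.0 / 3.0
        else:
            continue
        rows.append({"locus_id": fid, "contig": f.contig, "start": f.start,
                     "end": f.end, "cls": cls,
                     "mean_reads": float(rng.lognormal(
                         0.0, scfg.locus_mean_sigma)),
                     "maternal_bias": float(bias)})
    df = pd.DataFrame(rows).set_index("locus_id")
    # scale means so a fully active (WT) library totals the nominal size
    target = scfg.reads_per_library * (1.0 - scfg.background_fraction)
    df["mean_reads"] *= target / df["mean_reads"].sum()
    return df


def _build_gene_effects(rng, config, by_id, srna_loci) -> pd.DataFrame:
    mcfg = config.mrna
    gene_ids = sorted(i for i in by_id if i.startswith("gene_"))
    n = len(gene_ids)
    need = (mcfg.n_mat_only + mcfg.n_pat_only + mcfg.n_antagonistic +
            mcfg.n_weak_antagonistic + mcfg.n_same_sign)
    if need > n:
        raise ValueError("effect panel larger than the gene panel")
    perm = list(rng.permutation(gene_ids))
    groups = {}
    for name, count in (("mat_only", mcfg.n_mat_only),
                        ("pat_only", mcfg.n_pat_only),
                        ("antagonistic", mcfg.n_antagonistic),
                        ("weak_antagonistic", mcfg.n_weak_antagonistic),
                        ("same_sign", mcfg.n_same_sign)):
        groups[name] = [perm.pop() for _ in range(count)]
    panel_of = {g: name for name, ids in groups.items() for g in ids}
    imprint_pool = list(rng.permutation(gene_ids))
    megs = set(imprint_pool[:mcfg.n_meg])
    pegs = set(imprint_pool[mcfg.n_meg:mcfg.n_meg + mcfg.n_peg])

    def draw_effect(lo, hi):
        return float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))

    rows = []
    for gid in gene_ids:
        f = by_id[gid]
        beta_mat = beta_pat = 0.0
        if gid in groups["mat_only"]:
            beta_mat = draw_effect(*mcfg.effect_range)
        elif gid in groups["pat_only"]:
            beta_pat = draw_effect(*mcfg.effect_range)
        elif gid in groups["antagonistic"]:
            beta_mat = draw_effect(*mcfg.antagonistic_range)
            beta_pat = -np.sign(beta_mat) * rng.uniform(
                *mcfg.antagonistic_range)
        elif gid in groups["weak_antagonistic"]:
            beta_mat = draw_effect(*mcfg.weak_effect_range)
            beta_pat = -mcfg.antagonism_ratio * beta_mat
        elif gid in groups["same_sign"]:
            sign = rng.choice([-1.0, 1.0])
            beta_mat = sign * rng.uniform(*mcfg.effect_range)
            beta_pat = sign * rng.uniform(*mcfg.effect_range)
        imprint = ("maternal" if gid in megs else
                   "paternal" if gid in pegs else "none")
        rows.append({
            "gene_id": gid, "contig": f.contig, "start": f.start,
            "end": f.end, "strand": f.strand,
            "beta0": float(rng.uniform(*mcfg.beta0_range)),
            "beta_mat": beta_mat, "beta_pat": beta_pat,
            "imprint": imprint,
            "panel": panel_of.get(gid, "none"),
            "antagonistic": bool(beta_mat * beta_pat < 0),
            "has_srna": gid in srna_loci.index,
        })
    df = pd.DataFrame(rows).set_index("gene_id")
    # cleavage targets: sRNA-bearing genes get an internal cleavage site
    candidates = sorted(df.index[df["has_srna"]])
    n_cleave = min(config.nanopare.n_cleavage_targets, len(candidates))
    chosen = set(rng.choice(candidates, n_cleave, replace=False))
    df["cleavage_target"] = [g in chosen for g in df.index]
    return df


def _build_meth_regions(config, by_id) -> pd.DataFrame:
    mcfg = config.methylome
    rows = []
    for fid, f in by_id.items():
        if fid.startswith("isr_mat_"):
            memory = "mat"
        elif fid.startswith("isr_pat_"):
            memory = "pat"
        elif f.feature_class == "TE":
            memory = "both"  # lost only when both parents are mutant
        else:
            continue
        rows.append({"region_id": fid, "contig": f.contig,
                     "start": f.start, "end": f.end, "memory": memory,
                     "wt_chh": mcfg.rddm_chh,
                     "lost_chh": mcfg.rddm_chh_lost})
    return pd.DataFrame(rows).set_index("region_id")


def region_chh_level(truth: GroundTruth, region_id: str,
                     genotype: str) -> float:
    """True CHH methylation of an RdDM target region in a genotype."""
    row = truth.meth_regions.loc[region_id]
    if row["memory"] == "mat":
        lost = mother_mutant(genotype)
    elif row["memory"] == "pat":
        lost = father_mutant(genotype)
    else:
        lost = mother_mutant(genotype) and father_mutant(genotype)
    return float(row["lost_chh"] if lost else row["wt_chh"])


# ---------------------------------------------------------------------------
# sRNA reads
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: float, dispersion: float) -> int:
    """Negative binomial via gamma-Poisson mixing."""
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return int(rng.poisson(lam))


def simulate_srna_reads(truth: GroundTruth, genotype: str, replicate: int = 0,
                        seed: int | None = None) -> list[AlignedRead]:
    """One small-RNA library as error-free pre-aligned reads.

    Per-locus read counts are NB around the truth mean (zero when the locus
    is inactive in this genotype); each read's allele follows the locus's
    maternal bias, its size the class's size distribution, and its sequence
    is lifted verbatim from the corresponding parental genome (sequence is
    stored reference-oriented). Background reads are uniform over the
    genome with degradation-like sizes. Reads never carry alignment errors,
    so allele assignment can be scored against truth exactly.
    """
    _check_genotype(genotype)
    cfg = truth.config.srna
    if seed is None:
        seed = child_seed(truth.config.seed, "srna", genotype, replicate)
    rng = np.random.default_rng(seed)
    reads: list[AlignedRead] = []
    counter = 0

    for locus_id, locus in truth.srna_loci.iterrows():
        if not locus_active(locus["cls"], genotype):
            continue
        n = _nb_draw(rng, locus["mean_reads"], cfg.dispersion)
        if n == 0:
            continue
        probs = (cfg.mirna_size_probs if locus["cls"] == LOCUS_MIRNA
                 else cfg.size_probs)
        sizes = rng.choice(list(probs), n, p=list(probs.values()))
        maternal = rng.random(n) < locus["maternal_bias"]
        is_te = locus_id.startswith("te_")
        multi = (rng.random(n) < cfg.multimapper_fraction) if is_te else \
            np.zeros(n, dtype=bool)
        span = int(locus["end"] - locus["start"])
        for i in range(n):
            size = int(sizes[i])
            offset = int(rng.integers(0, max(span - size, 1)))
            start = int(locus["start"]) + offset
            contig = locus["contig"]
            source = truth.maternal_sequence(contig) if maternal[i] \
                else truth.paternal_sequence(contig)
            reads.append(AlignedRead(
                f"{genotype}.{replicate}.{counter}", contig, start,
                "+" if rng.random() < 0.5 else "-",
                source[start:start + size], 2 if multi[i] else 1))
            counter += 1

    # uniform degradation-like background
    n_bg = rng.poisson(cfg.reads_per_library * cfg.background_fraction)
    contigs = list(truth.genome.contigs)
    lengths = np.array([len(truth.genome[c]) for c in contigs], dtype=float)
    which = rng.choice(len(contigs), n_bg, p=lengths / lengths.sum())
    for i in range(n_bg):
        contig = contigs[which[i]]
        size = int(rng.integers(cfg.background_sizes[0],
                                cfg.background_sizes[1] + 1))
        start = int(rng.integers(0, len(truth.genome[contig]) - size))
        maternal = rng.random() < truth.maternal_genome_dosage
        source = truth.maternal_sequence(contig) if maternal \
            else truth.paternal_sequence(contig)
        reads.append(AlignedRead(
            f"{genotype}.{replicate}.bg{i}", contig, start,
            "+" if rng.random() < 0.5 else "-",
            source[start:start + size], 1))
    return reads


# ---------------------------------------------------------------------------
# DNA reads (dosage control)
# ---------------------------------------------------------------------------

def simulate_dna_reads(truth: GroundTruth, n_reads: int = 50_000,
                       read_length: int = 75,
                       seed: int | None = None) -> list[AlignedRead]:
    """Uniformly placed genomic DNA reads with 2:1 maternal dosage.

    The maternal fraction of DNA-derived reads equals the triploid genome
    dosage (default 2/3) at every locus; used to validate allele
    assignment and the methylome dosage filter.
    """
    if seed is None:
        seed = child_seed(truth.config.seed, "dna")
    rng = np.random.default_rng(seed)
    nuclear = [c for c in truth.genome.contigs
               if c != truth.config.genome.chloroplast_name]
    lengths = np.array([len(truth.genome[c]) for c in nuclear], dtype=float)
    which = rng.choice(len(nuclear), n_reads, p=lengths / lengths.sum())
    maternal = rng.random(n_reads) < truth.maternal_genome_dosage
    reads = []
    for i in range(n_reads):
        contig = nuclear[which[i]]
        start = int(rng.integers(0, len(truth.genome[contig]) - read_length))
        source = truth.maternal_sequence(contig) if maternal[i] \
            else truth.paternal_sequence(contig)
        reads.append(AlignedRead(
            f"dna.{i}", contig, start, "+" if rng.random() < 0.5 else "-",
            source[start:start + read_length], 1))
    return reads


# ---------------------------------------------------------------------------
# mRNA counts
# ---------------------------------------------------------------------------

def simulate_mrna_counts(truth: GroundTruth, genotypes=GENOTYPES,
                         n_replicates: int | None = None,
                         seed: int | None = None
                         ) -> tuple[CountMatrix, CountMatrix, CountMatrix]:
    """NB gene counts for each genotype plus the allelic split.

    Per gene, log2 mean = beta0 + beta_mat*I(mother mutant) +
    beta_pat*I(father mutant) (exactly additive in the null); counts are
    NB(mean, dispersion). A Binomial(informative_fraction) subset of each
    gene's reads is allele informative and splits maternal:paternal by a
    beta-binomial centered on 2/3 for non-imprinted genes and near 1 (or
    0) for maternally (paternally) expressed imprinted genes.

    Returns (total, maternal, paternal) count matrices; maternal +
    paternal = the allele-informative subset, not the total.
    """
    cfg = truth.config.mrna
    if n_replicates is None:
        n_replicates = cfg.n_replicates
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per genotype for testing")
    genes = truth.genes
    mu_allelic = {"none": truth.maternal_genome_dosage,
                  "maternal": cfg.imprint_bias,
                  "paternal": 1.0 - cfg.imprint_bias}

    columns, meta_rows = [], []
    total, mat, pat = {}, {}, {}
    for genotype in genotypes:
        _check_genotype(genotype)
        means = np.array([truth.mrna_mean(g, genotype) for g in genes.index])
        for rep in range(n_replicates):
            if seed is None:
                s = child_seed(truth.config.seed, "mrna", genotype, rep)
            else:
                s = child_seed(seed, "mrna", genotype, rep)
            rng = np.random.default_rng(s)
            r = 1.0 / cfg.dispersion
            counts = rng.negative_binomial(r, r / (r + means))
            informative = rng.binomial(counts, cfg.informative_fraction)
            bias = np.array([mu_allelic[i] for i in genes["imprint"]])
            p = rng.beta(bias * cfg.betabinom_nu,
                         (1.0 - bias) * cfg.betabinom_nu)
            m = rng.binomial(informative, p)
            name = f"{genotype}_{rep + 1}"
            columns.append(name)
            meta_rows.append({"sample": name, "genotype": genotype,
                              "replicate": rep + 1})
            total[name] = counts
            mat[name] = m
            pat[name] = informative - m
    meta = pd.DataFrame(meta_rows).set_index("sample")
    fclass = pd.Series("gene", index=genes.index)

    def make(d):
        return CountMatrix(pd.DataFrame(d, index=genes.index)[columns],
                           fclass, meta)

    return make(total), make(mat), make(pat)


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _cytosine_positions(seq: str):
    """(plus_positions, minus_positions, contexts_plus, contexts_minus)."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    plus = np.nonzero(arr == b"C")[0]
    minus = np.nonzero(arr == b"G")[0]
    L = len(arr)

    def ctx(positions, strand):
        n1 = np.full(len(positions), b"N", dtype="S1")
        n2 = np.full(len(positions), b"N", dtype="S1")
        if strand == "+":
            ok1 = positions + 1 < L
            ok2 = positions + 2 < L
            n1[ok1] = arr[positions[ok1] + 1]
            n2[ok2] = arr[positions[ok2] + 2]
            g = b"G"
        else:
            ok1 = positions - 1 >= 0
            ok2 = positions - 2 >= 0
            n1[ok1] = arr[positions[ok1] - 1]
            n2[ok2] = arr[positions[ok2] - 2]
            g = b"C"  # complement of G read 5'->3' on the minus strand
        out = np.where(n1 == g, "CG", np.where(n2 == g, "CHG", "CHH"))
        out[(n1 == b"N") | ((n1 != g) & (n2 == b"N"))] = ""
        return out

    return plus, minus, ctx(plus, "+"), ctx(minus, "-")


def simulate_methylome(truth: GroundTruth, genotype: str, replicate: int = 0,
                       seed: int | None = None,
                       contigs: list[str] | None = None) -> pd.DataFrame:
    """Allele-resolved bisulfite calls for one library (CX-style table).

    Every cytosine of the requested contigs is covered at Poisson depth
    split 2:1 maternal:paternal on nuclear contigs; methylated counts are
    Binomial(depth, p_observed) where p_observed folds the bisulfite
    conversion failure into the true methylation level (a truly
    unmethylated C reads methylated with probability 1 - conversion_rate).
    CHH levels inside RdDM target regions depend on the genotype through
    the region's parental memory; the chloroplast is truly unmethylated
    and reported with allele "ambiguous".
    """
    _check_genotype(genotype)
    cfg = truth.config.methylome
    if seed is None:
        seed = child_seed(truth.config.seed, "methylome", genotype, replicate)
    rng = np.random.default_rng(seed)
    chloroplast = truth.config.genome.chloroplast_name
    if contigs is None:
        contigs = list(truth.genome.contigs)

    frames = []
    for contig in contigs:
        seq = truth.genome[contig]
        plus, minus, ctx_plus, ctx_minus = _cytosine_positions(seq)
        for strand, positions, contexts in (("+", plus, ctx_plus),
                                            ("-", minus, ctx_minus)):
            ok = contexts != ""
            positions, contexts = positions[ok], contexts[ok]
            p_true = np.zeros(len(positions))
            if contig != chloroplast:
                for context, level in cfg.baseline.items():
                    p_true[contexts == context] = level
                regions = truth.meth_regions
                for region_id, r in regions[regions["contig"] ==
                                            contig].iterrows():
                    level = region_chh_level(truth, region_id, genotype)
                    inside = (positions >= r["start"]) & \
                        (positions < r["end"]) & (contexts == "CHH")
                    p_true[inside] = level
            p_obs = p_true + (1.0 - p_true) * (1.0 - cfg.conversion_rate)
            if contig == chloroplast:
                depth = rng.poisson(cfg.depth, len(positions))
                meth = rng.binomial(depth, p_obs)
                frames.append(pd.DataFrame({
                    "contig": contig, "pos": positions, "strand": strand,
                    "context": contexts, "n_meth": meth, "n_total": depth,
                    "allele": "ambiguous"}))
            else:
                for allele, frac in (("maternal", cfg.maternal_fraction),
                                     ("paternal",
                                      1.0 - cfg.maternal_fraction)):
                    depth = rng.poisson(cfg.depth * frac, len(positions))
                    meth = rng.binomial(depth, p_obs)
                    frames.append(pd.DataFrame({
                        "contig": contig, "pos": positions,
                        "strand": strand, "context": contexts,
                        "n_meth": meth, "n_total": depth, "allele": allele}))
    out = pd.concat(frames, ignore_index=True)
    out["n_unmeth"] = out["n_total"] - out["n_meth"]
    return out


# ---------------------------------------------------------------------------
# NanoPARE-style 5' ends
# ---------------------------------------------------------------------------

def simulate_nanopare(truth: GroundTruth, genotype: str, replicate: int = 0,
                      seed: int | None = None) -> pd.DataFrame:
    """Per-nucleotide 5'-end counts (contig, pos, strand, count) for one
    library.

    Each gene gets a TSS spike at its annotated 5' end scaled to its mRNA
    mean in this genotype; cleavage-target genes additionally get an
    internal spike at their midpoint whenever their sRNA locus is active
    in this genotype (absent in the null). A sparse uniform noise floor
    covers gene bodies.
    """
    _check_genotype(genotype)
    cfg = truth.config.nanopare
    if seed is None:
        seed = child_seed(truth.config.seed, "nanopare", genotype, replicate)
    rng = np.random.default_rng(seed)
    rows = []
    for gene_id, g in truth.genes.iterrows():
        tss = int(g["start"]) if g["strand"] == "+" else int(g["end"]) - 1
        mean = truth.mrna_mean(gene_id, genotype)
        count = int(rng.poisson(cfg.tss_scale * mean))
        if count:
            rows.append((g["contig"], tss, g["strand"], count))
        if g["cleavage_target"] and locus_active(LOCUS_POLIV, genotype):
            site = int((g["start"] + g["end"]) // 2)
            count = int(rng.poisson(cfg.cleavage_mean))
            if count:
                rows.append((g["contig"], site, g["strand"], count))
        n_noise = rng.poisson(cfg.noise_per_bp * (g["end"] - g["start"]))
        for _ in range(n_noise):
            pos = int(rng.integers(g["start"], g["end"]))
            rows.append((g["contig"], pos, g["strand"], 1))
    df = pd.DataFrame(rows, columns=["contig", "pos", "strand", "count"])
    return df.groupby(["contig", "pos", "strand"], as_index=False)["count"] \
        .sum()
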