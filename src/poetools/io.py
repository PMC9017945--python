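"""Readers, writers and domain types for the formats the pipeline touches.

All internal coordinates are 0-based half-open; every conversion from a
1-based convention (VCF POS, GFF3 start/end) happens here, at the I/O
boundary, and nowhere else.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGTN")

#: column order of the documented SAM-like tab-separated alignment dialect
ALIGNMENT_COLUMNS = ("read_id", "contig", "start", "strand", "sequence", "n_hits")

#: column order of the CX-style per-cytosine methylation table
CX_COLUMNS = ("contig", "pos", "strand", "context", "n_meth", "n_unmeth", "allele")


class FormatError(ValueError):
    """A malformed input file or record."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """An in-memory genome: ordered mapping of contig name -> uppercase sequence."""

    contigs: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self.contigs == other.contigs


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic single-nucleotide substitution between the parental genomes.

    ``parent_of_ref`` names which parental genome carries ``ref_base`` (in a
    Ler mother x Col-0 reference cross the reference allele is paternal).
    """

    contig: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    parent_of_ref: str = "paternal"

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise FormatError(f"SNP at {self.contig}:{self.position} has ref == alt")
        if self.parent_of_ref not in ("maternal", "paternal"):
            raise FormatError(f"bad parent_of_ref {self.parent_of_ref!r}")

    @property
    def maternal_base(self) -> str:
        return self.ref_base if self.parent_of_ref == "maternal" else self.alt_base

    @property
    def paternal_base(self) -> str:
        return self.ref_base if self.parent_of_ref == "paternal" else self.alt_base


class SnpTable:
    """Sorted, per-contig-indexed collection of :class:`SnpRecord`."""

    def __init__(self, records: list[SnpRecord]):
        records = sorted(records, key=lambda r: (r.contig, r.position))
        for a, b in zip(records, records[1:]):
            if a.contig == b.contig and a.position == b.position:
                raise FormatError(
                    f"duplicate SNP position {a.contig}:{a.position}"
                )
        self.records = records
        self._by_contig: dict[str, tuple[list[int], list[SnpRecord]]] = {}
        for rec in records:
            pos, recs = self._by_contig.setdefault(rec.contig, ([], []))
            pos.append(rec.position)
            recs.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, SnpTable) and self.records == other.records

    def in_span(self, contig: str, start: int, end: int) -> list[SnpRecord]:
        """SNPs with position in the half-open interval [start, end)."""
        if contig not in self._by_contig:
            return []
        pos, recs = self._by_contig[contig]
        return recs[bisect_left(pos, start):bisect_right(pos, end - 1)]

    def swap_parents(self) -> "SnpTable":
        """Exchange the maternal/paternal designation of every record."""
        flip = {"maternal": "paternal", "paternal": "maternal"}
        return SnpTable(
            [
                SnpRecord(r.contig, r.position, r.ref_base, r.alt_base,
                          flip[r.parent_of_ref])
                for r in self.records
            ]
        )


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with a feature identity and class."""

    contig: str
    start: int
    end: int
    strand: str = "."
    feature_id: str = ""
    feature_class: str = "other"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"bad interval {self.feature_id}: [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read; ``start`` is the 5'-most reference coordinate of the
    alignment span (not the biological 5' end for minus-strand reads)."""

    read_id: str
    contig: str
    start: int
    strand: str
    sequence: str
    n_hits: int = 1

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class MethylCall:
    """Bisulfite evidence for one cytosine on one strand (one allele bin)."""

    contig: str
    position: int
    strand: str
    context: str  # CG | CHG | CHH (or "" before context annotation)
    n_methylated: int
    n_total: int
    allele: str = "ambiguous"  # maternal | paternal | ambiguous

    def __post_init__(self):
        if not (0 <= self.n_methylated <= self.n_total):
            raise FormatError("need 0 <= n_methylated <= n_total")


class CountMatrix:
    """Features x samples non-negative count matrix with metadata.

    Thin wrapper over a pandas DataFrame (``counts``), a per-feature class
    Series (``feature_class``) and a per-sample metadata DataFrame
    (``sample_meta`` with columns ``genotype`` and ``replicate``).
    """

    GENOTYPES = ("WT", "mat_het", "pat_het", "null")

    def __init__(self, counts: pd.DataFrame, feature_class: pd.Series | None = None,
                 sample_meta: pd.DataFrame | None = None):
        if (np.asarray(counts) < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        if feature_class is None:
            feature_class = pd.Series("other", index=counts.index)
        self.feature_class = feature_class.reindex(counts.index)
        if sample_meta is None:
            sample_meta = pd.DataFrame(index=counts.columns)
        if "genotype" in sample_meta:
            bad = set(sample_meta["genotype"]) - set(self.GENOTYPES)
            if bad:
                raise ValueError(f"unknown genotype labels: {sorted(bad)}")
        self.sample_meta = sample_meta.reindex(counts.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_features(self, ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[ids], self.feature_class.loc[ids],
                           self.sample_meta)

    def samples_for(self, genotype: str) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["genotype"] == genotype])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence` (uppercased).

    Raises :class:`FormatError` on duplicate contig names or characters
    outside {A,C,G,T,N}.
    """
    genome = GenomeSequence()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome.contigs:
            raise FormatError(f"duplicate contig name {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - NUCLEOTIDES
        if bad:
            offset = next(i for i, c in enumerate(seq) if c in bad)
            raise FormatError(
                f"non-nucleotide character {seq[offset]!r} in contig "
                f"{record.id} at position {offset}"
            )
        genome.contigs[record.id] = seq
    if not genome.contigs:
        logger.warning("FASTA file %s contained no records", path)
    return genome


def write_genome(genome: GenomeSequence, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF subset (SNPs)
# ---------------------------------------------------------------------------

def read_snps(path, genome: GenomeSequence | None = None,
              parent_of_ref: str = "paternal") -> tuple[SnpTable, int]:
    """Read a VCF-subset file of biallelic SNPs.

    Only biallelic single-nucleotide records are kept (indels and
    multi-allelic records are skipped and counted: the pseudogenome is
    substitution-only, so lengths must be preserved). VCF POS is 1-based and
    converted to 0-based here.

    Returns ``(table, n_skipped)``. If ``genome`` is given, every REF base is
    validated against it (mismatch is a hard error).
    """
    records: list[SnpRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            contig, pos, ref, alt = fields[0], fields[1], fields[3], fields[4]
            if len(ref) != 1 or len(alt) != 1 or "," in alt or ref == alt:
                n_skipped += 1
                continue
            position = int(pos) - 1
            if genome is not None:
                actual = genome[contig][position]
                if actual != ref.upper():
                    raise FormatError(
                        f"REF {ref} at {contig}:{pos} disagrees with genome "
                        f"base {actual}"
                    )
            records.append(SnpRecord(contig, position, ref.upper(), alt.upper(),
                                     parent_of_ref))
    return SnpTable(records), n_skipped


def write_snps(snps: SnpTable, path) -> None:
    """Write a minimal VCF (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in snps:
            fh.write(f"{r.contig}\t{r.position + 1}\t.\t{r.ref_base}\t"
                     f"{r.alt_base}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# BED / GFF3 intervals
# ---------------------------------------------------------------------------

def read_intervals(path, dialect: str, feature_class: str | None = None,
                   class_map: dict[str, str] | None = None) -> list[GenomicInterval]:
    """Read BED (taken verbatim, 0-based half-open) or GFF3 (1-based closed,
    converted to 0-based half-open) intervals.

    For GFF3 the feature class comes from mapping column 3 (type) through
    ``class_map``; for BED a uniform ``feature_class`` may be supplied.
    """
    if dialect not in ("BED", "GFF3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            f = line.split("\t")
            try:
                if dialect == "BED":
                    contig, start, end = f[0], int(f[1]), int(f[2])
                    name = f[3] if len(f) > 3 else f"{contig}:{start}-{end}"
                    strand = f[5] if len(f) > 5 else "."
                    cls = feature_class or "other"
                else:
                    contig = f[0]
                    start, end = int(f[3]) - 1, int(f[4])
                    strand = f[6] if f[6] in "+-" else "."
                    cls = (class_map or {}).get(f[2], feature_class or "other")
                    name = _gff_attr(f[8], "ID") if len(f) > 8 else ""
                    name = name or f"{contig}:{start}-{end}"
                if start >= end:
                    raise FormatError(
                        f"{path} line {lineno}: empty/inverted interval "
                        f"[{start},{end})"
                    )
                out.append(GenomicInterval(contig, start, end, strand, name, cls))
            except (IndexError, ValueError) as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
    return out


def _gff_attr(attrs: str, key: str) -> str:
    for item in attrs.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return ""


def write_intervals_bed(intervals, path) -> None:
    """BED6 writer (score column carries the feature class)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.feature_id}\t"
                     f"{iv.feature_class}\t{iv.strand}\n")


def write_intervals_gff3(intervals, path, source: str = "poetools") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            fh.write(f"{iv.contig}\t{source}\t{iv.feature_class}\t"
                     f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                     f"ID={iv.feature_id}\n")


# ---------------------------------------------------------------------------
# SAM-like alignment TSV
# ---------------------------------------------------------------------------

def read_alignments(path, genome: GenomeSequence | None = None,
                    max_bad_lines: int = 100):
    """Stream :class:`AlignedRead` records from the 6-column TSV dialect.

    Malformed or empty-sequence lines are skipped and counted, up to
    ``max_bad_lines`` (beyond which a :class:`FormatError` is raised). A
    contig missing from ``genome`` (when given) is a hard error. This is a
    generator; the skip count is available afterwards on the generator's
    ``.n_skipped`` attribute via :func:`read_alignments_list`.
    """
    return _AlignmentReader(path, genome, max_bad_lines)


class _AlignmentReader:
    def __init__(self, path, genome, max_bad_lines):
        self.path = path
        self.genome = genome
        self.max_bad_lines = max_bad_lines
        self.n_skipped = 0

    def __iter__(self):
        with open(self.path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                try:
                    read_id, contig, start, strand, seq, n_hits = f[:6]
                    start = int(start)
                    n_hits = int(n_hits)
                    if not seq or strand not in "+-" or n_hits < 1 or start < 0:
                        raise ValueError("malformed record")
                except ValueError:
                    self.n_skipped += 1
                    if self.n_skipped > self.max_bad_lines:
                        raise FormatError(
                            f"{self.path}: more than {self.max_bad_lines} "
                            "malformed lines"
                        )
                    continue
                if self.genome is not None:
                    if contig not in self.genome:
                        raise FormatError(f"unknown contig {contig!r} in "
                                          f"{self.path}")
                yield AlignedRead(read_id, contig, start, strand, seq.upper(),
                                  n_hits)


def read_alignments_list(path, genome: GenomeSequence | None = None,
                         max_bad_lines: int = 100):
    """Eager variant of :func:`read_alignments`; returns (reads, n_skipped)."""
    reader = _AlignmentReader(path, genome, max_bad_lines)
    reads = list(reader)
    return reads, reader.n_skipped


def write_alignments(reads, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ALIGNMENT_COLUMNS) + "\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.contig}\t{r.start}\t{r.strand}\t"
                     f"{r.sequence}\t{r.n_hits}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track, path, name: str = "track") -> None:
    """Write (contig, start, end, value) tuples as bedGraph.

    Unsorted input is sorted first (with a warning); spans must be
    non-negative.
    """
    track = list(track)
    if track != sorted(track, key=lambda t: (t[0], t[1])):
        warnings.warn("bedGraph input not sorted; sorting before writing")
        track = sorted(track, key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for contig, start, end, value in track:
            if end < start:
                raise FormatError(f"negative span [{start},{end})")
            fh.write(f"{contig}\t{start}\t{end}\t{value:g}\n")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            contig, start, end, value = line.split("\t")
            out.append((contig, int(start), int(end), float(value)))
    return out


# ---------------------------------------------------------------------------
# CX-style per-cytosine methylation table
# ---------------------------------------------------------------------------

def read_methylation(path) -> pd.DataFrame:
    """Read a CX-style TSV into the canonical methylation table.

    Columns: contig, pos (0-based), strand, context, n_meth, n_unmeth,
    allele. Returns a DataFrame with an additional ``n_total`` column.
    """
    df = pd.read_csv(path, sep="\t", comment="#", names=list(CX_COLUMNS),
                     dtype={"contig": str, "pos": np.int64, "strand": str,
                            "context": str, "n_meth": np.int64,
                            "n_unmeth": np.int64, "allele": str})
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        raise FormatError(f"{path}: negative methylation counts")
    df["n_total"] = df["n_meth"] + df["n_unmeth"]
    return df


def write_methylation(table: pd.DataFrame, path) -> None:
    df = table.copy()
    if "n_unmeth" not in df:
        df["n_unmeth"] = df["n_total"] - df["n_meth"]
    df[list(CX_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def write_counts(cm: CountMatrix, path) -> None:
    df = cm.counts.copy()
    df.insert(0, "feature_class", cm.feature_class)
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_counts(path, sample_meta: pd.DataFrame | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    feature_class = df.pop("feature_class")
    return CountMatrix(df, feature_class, sample_meta)
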