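"""Small-RNA preprocessing, size binning, window/feature counting and
simplified cluster calling with predominant-size classification.

Endosperm small RNAs are dominated by 24-nt Pol IV products; the cluster
caller therefore reports, per cluster, the fraction of reads inside the
dicer-size range [dicermin, dicermax] and the modal ("predominant") size,
with an explicit "no predominant size class" outcome for ties or
dicer-poor clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allelic import five_prime_position
from .io import AlignedRead, CountMatrix, GenomicInterval


def deduplicate(reads) -> tuple[list[AlignedRead], int]:
    """Collapse PCR duplicates: one representative per distinct sequence.

    Library protocols attach random terminal bases before amplification, so
    two biological reads rarely share an exact sequence string; identical
    strings are PCR copies. Returns (unique reads, number removed).
    """
    seen: set[str] = set()
    out = []
    for read in reads:
        if read.sequence in seen:
            continue
        seen.add(read.sequence)
        out.append(read)
    return out, len(reads) - len(out)


def bin_by_size(reads, min_size: int = 21, max_size: int = 24,
                denominator: str = "all"):
    """Split reads into per-size bins over [min_size, max_size].

    Returns ``(bins, fractions)`` where ``bins`` maps size -> list of reads
    and ``fractions`` maps size -> fraction of the denominator
    (``denominator="all"`` uses every input read, ``"in_range"`` only reads
    inside the bin range).
    """
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    bins: dict[int, list[AlignedRead]] = {s: [] for s in
                                          range(min_size, max_size + 1)}
    n_total = 0
    for read in reads:
        n_total += 1
        if min_size <= read.length <= max_size:
            bins[read.length].append(read)
    n_in_range = sum(len(v) for v in bins.values())
    denom = n_total if denominator == "all" else n_in_range
    fractions = {s: (len(v) / denom if denom else 0.0)
                 for s, v in bins.items()}
    return bins, fractions


def window_grid(contig_length: int, window_bp: int = 300,
                step_bp: int = 100) -> np.ndarray:
    """Start coordinates of sliding windows tiling [0, contig_length).

    Windows start at multiples of ``step_bp``; the last window is the last
    one whose start lies inside the contig and that retains at least one
    base in it (windows may overhang the contig end, as interval tools do).
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    n = max(1, int(np.ceil((contig_length - window_bp) / step_bp)) + 1)
    starts = np.arange(n) * step_bp
    return starts[starts < contig_length]


def count_windows(reads_by_sample: dict[str, list[AlignedRead]],
                  contig_lengths: dict[str, int], window_bp: int = 300,
                  step_bp: int = 100, mode: str = "overlap",
                  sample_meta: pd.DataFrame | None = None) -> CountMatrix:
    """Count read 5' starts in sliding windows across every contig.

    ``mode="overlap"`` (default, matching interval-intersection tools)
    counts a read in every window containing its 5' coordinate;
    ``mode="conserve"`` counts it only in the window whose start-offset bin
    contains it, so column sums equal read totals. Window feature ids are
    ``contig:start-end``.
    """
    if mode not in ("overlap", "conserve"):
        raise ValueError(f"unknown mode {mode!r}")
    index = []
    slices = {}
    offset = 0
    grids = {}
    for contig, length in contig_lengths.items():
        starts = window_grid(length, window_bp, step_bp)
        grids[contig] = starts
        index.extend(f"{contig}:{s}-{s + window_bp}" for s in starts)
        slices[contig] = (offset, offset + len(starts))
        offset += len(starts)

    data = {}
    k = -(-window_bp // step_bp)  # windows overlapping a point
    for sample, reads in reads_by_sample.items():
        col = np.zeros(offset, dtype=float)
        pos_by_contig: dict[str, list[int]] = {}
        for read in reads:
            pos_by_contig.setdefault(read.contig, []).append(
                five_prime_position(read))
        for contig, positions in pos_by_contig.items():
            if contig not in grids:
                continue
            lo, hi = slices[contig]
            n_windows = hi - lo
            pos = np.asarray(positions)
            if mode == "conserve":
                # positions past the last window start bin into the last
                # window so totals are conserved
                idx = np.minimum(pos // step_bp, n_windows - 1)
                np.add.at(col, lo + idx, 1.0)
            else:
                base = pos // step_bp
                for j in range(k):
                    idx = base - j
                    starts = idx * step_bp
                    ok = (idx >= 0) & (idx < n_windows) & \
                         (pos < starts + window_bp)
                    np.add.at(col, lo + idx[ok], 1.0)
        data[sample] = col
    counts = pd.DataFrame(data, index=index)
    return CountMatrix(counts,
                       pd.Series("window", index=counts.index),
                       sample_meta)


def count_features(reads_by_sample: dict[str, list[AlignedRead]],
                   features: list[GenomicInterval],
                   sample_meta: pd.DataFrame | None = None) -> CountMatrix:
    """Per-feature read counts (5'-start containment, ties to the
    earlier-sorted feature) preserving feature classes."""
    from .allelic import _feature_lookup
    lookup = _feature_lookup(features)
    ids = [f.feature_id for f in features]
    classes = pd.Series([f.feature_class for f in features], index=ids)
    data = {}
    for sample, reads in reads_by_sample.items():
        col = dict.fromkeys(ids, 0.0)
        for read in reads:
            feature = lookup(read.contig, five_prime_position(read))
            if feature is not None:
                col[feature.feature_id] += 1
        data[sample] = [col[i] for i in ids]
    counts = pd.DataFrame(data, index=ids)
    return CountMatrix(counts, classes, sample_meta)


@dataclass
class SrnaCluster:
    """A called sRNA cluster with size composition."""

    interval: GenomicInterval
    total: float
    size_counts: dict[int, float]  # sizes dicermin..dicermax; -1 = "other"
    rpm: float
    dicer_fraction: float
    predominant_size: int | None  # None = no predominant size class

    @property
    def n_reads(self) -> float:
        return self.total


def call_clusters(reads, library_size: int | None = None,
                  mincov_rpm: float = 0.5, pad: int = 75,
                  dicermin: int = 20, dicermax: int = 25,
                  dicer_threshold: float = 0.8,
                  multimappers: str = "weighted") -> list[SrnaCluster]:
    """Call sRNA clusters from one library's aligned reads.

    Read 5'-start positions with coverage are merged into islands; islands
    closer than ``pad`` bp are merged; clusters below ``mincov_rpm`` reads
    per million are discarded. A cluster's predominant size is the modal
    read length within [dicermin, dicermax] when the dicer-range fraction of
    its reads is at least ``dicer_threshold`` and the mode is a strict
    plurality; otherwise there is no predominant size class.

    Multimapped reads (``multimappers="weighted"``) contribute fractional
    weight proportional to the unique-read start coverage within +-pad of
    their reported site, relative to a genome-average unique coverage for
    their unreported alternative sites; ``multimappers="unique"`` drops them.
    """
    if library_size is None:
        library_size = len(reads)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if multimappers not in ("weighted", "unique"):
        raise ValueError(f"unknown multimapper mode {multimappers!r}")

    by_contig: dict[str, list] = {}
    for read in reads:
        by_contig.setdefault(read.contig, []).append(read)

    clusters: list[SrnaCluster] = []
    for contig in sorted(by_contig):
        creads = by_contig[contig]
        pos = np.array([five_prime_position(r) for r in creads])
        unique_mask = np.array([r.n_hits == 1 for r in creads])
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        creads = [creads[i] for i in order]
        unique_mask = unique_mask[order]

        upos = np.sort(pos[unique_mask])
        span = (pos.max() - pos.min() + 2 * pad + 1) if len(pos) else 1
        mean_unique = (2 * pad + 1) * len(upos) / max(span, 1)

        weights = np.ones(len(creads))
        if multimappers == "unique":
            weights[~unique_mask] = 0.0
        else:
            for i, read in enumerate(creads):
                if read.n_hits == 1:
                    continue
                local = np.searchsorted(upos, pos[i] + pad, "right") - \
                    np.searchsorted(upos, pos[i] - pad, "left")
                denom = local + (read.n_hits - 1) * mean_unique
                weights[i] = local / denom if denom > 0 else 0.0

        # merge covered start positions into islands <= pad apart
        keep = weights > 0
        if not keep.any():
            continue
        kpos = pos[keep]
        breaks = np.nonzero(np.diff(kpos) > pad)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(kpos) - 1]])
        kept_idx = np.nonzero(keep)[0]
        for s, e in zip(starts, ends):
            members = kept_idx[s:e + 1]
            total = float(weights[members].sum())
            rpm = 1e6 * total / library_size
            if rpm < mincov_rpm:
                continue
            sizes: dict[int, float] = {sz: 0.0 for sz in
                                       range(dicermin, dicermax + 1)}
            sizes[-1] = 0.0
            lo = int(pos[members].min())
            hi = int(max(creads[i].end for i in members))
            for i in members:
                length = creads[i].length
                key = length if dicermin <= length <= dicermax else -1
                sizes[key] += weights[i]
            dicer_total = total - sizes[-1]
            dicer_fraction = dicer_total / total if total else 0.0
            predominant: int | None = None
            if dicer_fraction >= dicer_threshold and dicer_total > 0:
                in_range = {sz: w for sz, w in sizes.items() if sz != -1}
                best = max(in_range.values())
                modes = [sz for sz, w in in_range.items() if w == best]
                if len(modes) == 1:  # strict plurality; tie -> none
                    predominant = modes[0]
            clusters.append(SrnaCluster(
                GenomicInterval(contig, lo, hi, ".",
                                f"{contig}:{lo}-{hi}", "window"),
                total, sizes, rpm, dicer_fraction, predominant))
    return clusters


def write_clusters_bed(clusters, path) -> None:
    """BED6+ with rpm in the score column and predominant size adjacent."""
    with open(path, "w") as fh:
        for c in clusters:
            iv = c.interval
            size = c.predominant_size if c.predominant_size is not None \
                else "none"
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.feature_id}\t"
                     f"{c.rpm:.3f}\t{iv.strand}\t{size}\t"
                     f"{c.dicer_fraction:.3f}\n")
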