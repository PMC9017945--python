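"""Allelic-bias classification, ISR summarization, and enrichment tests.

A locus is *biallelic* when 20-80% (inclusive) of its allele-informative
reads come from the maternal alleles, maternally biased above 80%, and
paternally biased below 20%; loci with fewer than 10 informative reads are
untestable. ISRs (imprinted sRNA regions) arrive as external interval
sets; their per-genotype signal is summarized as the median count of the
merged windows overlapping each region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allelic import AllelicCounts
from .io import CountMatrix, GenomicInterval

MATERNALLY_BIASED = "maternally_biased"
PATERNALLY_BIASED = "paternally_biased"
BIALLELIC = "biallelic"
UNTESTABLE = "untestable"


@dataclass(frozen=True)
class BiasClass:
    feature_id: str
    percent_maternal: float | None
    bias: str


def classify_bias(allelic_counts: list[AllelicCounts], floor: int = 10,
                  lower: float = 20.0, upper: float = 80.0
                  ) -> list[BiasClass]:
    """Classify loci by percent-maternal sRNA/mRNA origin.

    The boundaries are inclusive toward biallelic: exactly 20% or 80%
    maternal is biallelic. Loci with fewer than ``floor`` informative reads
    are untestable regardless of their point estimate.
    """
    out = []
    for ac in allelic_counts:
        pm = ac.percent_maternal
        if ac.informative < floor or pm is None:
            cls = UNTESTABLE
        elif pm > upper:
            cls = MATERNALLY_BIASED
        elif pm < lower:
            cls = PATERNALLY_BIASED
        else:
            cls = BIALLELIC
        out.append(BiasClass(ac.feature_id, pm, cls))
    return out


def _parse_window_id(feature_id: str) -> tuple[str, int, int]:
    contig, span = feature_id.rsplit(":", 1)
    start, end = span.split("-")
    return contig, int(start), int(end)


def isr_summary(window_counts: CountMatrix, isr_intervals: list[GenomicInterval],
                normalize: pd.Series | None = None,
                differential: pd.DataFrame | None = None) -> pd.DataFrame:
    """Median per-genotype window counts over each imprinted sRNA region.

    For each ISR the overlapping count windows are found, (transitively)
    merged, and the median normalized count per sample reported (median of
    an even window count is the midpoint of the two central values). ISRs
    with no overlapping window are reported with missing values. When a
    ``differential`` result table indexed by window id is supplied, the
    fraction of the ISR's windows called up/down is attached.
    """
    ids = window_counts.feature_ids
    parsed = [_parse_window_id(i) for i in ids]
    counts = window_counts.counts
    if normalize is not None:
        counts = counts / normalize.reindex(counts.columns)
    rows = []
    for isr in isr_intervals:
        member_idx = [i for i, (c, s, e) in enumerate(parsed)
                      if c == isr.contig and s < isr.end and e > isr.start]
        row: dict = {"isr_id": isr.feature_id, "contig": isr.contig,
                     "start": isr.start, "end": isr.end,
                     "n_windows": len(member_idx)}
        if member_idx:
            sub = counts.iloc[member_idx]
            for sample in counts.columns:
                row[f"median_{sample}"] = float(np.median(sub[sample]))
            if differential is not None:
                calls = differential.reindex([ids[i] for i in member_idx])
                row["n_windows_called"] = int(
                    calls["call"].isin(["up", "down"]).sum())
        else:
            for sample in counts.columns:
                row[f"median_{sample}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def hypergeom_enrichment(k_overlap: int, set1_size: int, set2_size: int,
                         universe_size: int) -> float:
    """Upper-tail hypergeometric overlap probability P(X >= k).

    X counts the overlap when ``set2_size`` draws are taken from a universe
    containing ``set1_size`` marked elements. Computed with the exact
    (log-space stable) hypergeometric survival function.
    """
    if not (0 <= k_overlap <= min(set1_size, set2_size) and
            max(set1_size, set2_size) <= universe_size):
        raise ValueError(
            f"inconsistent sizes: k={k_overlap}, sets=({set1_size}, "
            f"{set2_size}), universe={universe_size}"
        )
    return float(stats.hypergeom.sf(k_overlap - 1, universe_size,
                                    set1_size, set2_size))
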