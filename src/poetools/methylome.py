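"""Windowed bisulfite methylation quantification and dosage-aware DMR calling.

The canonical in-memory methylome is a pandas DataFrame with one row per
(cytosine, strand, allele) carrying ``contig, pos, strand, context,
n_meth, n_total, allele`` (the CX-style table from :mod:`poetools.io`).

Comparisons follow the endosperm-specific filter chain: windows need at
least 3 cytosines informative in BOTH samples and a mean depth of 6 reads
per such cytosine; windows whose DNA reads are not ~2/3 maternal
(67 +/- 15%) are discarded (triploid dosage filter against allele-biased
coverage); windows methylation-variable between replicates of one genotype
are masked; and context-specific difference thresholds (CHH 10, CHG 20,
CG 30 percentage points) define differential windows that merge into DMRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeSequence
from .srna import window_grid

CONTEXT_THRESHOLDS = {"CHH": 10.0, "CHG": 20.0, "CG": 30.0}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _context_of(triplet: str) -> str:
    """CG/CHG/CHH from a 5'->3' triplet starting at the cytosine."""
    if len(triplet) < 2:
        return ""
    if triplet[1] == "G":
        return "CG"
    if len(triplet) < 3:
        return ""
    return "CHG" if triplet[2] == "G" else "CHH"


def pileup_contexts(calls: pd.DataFrame, genome: GenomeSequence) -> pd.DataFrame:
    """Annotate each cytosine call with its CG/CHG/CHH context.

    ``pos`` is the reference coordinate of the cytosine; for minus-strand
    calls the cytosine pairs with a reference G and its context is read
    5'->3' on the reverse complement. Calls whose reference base is not C
    (plus strand) or G (minus strand) are a hard error; cytosines too close
    to a contig end for their context to be determined are dropped.
    """
    out = []
    for (contig, strand), grp in calls.groupby(["contig", "strand"],
                                               sort=False):
        seq = genome[contig]
        L = len(seq)
        pos = grp["pos"].to_numpy()
        if strand == "+":
            bases = np.array([seq[p] for p in pos])
            if (bases != "C").any():
                bad = pos[bases != "C"][0]
                raise ValueError(
                    f"call at {contig}:{bad}(+) is not a reference C")
            keep = pos <= L - 2
            ctx = [_context_of(seq[p:p + 3]) for p in pos[keep]]
        else:
            bases = np.array([seq[p] for p in pos])
            if (bases != "G").any():
                bad = pos[bases != "G"][0]
                raise ValueError(
                    f"call at {contig}:{bad}(-) is not a reference G")
            keep = pos >= 1
            ctx = [_context_of(
                seq[max(p - 2, 0):p + 1].translate(_COMPLEMENT)[::-1])
                for p in pos[keep]]
        sub = grp.loc[keep].copy()
        sub["context"] = ctx
        out.append(sub)
    result = pd.concat(out, ignore_index=True) if out else calls.iloc[0:0]
    return result[result["context"] != ""].reset_index(drop=True)


def conversion_qc(calls: pd.DataFrame, chloroplast_contig: str,
                  min_depth: int = 10, floor: float = 98.0
                  ) -> tuple[float, bool]:
    """Estimate bisulfite conversion from the (unmethylated) chloroplast.

    Pools cytosines on the chloroplast contig with total depth >=
    ``min_depth`` (summed over alleles/strand rows at one position) and
    returns ``(rate_percent, passed)`` where
    rate = 100 * (1 - sum(meth)/sum(total)) and ``passed`` is rate >= floor.
    """
    cp = calls[calls["contig"] == chloroplast_contig]
    per_site = cp.groupby(["pos", "strand"])[["n_meth", "n_total"]].sum()
    per_site = per_site[per_site["n_total"] >= min_depth]
    if per_site.empty:
        raise ValueError(
            f"no chloroplast cytosine reaches depth {min_depth}; cannot "
            "estimate conversion"
        )
    rate = 100.0 * (1.0 - per_site["n_meth"].sum() / per_site["n_total"].sum())
    return rate, rate >= floor


def _collapse_alleles(calls: pd.DataFrame) -> pd.DataFrame:
    """Sum evidence over alleles/strand rows per (contig, pos, strand)."""
    return (calls.groupby(["contig", "pos", "strand", "context"],
                          as_index=False)[["n_meth", "n_total"]].sum())


def window_methylation(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                       contig_lengths: dict[str, int], window_bp: int = 300,
                       step_bp: int = 100, min_common_c: int = 3,
                       min_depth: float = 6.0,
                       depth_rule: str = "mean") -> pd.DataFrame:
    """Per-window, per-context methylation for two conditions on the common
    informative cytosines.

    Only cytosines covered (n_total > 0) in BOTH conditions contribute.
    Windows are kept when they hold >= ``min_common_c`` common cytosines
    and the per-condition depth over those cytosines satisfies
    ``min_depth`` (``depth_rule="mean"`` compares the mean depth,
    ``"strict"`` requires every cytosine to reach it). Percent methylation
    is the coverage-weighted 100 * sum(m)/sum(t).

    Returns a DataFrame with columns contig, start, end, context,
    n_common, pct_a, pct_b, depth_a, depth_b, delta (= pct_b - pct_a) and
    the underlying count sums.
    """
    a = _collapse_alleles(calls_a)
    b = _collapse_alleles(calls_b)
    merged = a.merge(b, on=["contig", "pos", "strand", "context"],
                     how="inner", suffixes=("_a", "_b"))
    merged = merged[(merged["n_total_a"] > 0) & (merged["n_total_b"] > 0)]

    rows = []
    k = -(-window_bp // step_bp)
    for (contig, context), grp in merged.groupby(["contig", "context"],
                                                 sort=True):
        if contig not in contig_lengths:
            continue
        starts = window_grid(contig_lengths[contig], window_bp, step_bp)
        n_windows = len(starts)
        pos = grp["pos"].to_numpy()
        cols = {c: grp[c].to_numpy(dtype=float)
                for c in ("n_meth_a", "n_total_a", "n_meth_b", "n_total_b")}
        base = pos // step_bp
        pieces = []
        for j in range(k):
            idx = base - j
            w_start = idx * step_bp
            ok = (idx >= 0) & (idx < n_windows) & (pos < w_start + window_bp)
            if not ok.any():
                continue
            agg = pd.DataFrame({"idx": idx[ok]})
            for c, v in cols.items():
                agg[c] = v[ok]
            agg["n"] = 1.0
            if depth_rule == "strict":
                agg["ok_depth"] = ((agg["n_total_a"] >= min_depth) &
                                   (agg["n_total_b"] >= min_depth)) * 1.0
            pieces.append(agg)
        if not pieces:
            continue
        g = pd.concat(pieces).groupby("idx").sum()
        for widx, r in g.iterrows():
            rows.append((contig, int(widx) * step_bp, context,
                         r["n"], r["n_meth_a"], r["n_total_a"],
                         r["n_meth_b"], r["n_total_b"],
                         r.get("ok_depth", np.nan)))
    df = pd.DataFrame(rows, columns=["contig", "start", "context", "n_common",
                                     "m_a", "t_a", "m_b", "t_b", "n_deep"])
    if df.empty:
        return df
    df["end"] = df["start"] + window_bp
    df["depth_a"] = df["t_a"] / df["n_common"]
    df["depth_b"] = df["t_b"] / df["n_common"]
    keep = df["n_common"] >= min_common_c
    if depth_rule == "strict":
        keep &= df["n_deep"] == df["n_common"]
    else:
        keep &= (df["depth_a"] >= min_depth) & (df["depth_b"] >= min_depth)
    df = df[keep].copy()
    df["pct_a"] = 100.0 * df["m_a"] / df["t_a"]
    df["pct_b"] = 100.0 * df["m_b"] / df["t_b"]
    df["delta"] = df["pct_b"] - df["pct_a"]
    cols = ["contig", "start", "end", "context", "n_common", "pct_a",
            "pct_b", "delta", "depth_a", "depth_b", "m_a", "t_a", "m_b",
            "t_b"]
    return df[cols].sort_values(["contig", "context", "start"]) \
        .reset_index(drop=True)


def window_maternal_fraction(calls: pd.DataFrame,
                             contig_lengths: dict[str, int],
                             window_bp: int = 300,
                             step_bp: int = 100) -> pd.DataFrame:
    """Percent-maternal DNA read fraction per window from allele-resolved
    coverage (rows with allele maternal/paternal; ambiguous rows ignored)."""
    res = calls[calls["allele"].isin(["maternal", "paternal"])]
    rows = []
    k = -(-window_bp // step_bp)
    for contig, grp in res.groupby("contig", sort=True):
        if contig not in contig_lengths:
            continue
        starts = window_grid(contig_lengths[contig], window_bp, step_bp)
        n_windows = len(starts)
        pos = grp["pos"].to_numpy()
        mat = np.where(grp["allele"].to_numpy() == "maternal",
                       grp["n_total"].to_numpy(dtype=float), 0.0)
        tot = grp["n_total"].to_numpy(dtype=float)
        base = pos // step_bp
        mat_sum = np.zeros(n_windows)
        tot_sum = np.zeros(n_windows)
        for j in range(k):
            idx = base - j
            w_start = idx * step_bp
            ok = (idx >= 0) & (idx < n_windows) & (pos < w_start + window_bp)
            np.add.at(mat_sum, idx[ok], mat[ok])
            np.add.at(tot_sum, idx[ok], tot[ok])
        informative = tot_sum > 0
        rows.append(pd.DataFrame({
            "contig": contig,
            "start": starts[informative],
            "end": starts[informative] + window_bp,
            "percent_maternal": 100.0 * mat_sum[informative] /
            tot_sum[informative],
            "n_allelic_reads": tot_sum[informative],
        }))
    if not rows:
        return pd.DataFrame(columns=["contig", "start", "end",
                                     "percent_maternal", "n_allelic_reads"])
    return pd.concat(rows, ignore_index=True)


def dosage_filter(windows: pd.DataFrame, maternal_fraction: pd.DataFrame,
                  center: float = 67.0, tolerance: float = 15.0
                  ) -> pd.DataFrame:
    """Keep windows whose DNA reads are ``center +/- tolerance`` percent
    maternal (inclusive bounds, default [52, 82]); windows with no
    allele-informative DNA reads are dropped."""
    frac = maternal_fraction.set_index(["contig", "start"])["percent_maternal"]
    key = list(zip(windows["contig"], windows["start"]))
    pm = np.array([frac.get(k, np.nan) for k in key])
    keep = np.isfinite(pm) & (pm >= center - tolerance) & \
        (pm <= center + tolerance)
    return windows[keep].reset_index(drop=True)


def _merge_spans(spans: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping-or-touching (contig, start, end) spans."""
    merged: list[list] = []
    for contig, start, end in sorted(spans):
        if merged and merged[-1][0] == contig and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([contig, start, end])
    return [tuple(m) for m in merged]


def replicate_mask(windows_rep_pair: pd.DataFrame,
                   thresholds: dict[str, float] = CONTEXT_THRESHOLDS
                   ) -> list[tuple[str, int, int, str]]:
    """Regions methylation-variable between two replicates of one genotype.

    ``windows_rep_pair`` is :func:`window_methylation` output for rep1 vs
    rep2. Windows whose |delta| meets the context's DMR threshold are
    merged (per context) into an exclusion set of (contig, start, end,
    context) spans.
    """
    out = []
    for context, grp in windows_rep_pair.groupby("context"):
        thr = thresholds.get(context)
        if thr is None:
            continue
        flagged = grp[np.abs(grp["delta"]) >= thr]
        spans = _merge_spans(list(zip(flagged["contig"], flagged["start"],
                                      flagged["end"])))
        out.extend((c, s, e, context) for c, s, e in spans)
    return out


def apply_mask(windows: pd.DataFrame,
               mask: list[tuple[str, int, int, str]]) -> pd.DataFrame:
    """Drop windows overlapping any mask span of the same context."""
    if not mask or windows.empty:
        return windows
    drop = np.zeros(len(windows), dtype=bool)
    for contig, mstart, mend, context in mask:
        drop |= ((windows["contig"] == contig) &
                 (windows["context"] == context) &
                 (windows["start"] < mend) &
                 (windows["end"] > mstart)).to_numpy()
    return windows[~drop].reset_index(drop=True)


@dataclass
class Dmr:
    """A merged differentially methylated region (condition B vs A)."""

    contig: str
    start: int
    end: int
    context: str
    direction: str  # hyper | hypo (B relative to A)
    pct_a: float
    pct_b: float
    n_windows: int

    @property
    def delta(self) -> float:
        return self.pct_b - self.pct_a


def call_dmrs(windows: pd.DataFrame,
              thresholds: dict[str, float] = CONTEXT_THRESHOLDS) -> list[Dmr]:
    """Merge same-context, same-direction differential windows into DMRs.

    A window is differential when |pct_b - pct_a| >= the context threshold.
    Overlapping differential windows of one context and direction merge;
    the merged region's percent methylation is recomputed from the summed
    constituent-window counts. Mixed-direction overlaps are never merged.
    """
    dmrs: list[Dmr] = []
    for (context, _), grp in windows.groupby(
            ["context", np.sign(windows["delta"])]):
        thr = thresholds.get(context)
        if thr is None:
            continue
        flagged = grp[np.abs(grp["delta"]) >= thr].sort_values(
            ["contig", "start"])
        if flagged.empty:
            continue
        direction = "hyper" if flagged["delta"].iloc[0] > 0 else "hypo"
        current: list = []
        for row in flagged.itertuples():
            if current and current[-1].contig == row.contig and \
                    row.start < current[-1].end:
                current.append(row)
            else:
                if current:
                    dmrs.append(_finish_dmr(current, context, direction))
                current = [row]
        if current:
            dmrs.append(_finish_dmr(current, context, direction))
    dmrs.sort(key=lambda d: (d.contig, d.start, d.context))
    return dmrs


def _finish_dmr(rows, context, direction) -> Dmr:
    m_a = sum(r.m_a for r in rows)
    t_a = sum(r.t_a for r in rows)
    m_b = sum(r.m_b for r in rows)
    t_b = sum(r.t_b for r in rows)
    return Dmr(rows[0].contig, min(r.start for r in rows),
               max(r.end for r in rows), context, direction,
               100.0 * m_a / t_a, 100.0 * m_b / t_b, len(rows))
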