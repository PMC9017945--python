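"""Antagonistic parental-effect inference on endosperm transcriptomes.

Reciprocal heterozygotes separate the two parental contributions: a gene
whose transcript rises when the mutation comes through the mother but
falls when it comes through the father (or vice versa) is under
*antagonistic* maternal/paternal control. If the mutation has no zygotic
effect, the homozygous null should show the *sum* of the two parental
log2 effects -- the additive prediction tested here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


SET_LABELS = ("mat_only", "pat_only", "both_het", "mat_and_null",
              "pat_and_null", "null_only", "all_three", "none")


def _called(call) -> bool:
    return call in ("up", "down")


def partition_sets(res_mat: pd.DataFrame, res_pat: pd.DataFrame,
                   res_null: pd.DataFrame) -> pd.DataFrame:
    """Label each gene by which contrasts call it misregulated.

    The three inputs are classified differential tables (columns
    ``log2_fold_change`` and ``call``) for mat_het vs WT, pat_het vs WT and
    null vs WT. Gene universes are intersected (with a warning when they
    differ). The ``set_label`` partition is driven by the two heterozygote
    contrasts with the null used to split maternal-only genes
    (``mat_only`` vs ``mat_and_null``), mirroring how the misregulation
    sets are compared downstream.
    """
    import warnings

    universe = res_mat.index.intersection(res_pat.index) \
        .intersection(res_null.index)
    if not (len(universe) == len(res_mat) == len(res_pat) == len(res_null)):
        warnings.warn("gene universes differ between contrasts; "
                      "restricting to their intersection")
    rows = []
    for gene in universe:
        cm, cp, cn = (res_mat.loc[gene, "call"], res_pat.loc[gene, "call"],
                      res_null.loc[gene, "call"])
        in_m, in_p, in_n = _called(cm), _called(cp), _called(cn)
        if in_m and in_p:
            label = "all_three" if in_n else "both_het"
        elif in_m:
            label = "mat_and_null" if in_n else "mat_only"
        elif in_p:
            label = "pat_and_null" if in_n else "pat_only"
        elif in_n:
            label = "null_only"
        else:
            label = "none"
        rows.append({
            "gene_id": gene,
            "lfc_mat": res_mat.loc[gene, "log2_fold_change"],
            "lfc_pat": res_pat.loc[gene, "log2_fold_change"],
            "lfc_null": res_null.loc[gene, "log2_fold_change"],
            "call_mat": cm, "call_pat": cp, "call_null": cn,
            "set_label": label,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def opposite_direction_test(res_mat: pd.DataFrame, res_pat: pd.DataFrame
                            ) -> dict:
    """Count genes misregulated in both heterozygotes and test whether
    opposite-direction changes are enriched.

    ``shared`` genes are those called in both contrasts; an ``opposite``
    gene has sign(log2FC_mat) != sign(log2FC_pat). Under the null that
    direction in one contrast is independent of the other, the number of
    same-direction up/up genes among the shared set is hypergeometric in
    the two up-margins; the reported p is the upper-tail probability of at
    least the observed number of opposite-direction genes.
    """
    universe = res_mat.index.intersection(res_pat.index)
    m = res_mat.loc[universe]
    p = res_pat.loc[universe]
    shared = universe[[_called(a) and _called(b)
                       for a, b in zip(m["call"], p["call"])]]
    n_shared = len(shared)
    if n_shared == 0:
        return {"n_shared": 0, "n_opposite": 0, "p_enrichment": None}
    sm = np.sign(m.loc[shared, "log2_fold_change"])
    sp = np.sign(p.loc[shared, "log2_fold_change"])
    n_opposite = int((sm != sp).sum())
    m_up = int((sm > 0).sum())
    p_up = int((sp > 0).sum())
    # opposite = m_up + p_up - 2*X with X = #(up in both) hypergeometric
    x_max = (m_up + p_up - n_opposite) / 2
    p_enrich = float(stats.hypergeom.cdf(np.floor(x_max), n_shared, m_up,
                                         p_up))
    return {"n_shared": n_shared, "n_opposite": n_opposite,
            "p_enrichment": p_enrich}


def additive_prediction(lfc_mat, lfc_pat):
    """Predicted null log2FC under purely additive parental effects.

    Returns ``(predicted_log2fc, predicted_fold)`` where the fold is
    2**predicted_log2fc; commutative and linear in its arguments.
    """
    pred = np.asarray(lfc_mat, dtype=float) + np.asarray(lfc_pat, dtype=float)
    return pred, 2.0 ** pred


def additivity_table(triples: pd.DataFrame) -> pd.DataFrame:
    """Per-gene observed-vs-predicted null effects (genes with both
    heterozygote estimates; others skipped)."""
    ok = triples[["lfc_mat", "lfc_pat", "lfc_null"]].notna().all(axis=1)
    sub = triples[ok]
    pred, fold = additive_prediction(sub["lfc_mat"], sub["lfc_pat"])
    return pd.DataFrame({
        "lfc_null_observed": sub["lfc_null"],
        "lfc_null_predicted": pred,
        "fold_predicted": fold,
        "discrepancy": sub["lfc_null"] - pred,
    }, index=sub.index)


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def inverse_slope(triples: pd.DataFrame, genes=None, x: str = "lfc_mat",
                  y: str = "lfc_pat") -> SlopeFit:
    """Ordinary least squares of the paternal on the maternal effect.

    A negative slope over a gene class quantifies the inverse mat/pat
    relationship. Needs >= 3 genes and nonzero variance in x; otherwise the
    fit is undefined (NaN fields).
    """
    sub = triples if genes is None else triples.loc[genes]
    sub = sub[[x, y]].dropna()
    if len(sub) < 3 or np.isclose(sub[x].var(), 0.0):
        return SlopeFit(np.nan, np.nan, np.nan, len(sub))
    fit = stats.linregress(sub[x], sub[y])
    return SlopeFit(float(fit.slope), float(fit.intercept),
                    float(fit.rvalue ** 2), len(sub))


def antagonism_summary(res_mat: pd.DataFrame, res_pat: pd.DataFrame,
                       res_null: pd.DataFrame) -> dict:
    """Full antagonism analysis: set partition, opposite-direction test,
    additivity, and the class-wise inverse-slope fits."""
    triples = partition_sets(res_mat, res_pat, res_null)
    opposite = opposite_direction_test(res_mat, res_pat)
    # slope classes condition on the maternal and null calls only: the
    # inverse mat/pat relationship shows up in genes misregulated upon loss
    # of maternal function but NOT in the null (where the two parental
    # pulls cancel), regardless of whether the paternal contrast reaches
    # its own call threshold
    mat_called = triples["call_mat"].isin(["up", "down"])
    null_called = triples["call_null"].isin(["up", "down"])
    slope_classes = {
        "mat_only": triples.index[mat_called & ~null_called],
        "mat_and_null": triples.index[mat_called & null_called],
    }
    slopes = {}
    for label, genes in slope_classes.items():
        fit = inverse_slope(triples, genes)
        slopes[label] = {"slope": fit.slope, "intercept": fit.intercept,
                         "r_squared": fit.r_squared, "n": fit.n}
    return {
        "triples": triples,
        "set_sizes": triples["set_label"].value_counts().to_dict(),
        **opposite,
        "slopes": slopes,
        "additivity": additivity_table(triples),
    }
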