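"""Count-based two-group negative-binomial differential abundance.

The engine combines median-of-ratios size factors computed over a caller
chosen *reference feature set* with a per-feature NB Wald test. The
reference-set twist matters for Pol IV small-RNA libraries: most
TE-derived sRNAs vanish in the nrpd1 null, so a global size-factor
estimate mistakes biology for library depth and deflates every fold
change. Restricting the estimate to genic/miRNA features (whose sRNAs are
largely Pol IV independent) recovers an honest library-size proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

DISPERSION_FLOOR = 1e-8

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"
CALL_UNTESTED = "untested"


def _counts_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def size_factors_from_reference(counts, reference_ids) -> pd.Series:
    """Median-of-ratios size factors over a reference feature subset.

    factor_j = median over reference features i of K_ij / geomean_j(K_ij),
    restricted to reference features whose geometric mean is positive, then
    rescaled to geometric mean 1. With reference = all features this is the
    standard global median-of-ratios estimator.
    """
    mat = _counts_frame(counts)
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("reference_ids must be non-empty")
    ref = mat.loc[reference_ids].to_numpy(dtype=float)
    all_positive = (ref > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no reference feature has positive counts in every sample; "
            "supply a larger reference set"
        )
    ref = ref[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=mat.columns, name="size_factor")


def nb_test(counts, size_factors: pd.Series, groups: dict[str, str] | pd.Series,
            group_a: str | None = None, group_b: str | None = None,
            pseudocount: float = 0.5,
            moderation_df: float = 9.0) -> pd.DataFrame:
    """Per-feature two-group NB Wald test on normalized counts.

    ``groups`` maps sample id -> group label; ``group_a`` is the reference
    condition (defaults to the first label encountered) and the reported
    log2 fold change is condition B over A.

    Per feature: normalized counts q_ij = K_ij / factor_j; the displayed
    log2FC uses a pseudocount (0.5) on the group means, while the Wald
    statistic uses the untransformed means; the NB dispersion is a pooled
    within-group method-of-moments estimate, moderated toward the
    across-feature median dispersion with ``moderation_df`` prior degrees
    of freedom (empirical-Bayes shrinkage; per-feature dispersions from 2-3
    replicates are too noisy to use raw), and floored at 1e-8; the
    two-sided p value refers log2(mean_B/mean_A)/SE (SE by the delta
    method under NB(mean, dispersion)) to a t distribution with
    n_A + n_B - 2 + moderation_df degrees of freedom, matching the
    information in the moderated dispersion estimate (the normal reference
    is anti-conservative at small replicate numbers). Features all-zero in
    both groups get p = NaN (untested).
    """
    mat = _counts_frame(counts)
    groups = pd.Series(groups)
    labels = list(dict.fromkeys(groups[s] for s in mat.columns))
    if group_a is None:
        group_a = labels[0]
    if group_b is None:
        group_b = next(l for l in labels if l != group_a)
    samples_a = [s for s in mat.columns if groups[s] == group_a]
    samples_b = [s for s in mat.columns if groups[s] == group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need at least 2 samples per group")

    sf = size_factors.reindex(mat.columns)
    q = mat.to_numpy(dtype=float) / sf.to_numpy()
    qa = q[:, [mat.columns.get_loc(s) for s in samples_a]]
    qb = q[:, [mat.columns.get_loc(s) for s in samples_b]]
    inv_a = (1.0 / sf[samples_a].to_numpy())
    inv_b = (1.0 / sf[samples_b].to_numpy())

    mean_a, mean_b = qa.mean(axis=1), qb.mean(axis=1)
    var_a = qa.var(axis=1, ddof=1)
    var_b = qb.var(axis=1, ddof=1)
    na, nb = qa.shape[1], qb.shape[1]

    # pooled within-group method-of-moments dispersion:
    # Var(q) = mu * mean(1/s) + alpha * mu^2 per group
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (var_a - mean_a * inv_a.mean()) / mean_a**2
        alpha_b = (var_b - mean_b * inv_b.mean()) / mean_b**2
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        alpha = np.nanmean(
            np.where(np.isfinite(np.stack([alpha_a, alpha_b])),
                     np.stack([alpha_a, alpha_b]), np.nan), axis=0)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    alpha = np.clip(alpha, DISPERSION_FLOOR, None)
    resid_df = (na - 1) + (nb - 1)
    if moderation_df > 0:
        expressed = (mean_a > 0) | (mean_b > 0)
        prior = np.median(alpha[expressed]) if expressed.any() else 0.0
        alpha = (resid_df * alpha + moderation_df * prior) / \
            (resid_df + moderation_df)
        alpha = np.clip(alpha, DISPERSION_FLOOR, None)

    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    # Wald on the untransformed means; empty means are guarded with the
    # pseudocount in the log ratio, and a group observed at zero takes its
    # variance scale from the pooled mean (score-test style) -- the
    # evidence in "no counts at all" is how many were expected, not the
    # guard value, and the guard mean alone grossly understates it
    base_mean = (mean_a * na + mean_b * nb) / (na + nb)
    ma_g = np.where(mean_a > 0, mean_a, pseudocount / na)
    mb_g = np.where(mean_b > 0, mean_b, pseudocount / nb)
    ma_v = np.where(mean_a > 0, mean_a,
                    np.maximum(base_mean, pseudocount / na))
    mb_v = np.where(mean_b > 0, mean_b,
                    np.maximum(base_mean, pseudocount / nb))
    ln2sq = np.log(2.0) ** 2
    var_log_a = (ma_v * inv_a.sum() + alpha * ma_v**2 * na) / na**2 / \
        (ma_v**2 * ln2sq)
    var_log_b = (mb_v * inv_b.sum() + alpha * mb_v**2 * nb) / nb**2 / \
        (mb_v**2 * ln2sq)
    se = np.sqrt(var_log_a + var_log_b)
    wald_fc = np.log2(mb_g / ma_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = wald_fc / se
    p = 2.0 * stats.t.sf(np.abs(z), df=resid_df + moderation_df)
    untested = (mean_a == 0) & (mean_b == 0)
    p = np.where(untested, np.nan, p)
    log2fc = np.where(untested, np.nan, log2fc)

    return pd.DataFrame(
        {
            "base_mean": (mean_a * na + mean_b * nb) / (na + nb),
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "log2_fold_change": log2fc,
            "se": se,
            "dispersion": alpha,
            "p_value": p,
        },
        index=mat.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone); NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def classify_differential(results: pd.DataFrame, min_fold: float = 2.0,
                          alpha: float = 0.05, min_base: float = 5.0
                          ) -> pd.DataFrame:
    """Attach adjusted p values and up/down/ns/untested calls.

    A feature is called up or down only when |log2FC| >= log2(min_fold),
    p_adjusted <= alpha, and the reference-condition normalized mean is at
    least ``min_base`` (features below that count floor are untested).
    """
    out = results.copy()
    if "p_adjusted" not in out:
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    lfc = out["log2_fold_change"].to_numpy()
    padj = out["p_adjusted"].to_numpy()
    base_a = out["base_mean_a"].to_numpy()
    call = np.full(len(out), CALL_NS, dtype=object)
    call[~np.isfinite(padj)] = CALL_UNTESTED
    call[base_a < min_base] = CALL_UNTESTED
    sig = (np.abs(lfc) >= np.log2(min_fold)) & (padj <= alpha) & \
        (base_a >= min_base) & np.isfinite(padj)
    call[sig & (lfc > 0)] = CALL_UP
    call[sig & (lfc < 0)] = CALL_DOWN
    out["call"] = call
    return out


def run_differential(counts, groups, group_a: str, group_b: str,
                     reference_ids=None, min_fold: float = 2.0,
                     alpha: float = 0.05, min_base: float = 5.0
                     ) -> pd.DataFrame:
    """size factors -> NB Wald test -> BH adjustment -> threshold calls."""
    mat = _counts_frame(counts)
    if reference_ids is None:
        reference_ids = list(mat.index)
    factors = size_factors_from_reference(mat, reference_ids)
    res = nb_test(mat, factors, groups, group_a, group_b)
    return classify_differential(res, min_fold, alpha, min_base)
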