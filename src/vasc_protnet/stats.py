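"""Module-trait correlation, three-group differential abundance, enrichment ratios.

Differential abundance across control / AD / PSP uses one-way ANOVA with
Tukey-Kramer studentized-range pairwise p values; Tukey p values below a
fallback threshold (where the studentized-range tail is numerically
imprecise) are replaced by Bonferroni-corrected Welch t-test p values, with a
provenance flag recording which route produced each value.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AbundanceMatrix
from .network import bicor_cross

logger = logging.getLogger("vasc_protnet")

TUKEY_FALLBACK_THRESHOLD = 10 ** -8.5


def me_trait_correlation(mes: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Bicor of each module eigenprotein with each trait.

    Correlation over pairwise-complete samples; significance from the Student
    t transform ``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2 df,
    two-sided.  p is reported only when n >= 5.
    """
    traits = traits.set_index("sample_id") if "sample_id" in traits.columns else traits
    traits = traits.loc[mes.index]
    rows = []
    for trait in traits.columns:
        tv = traits[trait].to_numpy(float)
        finite = np.isfinite(tv)
        if finite.sum() and np.nanstd(tv) == 0:
            logger.warning("trait %r is constant; correlations missing", trait)
        for module in mes.columns:
            me = mes[module].to_numpy(float)
            ok = finite & np.isfinite(me)
            n = int(ok.sum())
            r = bicor_cross(me[None, :], tv[None, :], min_samples=5)[0, 0]
            if np.isnan(r) or n < 5:
                rows.append({"module": module, "trait": trait, "r": r, "p": np.nan, "n": n})
                continue
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
                p = 2.0 * sps.t.sf(abs(t), n - 2)
            rows.append({"module": module, "trait": trait, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def _group_order(levels: list[str]) -> list[str]:
    # control first, then the disease groups in a stable order
    ordered = [g for g in ("control", "AD", "PSP") if g in levels]
    return ordered + sorted(set(levels) - set(ordered))


def anova_tukey_de(
    matrix: AbundanceMatrix,
    groups: pd.Series,
    fallback_threshold: float = TUKEY_FALLBACK_THRESHOLD,
    pairwise: bool = True,
) -> pd.DataFrame:
    """Per-protein one-way ANOVA with Tukey-Kramer pairwise comparisons.

    Proteins with fewer than 3 observed values in any group are skipped (and
    logged).  Pairwise Tukey p values below ``fallback_threshold`` become
    ``min(1, 3 * Welch two-sided p)`` with provenance ``bonferroni_welch``.
    Log2 fold changes are group-mean differences.
    """
    groups = groups.set_axis(groups.index.astype(str))
    levels = _group_order(list(pd.unique(groups.dropna())))
    if len(levels) < 3:
        raise ValueError(f"need 3 groups, got {levels}")
    Y = matrix.data[groups.index].to_numpy()
    g_stats = {}
    for g in levels:
        sub = Y[:, (groups == g).to_numpy()]
        M = np.isfinite(sub)
        n = M.sum(axis=1).astype(float)
        with np.errstate(all="ignore"):
            mean = np.nanmean(sub, axis=1)
            var = np.nanvar(sub, axis=1, ddof=1)
        g_stats[g] = (n, mean, var)

    ns = np.column_stack([g_stats[g][0] for g in levels])
    valid = (ns >= 3).all(axis=1)
    n_skip = int((~valid).sum())
    if n_skip:
        logger.info("anova_tukey_de: skipped %d proteins with a group < 3 observations", n_skip)

    n_tot = ns.sum(axis=1)
    means = np.column_stack([g_stats[g][1] for g in levels])
    vars_ = np.column_stack([g_stats[g][2] for g in levels])
    grand = (ns * means).sum(axis=1) / n_tot
    ssb = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = (vars_ * (ns - 1)).sum(axis=1)
    dfb = len(levels) - 1
    dfw = n_tot - len(levels)
    with np.errstate(all="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
        msw = ssw / dfw
    anova_p = sps.f.sf(F, dfb, dfw)

    out = pd.DataFrame(index=matrix.data.index)
    for g in levels:
        out[f"mean_{g}"] = g_stats[g][1]
    out["anova_F"] = F
    out["anova_p"] = anova_p
    if levels[:3] == ["control", "AD", "PSP"]:
        pairs = [("AD", "control"), ("PSP", "control"), ("AD", "PSP")]
    else:
        pairs = list(itertools.combinations(levels, 2))
    for a, b in pairs:
        na, ma, va = g_stats[a]
        nb, mb, vb = g_stats[b]
        out[f"fc_{a}_vs_{b}"] = ma - mb
        if not pairwise:
            continue
        with np.errstate(all="ignore"):
            se = np.sqrt(msw / 2.0 * (1.0 / na + 1.0 / nb))
            q = np.abs(ma - mb) / se
        p_tukey = sps.studentized_range.sf(q, len(levels), dfw)
        fallback = p_tukey < fallback_threshold
        if fallback.any():
            with np.errstate(all="ignore"):
                se_w = np.sqrt(va / na + vb / nb)
                t = (ma - mb) / se_w
                df_w = se_w ** 4 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p_welch = 2.0 * sps.t.sf(np.abs(t), df_w)
            p_tukey = np.where(fallback, np.minimum(1.0, 3.0 * p_welch), p_tukey)
        out[f"p_{a}_vs_{b}"] = p_tukey
        out[f"provenance_{a}_vs_{b}"] = np.where(fallback, "bonferroni_welch", "tukey")
    return out.loc[valid]


def vascular_bulk_enrichment(
    vascular: AbundanceMatrix,
    bulk: AbundanceMatrix,
    assignments: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-protein (and per-module) mean log2(vascular / bulk) over paired samples.

    Proteins quantified in only one fraction are flagged
    ``unique_to_vascular`` / ``unique_to_bulk``.
    """
    paired = [s for s in vascular.sample_ids if s in set(bulk.sample_ids)]
    if not paired:
        raise ValueError("no paired samples between vascular and bulk matrices")
    v, b = vascular.data[paired], bulk.data[paired]
    all_proteins = list(dict.fromkeys(list(v.index) + list(b.index)))
    rows = []
    for p in all_proteins:
        in_v, in_b = p in v.index, p in b.index
        if in_v and in_b:
            diff = (v.loc[p] - b.loc[p]).dropna()
            rows.append({"protein": p, "mean_log2_ratio": diff.mean() if len(diff) else np.nan,
                         "status": "shared", "n_pairs": len(diff)})
        else:
            rows.append({"protein": p, "mean_log2_ratio": np.nan,
                         "status": "unique_to_vascular" if in_v else "unique_to_bulk",
                         "n_pairs": 0})
    prot_df = pd.DataFrame(rows).set_index("protein")
    mod_df = None
    if assignments is not None:
        shared = prot_df[prot_df["status"] == "shared"]
        joined = shared.join(assignments.rename("module"), how="inner")
        mod_df = (joined[joined["module"] != "unassigned"]
                  .groupby("module")["mean_log2_ratio"].agg(["mean", "size"])
                  .rename(columns={"mean": "mean_log2_ratio", "size": "n_proteins"}))
    return prot_df, mod_df


def select_classifier_proteins(
    de: pd.DataFrame,
    enrichment: pd.DataFrame,
    min_fold: float = 3.0,
    alpha: float = 0.05,
) -> list[str]:
    """Disease-classifier candidates: vascular-specific and fully differential.

    A protein qualifies if it is unique to the vasculature OR at least
    ``min_fold``-enriched there on average, AND all three pairwise p values
    are below ``alpha``.  Returned sorted by ANOVA p.
    """
    p_cols = [c for c in de.columns if c.startswith("p_")]
    if len(p_cols) != 3:
        raise ValueError(f"expected 3 pairwise p columns, found {p_cols}")
    common = de.index.intersection(enrichment.index)
    de = de.loc[common]
    enr = enrichment.loc[common]
    vascular_ok = (enr["status"] == "unique_to_vascular") | (
        enr["mean_log2_ratio"] >= np.log2(min_fold)
    )
    de_ok = (de[p_cols] < alpha).all(axis=1)
    hits = de.loc[vascular_ok & de_ok].sort_values("anova_p")
    return list(hits.index)


def caa_groups(caa: pd.Series) -> pd.Series:
    """Collapse the 0-3 CAA severity score into none / mild / moderate-severe."""
    mapping = {0: "none", 1: "mild", 2: "moderate_severe", 3: "moderate_severe"}
    return caa.map(mapping)
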