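"""Set overrepresentation in modules and permutation-based GWAS risk enrichment.

Cell-type markers, biofluid differential-abundance lists and any other gene
set are tested per module with a one-tailed Fisher exact test
(hypergeometric upper tail) and Benjamini-Hochberg FDR within each analysis
family.  Gene-level GWAS p values are summarized per module as the mean
-log10 of nominally significant hits, normalized against random protein sets
of equal size (a permutation normalized enrichment score, NES).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("vasc_protnet")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q values.

    ``q_(i) = min_{j >= i} (p_(j) * m / j)`` capped at 1, mapped back to the
    input order.  Missing p values propagate as missing and do not count
    toward m.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    out = np.empty(m)
    out[order] = qs
    q[ok] = out
    return q


def _as_module_sets(modules) -> dict[str, set]:
    if isinstance(modules, pd.Series):
        return {m: set(modules.index[modules == m])
                for m in modules.unique() if m != "unassigned"}
    return {m: set(v) for m, v in modules.items()}


def fisher_overrepresentation(
    modules,
    sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
) -> pd.DataFrame:
    """One-tailed Fisher exact overrepresentation of each set in each module.

    ``p = P(X >= overlap)`` for ``X ~ Hypergeom(N, set size, module size)``
    over the supplied background; odds ratios use the Haldane 0.5 correction
    when any 2x2 cell is empty; q values are BH-corrected across all
    (module, set) pairs tested here.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    module_sets = _as_module_sets(modules)
    for m, members in module_sets.items():
        if not members <= bg:
            raise ValueError(f"module {m} has members outside the background")
    rows = []
    N = len(bg)
    for m, members in module_sets.items():
        n_mod = len(members)
        for s, syms in sets.items():
            in_bg = set(syms) & bg
            n_set = len(in_bg)
            k = len(members & in_bg)
            p = float(sps.hypergeom.sf(k - 1, N, n_set, n_mod))
            a, b = k, n_mod - k
            c, d = n_set - k, N - n_mod - n_set + k
            if min(a, b, c, d) == 0:
                a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            rows.append({
                "module": m, "set": s, "overlap": k, "module_size": n_mod,
                "set_size": n_set, "background_size": N,
                "odds_ratio": (a * d) / (b * c), "p": p,
            })
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"])
    return out


def magma_spa(
    modules,
    gene_p_table: pd.DataFrame,
    nominal_alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation normalized enrichment score of GWAS gene-level risk per module.

    Gene symbols are mapped to network proteins case-insensitively (first
    match); the mapped intersection is the background.  Per module of size
    n_m the observed statistic is ``S = mean over module genes of
    (-log10 p) * 1[p < nominal_alpha]``; the null is the same statistic on
    ``n_perm`` random size-n_m draws from the background.  Reports
    ``NES = (S - mu_null) / sd_null``, the empirical p
    ``(1 + #{null >= S}) / (n_perm + 1)``, BH q across modules, and FDR flags
    at 5% and 10%.
    """
    module_sets = _as_module_sets(modules)
    universe = sorted(set().union(*module_sets.values())) if module_sets else []
    by_lower: dict[str, str] = {}
    for _, row in gene_p_table.iterrows():
        key = str(row["symbol"]).lower()
        if key not in by_lower:
            by_lower[key] = row["p"]
        else:
            logger.warning("magma_spa: ambiguous gene symbol %r; first match kept", row["symbol"])
    mapped = [p for p in universe if p.lower() in by_lower]
    n_unmapped = len(universe) - len(mapped)
    if n_unmapped:
        logger.info("magma_spa: %d network proteins without a gene p value", n_unmapped)
    pvals = np.array([by_lower[p.lower()] for p in mapped])
    with np.errstate(divide="ignore"):
        score = np.where(pvals < nominal_alpha, -np.log10(np.maximum(pvals, 1e-300)), 0.0)
    pos = {p: i for i, p in enumerate(mapped)}
    rng = np.random.default_rng(seed)

    rows = []
    for m, members in sorted(module_sets.items()):
        idx = [pos[p] for p in members if p in pos]
        if not idx:
            logger.warning("magma_spa: module %s has no mapped genes; skipped", m)
            continue
        n_m = len(idx)
        S = float(score[idx].mean())
        null = np.empty(n_perm)
        chunk = max(1, min(n_perm, 2000))
        done = 0
        while done < n_perm:
            c = min(chunk, n_perm - done)
            draws = rng.permuted(
                np.broadcast_to(np.arange(len(mapped)), (c, len(mapped))).copy(), axis=1
            )[:, :n_m]
            null[done:done + c] = score[draws].mean(axis=1)
            done += c
        mu, sd = null.mean(), null.std(ddof=1)
        nes = (S - mu) / sd if sd > 0 else 0.0
        emp_p = (1.0 + float((null >= S).sum())) / (n_perm + 1.0)
        rows.append({"module": m, "size": n_m, "S": S, "null_mean": mu, "null_sd": sd,
                     "NES": nes, "p": emp_p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"])
        out["fdr_5pct"] = out["q"] < 0.05
        out["fdr_10pct"] = out["q"] < 0.10
    return out
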