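"""Signed weighted co-expression network: bicor, TOM, modules, preservation.

The network is built from biweight midcorrelations (robust to the occasional
aberrant sample), raised to a soft power under the signed transform
``a_ij = ((1 + r_ij)/2)^beta``, and converted to topological overlap so that
two proteins are similar when they share neighbours, not merely when they
correlate.  Modules are branches of the average-linkage dendrogram of
``1 - TOM``, refined by a PAM-like assignment stage and by iterative
eigenprotein-membership (kME) reassignment, and assessed for preservation in
a second dataset with permutation Z statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import AbundanceMatrix

logger = logging.getLogger("vasc_protnet")

UNASSIGNED = "unassigned"


@dataclass
class NetworkParams:
    power: float = 9.0
    deep_split: int = 4
    min_module_size: int = 20
    merge_cut_height: float = 0.07
    tom_denominator: str = "mean"  # or "min"
    network_type: str = "signed"
    correlation: str = "bicor"
    pam_stage: bool = True
    pam_respects_dendro: bool = True
    kme_gap: float = 0.10
    kme_floor: float = 0.30
    reassign_max_iter: int = 30
    min_pairwise_samples: int = 5
    null_height_quantile: float = 0.005  # permutation-null calibration of the cut
    null_seed: int = 0

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0, 1)")
        if not 0 < self.kme_floor < 1:
            raise ValueError("kme_floor must be in (0, 1)")


@dataclass
class NetworkModel:
    assignments: pd.Series  # protein -> M1..Mk (decreasing size) or unassigned
    eigenproteins: pd.DataFrame  # samples x modules
    kme: pd.DataFrame  # proteins x modules
    prop_var_explained: pd.Series
    params: NetworkParams
    n_reassign_iterations: int = 0


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------


def _bicor_transform(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-biweight centered/weighted rows; missing entries become 0.

    Per row: m = median, u = (x - m) / (9 * MAD), w = (1 - u^2)^2 * 1[|u|<1],
    x~ = (x - m) * w.  Rows with MAD = 0 fall back to the Pearson transform
    (mean-centering); constant rows transform to all zeros.
    """
    M = np.isfinite(X)
    Xt = np.zeros_like(X, dtype=float)
    with np.errstate(all="ignore"):
        med = np.nanmedian(X, axis=1)
        mad = np.nanmedian(np.abs(X - med[:, None]), axis=1)
    robust = mad > 0
    if robust.any():
        u = (X[robust] - med[robust, None]) / (9.0 * mad[robust, None])
        w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
        Xt[robust] = (X[robust] - med[robust, None]) * w
    fallback = ~robust
    if fallback.any():
        with np.errstate(all="ignore"):
            mean = np.nanmean(X[fallback], axis=1)
        Xt[fallback] = X[fallback] - mean[:, None]
        n_const = int((np.nanstd(X[fallback], axis=1) == 0).sum())
        n_pearson = int(fallback.sum()) - n_const
        if n_pearson:
            logger.warning("bicor: %d rows with MAD = 0 use the Pearson fallback", n_pearson)
        if n_const:
            logger.warning("bicor: %d constant rows; their correlations are missing", n_const)
    Xt[~M] = 0.0
    return Xt, M


def bicor_cross(X: np.ndarray, Y: np.ndarray, min_samples: int = 5) -> np.ndarray:
    """Biweight midcorrelation of every row of X with every row of Y.

    Computed over pairwise-complete entries; pairs with fewer than
    ``min_samples`` shared observations are missing.
    """
    Xt, Mx = _bicor_transform(np.asarray(X, float))
    Yt, My = _bicor_transform(np.asarray(Y, float))
    num = Xt @ Yt.T
    sx = (Xt ** 2) @ My.T.astype(float)  # sum of x~^2 over shared support
    sy = Mx.astype(float) @ (Yt ** 2).T
    with np.errstate(all="ignore"):
        r = num / np.sqrt(sx * sy)
    n_shared = Mx.astype(float) @ My.T.astype(float)
    r[n_shared < min_samples] = np.nan
    return np.clip(r, -1.0, 1.0)


def bicor_matrix(matrix: AbundanceMatrix | np.ndarray, min_samples: int = 5) -> np.ndarray:
    """Symmetric bicor matrix across proteins (rows)."""
    X = matrix.values if isinstance(matrix, AbundanceMatrix) else np.asarray(matrix, float)
    r = bicor_cross(X, X, min_samples=min_samples)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    const = np.nanstd(X, axis=1) == 0
    r[const, :] = np.nan
    r[:, const] = np.nan
    return r


# ---------------------------------------------------------------------------
# adjacency and topological overlap
# ---------------------------------------------------------------------------


def signed_adjacency(correlations: np.ndarray, power: float = 9.0) -> np.ndarray:
    """Signed adjacency ``a_ij = ((1 + r_ij)/2)^power`` with unit diagonal.

    Missing correlations contribute no adjacency (0).
    """
    r = np.asarray(correlations, float)
    a = ((1.0 + np.nan_to_num(r, nan=-1.0)) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return a


def tom_similarity(adjacency: np.ndarray, denominator: str = "mean") -> np.ndarray:
    """Topological overlap matrix.

    ``TOM_ij = (l_ij + a_ij) / (D_ij - a_ij + 1)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``D_ij`` the mean (or min) of the
    connectivities ``k_i = sum_{u != i} a_iu``.
    """
    a = np.asarray(adjacency, float)
    if a.shape[0] != a.shape[1] or not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if denominator not in ("mean", "min"):
        raise ValueError("denominator must be 'mean' or 'min'")
    diag = np.diag(a)
    k = a.sum(axis=1) - diag
    l = a @ a - a * (diag[:, None] + diag[None, :])
    if denominator == "mean":
        D = (k[:, None] + k[None, :]) / 2.0
    else:
        D = np.minimum(k[:, None], k[None, :])
    with np.errstate(all="ignore"):
        tom = (l + a) / (D - a + 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# module detection (dynamic branch cut + PAM-like stage)
# ---------------------------------------------------------------------------


def _branch_tables(Z: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node height, parent pointer and parent height for a linkage tree."""
    n_nodes = 2 * n - 1
    height = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=int)
    for i in range(n - 1):
        c1, c2 = int(Z[i, 0]), int(Z[i, 1])
        node = n + i
        height[node] = Z[i, 2]
        parent[c1] = parent[c2] = node
    parent_height = np.where(parent >= 0, height[np.maximum(parent, 0)], np.inf)
    return height, parent, parent_height


def _node_members(Z: np.ndarray, n: int, node: int) -> np.ndarray:
    stack, members = [node], []
    while stack:
        v = stack.pop()
        if v < n:
            members.append(v)
        else:
            stack.extend((int(Z[v - n, 0]), int(Z[v - n, 1])))
    return np.array(members, dtype=int)


def relabel_by_size(assignments: pd.Series) -> pd.Series:
    """Rename modules M1..Mk by decreasing member count (ties by old label)."""
    counts = assignments[assignments != UNASSIGNED].value_counts()
    order = sorted(counts.index, key=lambda lab: (-counts[lab], str(lab)))
    mapping = {old: f"M{i + 1}" for i, old in enumerate(order)}
    mapping[UNASSIGNED] = UNASSIGNED
    out = assignments.map(mapping)
    out.name = "module"
    return out


def null_merge_heights(matrix: AbundanceMatrix, params: NetworkParams) -> np.ndarray:
    """Dendrogram merge heights after destroying all co-expression.

    Each protein's observed values are independently permuted across samples,
    the TOM dendrogram is rebuilt, and its merge heights characterize how
    tight a branch can get by chance at this sample size, missingness and
    network size.  Deterministic given ``params.null_seed``.
    """
    rng = np.random.default_rng(params.null_seed)
    X = matrix.values.copy()
    for i in range(X.shape[0]):
        obs = np.isfinite(X[i])
        X[i, obs] = rng.permutation(X[i, obs])
    adj = signed_adjacency(bicor_matrix(X, params.min_pairwise_samples), params.power)
    tom = tom_similarity(adj, params.tom_denominator)
    dissim = 1.0 - tom
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    return linkage(squareform(dissim, checks=False), method="average")[:, 2]


def detect_modules(
    tom: np.ndarray,
    params: NetworkParams | None = None,
    protein_ids: list[str] | None = None,
    matrix: AbundanceMatrix | None = None,
) -> pd.Series:
    """Initial module assignment from the TOM dendrogram.

    Average-linkage clustering of ``1 - TOM``.  A dendrogram node becomes a
    module when it has at least ``min_module_size`` members and its height
    (the dissimilarity at which its last members merge) lies below the branch
    cut; maximal such nodes are taken.  The cut is the smaller of (a) a
    ``deep_split``-controlled fraction of the merge-height range — higher
    ``deep_split`` demands tighter branches, splitting more deeply — and,
    when the data matrix is supplied, (b) a low quantile of the
    permutation-null merge heights (:func:`null_merge_heights`), so that no
    branch a co-expression-free dataset could produce is ever called a
    module.  A PAM-like stage then assigns leftover elements to the nearest
    module by average dissimilarity, restricted to modules under the
    element's nearest module-bearing ancestor when ``pam_respects_dendro``.
    """
    params = params or NetworkParams()
    n = tom.shape[0]
    ids = protein_ids if protein_ids is not None else [str(i) for i in range(n)]
    if n < params.min_module_size:
        logger.warning("fewer proteins (%d) than min_module_size; all unassigned", n)
        return pd.Series(UNASSIGNED, index=ids, name="module")
    dissim = 1.0 - np.asarray(tom, float)
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    heights = Z[:, 2]
    lo = float(np.percentile(heights, 5))
    hmax = float(heights.max())
    cut = lo + (0.95 - 0.025 * params.deep_split) * (hmax - lo)
    if matrix is not None:
        h_null = float(np.quantile(null_merge_heights(matrix, params), params.null_height_quantile))
        cut = min(cut, h_null)
        logger.info("detect_modules: null-calibrated cut %.3f (relative cut %.3f)", h_null, cut)
    height, parent, parent_height = _branch_tables(Z, n)

    labels = np.full(n, UNASSIGNED, dtype=object)
    module_nodes: dict[str, int] = {}
    k = 0
    for v in range(n, 2 * n - 1):
        # maximal nodes below the cut with enough members
        if height[v] > cut or parent_height[v] <= cut:
            continue
        members = _node_members(Z, n, v)
        if len(members) < params.min_module_size:
            continue
        k += 1
        lab = f"C{k}"
        labels[members] = lab
        module_nodes[lab] = v

    if params.pam_stage and module_nodes:
        # ancestors holding at least one module, per node
        holds_module = np.zeros(2 * n - 1, dtype=bool)
        for v in module_nodes.values():
            while v != -1:
                holds_module[v] = True
                v = parent[v]
        module_members = {lab: np.nonzero(labels == lab)[0] for lab in module_nodes}
        for i in np.nonzero(labels == UNASSIGNED)[0]:
            cands = list(module_nodes)
            if params.pam_respects_dendro:
                v = int(i)
                while v != -1 and not holds_module[v]:
                    v = parent[v]
                if v == -1:
                    continue
                anc = v
                cands = []
                for lab, node in module_nodes.items():
                    u = node
                    while u != -1 and u != anc:
                        u = parent[u]
                    if u == anc:
                        cands.append(lab)
            if not cands:
                continue
            avg = {lab: dissim[i, module_members[lab]].mean() for lab in cands}
            best = min(avg, key=avg.get)
            if avg[best] < cut:
                labels[i] = best

    return relabel_by_size(pd.Series(labels, index=ids, name="module"))


# ---------------------------------------------------------------------------
# eigenproteins, kME, merging, reassignment
# ---------------------------------------------------------------------------


def eigenproteins(
    matrix: AbundanceMatrix, assignments: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First-principal-component sample profile per module.

    Members are z-scored across samples (missing entries contribute 0 after
    scoring); the module eigenprotein is the leading right singular vector,
    sign-oriented so it correlates nonnegatively with the mean member profile,
    and standardized.  Also returns the proportion of member variance the
    eigenprotein explains.
    """
    modules = [m for m in assignments.unique() if m != UNASSIGNED]
    modules.sort(key=_module_order)
    mes, pves = {}, {}
    for m in modules:
        members = assignments.index[assignments == m]
        X = matrix.data.loc[members].to_numpy()
        mean = np.nanmean(X, axis=1, keepdims=True)
        sd = np.nanstd(X, axis=1, keepdims=True)
        with np.errstate(all="ignore"):
            Xz = (X - mean) / np.where(sd > 0, sd, np.nan)
        Xz = np.nan_to_num(Xz)
        _, s, Vt = np.linalg.svd(Xz, full_matrices=False)
        me = Vt[0]
        ref = Xz.mean(axis=0)
        if np.dot(me, ref) < 0:
            me = -me
        me = me - me.mean()
        if me.std() > 0:
            me = me / me.std()
        mes[m] = me
        pves[m] = float(s[0] ** 2 / (s ** 2).sum()) if s.size else 0.0
    me_df = pd.DataFrame(mes, index=matrix.sample_ids)
    return me_df, pd.Series(pves, name="prop_var_explained")


def _module_order(label: str) -> tuple:
    if isinstance(label, str) and label[1:].isdigit():
        return (0, int(label[1:]))
    return (1, str(label))


def kme_table(matrix: AbundanceMatrix, mes: pd.DataFrame, min_samples: int = 5) -> pd.DataFrame:
    """kME(i, m) = bicor(protein i profile, eigenprotein of module m)."""
    r = bicor_cross(matrix.values, mes.to_numpy().T, min_samples=min_samples)
    return pd.DataFrame(r, index=matrix.protein_ids, columns=mes.columns)


def merge_modules(
    assignments: pd.Series,
    matrix: AbundanceMatrix,
    merge_cut_height: float = 0.07,
) -> pd.Series:
    """Merge module pairs whose eigenproteins are nearly identical.

    Iteratively merges the pair with the smallest eigenprotein dissimilarity
    ``1 - cor(ME)`` below ``merge_cut_height``, recomputing eigenproteins
    after each merge, until no pair qualifies.
    """
    assignments = assignments.copy()
    while True:
        modules = [m for m in assignments.unique() if m != UNASSIGNED]
        if len(modules) < 2:
            break
        mes, _ = eigenproteins(matrix, assignments)
        corr = np.corrcoef(mes.to_numpy().T)
        dissim = 1.0 - corr
        np.fill_diagonal(dissim, np.inf)
        i, j = np.unravel_index(np.argmin(dissim), dissim.shape)
        if dissim[i, j] >= merge_cut_height:
            break
        keep, drop = mes.columns[i], mes.columns[j]
        logger.info("merging module %s into %s (1 - cor(ME) = %.3f)", drop, keep, dissim[i, j])
        assignments[assignments == drop] = keep
    return relabel_by_size(assignments)


def iterative_reassign(
    matrix: AbundanceMatrix,
    assignments: pd.Series,
    params: NetworkParams | None = None,
) -> tuple[pd.Series, int]:
    """Iterate module membership to a kME fixed point.

    Each pass recomputes eigenproteins and kMEs, then applies, per protein:
    (3) unassign if all kMEs are below ``kme_floor``; (2) assign an unassigned
    protein to its arg-max module if any kME exceeds the floor; (1) reassign
    an assigned protein to its arg-max module if the best kME beats its own by
    more than ``kme_gap``.  Ties break toward the lower module index.  Stops
    at the first pass that changes nothing (the confirming pass is counted).
    """
    params = params or NetworkParams()
    assignments = assignments.copy()
    n_iter = 0
    for n_iter in range(1, params.reassign_max_iter + 1):
        modules = [m for m in assignments.unique() if m != UNASSIGNED]
        if not modules:
            break
        mes, _ = eigenproteins(matrix, assignments)
        kme = kme_table(matrix, mes, min_samples=params.min_pairwise_samples)
        cols = sorted(kme.columns, key=_module_order)
        kme = kme[cols]
        K = np.nan_to_num(kme.to_numpy(), nan=-np.inf)
        best_idx = K.argmax(axis=1)  # first occurrence -> lower module index
        best_k = K[np.arange(len(K)), best_idx]
        best_lab = np.array(cols, dtype=object)[best_idx]
        cur = assignments.to_numpy(dtype=object)
        own_k = np.full(len(cur), -np.inf)
        for ci, lab in enumerate(cols):
            own_k[cur == lab] = K[cur == lab, ci]
        new = cur.copy()
        assigned = cur != UNASSIGNED
        new[assigned & (best_k < params.kme_floor)] = UNASSIGNED  # rule 3
        rule2 = ~assigned & (best_k > params.kme_floor)
        new[rule2] = best_lab[rule2]
        rule1 = assigned & (best_k >= params.kme_floor) & ((best_k - own_k) > params.kme_gap)
        new[rule1] = best_lab[rule1]
        n_changed = int((new != cur).sum())
        assignments = pd.Series(new, index=assignments.index, name="module")
        if n_changed == 0:
            break
    else:
        logger.warning("kME reassignment did not converge in %d iterations", params.reassign_max_iter)
    return relabel_by_size(assignments), n_iter


def audit_kme_rules(
    matrix: AbundanceMatrix,
    assignments: pd.Series,
    params: NetworkParams | None = None,
) -> pd.DataFrame:
    """Post-hoc check that an assignment satisfies the three kME rules.

    Returns a table of violations (empty at a true fixed point).
    """
    params = params or NetworkParams()
    mes, _ = eigenproteins(matrix, assignments)
    kme = kme_table(matrix, mes, min_samples=params.min_pairwise_samples)
    cols = sorted(kme.columns, key=_module_order)
    K = np.nan_to_num(kme[cols].to_numpy(), nan=-np.inf)
    best_k = K.max(axis=1)
    rows = []
    for i, prot in enumerate(assignments.index):
        lab = assignments.iloc[i]
        if lab == UNASSIGNED:
            if best_k[i] > params.kme_floor:
                rows.append({"protein": prot, "rule": 2, "detail": f"max kME {best_k[i]:.3f}"})
        else:
            own = K[i, cols.index(lab)]
            if best_k[i] < params.kme_floor:
                rows.append({"protein": prot, "rule": 3, "detail": f"all kME < {params.kme_floor}"})
            elif best_k[i] - own > params.kme_gap + 1e-12:
                rows.append({"protein": prot, "rule": 1, "detail": f"gap {best_k[i] - own:.3f}"})
    return pd.DataFrame(rows, columns=["protein", "rule", "detail"])


def build_network(matrix: AbundanceMatrix, params: NetworkParams | None = None) -> NetworkModel:
    """Full network construction: bicor -> adjacency -> TOM -> modules."""
    params = params or NetworkParams()
    r = bicor_matrix(matrix, min_samples=params.min_pairwise_samples)
    adj = signed_adjacency(r, power=params.power)
    tom = tom_similarity(adj, denominator=params.tom_denominator)
    assignments = detect_modules(tom, params, protein_ids=matrix.protein_ids, matrix=matrix)
    assignments = merge_modules(assignments, matrix, params.merge_cut_height)
    assignments, n_iter = iterative_reassign(matrix, assignments, params)
    mes, pve = eigenproteins(matrix, assignments)
    kme = kme_table(matrix, mes, min_samples=params.min_pairwise_samples)
    return NetworkModel(assignments, mes, kme, pve, params, n_iter)


# ---------------------------------------------------------------------------
# module preservation
# ---------------------------------------------------------------------------


def _preservation_stats(
    idx: np.ndarray,
    Xt: np.ndarray,
    Xg: np.ndarray,
    adj_t: np.ndarray,
    adj_g: np.ndarray,
) -> np.ndarray:
    """Density and connectivity statistics of one protein set.

    Returns [mean intramodular adjacency, prop. var. explained, mean |kME|,
    cor(kIM), cor(kME), cor(adjacency)] with density evaluated in the target
    and connectivity comparing template vs target.
    """

    def module_me_kme(X: np.ndarray) -> tuple[float, np.ndarray]:
        mean = np.nanmean(X, axis=1, keepdims=True)
        sd = np.nanstd(X, axis=1, keepdims=True)
        with np.errstate(all="ignore"):
            Xz = np.nan_to_num((X - mean) / np.where(sd > 0, sd, np.nan))
        _, s, Vt = np.linalg.svd(Xz, full_matrices=False)
        me = Vt[0]
        if np.dot(me, Xz.mean(axis=0)) < 0:
            me = -me
        pve = float(s[0] ** 2 / (s ** 2).sum()) if s.size else 0.0
        kme = bicor_cross(X, me[None, :])[:, 0]
        return pve, kme

    sub_t = adj_t[np.ix_(idx, idx)]
    sub_g = adj_g[np.ix_(idx, idx)]
    m = len(idx)
    off = ~np.eye(m, dtype=bool)
    mean_adj = float(sub_g[off].mean())
    pve_g, kme_g = module_me_kme(Xg[idx])
    _, kme_t = module_me_kme(Xt[idx])
    mean_kme = float(np.nanmean(np.abs(kme_g)))

    def safe_cor(x: np.ndarray, y: np.ndarray) -> float:
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            return 0.0
        return float(np.corrcoef(x[ok], y[ok])[0, 1])

    k_t = sub_t.sum(axis=1) - 1.0
    k_g = sub_g.sum(axis=1) - 1.0
    triu = np.triu_indices(m, 1)
    return np.array([
        mean_adj, pve_g, mean_kme,
        safe_cor(k_t, k_g), safe_cor(kme_t, kme_g), safe_cor(sub_t[triu], sub_g[triu]),
    ])


def module_preservation(
    template_matrix: AbundanceMatrix,
    template_assignments: pd.Series,
    target_matrix: AbundanceMatrix,
    n_perm: int = 500,
    seed: int = 0,
    params: NetworkParams | None = None,
) -> pd.DataFrame:
    """Permutation Z-summary preservation of template modules in a target.

    For each module, density statistics (mean intramodular adjacency,
    proportion of variance explained, mean |kME| in the target) and
    connectivity statistics (template-vs-target correlations of intramodular
    connectivity, kME, and intramodular adjacency) are compared with their
    distribution over ``n_perm`` random protein sets of equal size drawn from
    the shared protein universe.  ``Z_density`` and ``Z_connectivity`` are the
    medians of their groups' Z statistics and ``Z_summary`` their mean.
    """
    params = params or NetworkParams()
    shared = [p for p in template_matrix.protein_ids if p in set(target_matrix.protein_ids)]
    if len(shared) < len(template_matrix.protein_ids):
        logger.info("module_preservation: %d shared proteins used", len(shared))
    Xt = template_matrix.data.loc[shared].to_numpy()
    Xg = target_matrix.data.loc[shared].to_numpy()
    adj_t = signed_adjacency(bicor_matrix(Xt, params.min_pairwise_samples), params.power)
    adj_g = signed_adjacency(bicor_matrix(Xg, params.min_pairwise_samples), params.power)
    pos = {p: i for i, p in enumerate(shared)}
    rng = np.random.default_rng(seed)

    rows = []
    modules = [m for m in template_assignments.unique() if m != UNASSIGNED]
    modules.sort(key=_module_order)
    for m in modules:
        members = [p for p in template_assignments.index[template_assignments == m] if p in pos]
        if len(members) < 3:
            logger.warning("module %s has < 3 proteins in the shared universe; skipped", m)
            continue
        idx = np.array([pos[p] for p in members])
        obs = _preservation_stats(idx, Xt, Xg, adj_t, adj_g)
        null = np.empty((n_perm, 6))
        for b in range(n_perm):
            rand = rng.choice(len(shared), size=len(idx), replace=False)
            null[b] = _preservation_stats(rand, Xt, Xg, adj_t, adj_g)
        mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
        with np.errstate(all="ignore"):
            z = np.where(sd > 0, (obs - mu) / sd, 0.0)
        z_density = float(np.median(z[:3]))
        z_connectivity = float(np.median(z[3:]))
        rows.append({
            "module": m, "size": len(idx),
            "Z_density": z_density, "Z_connectivity": z_connectivity,
            "Z_summary": (z_density + z_connectivity) / 2.0,
            "n_permutations": n_perm,
        })
    return pd.DataFrame(rows).set_index("module")
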