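"""Multivariate structure: Euclidean distances, full-factorial PERMANOVA,
PCA with iterative missing-value imputation, Ward-on-squared-dissimilarity
hierarchical clustering, tree cutting and Baker's gamma dendrogram
comparison with a label-permutation null.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.sparse.linalg import svds

from .errors import SchemaError
from .seeds import substream
from .tables import FeatureTable

# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample labels."""

    matrix: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise SchemaError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise SchemaError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise SchemaError("distance matrix must have a zero diagonal")
        if np.any(m < 0):
            raise SchemaError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def euclidean_distances(
    values: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    average_by_genotype: bool = False,
) -> DistanceMatrix:
    """Euclidean distances between rows, optionally genotype-averaged.

    ``values`` must be complete (impute first); with averaging, replicate
    rows are first collapsed to one mean profile per genotype.
    """
    if values.isna().all(axis=0).any():
        raise SchemaError("a feature with all values missing cannot enter distances")
    if values.isna().any().any():
        raise SchemaError("missing values present; impute before computing distances")
    if average_by_genotype:
        if meta is None:
            raise SchemaError("averaging requires sample metadata")
        prof = values.groupby(meta["genotype"]).mean()
        labels = prof.index.tolist()
        mat = squareform(pdist(prof.to_numpy(), metric="euclidean"))
    else:
        labels = values.index.tolist()
        mat = squareform(pdist(values.to_numpy(), metric="euclidean"))
    return DistanceMatrix(mat, labels)


# ---------------------------------------------------------------------------
# PERMANOVA

DEFAULT_TERMS = (
    ("genotype",),
    ("tissue",),
    ("regime",),
    ("genotype", "tissue"),
    ("genotype", "regime"),
    ("tissue", "regime"),
    ("genotype", "tissue", "regime"),
)


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, df, ss, pseudo_f, p_value
    total_ss: float
    residual_ss: float
    residual_df: int
    n_permutations: int
    seed: int
    degenerate: bool = False
    dropped_terms: list = field(default_factory=list)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _orth_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0)
    rank = int((s > tol).sum())
    return u[:, :rank]


def permanova(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    terms=DEFAULT_TERMS,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type-I) distance-based multivariate ANOVA.

    Sums of squares come from the Gower-centred inner-product matrix
    partitioned by nested projection spaces in term order; significance by
    free permutation of sample labels with the add-one convention
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    n = dist.n
    meta = metadata.loc[dist.labels] if set(dist.labels) <= set(metadata.index) else metadata
    if len(meta) != n:
        raise SchemaError("metadata does not match distance-matrix labels")
    g = _gower_center(dist.matrix)
    total_ss = float(np.trace(g))
    if total_ss <= 1e-12:
        empty = pd.DataFrame(
            {"term": ["+".join(t) for t in terms], "df": 0, "ss": 0.0,
             "pseudo_f": np.nan, "p_value": np.nan}
        )
        return PermanovaResult(empty, 0.0, 0.0, n - 1, n_perm, seed, degenerate=True)

    # cumulative design spaces: intercept, then each term's cell dummies
    cols = [np.ones((n, 1))]
    bases = []
    dfs = []
    kept_terms = []
    dropped = []
    prev_rank = 1
    for term in terms:
        missing = [f for f in term if f not in meta.columns]
        if missing:
            dropped.append("+".join(term))
            continue
        key = meta[list(term)].astype(str).agg("|".join, axis=1)
        dummies = pd.get_dummies(key).to_numpy(dtype=float)
        cols.append(dummies)
        q = _orth_basis(np.concatenate(cols, axis=1))
        df_term = q.shape[1] - prev_rank
        if df_term == 0:
            dropped.append("+".join(term))
            warnings.warn(f"term {'+'.join(term)} has 0 df; dropped", stacklevel=2)
            cols.pop()
            continue
        bases.append(q)
        dfs.append(df_term)
        kept_terms.append(term)
        prev_rank = q.shape[1]

    # projection increments per term plus the residual projector
    hs = []
    prev_h = np.ones((n, n)) / n
    for q in bases:
        h = q @ q.T
        hs.append(h - prev_h)
        prev_h = h
    resid_h = np.eye(n) - prev_h
    resid_df = n - prev_rank
    if resid_df <= 0:
        raise SchemaError("no residual degrees of freedom for PERMANOVA")
    stack = np.stack(hs + [resid_h])  # (T+1, n, n)

    def all_ss(gmat):
        return np.einsum("tij,ij->t", stack, gmat)

    ss = all_ss(g)
    term_ss, resid_ss = ss[:-1], float(ss[-1])
    dfs_arr = np.asarray(dfs, dtype=float)
    f_obs = (term_ss / dfs_arr) / (resid_ss / resid_df)

    rng = substream(seed, "permanova")
    exceed = np.zeros(len(kept_terms))
    for _ in range(n_perm):
        idx = rng.permutation(n)
        gp = g[np.ix_(idx, idx)]
        ssp = all_ss(gp)
        fp = (ssp[:-1] / dfs_arr) / (ssp[-1] / resid_df)
        # tolerance so permutations equivalent to the observed grouping tie
        # with F_obs instead of losing to float rounding
        exceed += fp >= f_obs - 1e-10 * np.maximum(1.0, np.abs(f_obs))
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    table = pd.DataFrame(
        {
            "term": ["+".join(t) for t in kept_terms],
            "df": dfs,
            "ss": term_ss,
            "pseudo_f": f_obs,
            "p_value": pvals,
        }
    )
    return PermanovaResult(
        table, total_ss, resid_ss, int(resid_df), n_perm, seed, dropped_terms=dropped
    )


# ---------------------------------------------------------------------------
# PCA and imputation


@dataclass
class ImputeInfo:
    converged: bool
    n_iter: int
    last_change: float


def impute_pca(
    values: pd.DataFrame,
    n_components: int = 5,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> tuple[pd.DataFrame, ImputeInfo]:
    """Iterative low-rank imputation of missing cells.

    Missing cells start at feature means; then rank-``n_components``
    SVD reconstruction of the column-centred matrix and refilling of the
    missing cells alternate until the imputed cells move less than ``tol``
    (relative) or ``max_iter`` is hit. Observed cells are never altered.
    """
    x = values.to_numpy(dtype=float, copy=True)
    mask = np.isnan(x)
    if not mask.any():
        return values.copy(), ImputeInfo(True, 0, 0.0)
    if mask.all(axis=0).any():
        raise SchemaError("every feature needs at least one observed value")
    col_means = np.nanmean(x, axis=0)
    x[mask] = np.take(col_means, np.where(mask)[1])
    r = min(n_components, min(x.shape) - 1) if min(x.shape) > 1 else 1
    change = np.inf
    it = 0
    use_truncated = r < min(x.shape) // 5 and min(x.shape) > 60
    for it in range(1, max_iter + 1):
        mu = x.mean(axis=0)
        xc = x - mu
        if use_truncated:
            # deterministic Lanczos start vector; full SVD is wasteful here
            v0 = np.ones(min(xc.shape)) / np.sqrt(min(xc.shape))
            u, s, vt = svds(xc, k=r, v0=v0)
            order = np.argsort(s)[::-1]
            u, s, vt = u[:, order], s[order], vt[order]
        else:
            u, s, vt = np.linalg.svd(xc, full_matrices=False)
        recon = (u[:, :r] * s[:r]) @ vt[:r] + mu
        new_vals = recon[mask]
        old_vals = x[mask]
        denom = max(np.linalg.norm(old_vals), 1e-12)
        change = float(np.linalg.norm(new_vals - old_vals) / denom)
        x[mask] = new_vals
        if change < tol:
            break
    out = pd.DataFrame(x, index=values.index, columns=values.columns)
    return out, ImputeInfo(change < tol, it, change)


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray  # variance fractions, sum to 1
    dropped: list


def pca(values: pd.DataFrame, scale: bool = True) -> PCAResult:
    """Column-centred (optionally unit-variance) SVD principal components."""
    if values.isna().any().any():
        raise SchemaError("PCA requires a complete table; impute first")
    x = values.to_numpy(dtype=float, copy=True)
    mu = x.mean(axis=0)
    xc = x - mu
    dropped = []
    cols = values.columns
    if scale:
        sd = xc.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            dropped = cols[zero].tolist()
            warnings.warn(
                f"dropping {int(zero.sum())} zero-variance feature(s) before scaling",
                stacklevel=2,
            )
            xc = xc[:, ~zero]
            cols = cols[~zero]
            sd = sd[~zero]
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    ncomp = len(s)
    pcs = [f"PC{i + 1}" for i in range(ncomp)]
    scores = pd.DataFrame(u * s, index=values.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=cols, columns=pcs)
    return PCAResult(scores, loadings, explained, dropped)


# ---------------------------------------------------------------------------
# hierarchical clustering (Ward on squared dissimilarities)


@dataclass
class DendrogramTree:
    """Agglomerative merge tree: scipy-style ids, heights on the squared scale."""

    merges: list[tuple[int, int]]  # cluster ids; leaves are 0..n-1
    heights: list[float]
    labels: list

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_sets(self) -> list[frozenset]:
        """Leaf membership of each internal node, in merge order."""
        members = {i: frozenset([i]) for i in range(self.n_leaves)}
        out = []
        for m, (a, b) in enumerate(self.merges):
            node = self.n_leaves + m
            members[node] = members[a] | members[b]
            out.append(members[node])
        return out

    def cut(self, k: int) -> np.ndarray:
        return cut_tree(self, k)

    def to_newick(self) -> str:
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node_str = {i: str(self.labels[i]) for i in range(n)}
        for m, (a, b) in enumerate(self.merges):
            h = self.heights[m]
            node = n + m
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node_str[node] = f"({node_str[a]}:{la:g},{node_str[b]}:{lb:g})"
            height[node] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return node_str[root] + ";"


def hcluster_ward_squared(dist: DistanceMatrix) -> DendrogramTree:
    """Ward's method with dissimilarities squared before cluster updating.

    Lance-Williams recursion on the squared input dissimilarities; merge
    heights are the between-cluster values on that squared scale (equal to
    twice the increase in the Ward objective for Euclidean input). Ties
    break toward the lowest index pair, making the result deterministic.
    """
    n = dist.n
    if n < 2:
        raise ValueError("clustering needs at least 2 leaves")
    d = dist.matrix.astype(float) ** 2
    np.fill_diagonal(d, np.inf)
    sizes = {i: 1 for i in range(n)}
    ids = list(range(n))  # position -> cluster id
    work = d.copy()
    merges: list[tuple[int, int]] = []
    heights: list[float] = []
    for step in range(n - 1):
        m = work
        pos = np.unravel_index(np.argmin(m), m.shape)
        i, j = min(pos), max(pos)
        h = float(m[i, j])
        ca, cb = ids[i], ids[j]
        new_id = n + step
        ni, nj = sizes[ca], sizes[cb]
        # Lance-Williams Ward update against every other active cluster
        rest = [p for p in range(m.shape[0]) if p not in (i, j)]
        if rest:
            nk = np.array([sizes[ids[p]] for p in rest], dtype=float)
            dik = m[i, rest]
            djk = m[j, rest]
            dij = m[i, j]
            new_d = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
        keep = rest
        sub = m[np.ix_(keep, keep)]
        size = len(keep) + 1
        nm = np.full((size, size), np.inf)
        nm[:-1, :-1] = sub
        if rest:
            nm[-1, :-1] = new_d
            nm[:-1, -1] = new_d
        work = nm
        ids = [ids[p] for p in keep] + [new_id]
        sizes[new_id] = ni + nj
        merges.append((ca, cb))
        heights.append(h)
    return DendrogramTree(merges, heights, list(dist.labels))


def cut_tree(tree: DendrogramTree, k: int) -> np.ndarray:
    """Cluster labels after the first n-k merges; labels ordered by first leaf."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError("k must be in [1, n_leaves]")
    parent = list(range(n + len(tree.merges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in range(n - k):
        a, b = tree.merges[m]
        node = n + m
        parent[find(a)] = node
        parent[find(b)] = node
    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel)
        labels[i] = relabel[r]
    return labels


# ---------------------------------------------------------------------------
# Baker's gamma


def pair_depth_matrix(tree: DendrogramTree) -> np.ndarray:
    """For each leaf pair, the lowest cluster count at which they co-cluster."""
    n = tree.n_leaves
    depth = np.zeros((n, n))
    members = {i: [i] for i in range(n)}
    for m, (a, b) in enumerate(tree.merges):
        count = n - 1 - m  # clusters remaining after this merge
        la, lb = members[a], members[b]
        for x in la:
            depth[x, lb] = count
        for y in lb:
            depth[y, la] = count
        members[n + m] = la + lb
    return depth


def bakers_gamma(tree1: DendrogramTree, tree2: DendrogramTree) -> float:
    """Spearman correlation of pairwise co-clustering depths (ties averaged)."""
    if sorted(map(str, tree1.labels)) != sorted(map(str, tree2.labels)):
        raise ValueError("trees must share the same leaf-label set")
    m1 = pair_depth_matrix(tree1)
    m2 = pair_depth_matrix(tree2)
    # align tree2's leaf order to tree1's labels
    pos2 = {str(lab): i for i, lab in enumerate(tree2.labels)}
    order = [pos2[str(lab)] for lab in tree1.labels]
    m2 = m2[np.ix_(order, order)]
    iu = np.triu_indices(tree1.n_leaves, k=1)
    v1, v2 = m1[iu], m2[iu]
    rho = stats.spearmanr(v1, v2).statistic
    return float(rho)


@dataclass
class GammaTestResult:
    gamma: float
    p_value: float
    n_permutations: int
    seed: int
    null_gammas: np.ndarray = field(repr=False, default=None)


def gamma_permutation_test(
    tree1: DendrogramTree,
    tree2: DendrogramTree,
    n_perm: int = 1000,
    seed: int = 0,
) -> GammaTestResult:
    """Permute the leaf labels of one tree to build the gamma null.

    p = (1 + #{gamma_perm >= gamma_obs}) / (1 + n_perm).
    """
    gamma_obs = bakers_gamma(tree1, tree2)
    n = tree1.n_leaves
    m1 = pair_depth_matrix(tree1)
    m2 = pair_depth_matrix(tree2)
    pos2 = {str(lab): i for i, lab in enumerate(tree2.labels)}
    order = np.array([pos2[str(lab)] for lab in tree1.labels])
    m2 = m2[np.ix_(order, order)]
    iu = np.triu_indices(n, k=1)
    v1 = stats.rankdata(m1[iu])
    rng = substream(seed, "bakers_gamma")
    exceed = 0
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        vp = m2[np.ix_(perm, perm)][iu]
        rho = stats.spearmanr(v1, vp).statistic
        nulls[b] = rho
        if rho >= gamma_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return GammaTestResult(gamma_obs, float(p), n_perm, seed, nulls)
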