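"""Weighted coexpression network construction and module detection.

One network is built per cytokine condition over a shared probe universe:
unsigned soft-threshold adjacency ``a_ij = |cor(x_i, x_j)|^beta`` (beta = 8),
topological overlap similarity, average-linkage clustering of ``1 - TOM``,
adaptive (dynamic) decomposition of the dendrogram into modules, and merging
of modules whose eigengenes are highly correlated.  Intramodular connectivity
``kWithin`` and the top-weight edge list with betweenness centrality feed the
downstream comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .containers import UNASSIGNED, ExpressionMatrix, ModulePartition

#: Module label palette, assigned to detected modules in decreasing size
#: order.  Grey is reserved for unassigned probes.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta", "sienna", "yellowgreen", "skyblue3",
    "plum", "orangered", "mediumpurple", "lightsteelblue", "lightcoral",
    "ivory", "floralwhite", "darkslateblue", "coral", "brown4", "bisque",
    "darkseagreen", "cornflowerblue", "seagreen", "azure",
]


def _extra_color(i: int) -> str:
    return f"module_{i:03d}"


def module_color(i: int) -> str:
    """i-th module color (stable, unbounded)."""
    return MODULE_COLORS[i] if i < len(MODULE_COLORS) else _extra_color(i)


# ---------------------------------------------------------------------------
# adjacency and topological overlap
# ---------------------------------------------------------------------------

def adjacency(x: ExpressionMatrix, power: float = 8.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency ``|cor|^power`` for one condition's
    samples.

    Pearson correlations are computed across the supplied samples; probes
    with zero variance get correlation 0 with every other probe.  The
    diagonal is set to 0 so that row sums are connectivities.
    """
    v = x.values.to_numpy()
    if v.shape[1] < 3:
        raise ValueError("adjacency needs at least 3 samples")
    sd = v.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(v)
    r[~np.isfinite(r)] = 0.0
    constant = sd == 0
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=x.probes, columns=x.probes)


def tom(a: pd.DataFrame, tol: float = 1e-10) -> pd.DataFrame:
    """Topological overlap similarity of an adjacency matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` (u != i, j) and ``k_i`` the connectivity of
    node i.  The diagonal is 1.
    """
    m = a.to_numpy(dtype=float).copy()
    if m.shape[0] != m.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(m - m.T).max() > tol:
        raise ValueError("adjacency is not symmetric")
    np.fill_diagonal(m, 0.0)
    k = m.sum(axis=1)
    l = m @ m  # diag(m) == 0, so the u == i and u == j terms vanish
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (l + m) / (min_k + 1.0 - m)
    t[~np.isfinite(t)] = 0.0
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=a.index, columns=a.columns)


def tom_dissimilarity(t: pd.DataFrame) -> pd.DataFrame:
    return 1.0 - t


# ---------------------------------------------------------------------------
# dendrogram and dynamic tree cut
# ---------------------------------------------------------------------------

def cluster_dendrogram(diss: pd.DataFrame) -> np.ndarray:
    """Average-linkage hierarchical tree over a dissimilarity matrix.

    Returns a scipy linkage matrix; leaf order matches ``diss.index``.
    """
    d = diss.to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("dissimilarity contains non-finite values")
    if np.abs(np.diag(d)).max() > 1e-12 or np.abs(d - d.T).max() > 1e-10:
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    return linkage(squareform(d, checks=False), method="average")


@dataclass
class _CutParams:
    min_size: int
    cut_height: float
    deep_split: bool
    split_gap: float
    fringe_frac: float
    min_cohesion: float
    assemble_frac: float


def dynamic_tree_cut(
    tree: np.ndarray,
    diss: pd.DataFrame,
    min_size: int = 8,
    cut_height: float = 0.995,
    deep_split: bool = True,
    split_gap: float = 0.0,
    fringe_frac: float = 0.25,
    min_cohesion: float = 0.02,
    assemble_frac: float = 0.6,
) -> ModulePartition:
    """Adaptive decomposition of a dendrogram into modules.

    The static cut at ``cut_height`` yields candidate branches.  With
    ``deep_split`` each branch is recursively decomposed: an internal join
    whose height exceeds both children's heights by more than ``split_gap``
    and whose children both hold at least ``min_size`` leaves is split;
    joins attaching a sub-``min_size`` side branch are treated as scattered
    fringe -- the descent continues into the dominant child and the fringe
    leaves are pooled, to be re-attached afterwards to the core they are
    closest to (mean dissimilarity).  Mild over-splitting is expected and is
    repaired downstream by eigengene merging.  Every cluster is finally
    trimmed of loose members: a member whose mean dissimilarity to the rest
    of the cluster exceeds ``median + fringe_frac * (1 - median)`` is
    released to grey (iterated to a fixed point).  Clusters falling below
    ``min_size`` dissolve into grey, as do clusters whose median pairwise
    similarity ``1 - diss`` is below ``min_cohesion``: at soft power 8 a
    pairwise correlation of ~0.6 already yields adjacency ~0.02, so looser
    clusters are indistinguishable from chance co-clustering of noise.
    Finally, because maximal splitting shatters large homogeneous branches,
    clusters are greedily reassembled whenever the similarity between two
    clusters is at least ``assemble_frac`` of the looser one's internal
    cohesion -- fragments of one module reunite (their cross-similarity
    matches their internal similarity) while genuinely distinct modules,
    whose cross-similarity is far below their cohesion, stay apart.

    Labels are colors assigned in decreasing size order; connectivity is
    computed separately (:func:`intramodular_connectivity`).
    """
    params = _CutParams(
        min_size, cut_height, deep_split, split_gap, fringe_frac, min_cohesion,
        assemble_frac,
    )
    d = diss.to_numpy(dtype=float)
    root, _ = to_tree(tree, rd=True)

    # 1. static cut: forest of maximal subtrees at or below cut_height
    branches: list = []

    def collect(node) -> None:
        if node.dist > params.cut_height and not node.is_leaf():
            collect(node.left)
            collect(node.right)
        else:
            branches.append(node)

    collect(root)

    # 2. deep split inside each branch, then re-attach pooled fringe leaves
    clusters: list[list[int]] = []
    for b in branches:
        if params.deep_split:
            cores, pool = _split_branch(b, params)
        else:
            cores, pool = [b.pre_order()], []
        if pool and cores:
            assign = [
                int(np.argmin([d[leaf, c].mean() for c in cores])) for leaf in pool
            ]
            for leaf, i in zip(pool, assign):
                cores[i].append(leaf)
        elif pool:
            cores = [pool]
        clusters.extend(cores)

    # 3. fringe trimming and cohesion screen against the dissimilarity matrix
    trimmed: list[list[int]] = []
    for c in clusters:
        core = _trim_fringe(c, d, params)
        if len(core) < params.min_size:
            continue
        sub = d[np.ix_(core, core)]
        median_sim = 1.0 - float(np.median(sub[np.triu_indices(len(core), 1)]))
        if median_sim >= params.min_cohesion:
            trimmed.append(core)

    # 4. reassemble fragments of shattered homogeneous branches
    assembled = _assemble(trimmed, d, params)

    labels = pd.Series(UNASSIGNED, index=diss.index, dtype=object, name="module")
    assembled.sort(key=len, reverse=True)
    for i, c in enumerate(assembled):
        labels.iloc[c] = module_color(i)
    return ModulePartition(labels)


def _cohesion(core: list[int], d: np.ndarray) -> float:
    sub = d[np.ix_(core, core)]
    return 1.0 - float(np.median(sub[np.triu_indices(len(core), 1)]))


def _assemble(
    clusters: list[list[int]], d: np.ndarray, params: _CutParams
) -> list[list[int]]:
    """Greedy agglomeration of clusters whose cross-similarity is a large
    fraction of the looser cluster's internal cohesion."""
    clusters = [list(c) for c in clusters]
    while len(clusters) > 1:
        coh = [_cohesion(c, d) for c in clusters]
        best, best_ratio = None, params.assemble_frac
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                cross = 1.0 - float(d[np.ix_(clusters[i], clusters[j])].mean())
                ratio = cross / max(min(coh[i], coh[j]), 1e-12)
                if ratio >= best_ratio:
                    best, best_ratio = (i, j), ratio
        if best is None:
            break
        i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return clusters


def _split_branch(node, params: _CutParams) -> tuple[list[list[int]], list[int]]:
    """Branch decomposition: returns (cores, pooled fringe leaves).

    Joins whose children both hold at least ``min_size`` leaves (and exceed
    the children's heights by more than ``split_gap``) are split; joins
    attaching a sub-``min_size`` side branch pool that branch as fringe and
    descend into the dominant child.  Iterative to cope with the long
    single-attachment chains that average linkage produces on noise.
    """
    cores: list[list[int]] = []
    pool: list[int] = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf() or n.get_count() < 2 * params.min_size:
            cores.append(n.pre_order())
            continue
        left, right = n.left, n.right
        nl, nr = left.get_count(), right.get_count()
        gap = n.dist - max(left.dist, right.dist)
        if nl >= params.min_size and nr >= params.min_size and gap >= params.split_gap:
            stack.append(left)
            stack.append(right)
        elif min(nl, nr) < params.min_size:
            main, fringe = (left, right) if nl >= nr else (right, left)
            pool.extend(fringe.pre_order())
            stack.append(main)
        else:
            cores.append(n.pre_order())
    return cores, pool


def _trim_fringe(members: list[int], d: np.ndarray, params: _CutParams) -> list[int]:
    """Iteratively release members loosely attached to their cluster.

    Scattered probes (noise attaching near the top of a branch) sit much
    farther from the cluster body than genuine members; the threshold adapts
    to how tight the cluster is.
    """
    core = list(members)
    while len(core) > params.min_size:
        sub = d[np.ix_(core, core)]
        mean_d = (sub.sum(axis=1)) / (len(core) - 1)
        med = float(np.median(mean_d))
        cutoff = med + params.fringe_frac * (1.0 - med)
        keep = mean_d <= cutoff
        if keep.all():
            break
        core = [c for c, k in zip(core, keep) if k]
    return core


# ---------------------------------------------------------------------------
# eigengenes and module merging
# ---------------------------------------------------------------------------

def module_eigengene(x: ExpressionMatrix, part: ModulePartition) -> pd.DataFrame:
    """First principal component of each module's standardized submatrix.

    Returns a samples x modules DataFrame of unit-norm eigengene scores,
    sign-oriented to correlate positively with the module's mean expression
    profile.  Grey is excluded.
    """
    out = {}
    for mod in part.module_names:
        probes = part.members(mod)
        if len(probes) == 0:
            raise ValueError(f"module {mod!r} is empty")
        sub = x.values.loc[probes].to_numpy()
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        # samples-space PC1 of the standardized module matrix
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        pc1 = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.corrcoef(pc1, mean_profile)[0, 1] < 0:
            pc1 = -pc1
        out[mod] = pc1
    return pd.DataFrame(out, index=x.values.columns)


def merge_modules(
    x: ExpressionMatrix,
    part: ModulePartition,
    merge_cut: float = 0.2,
    max_iter: int = 20,
) -> ModulePartition:
    """Merge modules whose eigengenes are closer than ``merge_cut``.

    Eigengene dissimilarity ``1 - cor`` is clustered (average linkage) and cut
    at ``merge_cut``; groups landing in one cluster are merged under the label
    of the group's largest module.  Eigengenes are recomputed and the process
    iterated until no merge occurs.  Grey is never merged.
    """
    current = part
    for _ in range(max_iter):
        names = current.module_names
        if len(names) < 2:
            break
        eig = module_eigengene(x, current)
        corr = np.corrcoef(eig.to_numpy().T)
        dis = 1.0 - corr
        np.fill_diagonal(dis, 0.0)
        dis = np.clip((dis + dis.T) / 2.0, 0.0, None)
        z = linkage(squareform(dis, checks=False), method="average")
        groups = fcluster(z, t=merge_cut, criterion="distance")
        if len(set(groups)) == len(names):
            break
        sizes = current.sizes()
        mapping: dict[str, str] = {}
        for g in set(groups):
            group_mods = [names[i] for i in range(len(names)) if groups[i] == g]
            target = max(group_mods, key=lambda m: (sizes.get(m, 0), m))
            for m in group_mods:
                mapping[m] = target
        current = current.relabel(mapping)
    return current


def intramodular_connectivity(a: pd.DataFrame, part: ModulePartition) -> pd.Series:
    """kWithin: per probe, summed adjacency to same-module probes.

    Grey probes get kWithin 0 by convention.
    """
    if not a.index.equals(part.labels.index):
        raise ValueError("adjacency and partition must share the probe index")
    m = a.to_numpy(dtype=float)
    kw = np.zeros(len(a))
    labels = part.labels.to_numpy()
    for mod in part.module_names:
        idx = np.flatnonzero(labels == mod)
        kw[idx] = m[np.ix_(idx, idx)].sum(axis=1)
    return pd.Series(kw, index=a.index, name="kWithin")


# ---------------------------------------------------------------------------
# edge export and betweenness
# ---------------------------------------------------------------------------

def top_edges(t: pd.DataFrame, budget: int = 50_000) -> pd.DataFrame:
    """The ``budget`` highest-TOM undirected edges, sorted by weight.

    Each edge appears once with ``source < target`` (lexicographically); ties
    at the cutoff weight are broken by (source, target) order.
    """
    m = t.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(t), k=1)
    edges = pd.DataFrame(
        {
            "source": t.index.to_numpy()[iu],
            "target": t.columns.to_numpy()[ju],
            "weight": m[iu, ju],
        }
    )
    edges = edges.sort_values(
        ["weight", "source", "target"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return edges.iloc[:budget].copy()


def betweenness(edges: pd.DataFrame) -> pd.Series:
    """Unnormalized shortest-path betweenness of the edge-list graph.

    Edges are treated as unweighted: TOM weights are similarities, not
    distances, so hop counts define the shortest paths.  Every unordered node
    pair contributes once, split across equally short paths.
    """
    g = nx.from_pandas_edgelist(edges, "source", "target")
    bc = nx.betweenness_centrality(g, normalized=False)
    return pd.Series(bc, name="betweenness").sort_index()


# ---------------------------------------------------------------------------
# one-condition pipeline bundle
# ---------------------------------------------------------------------------

@dataclass
class CoexprNetwork:
    """Everything derived from one condition's expression submatrix."""

    condition: str
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    tree: np.ndarray
    partition: ModulePartition


def build_network(
    x: ExpressionMatrix,
    condition: str,
    power: float = 8.0,
    min_size: int = 8,
    cut_height: float = 0.995,
    deep_split: bool = True,
    merge_cut: float = 0.2,
) -> CoexprNetwork:
    """Full per-condition pipeline: adjacency -> TOM -> dendrogram -> dynamic
    cut -> eigengene merge -> kWithin."""
    sub = x.condition_view(condition)
    a = adjacency(sub, power=power)
    t = tom(a)
    diss = tom_dissimilarity(t)
    tree = cluster_dendrogram(diss)
    part = dynamic_tree_cut(
        tree, diss, min_size=min_size, cut_height=cut_height, deep_split=deep_split
    )
    part = merge_modules(sub, part, merge_cut=merge_cut)
    part = ModulePartition(part.labels, intramodular_connectivity(a, part))
    return CoexprNetwork(condition, a, t, tree, part)
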