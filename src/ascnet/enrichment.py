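"""Signature construction and hypergeometric enrichment of module trend lists.

The workflow mirrors a classic over-representation analysis: build a gene-set
collection from GMT files and/or from ontology annotations propagated to the
root, split each module's probes into up- and down-trending lists from the
donor-averaged time course, then score every (signature, list) pair with an
exact hypergeometric test whose tail probability is expressed as a signed
z-score.  The signature x list z-matrix, zeroed where p > 0.05 and ordered by
hierarchical clustering (1 - Pearson, complete linkage), is the tabular form
of the enrichment heat map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, norm

from .containers import ExpressionMatrix, ModulePartition


# ---------------------------------------------------------------------------
# ontology propagation
# ---------------------------------------------------------------------------

PROPAGATION_RELATIONS = ("is_a", "part_of")


def propagate_annotations(
    onto: nx.MultiDiGraph, annotations: pd.DataFrame
) -> dict[str, list[str]]:
    """Annotate each gene to every ancestor of its directly annotated terms.

    ``onto`` follows the obonet convention (edges child -> parent, keyed by
    relation); only ``is_a`` and ``part_of`` edges are followed.  Annotations
    to unknown terms are dropped with a warning.  Each term (with at least one
    gene after propagation) becomes a gene set.
    """
    allowed = nx.DiGraph()
    allowed.add_nodes_from(onto.nodes)
    allowed.add_edges_from(
        (u, v) for u, v, k in onto.edges(keys=True) if k in PROPAGATION_RELATIONS
    )
    term_genes: dict[str, set[str]] = {}
    ancestor_cache: dict[str, set[str]] = {}
    for gene, term in annotations[["gene", "term"]].itertuples(index=False):
        if term not in onto:
            warnings.warn(f"annotation to unknown term {term!r} dropped", stacklevel=2)
            continue
        if term not in ancestor_cache:
            # child -> parent edges: ancestors are the reachable set
            ancestor_cache[term] = {term} | nx.descendants(allowed, term)
        for t in ancestor_cache[term]:
            term_genes.setdefault(t, set()).add(gene)
    return {t: sorted(genes) for t, genes in sorted(term_genes.items())}


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrich(
    gene_list, signature, population
) -> tuple[float, float, float]:
    """Exact hypergeometric enrichment of ``signature`` in ``gene_list``.

    The draw is the gene list, the successes are the signature genes, the
    population is the probes on the platform.  Returns
    ``(p_enrich, p_deplete, z)`` where ``p_enrich = P(X >= k)``,
    ``p_deplete = P(X <= k)`` and the signed z-score is the standard-normal
    quantile of the smaller tail, positive when the overlap exceeds its
    expectation ``n*K/N``.
    """
    population = set(population)
    gene_list = set(gene_list)
    if not gene_list <= population:
        raise ValueError("gene list must be a subset of the population")
    signature = set(signature) & population
    n_pop, n_sig, n_list = len(population), len(signature), len(gene_list)
    k = len(gene_list & signature)
    dist = hypergeom(n_pop, n_sig, n_list)
    p_enrich = float(dist.sf(k - 1))
    p_deplete = float(dist.cdf(k))
    expected = n_list * n_sig / n_pop if n_pop else 0.0
    if k >= expected:
        z = float(norm.isf(min(max(p_enrich, 1e-300), 1.0)))
    else:
        z = -float(norm.isf(min(max(p_deplete, 1e-300), 1.0)))
    return p_enrich, p_deplete, z


# ---------------------------------------------------------------------------
# trend lists
# ---------------------------------------------------------------------------

@dataclass
class TrendLists:
    """Per-module up/down probe lists with the underlying trend values.

    ``lists`` maps ``"{module}_up"`` / ``"{module}_down"`` to probe lists
    (only lists with >= ``min_genes`` survivors are kept).  ``trend`` and
    ``sd`` record each retained probe's net time-course change and standard
    deviation before list-size filtering.
    """

    lists: dict[str, list[str]] = field(default_factory=dict)
    trend: pd.Series = field(default_factory=pd.Series)
    sd: pd.Series = field(default_factory=pd.Series)


def trend_split(
    part: ModulePartition,
    x: ExpressionMatrix,
    condition: str,
    sd_min: float = 0.2,
    min_genes: int = 5,
) -> TrendLists:
    """Split each module's probes into up- and down-trend lists.

    Per probe the donor-averaged log2 profile over the condition's timepoints
    is reduced to a trend by summing consecutive-timepoint differences (which
    telescopes to last minus first).  Probes with time-course SD <= ``sd_min``
    are dropped; probes with trend exactly 0 belong to neither list; lists
    with fewer than ``min_genes`` members are discarded.
    """
    prof = x.donor_average(condition)
    if prof.shape[1] < 2:
        raise ValueError("trend analysis needs at least 2 timepoints")
    diffs = prof.to_numpy()[:, 1:] - prof.to_numpy()[:, :-1]
    trend = pd.Series(diffs.sum(axis=1), index=prof.index, name="trend")
    sd = prof.std(axis=1, ddof=1)
    keep = sd > sd_min

    out = TrendLists(trend=trend[keep], sd=sd[keep])
    for mod in part.module_names:
        members = part.members(mod).intersection(prof.index)
        m_keep = [p for p in members if keep.loc[p]]
        up = sorted(p for p in m_keep if trend.loc[p] > 0)
        down = sorted(p for p in m_keep if trend.loc[p] < 0)
        if len(up) >= min_genes:
            out.lists[f"{mod}_up"] = up
        if len(down) >= min_genes:
            out.lists[f"{mod}_down"] = down
    return out


# ---------------------------------------------------------------------------
# enrichment matrix (heat-map table)
# ---------------------------------------------------------------------------

def enrichment_matrix(
    lists: dict[str, list[str]],
    signatures: dict[str, list[str]],
    population,
    p_max: float = 0.05,
    cluster: bool = True,
) -> pd.DataFrame:
    """Signed z-score matrix of signatures (rows) x trend lists (columns).

    z-scores are set to 0 wherever both tail p-values exceed ``p_max``;
    columns (module trend lists) with no surviving enrichment are removed;
    rows and columns are ordered by hierarchical clustering with correlation
    distance and complete linkage when ``cluster`` is true.
    """
    if not lists:
        raise ValueError("no trend lists supplied")
    z = pd.DataFrame(0.0, index=list(signatures), columns=list(lists))
    for col, probes in lists.items():
        for sig_name, sig in signatures.items():
            p_en, p_de, zval = hypergeom_enrich(probes, sig, population)
            z.loc[sig_name, col] = zval if min(p_en, p_de) <= p_max else 0.0
    z = z.loc[:, (z != 0).any(axis=0)]
    if cluster and z.shape[0] > 2 and z.shape[1] > 2:
        z = z.iloc[_cluster_order(z.to_numpy()), :]
        z = z.iloc[:, _cluster_order(z.to_numpy().T)]
    return z


def _cluster_order(m: np.ndarray) -> np.ndarray:
    """Row order from complete-linkage clustering of 1 - Pearson distance."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(m)
    corr = np.nan_to_num(corr, nan=0.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return leaves_list(linkage(squareform(d, checks=False), method="complete"))
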