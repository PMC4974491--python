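"""Cross-condition module comparison and label harmonization.

Module memberships from two conditions are compared with one-sided Fisher
exact tests on the shared probe universe, giving an overlap-count matrix and a
-log10 p significance matrix (the heat-map representation).  Labels are then
harmonized greedily so that maximally overlapping modules share a color,
making per-module quantities comparable across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import count

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .containers import UNASSIGNED, ModulePartition
from .network import MODULE_COLORS, module_color


@dataclass
class OverlapResult:
    """Pairwise overlap of two module partitions (A-modules x B-modules)."""

    counts: pd.DataFrame
    pvalues: pd.DataFrame
    universe_size: int
    sizes_a: pd.Series = field(default_factory=pd.Series)
    sizes_b: pd.Series = field(default_factory=pd.Series)

    @property
    def neglog10_p(self) -> pd.DataFrame:
        return -np.log10(self.pvalues.clip(lower=1e-300))


def overlap_matrix(
    part_a: ModulePartition, part_b: ModulePartition, universe=None
) -> OverlapResult:
    """Fisher-exact overlap between every (A-module, B-module) pair.

    For modules m (in A) and n (in B) the 2x2 table is
    ``[[|m&n|, |m-n|], [|n-m|, |U-(m|n)|]]`` and p is the one-sided
    (enrichment) Fisher exact tail.  Grey probes belong to the universe but
    grey is not compared as a module.
    """
    if universe is None:
        universe = part_a.labels.index
    universe = pd.Index(universe)
    if not (
        part_a.labels.index.sort_values().equals(universe.sort_values())
        and part_b.labels.index.sort_values().equals(universe.sort_values())
    ):
        raise ValueError("partitions must be defined on the same probe universe")

    mods_a, mods_b = part_a.module_names, part_b.module_names
    n_u = len(universe)
    counts = pd.DataFrame(0, index=mods_a, columns=mods_b, dtype=int)
    pvals = pd.DataFrame(1.0, index=mods_a, columns=mods_b, dtype=float)
    sets_b = {n: set(part_b.members(n)) for n in mods_b}
    for m in mods_a:
        set_m = set(part_a.members(m))
        for n in mods_b:
            set_n = sets_b[n]
            k = len(set_m & set_n)
            table = [
                [k, len(set_m) - k],
                [len(set_n) - k, n_u - len(set_m | set_n)],
            ]
            counts.loc[m, n] = k
            pvals.loc[m, n] = fisher_exact(table, alternative="greater")[1]
    return OverlapResult(
        counts,
        pvals,
        n_u,
        pd.Series({m: int((part_a.labels == m).sum()) for m in mods_a}),
        pd.Series({n: int((part_b.labels == n).sum()) for n in mods_b}),
    )


def harmonize_labels(overlap: OverlapResult, p_max: float = 0.01) -> dict[str, str]:
    """Greedy color mapping for partition B so matched modules share A's color.

    Unmatched (A, B) pairs are taken in order of smallest p, ties broken by
    larger overlap count then lexicographic labels; pairs with p > ``p_max``
    never match.  B modules left unmatched receive fresh colors not used by A.
    Grey maps to grey.
    """
    pairs = []
    for m in overlap.pvalues.index:
        for n in overlap.pvalues.columns:
            pairs.append(
                (float(overlap.pvalues.loc[m, n]), -int(overlap.counts.loc[m, n]), m, n)
            )
    pairs.sort()
    mapping: dict[str, str] = {UNASSIGNED: UNASSIGNED}
    used_a: set[str] = set()
    for p, neg_k, m, n in pairs:
        if p > p_max or -neg_k == 0:
            break
        if m in used_a or n in mapping:
            continue
        mapping[n] = m
        used_a.add(m)
    taken = set(overlap.pvalues.index) | set(mapping.values())
    fresh = (c for c in (module_color(i) for i in count()) if c not in taken)
    for n in overlap.pvalues.columns:
        if n not in mapping:
            mapping[n] = n if n not in taken else next(fresh)
            taken.add(mapping[n])
    return mapping


def harmonize_partition(
    part_b: ModulePartition, overlap: OverlapResult, p_max: float = 0.01
) -> ModulePartition:
    """Apply :func:`harmonize_labels` to partition B."""
    mapping = harmonize_labels(overlap, p_max=p_max)
    out = part_b.relabel(mapping)
    return ModulePartition(out.labels, part_b.kwithin)
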