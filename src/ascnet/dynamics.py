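"""Differential connectivity ("rewiring") analysis between treatment pairs.

Within-module connectivity is scaled to [0, 1] per module, so the change in a
probe's scaled connectivity between two conditions (Delta k) can be plotted
against its moderated T-statistic at a chosen timepoint.  Probes are
classified by the scatter-plot quadrant logic: significant expression change
only ("blue"), significant expression and connectivity change ("red"), or
highly connected in both conditions without either change ("green").  A
complementary rewiring statistic asks what percentage of a probe's top-n
strongest TOM neighbors is shared between the two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import UNASSIGNED, DEResult, ModulePartition

CLASS_EXPRESSION = "expression"
CLASS_BOTH = "expression_and_connectivity"
CLASS_HIGH_K = "highly_connected"
CLASS_NONE = "none"


def scale_connectivity(kwithin: pd.Series, part: ModulePartition) -> pd.Series:
    """Scale kWithin to [0, 1] within each module: ``(k - min)/(max - min)``.

    Members of single-probe or constant-connectivity modules get 0; grey
    probes are returned as NaN (they have no module to be scaled within).
    """
    if not kwithin.index.equals(part.labels.index):
        raise ValueError("kWithin and partition must share the probe index")
    out = pd.Series(np.nan, index=kwithin.index, name="scaled_k")
    for mod in part.module_names:
        members = part.members(mod)
        k = kwithin.loc[members]
        span = k.max() - k.min()
        out.loc[members] = 0.0 if span == 0 else (k - k.min()) / span
    return out


def classify_genes(
    scaled_a: pd.Series,
    scaled_b: pd.Series,
    de: DEResult,
    k_thresh: float = 0.285,
    t_thresh: float = 3.0,
    high_k: float = 0.9,
) -> pd.DataFrame:
    """Connectivity-vs-expression classification of every probe.

    Precedence: |T| and |Delta k| both beyond threshold -> ``red``
    (expression_and_connectivity); |T| alone -> ``blue`` (expression); scaled
    connectivity >= ``high_k`` in BOTH conditions -> ``green``
    (highly_connected); otherwise ``none``.  Probes grey in either condition
    carry NaN Delta k and can only be classified via their T-statistic.
    """
    if not (scaled_a.index.equals(scaled_b.index) and scaled_a.index.equals(de.table.index)):
        raise ValueError("probe indices of connectivities and DE result must match")
    t = de.table["T"]
    dk = scaled_b - scaled_a
    out = pd.DataFrame(
        {
            "scaled_a": scaled_a,
            "scaled_b": scaled_b,
            "delta_k": dk,
            "T": t,
        }
    )
    sig_t = t.abs() > t_thresh
    sig_k = dk.abs() > k_thresh
    high = (scaled_a >= high_k) & (scaled_b >= high_k)
    cls = np.where(
        sig_t & sig_k.fillna(False),
        CLASS_BOTH,
        np.where(sig_t, CLASS_EXPRESSION, np.where(high.fillna(False), CLASS_HIGH_K, CLASS_NONE)),
    )
    out["class"] = cls
    return out


def neighbor_overlap(
    tom_a: pd.DataFrame,
    tom_b: pd.DataFrame,
    probe: str,
    top_n: int = 100,
) -> float:
    """Percent of shared top-``top_n`` TOM neighbors between two conditions.

    Other probes are ranked by TOM weight to ``probe`` in each condition (ties
    broken by lexicographic probe id); the statistic is
    ``100 * |topA & topB| / top_n``.
    """
    if not tom_a.index.equals(tom_b.index):
        raise ValueError("TOM matrices must share the probe universe")
    if top_n >= len(tom_a) - 1 + 1:
        raise ValueError("top_n must be smaller than the universe size")
    top = {}
    for name, t in (("a", tom_a), ("b", tom_b)):
        w = t.loc[probe].drop(probe)
        ranked = (
            pd.DataFrame({"w": -w.to_numpy(), "probe": w.index})
            .sort_values(["w", "probe"], kind="stable")["probe"]
            .iloc[:top_n]
        )
        top[name] = set(ranked)
    return 100.0 * len(top["a"] & top["b"]) / top_n


@dataclass
class ConnectivityComparison:
    """Bundled rewiring comparison between two conditions."""

    table: pd.DataFrame
    condition_a: str
    condition_b: str
    timepoint: float


def compare_conditions(
    part_a: ModulePartition,
    part_b: ModulePartition,
    de: DEResult,
    k_thresh: float = 0.285,
    t_thresh: float = 3.0,
    high_k: float = 0.9,
) -> pd.DataFrame:
    """Scale both conditions' kWithin (on harmonized labels) and classify.

    ``part_b`` is expected to carry harmonized module labels so "within each
    module" means the same module on both sides.
    """
    if part_a.kwithin is None or part_b.kwithin is None:
        raise ValueError("partitions must carry kWithin")
    sa = scale_connectivity(part_a.kwithin, part_a)
    sb = scale_connectivity(part_b.kwithin, part_b)
    return classify_genes(sa, sb, de, k_thresh=k_thresh, t_thresh=t_thresh, high_k=high_k)
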