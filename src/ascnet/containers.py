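"""Core in-memory containers shared by every pipeline stage.

The universal currency is the :class:`ExpressionMatrix`: a probes x samples
matrix of log2 intensities whose samples are annotated with the experimental
design (condition, timepoint in hours, donor).  Sample identifiers encode the
design as ``{condition}_t{timepoint}_d{donor}`` so that matrices written to TSV
remain self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Label used for probes not assigned to any module.
UNASSIGNED = "grey"

SAMPLE_COLUMNS = ("condition", "timepoint", "donor")


def sample_id(condition: str, timepoint: float, donor: str | int) -> str:
    """Canonical sample identifier, e.g. ``ifn_alpha_t6_d2``."""
    return f"{condition}_t{timepoint:g}_d{donor}"


def parse_sample_id(sid: str) -> tuple[str, float, str]:
    """Invert :func:`sample_id`.

    Condition names may themselves contain underscores, so the identifier is
    split on the last ``_t`` / ``_d`` markers.
    """
    head, _, donor = sid.rpartition("_d")
    cond, _, tp = head.rpartition("_t")
    if not cond or not tp or not donor:
        raise ValueError(f"sample id {sid!r} does not follow condition_t<h>_d<donor>")
    return cond, float(tp), donor


@dataclass
class ExpressionMatrix:
    """Log2 expression values (probes x samples) plus design annotations.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample.
    samples
        DataFrame indexed by sample id with columns ``condition``,
        ``timepoint`` (hours) and ``donor``.  If omitted it is reconstructed
        from the sample identifiers.
    probe_symbols
        Optional probe id -> gene symbol mapping.
    """

    values: pd.DataFrame
    samples: pd.DataFrame | None = None
    probe_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.samples is None:
            parsed = [parse_sample_id(s) for s in self.values.columns]
            self.samples = pd.DataFrame(
                parsed, index=self.values.columns, columns=list(SAMPLE_COLUMNS)
            )
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("sample annotations do not cover the value columns")
        if self.values.index.has_duplicates:
            raise ValueError("probe ids must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    # -- convenience accessors -------------------------------------------------

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    @property
    def timepoints(self) -> list[float]:
        return sorted(set(self.samples["timepoint"]))

    @property
    def donors(self) -> list[str]:
        return list(dict.fromkeys(self.samples["donor"]))

    def condition_view(self, condition: str) -> "ExpressionMatrix":
        """Sub-matrix restricted to one condition's samples (all timepoints)."""
        mask = self.samples["condition"] == condition
        if not mask.any():
            raise KeyError(f"no samples for condition {condition!r}")
        return ExpressionMatrix(
            self.values.loc[:, mask.to_numpy()],
            self.samples.loc[mask],
            self.probe_symbols,
        )

    def subset_probes(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[probes], self.samples, self.probe_symbols)

    def group(self, condition: str, timepoint: float) -> pd.DataFrame:
        """Donor-replicate columns for one (condition, timepoint) cell."""
        mask = (self.samples["condition"] == condition) & (
            self.samples["timepoint"] == timepoint
        )
        return self.values.loc[:, mask.to_numpy()]

    def donor_average(self, condition: str) -> pd.DataFrame:
        """Probe x timepoint matrix of donor-averaged values for a condition."""
        sub = self.condition_view(condition)
        tps = sub.samples["timepoint"]
        out = {tp: sub.values.loc[:, (tps == tp).to_numpy()].mean(axis=1) for tp in sub.timepoints}
        return pd.DataFrame(out)


@dataclass
class GroundTruth:
    """Planted structure behind a simulated dataset.

    ``labels`` maps every probe either to the name of the module it was
    planted in or to ``"background"``.  ``profiles`` stores, for each planted
    module and condition, the noise-free mean temporal profile (log2 offsets
    from the probe baseline, one value per timepoint).
    """

    labels: pd.Series
    profiles: dict[tuple[str, str], np.ndarray]
    timepoints: list[float]

    BACKGROUND = "background"

    def module_probes(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    @property
    def modules(self) -> list[str]:
        return [m for m in dict.fromkeys(self.labels) if m != self.BACKGROUND]


@dataclass
class ModulePartition:
    """Probe -> module assignment with per-probe intramodular connectivity.

    Module labels double as display colors (the convention of the coexpression
    network field); ``"grey"`` marks unassigned probes and is never treated as
    a module.
    """

    labels: pd.Series
    kwithin: pd.Series | None = None
    colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kwithin is not None and not self.labels.index.equals(self.kwithin.index):
            raise ValueError("kWithin index must match labels index")
        for lab in self.module_names:
            self.colors.setdefault(lab, lab)

    @property
    def module_names(self) -> list[str]:
        return [l for l in dict.fromkeys(self.labels) if l != UNASSIGNED]

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels != UNASSIGNED].value_counts()
        return counts.sort_values(ascending=False)

    @property
    def grey_fraction(self) -> float:
        return float((self.labels == UNASSIGNED).mean())

    def relabel(self, mapping: dict[str, str]) -> "ModulePartition":
        """Return a copy with module labels renamed (grey untouched)."""
        mapping = {k: v for k, v in mapping.items() if k != UNASSIGNED}
        new = self.labels.map(lambda l: mapping.get(l, l))
        return ModulePartition(new, self.kwithin)


@dataclass
class DEResult:
    """Per-probe moderated differential-expression statistics for one
    (contrast, timepoint) family.

    ``table`` columns: ``logFC`` (log2 A-minus-B), ``T`` (moderated
    t-statistic), ``p`` (raw two-sided p), ``q`` (Benjamini-Hochberg adjusted).
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    timepoint: float
    prior_df: float = np.nan
    prior_var: float = np.nan

    def __post_init__(self) -> None:
        missing = {"logFC", "T", "p", "q"} - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns {sorted(missing)}")

    def significant(self, fdr: float = 0.05) -> pd.Index:
        return self.table.index[self.table["q"] < fdr]
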