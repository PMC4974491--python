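"""Synthetic expression time courses emulating the plasmablast->plasma-cell
differentiation study design.

The generator plants coexpression modules into a probes x samples log2 matrix
covering three cytokine conditions (``none``, ``ifn_alpha``, ``ifn_gamma``),
eight timepoints over four days and three donors.  Each planted module has a
named temporal profile kind (monotone trends, an early-sustained interferon
pulse, transient pulses, a late step), a condition mask restricting where it is
active, and a log2 amplitude.  Probe values are

    baseline_i + amplitude * profile(t) * active(condition)
    + donor offset_(i,donor) + N(0, noise_sd^2)

with background probes receiving baseline plus noise only.  A detection
p-value matrix mimics the behaviour of array detection calls: the probability
that a value is flagged undetected follows a logistic link that increases as
the probe's mean intensity decreases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroundTruth, sample_id

DEFAULT_TIMEPOINTS = (0.0, 2.0, 4.0, 6.0, 12.0, 24.0, 48.0, 96.0)
DEFAULT_CONDITIONS = ("none", "ifn_alpha", "ifn_gamma")


# ---------------------------------------------------------------------------
# temporal profile kinds
# ---------------------------------------------------------------------------

def _nearest(grid: np.ndarray, hour: float) -> float:
    return float(grid[np.argmin(np.abs(grid - hour))])


def _monotone_up(t: np.ndarray) -> np.ndarray:
    # saturating induction, half-maximal at 12 h
    f = t / (t + 12.0)
    return f / f.max() if f.max() > 0 else f


def _gradual_up(t: np.ndarray) -> np.ndarray:
    # steady rise on a log-time axis, reaching its maximum at the last timepoint
    f = np.log1p(t)
    return f / f.max() if f.max() > 0 else f


def _early_pulse(t: np.ndarray, peak: float = 6.0, sustain: float = 0.85) -> np.ndarray:
    """Linear rise to the grid point nearest ``peak``, then a sustained plateau."""
    p = _nearest(t, peak)
    out = np.where(t <= p, np.divide(t, p, out=np.zeros_like(t), where=p > 0), sustain)
    out[t == p] = 1.0
    return out


def _late_step(t: np.ndarray, onset: float = 24.0) -> np.ndarray:
    return (t > onset).astype(float)


def _delayed_up(t: np.ndarray, onset: float = 6.0) -> np.ndarray:
    """Flat until ``onset``, then a gradual log-time rise to 1 at the end."""
    f = np.log1p(np.maximum(t - onset, 0.0))
    return f / f.max() if f.max() > 0 else f


def _transient_pulse(t: np.ndarray, peak: float = 2.0) -> np.ndarray:
    """Triangular (in log-time) pulse: 0 -> 1 at ``peak`` -> 0 by ~4x peak."""
    p = _nearest(t, peak)
    lt, lp, lend = np.log1p(t), math.log1p(p), math.log1p(4.0 * p)
    rise = np.divide(lt, lp, out=np.zeros_like(t), where=lp > 0)
    fall = (lend - lt) / (lend - lp)
    return np.clip(np.where(t <= p, rise, fall), 0.0, 1.0)


def profile_values(kind: str, timepoints) -> np.ndarray:
    """Evaluate a profile kind on a timepoint grid (unit amplitude).

    ``kind`` is either a bare name (``monotone_up``, ``monotone_down``,
    ``early_pulse``, ``gradual_up``, ``late_step``, ``delayed_up``,
    ``transient_pulse``) or a parameterized form ``name:hours`` giving the
    pulse peak / step or rise onset, e.g. ``transient_pulse:24`` or
    ``late_step:48``.
    """
    t = np.asarray(timepoints, dtype=float)
    name, _, arg = kind.partition(":")
    hours = float(arg) if arg else None
    if name == "monotone_up":
        return _monotone_up(t)
    if name == "monotone_down":
        return -_monotone_up(t)
    if name == "gradual_up":
        return _gradual_up(t)
    if name == "early_pulse":
        return _early_pulse(t, peak=hours if hours is not None else 6.0)
    if name == "late_step":
        return _late_step(t, onset=hours if hours is not None else 24.0)
    if name == "delayed_up":
        return _delayed_up(t, onset=hours if hours is not None else 6.0)
    if name == "transient_pulse":
        return _transient_pulse(t, peak=hours if hours is not None else 2.0)
    raise ValueError(f"unknown profile kind {kind!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedModule:
    """One planted coexpression module.

    ``conditions`` is the set of conditions in which the module's profile is
    active (``None`` means all conditions); elsewhere its probes behave like
    background noise.  ``amplitude`` is the peak effect in log2 units; each
    probe's own amplitude is jittered by a lognormal factor with coefficient
    of variation ``amplitude_cv`` (genes within a real coexpression module
    respond with a common shape but heterogeneous magnitudes; identical
    magnitudes would make significance flip in lockstep across probes).
    """

    name: str
    size: int
    kind: str
    conditions: tuple[str, ...] | None = None
    amplitude: float = 2.5
    amplitude_cv: float = 0.3

    def active_in(self, condition: str) -> bool:
        return self.conditions is None or condition in self.conditions


@dataclass(frozen=True)
class SimulationConfig:
    n_probes: int = 2000
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_donors: int = 3
    planted_modules: tuple[PlantedModule, ...] = ()
    noise_sd: float = 0.5
    donor_sd: float = 0.2
    detection_dropout_rate: float = 0.05
    baseline_range: tuple[float, float] = (6.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.size for m in self.planted_modules) > self.n_probes:
            raise ValueError("planted module sizes exceed n_probes")
        if any(m.amplitude <= 0 for m in self.planted_modules):
            raise ValueError("module amplitudes must be > 0")
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 2 or not (np.diff(tp) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if not 0 <= self.detection_dropout_rate < 1:
            raise ValueError("detection_dropout_rate must be in [0, 1)")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def study_default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-design default: three shared differentiation modules plus one
    IFN-alpha-specific early-sustained module and one gradually rising
    IFN-gamma module.

    The shared secretory (up) and cell-cycle (down) modules are deliberately
    anti-correlated; an unsigned network merges them into one module whose
    trend split later separates the up- and down-regulated components, as in
    the real analysis.
    """
    modules = (
        PlantedModule("secretory_up", 300, "monotone_up"),
        PlantedModule("cell_cycle_down", 300, "monotone_down"),
        PlantedModule("late_step", 150, "late_step"),
        PlantedModule("ifn_alpha_early", 120, "early_pulse", ("ifn_alpha",), 2.5),
        PlantedModule("ifn_gamma_gradual", 120, "gradual_up", ("ifn_gamma",), 2.5),
    )
    return SimulationConfig(planted_modules=modules, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# time-course generator
# ---------------------------------------------------------------------------

def _probe_ids(n: int) -> pd.Index:
    return pd.Index([f"probe_{i:05d}" for i in range(n)], name="probe")


def simulate_timecourse(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate an expression matrix, detection p-values, and ground truth.

    Returns
    -------
    (ExpressionMatrix, DataFrame, GroundTruth)
        The detection DataFrame holds per-value detection p-values aligned
        with the expression matrix; values >= 0.05 represent undetected calls.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.timepoints, dtype=float)
    probes = _probe_ids(config.n_probes)
    donors = [str(d + 1) for d in range(config.n_donors)]

    cols = [
        sample_id(c, tp, d)
        for c in config.conditions
        for tp in t
        for d in donors
    ]
    n_samples = len(cols)

    baseline = rng.uniform(*config.baseline_range, size=config.n_probes)

    # planted-module bookkeeping
    labels = np.full(config.n_probes, GroundTruth.BACKGROUND, dtype=object)
    start = 0
    module_rows: dict[str, slice] = {}
    for mod in config.planted_modules:
        module_rows[mod.name] = slice(start, start + mod.size)
        labels[start : start + mod.size] = mod.name
        start += mod.size

    profiles: dict[tuple[str, str], np.ndarray] = {}
    probe_amp: dict[str, np.ndarray] = {}
    for mod in config.planted_modules:
        unit = profile_values(mod.kind, t)
        if mod.amplitude_cv > 0:
            sigma = np.sqrt(np.log1p(mod.amplitude_cv**2))
            jitter = rng.lognormal(-0.5 * sigma**2, sigma, size=mod.size)
        else:
            jitter = np.ones(mod.size)
        probe_amp[mod.name] = mod.amplitude * jitter
        for cond in config.conditions:
            active = mod.active_in(cond)
            profiles[(mod.name, cond)] = mod.amplitude * unit * float(active)

    # donor offsets: per (probe, donor), shared across conditions and time
    donor_offset = rng.normal(0.0, config.donor_sd, size=(config.n_probes, config.n_donors))

    values = np.empty((config.n_probes, n_samples))
    j = 0
    for cond in config.conditions:
        for ti in range(len(t)):
            for di in range(config.n_donors):
                col = baseline + donor_offset[:, di]
                for mod in config.planted_modules:
                    unit_val = profiles[(mod.name, cond)][ti] / mod.amplitude
                    col[module_rows[mod.name]] += probe_amp[mod.name] * unit_val
                values[:, j] = col
                j += 1
    values += rng.normal(0.0, config.noise_sd, size=values.shape)

    vdf = pd.DataFrame(values, index=probes, columns=cols)
    symbols = pd.Series([f"G{i:05d}" for i in range(config.n_probes)], index=probes)
    expr = ExpressionMatrix(vdf, probe_symbols=symbols)

    detection = _simulate_detection(rng, vdf, config.detection_dropout_rate)

    truth = GroundTruth(
        labels=pd.Series(labels, index=probes, name="module"),
        profiles=profiles,
        timepoints=list(t),
    )
    return expr, detection, truth


def _simulate_detection(rng, values: pd.DataFrame, rate: float) -> pd.DataFrame:
    """Per-value detection p-values with a logistic mean-intensity link.

    The per-probe undetected probability is ``sigmoid((thresh - mean_i))``
    with ``thresh`` solved so the matrix-wide undetected rate equals ``rate``;
    low-intensity probes drop out preferentially.  Detected values get
    p ~ U(0, 0.01), undetected values p ~ U(0.05, 1).
    """
    mu = values.mean(axis=1).to_numpy()
    if rate <= 0:
        p_undet = np.zeros(len(mu))
    else:
        lo, hi = mu.min() - 50.0, mu.max() + 50.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if np.mean(1.0 / (1.0 + np.exp(mu - mid))) < rate:
                lo = mid
            else:
                hi = mid
        p_undet = 1.0 / (1.0 + np.exp(mu - 0.5 * (lo + hi)))
    undetected = rng.random(values.shape) < p_undet[:, None]
    pvals = rng.uniform(0.0, 0.01, size=values.shape)
    pvals[undetected] = rng.uniform(0.05, 1.0, size=int(undetected.sum()))
    return pd.DataFrame(pvals, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# signature collections and toy ontologies
# ---------------------------------------------------------------------------

def simulate_signatures(
    truth: GroundTruth,
    n_random: int = 50,
    seed: int = 0,
    member_fraction: float = 0.8,
    decoy_fraction: float = 0.2,
    random_size_range: tuple[int, int] = (20, 100),
) -> dict[str, list[str]]:
    """Gene-set collection with one signature per planted module plus decoys.

    Each module signature contains ``member_fraction`` of the module's probes
    (sampled without replacement) plus ``decoy_fraction * size`` probes drawn
    from outside the module.  ``n_random`` additional signatures are drawn
    uniformly from the whole probe universe, emulating the bulk of a large
    merged signature collection.
    """
    if truth.labels.empty:
        raise ValueError("ground truth is empty")
    rng = np.random.default_rng(seed)
    universe = truth.labels.index.to_numpy()
    sigs: dict[str, list[str]] = {}
    for mod in truth.modules:
        members = truth.module_probes(mod).to_numpy()
        n_true = int(round(member_fraction * len(members)))
        n_decoy = int(round(decoy_fraction * len(members)))
        outside = truth.labels.index[truth.labels != mod].to_numpy()
        chosen = list(rng.choice(members, n_true, replace=False)) + list(
            rng.choice(outside, n_decoy, replace=False)
        )
        sigs[f"sig_{mod}"] = sorted(chosen)
    lo, hi = random_size_range
    for i in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        sigs[f"sig_random_{i:03d}"] = sorted(rng.choice(universe, size, replace=False))
    return sigs


def simulate_ontology(
    truth: GroundTruth,
    depth: int = 2,
    seed: int = 0,
    leaf_annotation_fraction: float = 0.9,
):
    """Toy rooted is_a DAG with leaf-only annotations to planted-module probes.

    The DAG has a single root, ``depth`` levels of internal grouping terms,
    one leaf term per planted module, and (for depth >= 2) one in every two
    leaves receives a second parent so that multi-parent propagation is
    exercised.  Annotations are placed only at leaves, so reaching the root
    requires propagation.

    Returns
    -------
    (networkx.MultiDiGraph, pandas.DataFrame)
        Graph edges point child -> parent with a ``relation`` key (the obonet
        convention); the annotation table has columns ``gene`` and ``term``.
    """
    import networkx as nx

    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    g = nx.MultiDiGraph()
    root = "TOY:0000000"
    g.add_node(root, name="biological process (root)")

    modules = truth.modules or ["background"]
    # chain of internal levels; leaves hang off the deepest level
    internal: list[list[str]] = [[root]]
    term_no = 1
    for level in range(1, depth):
        width = max(2, math.ceil(len(modules) / 2))
        layer = []
        for i in range(width):
            term = f"TOY:{term_no:07d}"
            term_no += 1
            parent = internal[level - 1][i % len(internal[level - 1])]
            g.add_node(term, name=f"internal term L{level}.{i}")
            g.add_edge(term, parent, key="is_a")
            layer.append(term)
        internal.append(layer)

    annotations = []
    for i, mod in enumerate(modules):
        leaf = f"TOY:{term_no:07d}"
        term_no += 1
        g.add_node(leaf, name=f"process of {mod}")
        parents = internal[-1]
        g.add_edge(leaf, parents[i % len(parents)], key="is_a")
        if depth >= 2 and i % 2 == 1 and len(parents) > 1:
            # second parent: diamond-shaped multi-parent path to the root
            g.add_edge(leaf, parents[(i + 1) % len(parents)], key="part_of")
        probes = truth.module_probes(mod) if mod != "background" else truth.labels.index
        n_annot = max(1, int(round(leaf_annotation_fraction * len(probes))))
        for gene in rng.choice(probes.to_numpy(), n_annot, replace=False):
            annotations.append((gene, leaf))

    annot = pd.DataFrame(annotations, columns=["gene", "term"])
    return g, annot
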