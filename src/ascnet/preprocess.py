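"""Expression preprocessing and moderated differential expression.

The stages mirror a standard Illumina array workflow: drop probes that fail
the detection call on too many arrays, quantile normalize the surviving
matrix, keep the most variant probes as the network universe, and test each
(condition A vs condition B, timepoint) contrast with an empirical-Bayes
moderated t-statistic followed by Benjamini-Hochberg adjustment.

The moderated t squeezes each probe's pooled sample variance ``s^2`` (d
residual df) toward a global prior ``s0^2`` (d0 prior df)::

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    T         = (meanA - meanB) / (s_tilde * sqrt(1/nA + 1/nB))

with p-values from a t distribution on ``d + d0`` df.  The hyperparameters
(d0, s0^2) are estimated by matching moments of the log sample variances to a
scaled F distribution (Smyth 2004), including the trigamma inversion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import fdrcorrection

from .containers import DEResult, ExpressionMatrix


# ---------------------------------------------------------------------------
# filtering / normalization / universe selection
# ---------------------------------------------------------------------------

def filter_undetected(
    x: ExpressionMatrix,
    detection: pd.DataFrame,
    alpha_detect: float = 0.05,
    max_undetected: int = 3,
) -> ExpressionMatrix:
    """Remove probes not detected on ``max_undetected`` or more arrays.

    A value is called undetected when its detection p-value is >=
    ``alpha_detect``.  A probe is retained iff its number of undetected arrays
    is strictly below ``max_undetected`` (default 3: probes undetected on
    three or more arrays are removed).
    """
    if not (x.values.index.equals(detection.index) and x.values.columns.equals(detection.columns)):
        raise ValueError("detection matrix must share the expression matrix index/columns")
    n_undetected = (detection.to_numpy() >= alpha_detect).sum(axis=1)
    keep = x.probes[n_undetected < max_undetected]
    return x.subset_probes(keep)


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the common distribution of cross-column rank means.

    Ties within a column receive the mean of the rank-mean values their
    positions span, so tied input values stay tied.
    """
    v = x.values.to_numpy()
    if v.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    order = np.argsort(v, axis=0, kind="stable")
    ranked = np.take_along_axis(v, order, axis=0)
    mean_quantiles = ranked.mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        # average the rank-mean values over tied positions
        col = v[:, j]
        sort_idx = order[:, j]
        assigned = np.empty(v.shape[0])
        s = col[sort_idx]
        i = 0
        while i < len(s):
            k = i
            while k + 1 < len(s) and s[k + 1] == s[i]:
                k += 1
            assigned[i : k + 1] = mean_quantiles[i : k + 1].mean()
            i = k + 1
        out[sort_idx, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=x.values.index, columns=x.values.columns),
        x.samples,
        x.probe_symbols,
    )


def select_most_variant(x: ExpressionMatrix, n: int = 2000) -> ExpressionMatrix:
    """Keep the ``n`` probes with the largest variance across all samples.

    Variance is pooled over every condition and timepoint so that a single
    probe universe supports the cross-condition comparisons.  Boundary ties
    are broken by probe-id lexicographic order; original probe order is
    preserved in the output.
    """
    if n > len(x.probes):
        raise ValueError(f"requested {n} probes but only {len(x.probes)} available")
    var = x.values.var(axis=1, ddof=1)
    ranking = pd.DataFrame({"var": -var, "probe": var.index}).sort_values(
        ["var", "probe"], kind="stable"
    )
    chosen = set(ranking["probe"].iloc[:n])
    keep = x.probes[[p in chosen for p in x.probes]]
    return x.subset_probes(keep)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimates (prior_df d0, prior_var s0^2) from sample variances.

    Matches the first two moments of ``log(s2)`` to the log of a scaled F
    distribution with (df, d0) degrees of freedom.  Returns ``d0 = inf`` when
    the observed spread of log variances is no larger than expected from
    chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    # quantile-normalization ties can produce exactly-zero replicate
    # variances; a single log(0) outlier would wreck the moment estimates,
    # so numerically degenerate variances are excluded from estimation
    # (their posteriors are still shrunk like everyone else's)
    positive = s2 > max(1e-12, 1e-8 * float(np.median(s2)))
    if positive.sum() < 2:
        return np.inf, float(np.median(s2))
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)
    return float(d0), float(s0_2)


def moderated_t(
    x: ExpressionMatrix,
    contrast: tuple[str, str],
    timepoint: float,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> DEResult:
    """Moderated two-group comparison of donor replicates at one timepoint.

    ``contrast = (A, B)`` gives log-fold-changes as mean(A) - mean(B).  By
    default the shrinkage hyperparameters are estimated across probes; passing
    ``prior_df=0`` recovers the ordinary two-sample t-statistic and
    ``prior_df=numpy.inf`` fully shares one variance across probes.
    """
    cond_a, cond_b = contrast
    a = x.group(cond_a, timepoint).to_numpy()
    b = x.group(cond_b, timepoint).to_numpy()
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(
            f"need >=2 donor replicates per condition at t={timepoint:g} "
            f"(got {na} for {cond_a!r}, {nb} for {cond_b!r})"
        )
    df = na + nb - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df
    if prior_df is None or prior_var is None:
        d0_hat, s0_hat = fit_f_dist(s2, df)
        d0 = d0_hat if prior_df is None else prior_df
        s0_2 = s0_hat if prior_var is None else prior_var
    else:
        d0, s0_2 = prior_df, prior_var

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        # cap the total df at the information actually available (limma's rule)
        df_total = min(df + d0, df * len(s2))

    se_factor = np.sqrt(1.0 / na + 1.0 / nb)
    logfc = mean_a - mean_b
    t_stat = logfc / (np.sqrt(s2_post) * se_factor)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"logFC": logfc, "T": t_stat, "p": p, "q": q}, index=x.probes
    )
    return DEResult(table, contrast, timepoint, prior_df=d0, prior_var=s0_2)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return fdrcorrection(p, alpha=0.05, method="indep")[1]


def de_counts(results: list[DEResult], fdr: float = 0.05) -> pd.DataFrame:
    """Number of probes with q < fdr per (contrast, timepoint)."""
    if not results:
        raise ValueError("no DE results supplied")
    rows = [
        {
            "contrast": f"{r.contrast[0]}_vs_{r.contrast[1]}",
            "timepoint": r.timepoint,
            "count": int((r.table["q"] < fdr).sum()),
        }
        for r in results
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["contrast", "timepoint"], kind="stable")
        .reset_index(drop=True)
    )
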