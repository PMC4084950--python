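"""Replicate-level bookkeeping and statistics for simulation sweeps.

Each replicate is summarized by the median of its metric series across the
final 500 hours (the regime where the spacer locus is filled and dynamics
are most regular), classified as stable / viral-extinct / unfilled-locus,
and the summaries are compared across parameter values with Spearman rank
correlations, unbalanced one-way ANOVA with pairwise contrasts, and
linear-vs-quadratic AIC model comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .metrics import MetricsResult, SigmaVariant, compute_metrics
from .simulator import SimParams, TrajectoryRecord

DEFAULT_WINDOW = 500.0          # final-window length (h) for replicate medians
STABILITY_THRESHOLD = 3e5       # cells/mL, ~95% of the carrying capacity
STABILITY_SPAN = 100.0          # h the host total must stay above threshold


@dataclass
class ReplicateSummary:
    """Final-window medians and outcome bookkeeping for one replicate."""

    params: dict
    median_pdi: float
    median_idi: float
    median_hvi: float
    median_host_density: float
    median_viral_density: float
    median_host_strains: float
    median_viral_strains: float
    outcome: str
    stable: bool
    locus_filled: bool
    filled_before_end: bool
    peaks: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items() if k not in ("peaks", "params")}
        row.update({f"param_{k}": v for k, v in self.params.items()})
        return row


def find_host_peaks(
    times: np.ndarray,
    totals: np.ndarray,
    prominence: float | None = None,
    min_separation: float = 10.0,
    K: float = 3.158e5,
) -> pd.DataFrame:
    """Local maxima of the total host density series (host peaks).

    A peak is strictly greater than both neighbors, with minimum prominence
    0.05*K by default and at least ``min_separation`` hours between peaks
    (ties resolved to the earliest sample).
    """
    times = np.asarray(times, float)
    totals = np.asarray(totals, float)
    if len(totals) < 3:
        return pd.DataFrame(columns=["time", "host_total"])
    if prominence is None:
        prominence = 0.05 * K
    dt = np.median(np.diff(times)) if len(times) > 1 else 1.0
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = signal.find_peaks(totals, prominence=prominence, distance=distance)
    return pd.DataFrame(
        {"index": idx, "time": times[idx], "host_total": totals[idx]}
    )


def window_median(
    times: np.ndarray,
    values: np.ndarray,
    t_end: float,
    window: float = DEFAULT_WINDOW,
) -> float:
    """Median over all recorded points with time > t_end - window.

    Raises if the series ended before t_end (early-terminated replicates
    have no defined final-window median and are flagged upstream).
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times.size == 0 or times.max() < t_end - 1e-6:
        raise ValueError(
            f"series ends at t={times.max() if times.size else 'nan'} "
            f"before t_end={t_end}; final-window median undefined"
        )
    sel = times > t_end - window
    return float(np.median(values[sel]))


def is_stable(
    times: np.ndarray,
    totals: np.ndarray,
    threshold: float = STABILITY_THRESHOLD,
    min_span: float = STABILITY_SPAN,
) -> bool:
    """True iff the host total stays strictly above ``threshold`` over some
    run of consecutive recorded points spanning at least ``min_span`` hours."""
    times = np.asarray(times, float)
    totals = np.asarray(totals, float)
    above = totals > threshold
    start = None
    for t, ok in zip(times, above):
        if ok:
            if start is None:
                start = t
            if t - start >= min_span:
                return True
        else:
            start = None
    return False


def summarize_replicate(
    traj: TrajectoryRecord,
    window: float = DEFAULT_WINDOW,
    sigma: SigmaVariant = "pairwise",
) -> ReplicateSummary:
    """Final-window medians of DI metrics, densities and strain counts.

    Metric medians are NaN for replicates that ended before t_end; their
    outcome and locus bookkeeping is still reported.
    """
    times = traj.times
    host_totals = traj.host_totals
    viral_totals = traj.viral_totals
    t_end = traj.params.t_end
    peaks = find_host_peaks(times, host_totals, K=traj.params.K)

    ended_early = traj.outcome != "completed"
    if ended_early:
        med = dict.fromkeys(
            ["pdi", "idi", "hvi", "host_density", "viral_density",
             "host_strains", "viral_strains"], float("nan")
        )
    else:
        sel = np.flatnonzero(times > t_end - window)
        results = [compute_metrics(traj.community_at(i), sigma) for i in sel]
        med = {
            "pdi": float(np.median([m.pdi for m in results])),
            "idi": float(np.median([m.idi for m in results])),
            "hvi": float(np.median([m.hvi for m in results])),
            "host_density": window_median(times, host_totals, t_end, window),
            "viral_density": window_median(times, viral_totals, t_end, window),
            "host_strains": window_median(
                times, traj.host_strain_counts(), t_end, window),
            "viral_strains": window_median(
                times, traj.viral_strain_counts(), t_end, window),
        }

    return ReplicateSummary(
        params=traj.params.to_dict(),
        median_pdi=med["pdi"],
        median_idi=med["idi"],
        median_hvi=med["hvi"],
        median_host_density=med["host_density"],
        median_viral_density=med["viral_density"],
        median_host_strains=med["host_strains"],
        median_viral_strains=med["viral_strains"],
        outcome=traj.outcome,
        stable=is_stable(times, host_totals),
        locus_filled=traj.locus_filled_in_window,
        filled_before_end=traj.filled_before_end,
        peaks=peaks,
    )


def classify_outcomes(summaries: Iterable[ReplicateSummary]) -> dict:
    """Partition replicates into complete / viral_extinction / unfilled_locus.

    A replicate is ``unfilled_locus`` when its spacer loci were not all full
    throughout the final window, or when the virus died out before the loci
    ever filled; these replicates are excluded from population averages.
    ``viral_extinction`` counts post-fill extinctions. The classes partition
    the set. ``unfilled_viral_extinct`` additionally reports how many of the
    unfilled-locus replicates ended in viral extinction.
    """
    counts = {"complete": 0, "viral_extinction": 0, "unfilled_locus": 0,
              "host_extinction": 0, "unfilled_viral_extinct": 0}
    for s in summaries:
        if s.outcome == "host_extinction":
            counts["host_extinction"] += 1
        elif s.outcome == "viral_extinction" and not s.filled_before_end:
            counts["unfilled_locus"] += 1
            counts["unfilled_viral_extinct"] += 1
        elif not s.locus_filled:
            counts["unfilled_locus"] += 1
            if s.outcome == "viral_extinction":
                counts["unfilled_viral_extinct"] += 1
        elif s.outcome == "viral_extinction":
            counts["viral_extinction"] += 1
        else:
            counts["complete"] += 1
    return counts


def spearman_table(
    df: pd.DataFrame,
    x_vars: Sequence[str],
    y_vars: Sequence[str],
) -> pd.DataFrame:
    """Spearman rank correlations for each (x, y) pair, with p-values.

    Constant columns give an undefined rho, reported as NaN.
    """
    rows = []
    for x, y in itertools.product(x_vars, y_vars):
        xs, ys = df[x].to_numpy(float), df[y].to_numpy(float)
        ok = np.isfinite(xs) & np.isfinite(ys)
        xs, ys = xs[ok], ys[ok]
        if len(xs) < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.spearmanr(xs, ys)
        rows.append({"x": x, "y": y, "rho": rho, "p": p, "n": len(xs)})
    return pd.DataFrame(rows)


def linear_vs_quadratic_aic(x: np.ndarray, y: np.ndarray) -> dict:
    """Least-squares linear and quadratic fits compared by AIC.

    AIC = n ln(RSS/n) + 2k with k the number of fitted coefficients; the
    lower-AIC model is preferred.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values identical")
    out = {}
    n = len(x)
    # floor RSS at the square of machine-level residuals so an exact fit by
    # both models is decided by the parsimony penalty alone
    floor = n * (1e-12 * max(1.0, float(np.abs(y).max()))) ** 2
    for name, deg, k in (("linear", 1, 2), ("quadratic", 2, 3)):
        coef = np.polyfit(x, y, deg)
        resid = y - np.polyval(coef, x)
        rss = float(resid @ resid)
        aic = n * np.log(max(rss, floor) / n) + 2 * k
        out[name] = {"coef": coef.tolist(), "rss": rss, "aic": float(aic)}
    out["delta_aic"] = out["quadratic"]["aic"] - out["linear"]["aic"]
    out["choice"] = "quadratic" if out["delta_aic"] < 0 else "linear"
    return out


def unbalanced_anova_pairwise(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA across groups of unequal size, plus Holm-adjusted
    pairwise Welch t-tests.

    Groups with fewer than 2 members are excluded (with a warning entry).
    """
    import warnings

    usable = {}
    excluded = []
    for name, vals in groups.items():
        vals = np.asarray(vals, float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            excluded.append(name)
            warnings.warn(f"group {name!r} has <2 members; excluded")
        else:
            usable[name] = vals
    if len(usable) < 2:
        raise ValueError("need at least 2 usable groups")

    F, p = stats.f_oneway(*usable.values())
    pairs = list(itertools.combinations(sorted(usable), 2))
    raw = [stats.ttest_ind(usable[a], usable[b], equal_var=False).pvalue
           for a, b in pairs]
    if raw:
        adjusted = multipletests(raw, method="holm")[1]
    else:
        adjusted = []
    pairwise = pd.DataFrame(
        {"group_a": [a for a, _ in pairs],
         "group_b": [b for _, b in pairs],
         "p_raw": raw,
         "p_holm": adjusted}
    )
    return {"F": float(F), "p": float(p), "pairwise": pairwise,
            "excluded": excluded}


def subsample_compare(
    df: pd.DataFrame,
    bin_col: str,
    outcome_cols: Sequence[str] = ("stable", "viral_extinct"),
    n_sub: int = 230,
    reps: int = 10000,
    seed: int | None = None,
) -> dict:
    """Mean per-bin outcome proportions over random subsamples.

    Draws ``reps`` subsamples of ``n_sub`` replicates without replacement,
    computes the proportion of each boolean outcome per DI bin in each
    subsample, and compares bins by one-way ANOVA on the subsample
    proportions.
    """
    if n_sub > len(df):
        raise ValueError(f"n_sub={n_sub} exceeds population size {len(df)}")
    rng = np.random.default_rng(seed)
    bins = sorted(df[bin_col].dropna().unique())
    sums = {c: {b: [] for b in bins} for c in outcome_cols}
    values = df[[bin_col, *outcome_cols]].reset_index(drop=True)
    for _ in range(reps):
        idx = rng.choice(len(values), size=n_sub, replace=False)
        sub = values.iloc[idx]
        grouped = sub.groupby(bin_col, observed=True)[list(outcome_cols)].mean()
        for c in outcome_cols:
            for b in bins:
                if b in grouped.index:
                    sums[c][b].append(float(grouped.loc[b, c]))
    result = {}
    for c in outcome_cols:
        means = {b: (float(np.mean(v)) if v else float("nan"))
                 for b, v in sums[c].items()}
        comparisons = None
        usable = {str(b): np.asarray(v) for b, v in sums[c].items() if len(v) >= 2}
        if len(usable) >= 2:
            comparisons = unbalanced_anova_pairwise(usable)
        result[c] = {"bin_means": means, "anova": comparisons}
    return result


def assign_di_bins(
    df: pd.DataFrame,
    pdi_width: float = 0.1,
    idi_width: float = 0.6,
) -> pd.DataFrame:
    """Attach PDI/IDI bin labels (left edges) to a summary table."""
    out = df.copy()
    out["pdi_bin"] = np.floor(out["median_pdi"] / pdi_width) * pdi_width
    out["idi_bin"] = np.floor(out["median_idi"] / idi_width) * idi_width
    return out


def summaries_to_frame(summaries: Iterable[ReplicateSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])
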