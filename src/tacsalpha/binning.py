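"""Trial-order binning of baseline-relative power change, with Friedman and
Conover rank statistics.

Each post-stimulation trial n yields one relative power change,

    power_difference(n) = (power_trial(n) - avg_power_baseline)
                          / avg_power_baseline,

at ISF, averaged over the significant-cluster units and over time.  The 20
trials of a block are grouped, in trial order, into 5 bins of 4 trials.  A
Friedman test over participants x bins asks whether the power change drifts
with time on task; a pairwise Conover post hoc (Bonferroni over the 10
pairs) localises any omnibus effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

N_BINS = 5
TRIALS_PER_BIN = 4


@dataclass
class BinSeries:
    power_difference: np.ndarray  # one value per trial, NaN when flagged
    bin_means: np.ndarray  # (N_BINS,)
    participant: str | int = ""
    condition: str = ""
    block: str = ""

    @property
    def bin_edges(self) -> list[tuple[int, int]]:
        return [(b * TRIALS_PER_BIN, (b + 1) * TRIALS_PER_BIN)
                for b in range(N_BINS)]


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    posthoc: np.ndarray | None  # (k, k) Bonferroni-adjusted p matrix


def compute_bin_series(
    post_power: np.ndarray,
    base_power: np.ndarray,
    cluster_units: np.ndarray,
    rejected: np.ndarray | None = None,
    **meta,
) -> BinSeries:
    """Per-trial relative power change at ISF, binned by trial order.

    ``post_power``: (n_trials, n_units, n_times) per-trial power at ISF.
    ``base_power``: (n_base_trials, n_units[, n_times]) baseline power.
    Flagged trials contribute missing values but keep their positions, so
    bin membership stays tied to trial order.
    """
    post_power = np.asarray(post_power, dtype=float)
    base_power = np.asarray(base_power, dtype=float)
    cluster_units = np.asarray(cluster_units)
    n_trials = post_power.shape[0]
    if n_trials != N_BINS * TRIALS_PER_BIN:
        raise ValueError(
            f"expected {N_BINS * TRIALS_PER_BIN} trials, got {n_trials}"
        )
    # per-unit baseline average over trials (and time, if present)
    avg_base = base_power[:, cluster_units].mean(axis=0)
    while avg_base.ndim > 1:
        avg_base = np.nanmean(avg_base, axis=-1)
    if np.any(avg_base <= 0):
        raise ValueError("baseline power must be positive")
    pd_units = (
        np.nanmean(post_power[:, cluster_units], axis=-1) - avg_base
    ) / avg_base
    series = pd_units.mean(axis=1)
    if rejected is not None:
        series = np.where(np.asarray(rejected, dtype=bool), np.nan, series)
    bin_means = np.empty(N_BINS)
    for b in range(N_BINS):
        chunk = series[b * TRIALS_PER_BIN:(b + 1) * TRIALS_PER_BIN]
        if np.sum(np.isfinite(chunk)) < 2:
            raise ValueError(
                f"bin {b + 1} has fewer than 2 usable trials"
            )
        bin_means[b] = np.nanmean(chunk)
    return BinSeries(power_difference=series, bin_means=bin_means, **meta)


def trial_bin(trial_number: int) -> int:
    """1-based bin of a 1-based trial number (trials 1-4 -> bin 1, ...)."""
    if not (1 <= trial_number <= N_BINS * TRIALS_PER_BIN):
        raise ValueError("trial number out of range")
    return (trial_number - 1) // TRIALS_PER_BIN + 1


def conover_posthoc(table: np.ndarray, bonferroni: bool = True) -> np.ndarray:
    """Pairwise Conover test after Friedman, on an (n, k) block table.

    Uses the rank-based pairwise t statistic
    ``t = (R_i - R_j) / sqrt(2 (n*A1 - sum_j R_j^2) / ((n-1)(k-1)))``
    with ``A1`` the sum of squared within-block ranks and df = (n-1)(k-1);
    p values are two-sided and (by default) Bonferroni-adjusted over the
    k(k-1)/2 pairs.
    """
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    ranks = scipy.stats.rankdata(table, axis=1)
    R = ranks.sum(axis=0)
    a1 = float(np.sum(ranks**2))
    df = (n - 1) * (k - 1)
    denom2 = 2.0 * (n * a1 - float(np.sum(R**2))) / df
    m = k * (k - 1) // 2
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if denom2 <= 0:
                pij = 1.0 if R[i] == R[j] else 0.0
            else:
                t = abs(R[i] - R[j]) / np.sqrt(denom2)
                pij = 2.0 * scipy.stats.t.sf(t, df=df)
            if bonferroni:
                pij = min(1.0, pij * m)
            p[i, j] = p[j, i] = pij
    return p


def friedman_bins(
    tables: np.ndarray, posthoc: str = "auto"
) -> FriedmanResult:
    """Friedman test of the bin effect across participants.

    ``tables``: (n_participants, N_BINS) per-participant bin means.  Missing
    values are mean-imputed within the participant (Friedman needs complete
    blocks).  The Conover post hoc is computed when the omnibus p < 0.05
    (``posthoc='auto'``), always, or never.
    """
    tables = np.asarray(tables, dtype=float)
    if tables.ndim != 2 or tables.shape[1] != N_BINS:
        raise ValueError(f"tables must be (n_participants, {N_BINS})")
    n, k = tables.shape
    if n < 3:
        raise ValueError("Friedman test needs at least 3 participants")
    if np.any(~np.isfinite(tables)):
        row_mean = np.nanmean(tables, axis=1, keepdims=True)
        tables = np.where(np.isfinite(tables), tables, row_mean)
    constant_rows = np.all(tables == tables[:, :1], axis=1)
    if constant_rows.all():
        return FriedmanResult(chi2=0.0, df=k - 1, p=1.0, posthoc=None)
    chi2, p = scipy.stats.friedmanchisquare(*tables.T)
    result_posthoc = None
    if posthoc == "always" or (posthoc == "auto" and p < 0.05):
        result_posthoc = conover_posthoc(tables)
    elif posthoc not in ("auto", "never", "always"):
        raise ValueError(f"unknown posthoc policy {posthoc!r}")
    return FriedmanResult(chi2=float(chi2), df=k - 1, p=float(p),
                          posthoc=result_posthoc)
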