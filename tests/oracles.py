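"""Independent reference implementations used as test oracles.

Deliberately naive: plain loops, textbook formulas and networkx graph
walks, sharing no code with the package's vectorised paths.
"""

from __future__ import annotations

from itertools import product

import networkx as nx
import numpy as np
import scipy.stats


def periodogram_argmax(data: np.ndarray, fs: float, freqs: np.ndarray,
                       lo: float, hi: float) -> float:
    """Brute-force Hanning periodogram argmax over [lo, hi].

    ``data``: (units, trials, samples); power averaged over units/trials.
    """
    nu, nt, ns = data.shape
    n = nt * ns
    w = np.hanning(n + 2)[1:-1]  # symmetric non-zero-endpoint Hanning
    total = np.zeros(len(freqs))
    for u in range(nu):
        x = np.concatenate([data[u, t] for t in range(nt)]).astype(float)
        x = x - x.mean()
        for f_i, f in enumerate(freqs):
            c = np.cos(2 * np.pi * f * np.arange(n) / fs)
            s = np.sin(2 * np.pi * f * np.arange(n) / fs)
            total[f_i] += (np.dot(w * x, c) ** 2 + np.dot(w * x, s) ** 2)
    sel = (freqs >= lo) & (freqs <= hi)
    return float(freqs[sel][np.argmax(total[sel])])


def pooled_t(x, y) -> float:
    """Textbook two-sample pooled-variance t statistic (x vs y)."""
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    s1 = sum((v - m1) ** 2 for v in x) / (n1 - 1)
    s2 = sum((v - m2) ** 2 for v in y) / (n2 - 1)
    sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    return (m1 - m2) / (sp ** 0.5 * (1 / n1 + 1 / n2) ** 0.5)


def friedman_chi2(table: np.ndarray) -> float:
    """Friedman rank statistic, 12n/(k(k+1)) * sum (Rbar_j - (k+1)/2)^2,
    with mid-ranks (no tie correction; valid for untied tables)."""
    n, k = table.shape
    ranks = np.array([scipy.stats.rankdata(row) for row in table])
    rbar = ranks.mean(axis=0)
    return float(12 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2) ** 2))


def conover_pairwise_p(table: np.ndarray, i: int, j: int) -> float:
    """Conover's post-hoc comparison of treatments i, j after Friedman,
    computed step by step from the published rank formula (unadjusted)."""
    n, k = table.shape
    ranks = np.array([scipy.stats.rankdata(row) for row in table])
    col_sums = ranks.sum(axis=0)
    a1 = (ranks ** 2).sum()
    df = (n - 1) * (k - 1)
    se2 = 2.0 * (n * a1 - (col_sums ** 2).sum()) / df
    t = abs(col_sums[i] - col_sums[j]) / np.sqrt(se2)
    return float(2 * scipy.stats.t.sf(t, df))


def rank_sum_u(x, y) -> float:
    """Mann-Whitney U of the first sample, by direct rank computation."""
    pooled = list(x) + list(y)
    ranks = scipy.stats.rankdata(pooled)
    r1 = sum(ranks[: len(x)])
    return float(r1 - len(x) * (len(x) + 1) / 2)


def exhaustive_cluster_p(
    tacs: np.ndarray,
    control: np.ndarray,
    adjacency: np.ndarray,
    alpha_form: float = 0.05,
    min_size: int = 2,
):
    """Exhaustive sign-flip enumeration of the max-sum cluster null.

    Independent machinery: clusters found with networkx connected
    components, t statistics with scipy, and an explicit loop over all
    2^n sign assignments.  Returns a list of (members, sum_t, p) for the
    observed clusters.
    """
    d = np.asarray(tacs, float) - np.asarray(control, float)
    n = d.shape[0]
    crit = scipy.stats.t.ppf(1 - alpha_form / 2, df=n - 1)
    g = nx.Graph()
    n_elem = d.shape[1]
    g.add_nodes_from(range(n_elem))
    for a in range(n_elem):
        for b in range(a + 1, n_elem):
            if adjacency[a, b]:
                g.add_edge(a, b)

    def tmap(dd):
        out = np.zeros(n_elem)
        for e in range(n_elem):
            col = dd[:, e]
            s = col.std(ddof=1)
            out[e] = 0.0 if s == 0 else col.mean() / (s / np.sqrt(n))
        return out

    def clusters_of(t):
        found = []
        for sign in (1, -1):
            nodes = [e for e in range(n_elem) if sign * t[e] > crit]
            for comp in nx.connected_components(g.subgraph(nodes)):
                if len(comp) >= min_size:
                    found.append((sorted(comp), float(sum(t[m] for m in comp))))
        return found

    t_obs = tmap(d)
    observed = clusters_of(t_obs)
    maxima = []
    for signs in product((1, -1), repeat=n):
        dd = d * np.array(signs)[:, None]
        cl = clusters_of(tmap(dd))
        maxima.append(max((abs(s) for _, s in cl), default=0.0))
    maxima = np.array(maxima)
    results = []
    for members, sum_t in observed:
        p = float(np.mean(maxima >= abs(sum_t) - 1e-12))
        results.append((members, sum_t, p))
    return results


def alpha_band_gain(baseline, post, isf: float) -> float:
    """Injected-power-gain estimate from raw arrays: Welch PSD, alpha band
    power above a log-log-fitted 1/f background, post/baseline ratio - 1."""
    import scipy.signal as sps

    def alpha_power(ts):
        f, p = sps.welch(ts.data.astype(np.float64), fs=ts.sampling_rate,
                         nperseg=2000, axis=-1)
        p = p.mean(axis=(0, 1))
        inband = (f >= isf - 1.5) & (f <= isf + 1.5)
        bg_sel = ((f >= isf - 6) & (f <= isf - 3)) \
            | ((f >= isf + 3) & (f <= isf + 6))
        coef = np.polyfit(np.log(f[bg_sel]), np.log(p[bg_sel]), 1)
        bg = np.exp(np.polyval(coef, np.log(f[inband])))
        return np.sum(p[inband] - bg)

    return alpha_power(post) / alpha_power(baseline) - 1.0
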