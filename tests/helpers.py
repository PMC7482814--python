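"""Independent oracles and small generators shared across tests.

Everything here is deliberately naive (exhaustive scans, closed forms) and
must stay independent of the package's implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def single_changepoint_argmax(X: np.ndarray) -> int:
    """Exhaustive conjugate-posterior argmax over single change points.

    Flat prior over boundaries; per boundary the marginal likelihood of a
    two-segment Gaussian model with flat segment means and Jeffreys noise
    variance is ``(k1 k2)^(-m/2) RSS^(-m(n-2)/2)``.  Returns the 0-based
    boundary index (change after probe j).  Ties -> smallest j.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    best_j, best_lp = 0, -np.inf
    for j in range(n - 1):
        k1, k2 = j + 1, n - j - 1
        rss = 0.0
        for seg in (X[: j + 1], X[j + 1 :]):
            rss += ((seg - seg.mean(axis=0, keepdims=True)) ** 2).sum()
        if rss <= 1e-300:
            lp = np.inf
        else:
            lp = -(m / 2.0) * (np.log(k1) + np.log(k2)) - (
                m * (n - 2) / 2.0
            ) * np.log(rss)
        if lp > best_lp:
            best_j, best_lp = j, lp
    return best_j


def brute_force_probe_assignment(candidates, probe_map):
    """O(P*T) interval scan: probe -> tandems whose span contains it.

    Returns dict tandem_id -> list of probe ids surviving the uniqueness
    rule (probes contained in exactly one tandem span, matching strand),
    in transcript order.
    """
    per_tandem: dict[str, list[tuple[int, str]]] = {t.tandem_id: [] for t in candidates}
    for _, row in probe_map.iterrows():
        holders = []
        for t in candidates:
            lo, hi = t.genomic_span
            if row["chrom"] == t.chrom and lo <= row["start"] and row["end"] <= hi:
                holders.append(t)
        if len(holders) == 1 and row["strand"] == holders[0].strand:
            t = holders[0]
            key = -row["start"] if t.strand == "-" else row["start"]
            per_tandem[t.tandem_id].append((key, row["probe_id"]))
    return {
        tid: [pid for _, pid in sorted(pairs)] for tid, pairs in per_tandem.items()
    }


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """q_i = min_{k: p_k >= p_i} (m * p_k / rank_k), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = np.empty(m)
    for i in range(m):
        q[i] = min(min(m * ranked[k] / (k + 1) for k in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def adjusted_rand_index(a, b) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(a, b))


def planted_step_matrix(rng, n, m, j, effect, sigma):
    """n x m matrix with a mean step of ``effect`` after probe j plus noise."""
    X = np.zeros((n, m))
    X[j + 1 :, :] = effect
    return X + rng.normal(0.0, sigma, (n, m))
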