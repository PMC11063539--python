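"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions (scalar loops, exhaustive
pair counting, hand-computed risk sets) and deliberately shares no code
path with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2


# ---------------------------------------------------------------- kernels


def similarity_oracle(values: np.ndarray, alpha: float) -> np.ndarray:
    """Scalar per-pair Gaussian kernel on squared Euclidean distances."""
    n = values.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2 = 0.0
            for f in range(values.shape[1]):
                d2 += (values[i, f] - values[j, f]) ** 2
            out[i, j] = np.exp(-alpha * d2)
    return out


def neighborhood_oracle(
    a: np.ndarray,
    labels: np.ndarray,
    rep: np.ndarray,
    beta: float,
    mu: float,
) -> np.ndarray:
    """Entrywise evaluation of the neighborhood reweighting formula."""
    k = int(labels.max()) + 1
    centroids = [rep[labels == c].mean(axis=0) for c in range(k)]
    mean_dist = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        mean_dist.append(
            float(np.mean([np.linalg.norm(rep[i] - centroids[c]) for i in members]))
        )
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ci, cj = labels[i], labels[j]
            dv = float(np.linalg.norm(centroids[ci] - centroids[cj]))
            eta = (mean_dist[ci] + mean_dist[cj] + dv) / 3.0
            d_val = np.exp(beta * dv**2 / (eta + 1.0))
            out[i, j] = 2.0 * a[i, j] ** 2 / (d_val * (mu + mean_dist[ci] + mean_dist[cj]))
    return out


def triple_product_oracle(a_list: list[np.ndarray], abar_list: list[np.ndarray]) -> list[np.ndarray]:
    """Entrywise sum_{o' != o} Abar_o A_{o'} Abar_o^T, scalar loops only."""
    n = a_list[0].shape[0]
    out = []
    for o, b in enumerate(abar_list):
        acc = np.zeros((n, n))
        for o2, a in enumerate(a_list):
            if o2 == o:
                continue
            for i in range(n):
                for j in range(n):
                    s = 0.0
                    for p in range(n):
                        for q in range(n):
                            s += b[i, p] * a[p, q] * b[j, q]
                    acc[i, j] += s
        out.append(acc)
    return out


# ---------------------------------------------------------- pair counting


def pair_counts(a, b) -> tuple[int, int, int, int]:
    n = len(a)
    n11 = n10 = n01 = n00 = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a and same_b:
                n11 += 1
            elif same_a:
                n10 += 1
            elif same_b:
                n01 += 1
            else:
                n00 += 1
    return n11, n10, n01, n00


def ari_oracle(a, b) -> float:
    n11, n10, n01, n00 = pair_counts(a, b)
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        # both partitions trivial (all-singleton or single-cluster agreement)
        return 1.0
    return (n11 - expected) / (max_index - expected)


def fm_oracle(a, b) -> float:
    n11, n10, n01, _ = pair_counts(a, b)
    if n11 == 0:
        return 0.0
    return n11 / np.sqrt((n11 + n10) * (n11 + n01))


def set_partitions(n: int):
    """All partitions of {0..n-1} as restricted-growth label strings."""

    def rec(prefix: list[int], m: int):
        if len(prefix) == n:
            yield list(prefix)
            return
        for v in range(m + 1):
            yield from rec(prefix + [v], max(m, v + 1))

    if n == 0:
        return
    yield from rec([0], 1)


# ------------------------------------------------------------- silhouette


def silhouette_oracle(x: np.ndarray, labels: np.ndarray) -> float:
    """Direct per-point a(i)/b(i) silhouette on Euclidean distances."""
    n = len(labels)
    dist = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([dist[i, j] for j in own])
        b = min(
            np.mean([dist[i, j] for j in range(n) if labels[j] == g])
            for g in set(labels)
            if g != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


# ---------------------------------------------------------------- survival


def logrank_oracle(time, event, group) -> tuple[float, int, float]:
    """K-sample log-rank from pooled risk sets, hypergeometric variance."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    groups = np.unique(group)
    k = len(groups)
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_total = at_risk.sum()
        d_total = ((time == t) & (event == 1)).sum()
        n_g = np.array([(at_risk & (group == g)).sum() for g in groups])
        d_g = np.array([((time == t) & (event == 1) & (group == g)).sum() for g in groups])
        observed += d_g
        expected += d_total * n_g / n_total
        if n_total > 1:
            c = d_total * (n_total - d_total) / (n_total - 1)
            for j in range(k):
                for l in range(k):
                    cov[j, l] += c * (
                        (j == l) * n_g[j] / n_total - n_g[j] * n_g[l] / n_total**2
                    )
    z = (observed - expected)[:-1]
    stat = float(z @ np.linalg.solve(cov[:-1, :-1], z))
    return stat, k - 1, float(chi2.sf(stat, k - 1))


def km_oracle(time, event) -> list[tuple[float, float]]:
    """Hand product-limit estimate: [(event time, survival after)] steps."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    surv = 1.0
    steps = []
    for t in np.unique(time[event == 1]):
        n_at_risk = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        surv *= 1.0 - d / n_at_risk
        steps.append((float(t), surv))
    return steps
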