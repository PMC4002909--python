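"""Compiled inner loops for online SOM training.

The per-epoch presentation loop is inherently sequential (each winner
update changes the prototypes seen by the next pattern), so it is written
as a nopython kernel rather than vectorized.  The combined distance is
(1 - alpha) * ||x - w||_2 + alpha * b, with the biological term b read
from a per-epoch matrix B that is precomputed outside (it depends only on
the epoch's membership snapshot and on rho, not on the moving prototypes).
Passing alpha = 0 with an all-zero B reproduces standard Euclidean SOM
arithmetic bit-for-bit.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def run_epoch(data, weights, B, order, alpha, lr, radius, rows, cols):
    """Present patterns in ``order``; update winner + Chebyshev ball in place."""
    n, d = data.shape
    k = weights.shape[0]
    for t in range(order.shape[0]):
        idx = order[t]
        best = 0
        best_dist = np.inf
        for m in range(k):
            acc = 0.0
            for j in range(d):
                diff = data[idx, j] - weights[m, j]
                acc += diff * diff
            dist = (1.0 - alpha) * math.sqrt(acc) + alpha * B[idx, m]
            if dist < best_dist:  # strict: ties keep the lowest unit index
                best_dist = dist
                best = m
        br = best // cols
        bc = best % cols
        r0 = br - radius if br - radius > 0 else 0
        r1 = br + radius + 1 if br + radius + 1 < rows else rows
        c0 = bc - radius if bc - radius > 0 else 0
        c1 = bc + radius + 1 if bc + radius + 1 < cols else cols
        for r in range(r0, r1):
            for c in range(c0, c1):
                m = r * cols + c
                for j in range(d):
                    weights[m, j] += lr * (data[idx, j] - weights[m, j])


@njit(cache=True)
def run_epoch_online(data, weights, rho0, labels, counts, S, R, order,
                    alpha, lr, radius, rows, cols):
    """Online-membership epoch: each pattern's cluster membership moves to
    its winner immediately, so later patterns in the same epoch see it.

    Maintained aggregates (all updated in place):
      labels[l]   current cluster of pattern l
      counts[m]   |Omega_m|
      S[m]        sum of rho over unordered member pairs of Omega_m
      R[l, m]     sum of rho[l, j] over members j of Omega_m
    """
    n, d = data.shape
    k = weights.shape[0]
    qe = 0.0
    for t in range(order.shape[0]):
        idx = order[t]
        best = 0
        best_dist = np.inf
        for m in range(k):
            acc = 0.0
            for j in range(d):
                diff = data[idx, j] - weights[m, j]
                acc += diff * diff
            eps = math.sqrt(acc)
            # biological term from live aggregates
            if labels[idx] == m:
                n_out = counts[m] - 1
                s_out = S[m] - R[idx, m]
                n_in = counts[m]
                s_in = S[m]
            else:
                n_out = counts[m]
                s_out = S[m]
                n_in = counts[m] + 1
                s_in = S[m] + R[idx, m]
            pairs_out = n_out * (n_out - 1) / 2.0
            pairs_in = n_in * (n_in - 1) / 2.0
            pi_out = s_out / pairs_out if pairs_out > 0 else 0.0
            pi_in = s_in / pairs_in if pairs_in > 0 else 0.0
            denom = pi_out if pi_out > pi_in else pi_in
            b = (pi_out - pi_in) / denom if denom > 0 else 0.0
            dist = (1.0 - alpha) * eps + alpha * b
            if dist < best_dist:
                best_dist = dist
                best = m
        br = best // cols
        bc = best % cols
        r0 = br - radius if br - radius > 0 else 0
        r1 = br + radius + 1 if br + radius + 1 < rows else rows
        c0 = bc - radius if bc - radius > 0 else 0
        c1 = bc + radius + 1 if bc + radius + 1 < cols else cols
        for r in range(r0, r1):
            for c in range(c0, c1):
                m = r * cols + c
                for j in range(d):
                    weights[m, j] += lr * (data[idx, j] - weights[m, j])
        # move membership to the winner
        prev = labels[idx]
        if prev != best:
            S[prev] -= R[idx, prev]
            counts[prev] -= 1
            for j in range(n):
                R[j, prev] -= rho0[j, idx]
            S[best] += R[idx, best]
            counts[best] += 1
            for j in range(n):
                R[j, best] += rho0[j, idx]
            labels[idx] = best
        qe += best_dist
    return qe / n


@njit(cache=True)
def assign_all(data, weights, B, alpha):
    """Minimum-combined-distance unit per pattern; ties -> lowest index.

    Returns (labels, quantization error = mean winning distance).
    """
    n, d = data.shape
    k = weights.shape[0]
    labels = np.empty(n, dtype=np.int64)
    qe = 0.0
    for i in range(n):
        best = 0
        best_dist = np.inf
        for m in range(k):
            acc = 0.0
            for j in range(d):
                diff = data[i, j] - weights[m, j]
                acc += diff * diff
            dist = (1.0 - alpha) * math.sqrt(acc) + alpha * B[i, m]
            if dist < best_dist:
                best_dist = dist
                best = m
        labels[i] = best
        qe += best_dist
    return labels, qe / n
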