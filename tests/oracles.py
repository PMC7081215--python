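"""Independent second-route implementations used as test oracles.

These deliberately avoid the numerical strategies of the package code:
no log-space accumulation, direct dense determinants and inverses,
plain Python loops.  They share only the model definition (ridge
constant, prior form) with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

RIDGE = 1e-4  # must equal adipoloc.finemap.LD_RIDGE (part of the model definition)


def naive_enumerate_pips(z, se, signed_r, max_k, prior_p, prior_w):
    """Brute-force configuration posteriors: direct density arithmetic."""
    z = np.asarray(z, dtype=float)
    m = len(z)
    r = np.asarray(signed_r, dtype=float) + RIDGE * np.eye(m)
    s2 = prior_w / np.asarray(se, dtype=float) ** 2
    det_null = np.linalg.det(r)
    quad_null = z @ np.linalg.inv(r) @ z
    weights = {}
    for k in range(max_k + 1):
        for config in itertools.combinations(range(m), k):
            cov = r.copy()
            for i in config:
                cov = cov + s2[i] * np.outer(r[:, i], r[:, i])
            det = np.linalg.det(cov)
            quad = z @ np.linalg.inv(cov) @ z
            # density ratio against the null keeps magnitudes in range
            bf = (det / det_null) ** -0.5 * math.exp(-0.5 * (quad - quad_null))
            weights[config] = prior_p**k * (1 - prior_p) ** (m - k) * bf
    total = sum(weights.values())
    pip = np.zeros(m)
    for config, w in weights.items():
        for i in config:
            pip[i] += w / total
    return pip, {c: w / total for c, w in weights.items()}


def naive_mclpp(g, e, r2):
    """Double sum over all ordered pairs, plain loops."""
    total = 0.0
    for i in range(len(g)):
        for j in range(len(e)):
            total += g[i] * e[j] * r2[i][j]
    return total


def naive_shift_test(pip, positions, intervals, n_perm, max_shift, window, seed):
    """Straightforward re-implementation of the shift permutation test.

    Same RNG contract (one uniform integer offset per permutation from
    numpy's default generator), but overlap testing by per-position
    loops and interval shifts applied to the track rather than the
    positions.
    """

    def covered(pos, ivals):
        return any(s <= pos < e for s, e in ivals)

    def stat(ivals):
        hit = [p for x, p in zip(positions, pip) if covered(x, ivals)]
        return sum(hit) / len(hit) if hit else 0.0

    w0, w1 = window
    span = w1 - w0

    def shifted(ivals, d):
        out = []
        for s, e in ivals:
            s2, e2 = (s - w0 + d) % span, (e - w0 + d) % span
            if s2 < e2 or e2 == 0:
                out.append((w0 + s2, w0 + (e2 if e2 else span)))
            else:  # wraps across the window edge: split in two
                out.append((w0 + s2, w1))
                out.append((w0, w0 + e2))
        return out

    observed = stat(intervals)
    rng = np.random.default_rng(seed)
    offsets = rng.integers(-max_shift, max_shift + 1, size=n_perm)
    null = [stat(shifted(intervals, int(d))) for d in offsets]
    p = (1 + sum(s >= observed - 1e-12 for s in null)) / (1 + n_perm)
    return observed, null, p


def naive_ks_distance(a, b):
    """Sup of |ECDF difference| evaluated at every breakpoint."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        da = np.mean(a <= x)
        db = np.mean(b <= x)
        best = max(best, abs(da - db))
    return best


def greedy_credible_members(pips, level):
    """Accumulate descending normalized pips until the level is reached."""
    order = np.argsort(-np.asarray(pips, dtype=float), kind="stable")
    total = float(np.sum(pips))
    cum, members = 0.0, []
    for i in order:
        members.append(int(i))
        cum += pips[i] / total
        if cum >= level - 1e-12:
            break
    return members, cum
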