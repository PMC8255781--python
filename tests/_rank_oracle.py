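"""Brute-force oracle for the rank-based factorial statistics.

Deliberately naive and loop-based: midranks by counting comparisons,
covariance by explicit sums, contrast matrices written out via explicit
centering/averaging blocks, and the quadratic/trace forms assembled with
plain matrix algebra. Serves as an independent cross-check of
pharmaeeg.longstats on small complete (no missing data) datasets.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, f as f_dist


def oracle_midranks(values):
    values = list(values)
    n = len(values)
    out = np.empty(n)
    for i, v in enumerate(values):
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out[i] = less + (equal + 1) / 2.0
    return out


def _centering(k):
    return np.eye(k) - np.ones((k, k)) / k


def _averaging(k):
    return np.ones((1, k)) / k


def oracle_contrast(effect, n_levels, n_time):
    """Explicit Kronecker contrast for the requested effect."""
    if len(n_levels) == 1:
        a, t = n_levels[0], n_time
        blocks = {
            "group": (_centering(a), _averaging(t)),
            "time": (_averaging(a), _centering(t)),
            "group:time": (_centering(a), _centering(t)),
        }
        left, right = blocks[effect]
        return np.kron(left, right)
    a, b, t = n_levels[0], n_levels[1], n_time
    blocks = {
        "A": (_centering(a), _averaging(b), _averaging(t)),
        "B": (_averaging(a), _centering(b), _averaging(t)),
        "A:B": (_centering(a), _centering(b), _averaging(t)),
        "time": (_averaging(a), _averaging(b), _centering(t)),
        "A:time": (_centering(a), _averaging(b), _centering(t)),
        "B:time": (_averaging(a), _centering(b), _centering(t)),
        "A:B:time": (_centering(a), _centering(b), _centering(t)),
    }
    m1, m2, m3 = blocks[effect]
    return np.kron(np.kron(m1, m2), m3)


def oracle_statistics(groups, effect, n_levels=None):
    """WTS and ATS for complete balanced-by-group data.

    ``groups`` is a list of (n_units, n_time) arrays, ordered as the
    lexicographic whole-plot cells; ``n_levels`` gives the between-factor
    level counts (default: one factor with len(groups) levels).

    Returns dict with wts, wts_df, wts_p, ats, ats_df, ats_p.
    """
    n_levels = n_levels or [len(groups)]
    n_time = groups[0].shape[1]
    all_values = [v for g in groups for v in np.asarray(g).ravel()]
    N = len(all_values)
    ranks = oracle_midranks(all_values)

    # rebuild per-group rank matrices (same flattening order)
    rank_mats = []
    pos = 0
    for g in groups:
        g = np.asarray(g)
        k = g.size
        rank_mats.append(ranks[pos:pos + k].reshape(g.shape) / N)
        pos += k

    phat = []
    for M in rank_mats:
        for j in range(n_time):
            col = M[:, j]
            phat.append(sum(col) / len(col) - 0.5 / N)
    phat = np.array(phat)

    d = len(groups) * n_time
    V = np.zeros((d, d))
    for gi, M in enumerate(rank_mats):
        n_g = M.shape[0]
        S = np.zeros((n_time, n_time))
        means = M.mean(axis=0)
        for s in range(n_time):
            for t in range(n_time):
                acc = 0.0
                for i in range(n_g):
                    acc += (M[i, s] - means[s]) * (M[i, t] - means[t])
                S[s, t] = acc / (n_g - 1)
        V[gi * n_time:(gi + 1) * n_time, gi * n_time:(gi + 1) * n_time] = S / n_g

    C = oracle_contrast(effect, n_levels, n_time)
    Cp = C @ phat
    mid = C @ V @ C.T
    wts = float(Cp @ np.linalg.pinv(mid) @ Cp)
    wts_df = int(np.linalg.matrix_rank(C))
    wts_p = float(chi2.sf(wts, wts_df))

    T = C.T @ np.linalg.pinv(C @ C.T) @ C
    tv = float(np.trace(T @ V))
    ats = float(phat @ T @ phat) / tv
    ats_df = tv ** 2 / float(np.trace(T @ V @ T @ V))
    if "time" in effect:
        # within-unit effect: chi2(f)/f reference
        ats_p = float(chi2.sf(ats * ats_df, ats_df))
    else:
        # between-unit effect: Box-modified F(f, f0), denominator df from
        # the per-group diagonal blocks of T V
        TV = T @ V
        denom = 0.0
        for gi, M in enumerate(rank_mats):
            block = TV[gi * n_time:(gi + 1) * n_time,
                       gi * n_time:(gi + 1) * n_time]
            denom += float(np.trace(block)) ** 2 / (M.shape[0] - 1)
        f0 = tv ** 2 / denom
        ats_p = float(f_dist.sf(ats, ats_df, f0))
    return {"wts": wts, "wts_df": wts_df, "wts_p": wts_p,
            "ats": ats, "ats_df": ats_df, "ats_p": ats_p,
            "phat": phat, "V": V}
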