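"""Independent brute-force oracles used only by the test suite.

These are deliberately naive implementations: an event-driven structured
coalescent for two demes (the ms-style reference for the simulator), and
quadratic-time recounts of summary statistics. They share no code with
the package paths they check.
"""

from __future__ import annotations

import numpy as np


def structured_coalescent_classes(n1: int, n2: int, theta1: float, theta2: float,
                                  theta_anc: float, t_split: float,
                                  m12: float, m21: float, theta_locus: float,
                                  rng: np.random.Generator) -> tuple[int, int, int, int]:
    """One replicate of a two-deme coalescent; Wakeley–Hey class counts.

    Times in units of 4*Nref generations; coalescence rate per lineage
    pair in deme i is 2/theta_i (theta_i the size ratio); backward
    migration of a lineage out of deme i is the 4Nm rate of the incoming
    forward direction. ``theta_locus`` is the per-locus scaled mutation
    rate (theta_ref * L * ratio handled by the caller as a plain number:
    expected mutations on a branch of length tau are tau * theta_locus).

    Returns (Sf, Sx1, Sx2, Ss) for one locus.
    """
    # lineages: list of (deme, frozenset of sample ids); samples 0..2n1-1
    # are species 1, the rest species 2
    lineages = [(0, frozenset([i])) for i in range(2 * n1)]
    lineages += [(1, frozenset([2 * n1 + i])) for i in range(2 * n2)]
    edges: list[tuple[frozenset, float]] = []  # (leaf set, branch duration)
    starts = [0.0] * len(lineages)  # per-lineage birth time
    t = 0.0
    merged = False
    while len(lineages) > 1:
        k0 = sum(1 for d, _ in lineages if d == 0)
        k1 = sum(1 for d, _ in lineages if d == 1)
        if not merged:
            rate_c0 = k0 * (k0 - 1) / 2 * 2.0 / theta1
            rate_c1 = k1 * (k1 - 1) / 2 * 2.0 / theta2
            # forward migration 1->2 moves lineages backward from deme 2 to 1
            rate_m_from1 = k0 * m21
            rate_m_from2 = k1 * m12
            total = rate_c0 + rate_c1 + rate_m_from1 + rate_m_from2
            wait = np.inf if total == 0 else rng.exponential(1.0 / total)
            if t + wait >= t_split:
                # merge: everything enters the ancestral deme
                for i, (d, s) in enumerate(lineages):
                    lineages[i] = (2, s)
                t = t_split
                merged = True
                continue
            t += wait
            u = rng.uniform(0, total)
            if u < rate_c0:
                pool = [i for i, (d, _) in enumerate(lineages) if d == 0]
            elif u < rate_c0 + rate_c1:
                pool = [i for i, (d, _) in enumerate(lineages) if d == 1]
            elif u < rate_c0 + rate_c1 + rate_m_from1:
                i = rng.choice([i for i, (d, _) in enumerate(lineages) if d == 0])
                lineages[i] = (1, lineages[i][1])
                continue
            else:
                i = rng.choice([i for i, (d, _) in enumerate(lineages) if d == 1])
                lineages[i] = (0, lineages[i][1])
                continue
        else:
            k = len(lineages)
            total = k * (k - 1) / 2 * 2.0 / theta_anc
            t += rng.exponential(1.0 / total)
            pool = list(range(len(lineages)))
        a, b = rng.choice(pool, size=2, replace=False)
        a, b = (a, b) if a < b else (b, a)
        da, sa = lineages[a]
        db, sb = lineages[b]
        edges.append((sa, t - starts[a]))
        edges.append((sb, t - starts[b]))
        lineages[b] = lineages[-1]
        starts[b] = starts[-1]
        lineages[a] = (da, sa | sb)
        starts[a] = t
        lineages.pop()
        starts.pop()
    sf = sx1 = sx2 = ss = 0
    for leafset, dur in edges:
        n_mut = rng.poisson(dur * theta_locus)
        if n_mut == 0:
            continue
        i = sum(1 for x in leafset if x < 2 * n1)
        j = len(leafset) - i
        if (i == 0 and j == 0) or (i == 2 * n1 and j == 2 * n2):
            continue
        poly1 = 0 < i < 2 * n1
        poly2 = 0 < j < 2 * n2
        if poly1 and poly2:
            ss += n_mut
        elif poly1:
            sx1 += n_mut
        elif poly2:
            sx2 += n_mut
        else:
            sf += n_mut
    return sf, sx1, sx2, ss


def brute_rejection(stats: np.ndarray, observed: np.ndarray, scale: np.ndarray,
                    n_retain: int) -> tuple[np.ndarray, np.ndarray]:
    """Plain re-implementation of MAD-standardized nearest-row retention."""
    X = stats / scale
    y = observed / scale
    d = np.sqrt(((X - y) ** 2).sum(axis=1))
    idx = np.argsort(d, kind="stable")[:n_retain]
    return idx, d[idx]
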