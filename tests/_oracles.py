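"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (pure-Python BFS, exhaustive scans,
closed forms) that share no code with the package's production paths.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def brute_force_patches(
    positions: np.ndarray, areas: np.ndarray, labels: np.ndarray, link_distance: float
) -> list[tuple[int, frozenset[int]]]:
    """Connected same-label components by exhaustive pairwise adjacency +
    BFS.  Returns a list of (label, frozenset of dot indices)."""
    n = len(positions)
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
    adj = (d2 <= link_distance**2) & (labels[:, None] == labels[None, :])
    np.fill_diagonal(adj, False)
    seen = np.zeros(n, dtype=bool)
    out = []
    for start in range(n):
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            i = q.popleft()
            comp.append(i)
            for j in np.flatnonzero(adj[i]):
                if not seen[j]:
                    seen[j] = True
                    q.append(j)
        out.append((int(labels[start]), frozenset(comp)))
    return out


def brute_force_threshold(data: list[tuple[float, str]]) -> tuple[float, float]:
    """Exhaustive scan over all midpoints (plus sentinels) maximising
    balanced accuracy; ties to the smallest threshold."""
    sizes = sorted({x for x, _ in data})
    cands = [sizes[0] - 1.0]
    cands += [(a + b) / 2 for a, b in zip(sizes, sizes[1:])]
    cands += [sizes[-1] + 1.0]
    best = None
    for t in cands:
        tp = sum(1 for x, lab in data if lab == "insoluble" and x > t)
        fn = sum(1 for x, lab in data if lab == "insoluble" and x <= t)
        tn = sum(1 for x, lab in data if lab == "soluble" and x <= t)
        fp = sum(1 for x, lab in data if lab == "soluble" and x > t)
        acc = 0.5 * (tp / max(1, tp + fn) + tn / max(1, tn + fp))
        if best is None or acc > best[1] + 1e-12:
            best = (t, acc)
    return best


def two_sphere_sasa(r: float, probe: float, d: float) -> float:
    """Closed-form solvent-accessible area of two equal spheres."""
    R = r + probe
    if d >= 2 * R:
        return 2 * 4 * math.pi * R**2
    h = R - d / 2
    return 2 * (4 * math.pi * R**2 - 2 * math.pi * R * h)


def four_state_partition(pka1, pka2, w, pH, RT):
    """Hand-written 2-acid coupled partition function.

    Site charges: deprotonated -1, protonated 0; w is the unit-charge pair
    energy.  Returns (f1, f2, G).
    """
    ln10 = math.log(10.0)
    # states: (x1, x2) in {0,1}^2
    states = [(0, 0), (0, 1), (1, 0), (1, 1)]
    weights = []
    for x1, x2 in states:
        e = x1 * ln10 * RT * (pH - pka1) + x2 * ln10 * RT * (pH - pka2)
        e += w * (x1 - 1) * (x2 - 1)
        weights.append(math.exp(-e / RT))
    z = sum(weights)
    f1 = sum(wt for (x1, _), wt in zip(states, weights) if x1) / z
    f2 = sum(wt for (_, x2), wt in zip(states, weights) if x2) / z
    return f1, f2, -RT * math.log(z)
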