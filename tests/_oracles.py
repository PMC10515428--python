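"""Independent oracles used by the test suite.

Deliberately brute-force and separate from the implementation path:
flood-fill component labeling, root-finding/trapezoid TT/AOT references,
and a hand-written pooled-variance t-test.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.optimize import brentq

from barriermap.kinetics import KineticParams, eval_model


def flood_fill_components(mask: np.ndarray, connectivity: int = 6) -> list[set]:
    """Exhaustive BFS labeling of True voxels; returns a list of voxel sets."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for off in offsets:
                w = tuple(v[i] + off[i] for i in range(3))
                if any(c < 0 or c >= mask.shape[i] for i, c in enumerate(w)):
                    continue
                if mask[w] and not seen[w]:
                    seen[w] = True
                    q.append(w)
        comps.append(comp)
    return comps


def tt_root_finding(params: KineticParams, window, threshold=0.05, n_scan=20001):
    """TT by locating threshold crossings with brentq on a fine scan."""
    level = 1.0 + threshold

    def g(t):
        return eval_model(params, t) - level

    ts = np.linspace(window[0], window[1], n_scan)
    vals = np.array([g(t) for t in ts])
    crossings = [window[0]] if vals[0] >= 0 else []
    roots = []
    for i in range(len(ts) - 1):
        if vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, ts[i], ts[i + 1]))
    # walk intervals where the curve is above the level
    pts = sorted(set([window[0], window[1]] + roots))
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        mid = 0.5 * (a + b)
        if g(mid) >= 0:
            total += b - a
    return total


def aot_fine_trapezoid(params: KineticParams, window, threshold=0.05, n=200001):
    """AOT by trapezoid quadrature on a much finer grid."""
    ts = np.linspace(window[0], window[1], n)
    f = eval_model(params, ts)
    return float(np.trapezoid(np.clip(f - (1.0 + threshold), 0.0, None), ts))


def pooled_t_test(a, b):
    """Two-sided Student's t from the textbook pooled-variance formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p
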