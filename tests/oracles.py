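"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written with plain Python loops and no scipy/heapq so that the
checked code paths share nothing with these reference computations.
"""

from __future__ import annotations

import numpy as np

OFFS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
OFFS4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def flood_label(mask, connectivity=8):
    """Connected-component labeling by explicit stack-based flood fill."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    offs = OFFS8 if connectivity == 8 else OFFS4
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                labels[r0, c0] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr, dc in offs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = nxt
                            stack.append((rr, cc))
    return labels, nxt


def bellman_ford_costs(cost, blob, seed):
    """Geodesic cost from one seed by repeated full-grid relaxation."""
    h, w = blob.shape
    dist = {(r, c): float("inf") for r in range(h) for c in range(w) if blob[r, c]}
    dist[seed] = 0.0
    changed = True
    while changed:
        changed = False
        for (r, c), d in list(dist.items()):
            for dr, dc in OFFS8:
                rr, cc = r + dr, c + dc
                if (rr, cc) in dist:
                    nd = d + cost[rr, cc]
                    if nd < dist[(rr, cc)] - 1e-12:
                        dist[(rr, cc)] = nd
                        changed = True
    return dist


def watershed_ridge_oracle(s_ear, points, connectivity=8, topography_weight=1.0):
    """Ridge set by per-seed Bellman-Ford plus the basin-interface rule:
    at each cross-basin adjacency, the pixel with the smaller best/second-
    best cost margin joins the ridge (both on a tie); seeds never do."""
    s_ear = np.asarray(s_ear, dtype=float)
    fg = s_ear > 0.5
    cost = 1.0 + topography_weight * (1.0 - s_ear)
    labels, n = flood_label(fg, connectivity)
    ridge = np.zeros_like(fg)
    h, w = fg.shape
    for lab in range(1, n + 1):
        blob = labels == lab
        seeds = [tuple(p) for p in points if blob[tuple(p)]]
        if len(seeds) < 2:
            continue
        dists = [bellman_ford_costs(cost, blob, s) for s in seeds]

        def basin(cell):
            vals = [d[cell] for d in dists]
            return min(range(len(vals)), key=lambda k: (vals[k], k))

        def margin(cell):
            vals = sorted(d[cell] for d in dists)
            return vals[1] - vals[0]

        for r in range(h):
            for c in range(w):
                if not blob[r, c] or (r, c) in seeds:
                    continue
                for dr, dc in OFFS8:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and blob[rr, cc]:
                        if basin((rr, cc)) != basin((r, c)) and margin(
                            (r, c)
                        ) <= margin((rr, cc)) + 1e-9:
                            ridge[r, c] = True
    return ridge
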