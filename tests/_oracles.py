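"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: pure-Python pixel walking, explicit
set arithmetic, closed-form statistics — no shared code paths with the
package under test.
"""

import math

import numpy as np

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
            (0, 1), (1, -1), (1, 0), (1, 1)]


def _components(pixels: set) -> list[set]:
    """8-connected components of a pixel set, by explicit BFS."""
    remaining = set(pixels)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp, frontier = {seed}, [seed]
        while frontier:
            r, c = frontier.pop()
            for dr, dc in _OFFSETS:
                q = (r + dr, c + dc)
                if q in remaining:
                    remaining.discard(q)
                    comp.add(q)
                    frontier.append(q)
        comps.append(comp)
    return comps


def _walk_length(comp: set) -> float:
    """Geodesic length of a degree-≤2 pixel component by explicit walking.

    Paths are walked terminal-to-terminal accumulating 1/√2 steps; pure
    cycles report the total weight of their (unique) edges; a lone pixel
    has length 0.
    """
    if len(comp) == 1:
        return 0.0

    def nbrs(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in _OFFSETS
                if (p[0] + dr, p[1] + dc) in comp]

    terminals = [p for p in comp if len(nbrs(p)) <= 1]
    if not terminals:  # cycle: each unordered adjacent pair once
        total = 0.0
        for p in comp:
            for q in nbrs(p):
                if q > p:
                    total += math.hypot(q[0] - p[0], q[1] - p[1])
        return total
    pos, prev = terminals[0], None
    length = 0.0
    while True:
        nxt = [q for q in nbrs(pos) if q != prev]
        if not nxt:
            return length
        step = nxt[0]
        length += math.hypot(step[0] - pos[0], step[1] - pos[1])
        prev, pos = pos, step


def skeleton_summary_oracle(skel: np.ndarray) -> dict:
    """Exhaustive enumeration of branch statistics on a skeleton image.

    Same pixel-level definitions as the implementation (junction = ≥3
    skeleton neighbours, branches = components of the non-junction
    pixels), evaluated with set arithmetic and explicit walks.
    """
    pix = set(map(tuple, np.argwhere(np.asarray(skel, dtype=bool))))

    def degree(p):
        return sum(((p[0] + dr, p[1] + dc) in pix) for dr, dc in _OFFSETS)

    junctions = {p for p in pix if degree(p) >= 3}
    endpoints = {p for p in pix if degree(p) <= 1}
    branch_comps = _components(pix - junctions)
    skel_comps = _components(pix)

    per_comp = []
    for comp in skel_comps:
        per_comp.append(sum(1 for b in branch_comps if b <= comp))
    networks = [n for n in per_comp if n > 1]
    lengths = [_walk_length(b) for b in branch_comps]
    return {
        "n_individuals": sum(1 for n in per_comp if n <= 1),
        "n_networks": len(networks),
        "branches_per_network": (sum(networks) / len(networks)
                                 if networks else 0.0),
        "mean_branch_length": (sum(lengths) / len(lengths)
                               if lengths else 0.0),
        "n_branches": len(branch_comps),
        "n_junctions": len(_components(junctions)),
        "n_endpoints": len(endpoints),
    }


def draw_tube(shape, start, end, radius):
    """Digital straight tube: pixels within ``radius`` of the segment."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    p = np.array(start, dtype=float)
    q = np.array(end, dtype=float)
    d = q - p
    t = ((rr - p[0]) * d[0] + (cc - p[1]) * d[1]) / (d @ d)
    t = np.clip(t, 0.0, 1.0)
    dist = np.hypot(rr - (p[0] + t * d[0]), cc - (p[1] + t * d[1]))
    return dist <= radius


def bh_stepup_oracle(pvals, alpha=0.05):
    """Benjamini–Hochberg step-up by literal definition.

    Rejects hypotheses 1..k where k = max{i : p_(i) ≤ i·α/m}; also
    returns the adjusted q-values q_(i) = min_{j≥i} m·p_(j)/j.
    """
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k = rank
    reject = [False] * m
    for idx in order[:k]:
        reject[idx] = True
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return reject, q


def pearson_oracle(x, y):
    """Sample Pearson correlation from the covariance definition."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)
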