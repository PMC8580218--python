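"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: flow tracing is a
per-cell while loop over explicit neighbour comparisons, and over-water
distance is a queue-based breadth-first search.
"""

import collections
import math

# same physical convention as the package documents (E,SE,S,SW,W,NW,N,NE)
NEIGHBOURS = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


def trace_terminal(dem, land, start):
    """Follow steepest descent over land from ``start`` to its terminal cell."""
    r, c = start
    rows, cols = dem.shape
    while True:
        best_drop = 0.0
        best = None
        for dr, dc in NEIGHBOURS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols):
                continue
            if not land[nr, nc]:
                continue
            weight = math.sqrt(2.0) if (dr != 0 and dc != 0) else 1.0
            drop = (dem[r, c] - dem[nr, nc]) / weight
            if drop > best_drop:
                best_drop = drop
                best = (nr, nc)
        if best is None:
            return (r, c)
        r, c = best


def brute_force_basins(dem, land):
    """Map terminal cell -> set of member cells, by tracing every land cell."""
    basins = {}
    rows, cols = dem.shape
    for r in range(rows):
        for c in range(cols):
            if land[r, c]:
                term = trace_terminal(dem, land, (r, c))
                basins.setdefault(term, set()).add((r, c))
    return basins


def is_coastal(land, cell):
    r, c = cell
    rows, cols = land.shape
    for dr, dc in NEIGHBOURS:
        nr, nc = r + dr, c + dc
        if not (0 <= nr < rows and 0 <= nc < cols) or not land[nr, nc]:
            return True
    return False


def bfs_distance(ocean, source):
    """Queue-based BFS over 8-connected ocean cells; dict cell -> steps."""
    rows, cols = ocean.shape
    dist = {tuple(source): 0}
    queue = collections.deque([tuple(source)])
    while queue:
        r, c = queue.popleft()
        for dr, dc in NEIGHBOURS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and ocean[nr, nc] and (nr, nc) not in dist:
                dist[(nr, nc)] = dist[(r, c)] + 1
                queue.append((nr, nc))
    return dist
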