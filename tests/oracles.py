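"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: connected
components by breadth-first flood fill over explicit neighbor offsets, and
exceedance probabilities by Monte-Carlo sampling.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offsets = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offsets.append(d)
    return offsets


def bfs_flood_fill(mask: np.ndarray, seed: tuple[int, int, int], connectivity: int) -> set:
    """All voxels of the True-component of ``mask`` containing ``seed``."""
    if not mask[seed]:
        return set()
    offsets = neighbor_offsets(connectivity)
    shape = mask.shape
    visited = {seed}
    queue = deque([seed])
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in offsets:
            n = (x + dx, y + dy, z + dz)
            if any(c < 0 or c >= s for c, s in zip(n, shape)):
                continue
            if n in visited or not mask[n]:
                continue
            visited.add(n)
            queue.append(n)
    return visited


def mc_normal_cdf(mean: float, sd: float, x: float, n_draws: int, seed: int) -> float:
    """Monte-Carlo estimate of P(N(mean, sd) < x)."""
    rng = np.random.default_rng(seed)
    return float(np.mean(rng.normal(mean, sd, size=n_draws) < x))
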